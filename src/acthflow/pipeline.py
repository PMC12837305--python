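"""End-to-end orchestration: simulate -> screen -> describe -> reflimits -> model.

One config (YAML/JSON-style mapping, sections per stage) drives the run; a
single global seed expands to per-stage seeds through a documented counter
scheme (SeedSequence([seed, stage_index])), so any stage can be re-run in
isolation.  Every run writes its tables as CSV with stable column order,
plus the resolved config and a manifest with versions and seeds.  A stage
error aborts the run with the stage named and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calendar import PERIOD_EARLY, PERIOD_MID
from .cohort import CohortTable, load_cohort, write_cohort
from .descriptives import cohort_composition, event_marginal_means, summarize_events
from .mixedmodel import emm_pairwise, fit_period_model, univariable_screen
from .reflimits import MIN_GROUP_N, estimate_group_urls
from .screening import screen_cohort
from .simulate import SyntheticConfig, generate_cohort, truth_table

log = logging.getLogger("acthflow")

_STAGES = ("simulate", "screen", "describe", "reflimits", "model")

_DEFAULTS = {
    "seed": 0,
    "outdir": "results",
    "input": None,                  # cohort CSV; None -> simulate
    "simulate": {},                 # SyntheticConfig overrides
    "screen": {"q": 0.01, "rule": "per-period"},
    "describe": {},
    "reflimits": {"groups": None, "coverage": 0.95, "min_n": MIN_GROUP_N, "B": 2000},
    "model": {"periods": [PERIOD_MID, PERIOD_EARLY]},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from the global one (counter scheme, < 2^31)."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve a pipeline config; unknown keys are rejected."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update(overrides)
    cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
    for key, val in raw.items():
        if key not in _DEFAULTS:
            raise PipelineError("config", f"unknown config key {key!r}")
        if isinstance(_DEFAULTS[key], dict):
            unknown = (set(val) - set(_DEFAULTS[key])
                       if key != "simulate" else
                       set(val) - {f.name for f in dataclasses.fields(SyntheticConfig)})
            if unknown:
                raise PipelineError("config", f"unknown keys in {key!r}: {sorted(unknown)}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict | str | Path | None = None, outdir=None) -> dict:
    """Run the full analysis; returns a manifest of the artefacts written."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(outdir or config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    seed = int(config["seed"])

    def emit(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    try:
        # -- simulate / load --------------------------------------------------
        stage = "simulate"
        if config["input"] is not None:
            if not Path(config["input"]).exists():
                raise PipelineError(stage, f"input file not found: {config['input']}")
            cohort = load_cohort(config["input"])
        else:
            sim_kwargs = dict(config["simulate"])
            sim_kwargs.setdefault("seed", stage_seed(seed, "simulate"))
            scfg = SyntheticConfig(**sim_kwargs)
            cohort = generate_cohort(scfg)
            emit(truth_table(scfg), "truth.csv")
            write_cohort(cohort, out / "cohort.csv")
            written.append(out / "cohort.csv")
        log.info("stage simulate: cohort of %d animals, %d records",
                 len(cohort.animals), len(cohort))

        # -- screen ------------------------------------------------------------
        stage = "screen"
        outcome, analyzable = screen_cohort(cohort, q=config["screen"]["q"],
                                            rule=config["screen"]["rule"])
        emit(outcome.exclusion_report, "exclusions.csv")
        write_cohort(analyzable, out / "screened.csv")
        written.append(out / "screened.csv")
        log.info("stage screen: removed %d of %d animals",
                 len(outcome.exclusion_report), len(cohort.animals))

        # -- describe ----------------------------------------------------------
        stage = "describe"
        emit(summarize_events(analyzable), "table2.csv")
        emit(cohort_composition(cohort, analyzable), "table1.csv")
        emit(event_marginal_means(analyzable), "fig1_data.csv")

        # -- reference limits --------------------------------------------------
        stage = "reflimits"
        rcfg = config["reflimits"]
        groups = rcfg["groups"]
        sizes = analyzable.animals["equid_type"].value_counts()
        if groups is None:
            groups = [g for g, n in sizes.items() if n >= rcfg["min_n"]]
            log.info("stage reflimits: groups with >= %d animals: %s",
                     rcfg["min_n"], groups)
        for g in groups:
            urls = estimate_group_urls(analyzable, g, coverage=rcfg["coverage"],
                                       min_n=rcfg["min_n"], B=rcfg["B"],
                                       seed=stage_seed(seed, "reflimits"))
            emit(urls, f"fig2_data_{g}.csv")

        # -- mixed models ------------------------------------------------------
        stage = "model"
        for period in config["model"]["periods"]:
            screen_res = univariable_screen(analyzable, period)
            if "equid_type" in screen_res["retained"]:
                summary = screen_res["fits"]["equid_type"]
                emms, contrasts = emm_pairwise(summary)
                fe = summary.fixed_effects.copy()
                for nm, v in summary.variance_components.items():
                    fe[f"var_{nm}"] = v
                fe["df_method"] = summary.df_method
                emit(fe, f"table3_{period}.csv")
                emit(pd.DataFrame([emms]), f"emms_{period}.csv")
                emit(contrasts, f"contrasts_{period}.csv")
            else:
                emit(pd.DataFrame({"retained": screen_res["retained"]}),
                     f"table3_{period}.csv")
            log.info("stage model (%s): retained %s", period, screen_res["retained"])
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "acthflow_version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in _STAGES},
        "config": config,
        "outputs": [p.name for p in written],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    return manifest
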