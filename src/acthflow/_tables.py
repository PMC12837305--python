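"""Published summary surfaces of the donkey/hybrid seasonal ACTH cohort study.

These printed tables are the *inputs* that parameterize the synthetic cohort
generator and the bookkeeping checks: per-event descriptive statistics of
ACTH (pg/mL) for the analyzed animals, the enrolled/analyzed cohort
composition, and the ln-scale variance components of the period-split mixed
models.  Nothing here is a fitted result of this package.
"""

from __future__ import annotations

import math

STANDARD = "standard"
MINIATURE = "miniature"
HYBRID = "hybrid"
EQUID_TYPES = (STANDARD, MINIATURE, HYBRID)

#: Analyzed group sizes after outlier / insufficient-data exclusion.
ANALYZED_GROUP_SIZES = {STANDARD: 19, MINIATURE: 14, HYBRID: 28}

# Per-event descriptive statistics for the analyzed animals.
# Columns: mean, sd, median, min, q1, q3, max, n.  None = no data.
_COLS = ("mean", "sd", "median", "min", "q1", "q3", "max", "n")

_EVENT_STATS_RAW = {
    STANDARD: {
        "December_1-31": (16.2, 7.1, 13.6, 8.5, 12.3, 18.5, 37.7, 19),
        "January_1-31": (14.3, 3.4, 13.8, 8.9, 11.9, 15.8, 22.5, 19),
        "February_1-29": (12.6, 4.3, 11.2, 7.2, 10.7, 14.1, 24.2, 16),
        "March_1-31": (12.5, 3.5, 12.7, 4.6, 11.0, 14.8, 18.9, 19),
        "April_1-30": (14.5, 3.4, 14.1, 8.0, 11.6, 17.5, 19.8, 19),
        "May_1-31": (18.7, 6.1, 17.7, 7.6, 15.8, 23.8, 27.5, 19),
        "June_1-15": (18.9, 4.0, 19.1, 13.1, 15.5, 22.2, 25.4, 14),
        "June_16-30": (29.5, 11.6, 28.9, 15.2, 19.4, 37.0, 56.0, 19),
        "July_1-15": (38.0, 15.3, 33.8, 14.0, 28.6, 50.6, 78.0, 19),
        "July_16-31": (44.6, 16.8, 41.8, 5.3, 36.4, 53.5, 73.3, 19),
        "August_1-15": (52.8, 18.2, 46.7, 24.0, 44.0, 64.2, 90.1, 19),
        "August_16-31": (89.6, 39.5, 81.1, 47.9, 63.0, 112.5, 207.0, 19),
        "September_1-15": (86.2, 31.0, 75.6, 38.7, 65.8, 101.1, 144.0, 19),
        "September_16-30": (109.6, 52.6, 94.4, 41.7, 68.4, 139.5, 227.0, 19),
        "October_1-15": (98.4, 40.0, 95.6, 39.7, 64.6, 119.0, 179.0, 19),
        "October_16-31": (70.6, 45.3, 52.0, 16.9, 38.0, 91.2, 162.0, 19),
        "November_1-15": (53.0, 33.4, 43.6, 18.5, 34.3, 62.6, 142.0, 19),
        "November_16-30": (24.5, 7.2, 24.5, 12.4, 18.7, 28.7, 39.2, 19),
    },
    MINIATURE: {
        "December_1-31": (14.5, 5.4, 13.8, 6.1, 11.5, 15.8, 26.9, 14),
        "January_1-31": (11.6, 3.3, 11.8, 5.0, 10.1, 14.1, 16.0, 14),
        "February_1-29": (14.6, 14.1, 10.8, 4.0, 8.7, 13.6, 61.2, 14),
        "March_1-31": (10.9, 3.6, 11.1, 5.0, 8.6, 13.2, 16.8, 14),
        "April_1-30": (12.7, 3.3, 12.5, 6.6, 10.9, 14.8, 18.5, 14),
        "May_1-31": (19.7, 8.0, 19.4, 9.4, 14.8, 21.9, 42.8, 14),
        "June_1-15": (17.2, 4.2, 16.0, 12.5, 14.0, 20.6, 24.1, 13),
        "June_16-30": (34.5, 14.3, 32.2, 18.3, 28.4, 36.1, 79.2, 14),
        "July_1-15": (47.4, 10.8, 46.5, 29.9, 41.1, 54.5, 67.7, 14),
        "July_16-31": (51.4, 14.6, 48.5, 30.1, 42.4, 63.8, 78.7, 14),
        "August_1-15": (82.8, 36.6, 77.8, 27.0, 59.5, 96.1, 182.0, 14),
        "August_16-31": (87.2, 29.4, 83.8, 51.4, 62.2, 103.4, 144.0, 14),
        "September_1-15": (124.2, 56.7, 119.5, 55.7, 90.3, 143.0, 287.0, 14),
        "September_16-30": (134.6, 67.4, 116.5, 80.7, 88.6, 140.5, 318.0, 14),
        "October_1-15": (125.6, 41.2, 114.5, 77.2, 93.0, 145.8, 207.0, 14),
        "October_16-31": (95.3, 54.0, 80.7, 51.1, 64.9, 99.2, 263.0, 14),
        "November_1-15": (48.7, 25.8, 36.0, 19.8, 29.6, 64.6, 91.8, 14),
        "November_16-30": (28.9, 15.6, 25.0, 15.7, 20.1, 32.4, 77.1, 14),
    },
    HYBRID: {
        "December_1-31": (24.5, 15.7, 17.9, 6.4, 14.0, 35.3, 71.9, 28),
        "January_1-31": (20.5, 16.4, 15.5, 9.1, 13.1, 19.5, 87.7, 28),
        "February_1-29": (11.7, 4.1, 11.1, 5.2, 9.0, 14.5, 21.0, 28),
        "March_1-31": (70.4, 239.7, 13.4, 7.6, 12.5, 16.8, 1250.0, 28),
        "April_1-30": (9.7, 7.1, 7.3, 2.0, 5.8, 12.1, 37.9, 27),
        "May_1-31": (14.4, 2.5, 14.4, 12.6, 13.5, 15.2, 16.1, 2),
        "June_1-15": None,  # no data collected
        "June_16-30": (14.5, 8.8, 12.4, 6.2, 9.0, 16.3, 47.9, 28),
        "July_1-15": (24.0, 18.7, 16.0, 4.2, 12.4, 24.3, 69.6, 28),
        "July_16-31": (18.6, 6.1, 18.8, 7.4, 13.9, 23.8, 28.8, 28),
        "August_1-15": (23.6, 18.7, 19.0, 2.2, 14.5, 25.4, 102.0, 28),
        "August_16-31": (76.5, 97.5, 54.6, 23.0, 35.4, 79.1, 553.0, 28),
        "September_1-15": (94.6, 169.2, 58.0, 28.3, 36.8, 90.9, 946.0, 28),
        "September_16-30": (100.8, 189.6, 53.2, 35.1, 45.7, 82.3, 1054.0, 28),
        "October_1-15": (82.0, 54.2, 66.4, 31.0, 47.9, 91.5, 290.0, 28),
        "October_16-31": (63.4, 33.1, 50.8, 17.7, 43.1, 82.1, 145.0, 28),
        "November_1-15": (23.6, 1.6, 23.6, 22.5, 23.0, 24.1, 24.7, 2),
        "November_16-30": (21.7, 12.6, 17.9, 6.6, 14.5, 25.0, 61.1, 28),
    },
}

EVENT_STATS = {
    etype: {
        label: (dict(zip(_COLS, row)) if row is not None else None)
        for label, row in by_event.items()
    }
    for etype, by_event in _EVENT_STATS_RAW.items()
}


def published_event_stat(equid_type: str, label: str, stat: str):
    """Return one published per-event statistic, or None where no data exist."""
    row = EVENT_STATS[equid_type][label]
    return None if row is None else row[stat]


def default_ln_profile() -> dict:
    """ln-scale seasonal location profile per (equid_type, event label).

    The median of a lognormal variable is exp of its ln-scale location, so the
    published per-event medians are the direct estimates of the ln-ACTH
    seasonal profile.  The single event with no published data (hybrids,
    June_1-15) is filled by geometric interpolation between its calendar
    neighbours (May_1-31 and June_16-30 medians).
    """
    prof = {}
    for etype, by_event in EVENT_STATS.items():
        for label, row in by_event.items():
            if row is not None:
                prof[(etype, label)] = math.log(row["median"])
    gap = (HYBRID, "June_1-15")
    left = EVENT_STATS[HYBRID]["May_1-31"]["median"]
    right = EVENT_STATS[HYBRID]["June_16-30"]["median"]
    prof[gap] = 0.5 * (math.log(left) + math.log(right))
    return prof


# Cohort composition (enrolled vs analyzed), counts by type x variable level.
COMPOSITION = {
    STANDARD: {
        "enrolled": {
            "total": 21,
            "location": {"CA": 9, "MA": 5, "NY": 7},
            "sex": {"female": 14, "male": 7},
            "age_class": {"young": 18, "senior": 3},
        },
        "analyzed": {
            "total": 19,
            "location": {"CA": 8, "MA": 5, "NY": 6},
            "sex": {"female": 13, "male": 6},
            "age_class": {"young": 16, "senior": 3},
        },
    },
    MINIATURE: {
        "enrolled": {
            "total": 18,
            "location": {"CA": 17, "MA": 1},
            "sex": {"female": 12, "male": 6},
            "age_class": {"young": 17, "senior": 1},
        },
        "analyzed": {
            "total": 14,
            "location": {"CA": 13, "MA": 1},
            "sex": {"female": 9, "male": 5},
            "age_class": {"young": 13, "senior": 1},
        },
    },
    HYBRID: {
        "enrolled": {
            "total": 32,
            "location": {"TX": 29, "NY": 3},
            "sex": {"female": 18, "male": 14},
            "age_class": {"young": 17, "senior": 15},
        },
        "analyzed": {
            "total": 28,
            "location": {"TX": 26, "NY": 2},
            "sex": {"female": 16, "male": 12},
            "age_class": {"young": 17, "senior": 11},
        },
    },
}

# ln-scale variance components of the period-split mixed models
# (SDs; the animal-ID variance 0.10 corresponds to SD 0.32 in both periods).
VARIANCE_COMPONENTS = {
    "mid_aug_late_oct": {"sd_id": 0.32, "sd_month": 0.13, "sd_location": 2e-5, "sd_resid": 0.42},
    "early_nov_early_aug": {"sd_id": 0.32, "sd_month": 0.41, "sd_location": 2e-5, "sd_resid": 0.53},
}
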