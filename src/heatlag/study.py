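"""Published reference numbers for the Cyprus 2004-2010 cardiovascular
mortality study region.

These are the printed registry and meteorological summaries the synthetic
generator is calibrated to; the raw registry and station data themselves are
not publicly deposited, so they enter only as study-scale targets and worked
examples, never as fitted data.
"""

from __future__ import annotations

STUDY_DAYS = 2557  # 1/1/2004 .. 31/12/2010 inclusive (two leap days)

# Total circulatory-system deaths over the study period and the per-ICD-10
# category breakdown, as printed.  Note: the printed percentage share for
# I26-I51 (30.1%) is arithmetically inconsistent with its own count
# (4595/13889 = 33.1%); the counts are authoritative.
TOTAL_DEATHS = 13_889
CATEGORY_COUNTS = {
    "I10-I13": 1220,  # hypertensive diseases
    "I20-I25": 4773,  # ischaemic heart diseases
    "I26-I51": 4595,  # other heart diseases
    "I60-I69": 2893,  # cerebrovascular diseases
    "I71-I99": 408,   # remainder of circulatory-system diseases
}
PRINTED_SHARES_PCT = {
    "I10-I13": 8.8,
    "I20-I25": 34.4,
    "I26-I51": 30.1,  # inconsistent with the count; see module docstring
    "I60-I69": 20.8,
    "I71-I99": 2.9,
}
CATEGORIES = tuple(CATEGORY_COUNTS)

#: Reference (median), upper percentiles and maximum of each population-
#: weighted daily temperature series (deg C), as printed.
TEMPERATURE_TABLE = {
    "mean": {"reference": 20.0, "p90": 28.4, "p95": 29.4, "p99": 31.2, "upper_limit": 33.6},
    "max": {"reference": 25.9, "p90": 34.6, "p95": 35.6, "p99": 37.4, "upper_limit": 39.9},
    "min": {"reference": 14.1, "p90": 22.2, "p95": 23.3, "p99": 25.3, "upper_limit": 27.9},
}

N_STATIONS = 34
BASELINE_DEATHS_PER_DAY = TOTAL_DEATHS / STUDY_DAYS  # ~5.43


def category_shares() -> dict[str, float]:
    """Category shares of the total, computed from the printed counts."""
    return {k: v / TOTAL_DEATHS for k, v in CATEGORY_COUNTS.items()}
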