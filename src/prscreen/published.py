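"""Published PLCO screening-arm reference inputs.

These constants are the printed summary tables of the published PLCO
risk-adapted screening analysis: the screening-strategy contingency
tables, the person-year follow-up totals, the PRS group sizes, and the
age-/PRS-specific PSA cut-off values read off the published tdROC
analysis.  They are *inputs*: every percentage, rate or proportion this
package reports is recomputed from these counts by the metric code, never
copied.

Individual-level PLCO data (dbGaP) are not distributed and are not needed
to use any of these tables.
"""

from __future__ import annotations

import pandas as pd

AGE_GROUPS = ["<60", "60-64", "65-69", ">=70"]
PRS_STRATA = ["all", "low", "high"]

#: Age-/PRS-specific PSA cut-offs (ng/mL) from the published tdROC analysis
#: at the 10-year horizon, plus the corresponding tdAUCs.
PUBLISHED_CUTOFFS: dict[tuple[str, str], float] = {
    ("all", "<60"): 1.41,
    ("all", "60-64"): 1.46,
    ("all", "65-69"): 1.59,
    ("all", ">=70"): 2.12,
    ("low", "<60"): 1.42,
    ("low", "60-64"): 1.65,
    ("low", "65-69"): 1.60,
    ("low", ">=70"): 2.24,
    ("high", "<60"): 1.48,
    ("high", "60-64"): 1.47,
    ("high", "65-69"): 1.89,
    ("high", ">=70"): 2.72,
    # whole-stratum (age-pooled) cut-offs
    ("low", "all"): 1.42,
    ("high", "all"): 1.62,
}

PUBLISHED_TDAUCS: dict[tuple[str, str], float] = {
    ("all", "<60"): 0.832,
    ("all", "60-64"): 0.808,
    ("all", "65-69"): 0.806,
    ("all", ">=70"): 0.809,
    ("low", "<60"): 0.816,
    ("low", "60-64"): 0.796,
    ("low", "65-69"): 0.793,
    ("low", ">=70"): 0.788,
    ("high", "<60"): 0.840,
    ("high", "60-64"): 0.809,
    ("high", "65-69"): 0.804,
    ("high", ">=70"): 0.824,
    ("low", "all"): 0.818,
    ("high", "all"): 0.816,
}

#: Screening-arm contingency tables (cases/non-cases x positive/negative)
#: for the four positivity strategies, as published.
PUBLISHED_STRATEGY_COUNTS: dict[str, dict[str, int]] = {
    "traditional": {"tp": 1040, "fp": 1139, "fn": 2536, "tn": 24530},
    "improved1_age": {"tp": 2832, "fp": 7651, "fn": 744, "tn": 18018},
    "improved2_age_prs": {"tp": 2719, "fp": 6974, "fn": 857, "tn": 18695},
    "improved3_highprs_only": {"tp": 1498, "fp": 2484, "fn": 2078, "tn": 23185},
}

#: Screening-arm incidence follow-up summaries by PRS group and baseline
#: PSA positivity (PRS-specific cut-offs): events and person-years
#: (thousands).
PUBLISHED_INCIDENCE_ROWS: dict[str, dict[str, float]] = {
    "overall": {"n": 29245, "events": 3576, "py_thousands": 319.80},
    "low_psa_neg": {"n": 12084, "events": 364, "py_thousands": 140.35},
    "low_psa_pos": {"n": 6721, "events": 1306, "py_thousands": 71.25},
    "high_psa_neg": {"n": 6345, "events": 385, "py_thousands": 71.90},
    "high_psa_pos": {"n": 4095, "events": 1521, "py_thousands": 36.31},
}

#: PRS-group sizes in the full analysed cohort (both arms) and PSA
#: positivity counts within the screening-arm PRS groups.
PUBLISHED_PRS_SPLIT = {
    "n_total": 49907,
    "n_low": 31717,
    "n_high": 18190,
    "screening_low_total": 18805,
    "screening_low_psa_pos": 6721,
    "screening_high_total": 10440,
    "screening_high_psa_pos": 4095,
}

#: AUCs of the four PRS variants in the published analysis.
PUBLISHED_PRS_AUCS = {"PRS1": 0.607, "PRS2": 0.614, "PRS3": 0.630, "PRS4": 0.631}


def published_cutoff_table() -> pd.DataFrame:
    """Return the published cut-offs as a CutoffTable data frame.

    Columns match :func:`prscreen.tdroc.stratified_cutoffs` output with
    ``source`` set to ``"published"``.
    """
    rows = []
    for (stratum, age_group), cutoff in PUBLISHED_CUTOFFS.items():
        rows.append(
            {
                "stratum": stratum,
                "age_group": age_group,
                "cutoff_ng_ml": cutoff,
                "td_auc": PUBLISHED_TDAUCS.get((stratum, age_group)),
                "n": None,
                "n_cases": None,
                "reliable": True,
                "source": "published",
            }
        )
    return pd.DataFrame(rows)
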