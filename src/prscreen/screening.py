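"""Screening positivity strategies and their evaluation.

Four positivity rules on baseline PSA, all with strict inequality
(PSA > cut-off):

* ``traditional``             PSA > 4 ng/mL
* ``improved1_age``           PSA > age-specific cut-off (all participants)
* ``improved2_age_prs``       PSA > (PRS group x age)-specific cut-off
* ``improved3_highprs_only``  positive only when PRS group is high AND
  PSA > (high-PRS x age)-specific cut-off; low-PRS men are never positive

Each strategy is scored against observed prostate-cancer diagnosis with
the full confusion-matrix panel (sensitivity / specificity / PPV / NPV
with exact Clopper-Pearson CIs), the Gleason >=7 proportion among true
positives, and two false-positive proportions: among positive screens
(1 - PPV) and among all participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .published import AGE_GROUPS
from .tdroc import lookup_cutoff

__all__ = [
    "STRATEGIES",
    "ConfusionMatrix",
    "ScreeningMetrics",
    "classify",
    "evaluate",
    "metrics_from_counts",
    "missed_reduction",
    "compare_strategies",
    "strategy_report",
]

STRATEGIES = (
    "traditional",
    "improved1_age",
    "improved2_age_prs",
    "improved3_highprs_only",
)

TRADITIONAL_CUTOFF_NG_ML = 4.0


def classify(
    cohort: pd.DataFrame,
    strategy: str,
    cutoffs: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-participant screening positivity under one strategy.

    Requires ``psa_baseline_ng_ml`` and ``age_group`` columns, plus
    ``prs_group`` for the PRS-aware strategies.  Missing cut-off cells
    raise a KeyError naming the cell.
    """
    psa = cohort["psa_baseline_ng_ml"].to_numpy(dtype=float)
    if strategy == "traditional":
        pos = psa > TRADITIONAL_CUTOFF_NG_ML
        return pd.Series(pos, index=cohort.index, name=strategy)
    if cutoffs is None:
        raise ValueError(f"strategy {strategy!r} needs a cut-off table")
    age = cohort["age_group"].astype(str)
    thr = np.empty(len(cohort))
    if strategy == "improved1_age":
        for ag in AGE_GROUPS:
            thr[np.asarray(age == ag)] = lookup_cutoff(cutoffs, "all", ag)
        pos = psa > thr
    elif strategy == "improved2_age_prs":
        prs = cohort["prs_group"].astype(str)
        for g in ("low", "high"):
            for ag in AGE_GROUPS:
                m = np.asarray((prs == g) & (age == ag))
                if m.any():
                    thr[m] = lookup_cutoff(cutoffs, g, ag)
        pos = psa > thr
    elif strategy == "improved3_highprs_only":
        prs = cohort["prs_group"].astype(str)
        for ag in AGE_GROUPS:
            m = np.asarray(age == ag)
            if m.any():
                thr[m] = lookup_cutoff(cutoffs, "high", ag)
        pos = (prs.to_numpy() == "high") & (psa > thr)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return pd.Series(pos, index=cohort.index, name=strategy)


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fp


def _prop_ci(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return (100.0 * lo, 100.0 * hi)


@dataclass
class ScreeningMetrics:
    """Percent-scale metric panel with exact binomial CIs."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    high_grade_prop_among_tp: float
    fp_prop_among_positives: float
    fp_prop_among_all: float


def metrics_from_counts(
    tp: int, fp: int, fn: int, tn: int, n_high_grade_tp: int | None = None
) -> ScreeningMetrics:
    """Metric panel from raw confusion counts (percent scale).

    Zero denominators yield NaN rather than an error.
    """
    def pct(k, n):
        return 100.0 * k / n if n else np.nan

    n_all = tp + fp + fn + tn
    return ScreeningMetrics(
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp),
        npv=pct(tn, tn + fn),
        sensitivity_ci=_prop_ci(tp, tp + fn),
        specificity_ci=_prop_ci(tn, tn + fp),
        ppv_ci=_prop_ci(tp, tp + fp),
        npv_ci=_prop_ci(tn, tn + fn),
        high_grade_prop_among_tp=(
            pct(n_high_grade_tp, tp) if n_high_grade_tp is not None else np.nan
        ),
        fp_prop_among_positives=pct(fp, tp + fp),
        fp_prop_among_all=pct(fp, n_all),
    )


def evaluate(
    positivity, case, gleason_ge7=None
) -> tuple[ConfusionMatrix, ScreeningMetrics]:
    """Confusion matrix and metric panel of a positivity vector against
    observed case status; ``gleason_ge7`` (NaN for non-cases) feeds the
    high-grade proportion among true positives."""
    pos = np.asarray(positivity, dtype=bool)
    y = np.asarray(case, dtype=bool)
    if len(pos) != len(y):
        raise ValueError("positivity and case vectors differ in length")
    cm = ConfusionMatrix(
        tp=int((pos & y).sum()),
        fp=int((pos & ~y).sum()),
        fn=int((~pos & y).sum()),
        tn=int((~pos & ~y).sum()),
    )
    n_hg = None
    if gleason_ge7 is not None:
        g = np.asarray(gleason_ge7, dtype=float)
        n_hg = int(np.nansum(g[pos & y]))
    return cm, metrics_from_counts(cm.tp, cm.fp, cm.fn, cm.tn, n_hg)


def missed_reduction(cm_reference: ConfusionMatrix, cm_new: ConfusionMatrix) -> float:
    """Reduction in missed cancers, as a percent of all cases:
    (FN_reference - FN_new) / cases x 100."""
    if cm_reference.n_cases != cm_new.n_cases:
        raise ValueError("confusion matrices come from different cohorts")
    return 100.0 * (cm_reference.fn - cm_new.fn) / cm_reference.n_cases


def compare_strategies(
    positivity_a, positivity_b, case, metric: str = "sensitivity"
) -> float:
    """McNemar p-value for paired positivity vectors, restricted to
    cases (sensitivity) or non-cases (specificity).

    Uses the exact binomial test when discordant pairs are few (<25),
    otherwise the chi-square statistic (b - c)^2 / (b + c) without
    continuity correction.  No discordant pairs -> p = 1.
    """
    a = np.asarray(positivity_a, dtype=bool)
    b = np.asarray(positivity_b, dtype=bool)
    y = np.asarray(case, dtype=bool)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("inputs differ in length")
    sub = y if metric == "sensitivity" else ~y
    d10 = int((a[sub] & ~b[sub]).sum())
    d01 = int((~a[sub] & b[sub]).sum())
    n_disc = d10 + d01
    if n_disc == 0:
        return 1.0
    if n_disc < 25:
        return float(stats.binomtest(min(d10, d01), n_disc, 0.5).pvalue * 1.0)
    chi2 = (d10 - d01) ** 2 / n_disc
    return float(stats.chi2.sf(chi2, df=1))


def strategy_report(
    cohort: pd.DataFrame,
    cutoffs: pd.DataFrame,
    strategies: tuple[str, ...] = STRATEGIES,
    case_horizon_years: float | None = None,
) -> pd.DataFrame:
    """Full evaluation of each strategy against observed diagnosis, with
    McNemar comparisons vs the traditional strategy.

    By default a case is any diagnosis during available follow-up;
    ``case_horizon_years`` restricts the case definition to diagnoses
    within that horizon (e.g. 10 to align with the tdROC outcome).
    Returns one row per strategy: confusion counts, the percent metric
    panel, high-grade and false-positive proportions, and comparison
    p-values.
    """
    case = cohort["dx_event"].astype(bool)
    if case_horizon_years is not None:
        case = case & (cohort["t_dx_years"] <= case_horizon_years)
    gleason = cohort.get("gleason_ge7")
    pos_trad = classify(cohort, "traditional", cutoffs)
    rows = []
    for strat in strategies:
        pos = classify(cohort, strat, cutoffs)
        cm, met = evaluate(pos, case, gleason)
        row = {
            "strategy": strat,
            "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
            "sensitivity": met.sensitivity,
            "specificity": met.specificity,
            "ppv": met.ppv,
            "npv": met.npv,
            "high_grade_prop_among_tp": met.high_grade_prop_among_tp,
            "fp_among_positives": met.fp_prop_among_positives,
            "fp_among_all": met.fp_prop_among_all,
        }
        if strat == "traditional":
            row["p_vs_traditional_sens"] = np.nan
            row["p_vs_traditional_spec"] = np.nan
        else:
            row["p_vs_traditional_sens"] = compare_strategies(
                pos, pos_trad, case, "sensitivity"
            )
            row["p_vs_traditional_spec"] = compare_strategies(
                pos, pos_trad, case, "specificity"
            )
        rows.append(row)
    return pd.DataFrame(rows)
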