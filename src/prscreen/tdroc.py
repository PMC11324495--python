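"""Time-dependent ROC at a fixed horizon with IPCW.

Implements the cumulative-case / dynamic-control estimator: at horizon
``t`` the cases are subjects with an event by ``t`` and the controls are
subjects event-free and still under observation at ``t``.  Censoring is
corrected by inverse-probability-of-censoring weights from the
Kaplan-Meier estimate G of the censoring survival function:

* event by horizon at time T  ->  weight 1 / G(T-)
* under follow-up at horizon  ->  weight 1 / G(horizon)
* censored before horizon     ->  weight 0

Events at exactly the horizon count as cases.  The threshold grid is the
sorted unique marker values (exact empirical curve); the optimal cut-off
maximises the weighted Youden index with ties broken toward the smaller
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .published import AGE_GROUPS, published_cutoff_table

__all__ = [
    "TdROCResult",
    "censoring_km_weights",
    "td_roc",
    "stratified_cutoffs",
    "bootstrap_cutoff_stability",
    "published_cutoff_table",
]

MIN_RELIABLE_CASES = 20


def _censoring_km(time: np.ndarray, event: np.ndarray):
    """Step data of the censoring-distribution Kaplan-Meier G.

    Returns (times, G_right) where G_right[i] is G evaluated just after
    times[i]; G is right-continuous with drops at censoring times.  Ties
    between events and censorings at the same time are handled with the
    standard convention that events precede censorings, i.e. the at-risk
    set for a censoring at t is {time >= t}.
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = len(t)
    uniq = np.unique(t[e == 0])
    g = 1.0
    times, gvals = [], []
    for u in uniq:
        at_risk = n - np.searchsorted(t, u, side="left")
        d_cens = int(((t == u) & (e == 0)).sum())
        g *= 1.0 - d_cens / at_risk
        times.append(u)
        gvals.append(g)
    return np.array(times), np.array(gvals)


def _g_at(times: np.ndarray, gvals: np.ndarray, query: np.ndarray, left: bool) -> np.ndarray:
    """Evaluate G at query times; ``left`` gives the left limit G(t-)."""
    side = "left" if left else "right"
    idx = np.searchsorted(times, query, side=side) - 1
    out = np.ones(len(query))
    ok = idx >= 0
    out[ok] = gvals[idx[ok]]
    return out


def censoring_km_weights(time, event, horizon: float) -> np.ndarray:
    """Per-subject IPCW weights at ``horizon`` (see module docstring)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time <= 0):
        raise ValueError("all follow-up times must be > 0")
    kt, kg = _censoring_km(time, event)
    is_case = (event == 1) & (time <= horizon)
    at_horizon = time >= horizon
    w = np.zeros(len(time))
    g_case = _g_at(kt, kg, time[is_case], left=True)
    g_hor = _g_at(kt, kg, np.array([horizon]), left=True)[0]
    if np.any(g_case <= 0) or (at_horizon.any() and g_hor <= 0):
        raise ValueError(
            "censoring survival reaches 0 before a needed time; "
            "reduce the horizon"
        )
    w[is_case] = 1.0 / g_case
    w[at_horizon & ~is_case] = 1.0 / g_hor
    return w


@dataclass
class TdROCResult:
    horizon_years: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    td_auc: float
    optimal_cutoff: float
    n_cases: int
    n_controls: int
    mean_case_weight: float
    mean_control_weight: float

    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def td_roc(marker, time, event, horizon: float = 10.0) -> TdROCResult:
    """IPCW time-dependent ROC of a baseline marker at a fixed horizon.

    With zero censoring this reduces exactly, at every threshold, to the
    binary ROC of the outcome ``event by horizon``.
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    w = censoring_km_weights(time, event, horizon)
    is_case = (event == 1) & (time <= horizon)
    is_ctrl = (time >= horizon) & ~is_case
    n_cases, n_ctrl = int(is_case.sum()), int(is_ctrl.sum())
    if n_cases == 0 or n_ctrl == 0:
        raise ValueError(
            f"need >=1 case by horizon and >=1 control at horizon "
            f"(got {n_cases} cases, {n_ctrl} controls)"
        )
    grid = np.unique(marker)
    wc, mc = w[is_case], marker[is_case]
    wn, mn = w[is_ctrl], marker[is_ctrl]

    def _wcum_le(m, wgt):
        # weighted P(marker <= c) over the grid, via sorted cumulative sums
        order = np.argsort(m, kind="stable")
        csum = np.concatenate([[0.0], np.cumsum(wgt[order])])
        idx = np.searchsorted(m[order], grid, side="right")
        return csum[idx] / csum[-1]

    sens = 1.0 - _wcum_le(mc, wc)
    spec = _wcum_le(mn, wn)
    # trapezoid over the full curve including the (0,0)/(1,1) endpoints
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    youden = sens + spec - 1.0
    best = int(np.flatnonzero(youden == youden.max())[0])
    return TdROCResult(
        horizon_years=float(horizon),
        thresholds=grid,
        sensitivity=sens,
        specificity=spec,
        td_auc=auc,
        optimal_cutoff=float(grid[best]),
        n_cases=n_cases,
        n_controls=n_ctrl,
        mean_case_weight=float(wc.mean()),
        mean_control_weight=float(wn.mean()),
    )


# ---------------------------------------------------------------------------
# stratified cut-off tables

def _iter_cells(cohort: pd.DataFrame, by_prs: bool, by_age: bool):
    strata = ["all"]
    if by_prs:
        strata += ["low", "high"]
    ages = list(AGE_GROUPS) if by_age else []
    for stratum in strata:
        sub = cohort if stratum == "all" else cohort[cohort["prs_group"] == stratum]
        yield stratum, "all", sub
        for ag in ages:
            yield stratum, ag, sub[sub["age_group"].astype(str) == ag]


def stratified_cutoffs(
    cohort: pd.DataFrame,
    marker: str = "psa_baseline_ng_ml",
    by: tuple[str, ...] = ("prs", "age"),
    horizon: float = 10.0,
    time_col: str = "t_dx_years",
    event_col: str = "dx_event",
    min_cases: int = MIN_RELIABLE_CASES,
) -> pd.DataFrame:
    """Derive PSA cut-offs from tdROC within each (PRS stratum x age
    group) cell, including the pooled ``all`` margins.

    Cells with fewer than ``min_cases`` horizon cases are flagged
    ``reliable=False``; cells where the tdROC is undefined get a missing
    cut-off.  Returns a CutoffTable data frame with columns (stratum,
    age_group, cutoff_ng_ml, td_auc, n, n_cases, reliable, source).
    """
    by_prs = "prs" in by
    by_age = "age" in by
    rows = []
    for stratum, ag, sub in _iter_cells(cohort, by_prs, by_age):
        row = {
            "stratum": stratum,
            "age_group": ag,
            "cutoff_ng_ml": np.nan,
            "td_auc": np.nan,
            "n": len(sub),
            "n_cases": 0,
            "reliable": False,
            "source": "derived",
        }
        if len(sub):
            try:
                res = td_roc(
                    sub[marker], sub[time_col], sub[event_col], horizon=horizon
                )
                row.update(
                    cutoff_ng_ml=res.optimal_cutoff,
                    td_auc=res.td_auc,
                    n_cases=res.n_cases,
                    reliable=res.n_cases >= min_cases,
                )
            except ValueError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def lookup_cutoff(cutoffs: pd.DataFrame, stratum: str, age_group: str) -> float:
    """Fetch one cut-off cell, raising a clear error when absent."""
    hit = cutoffs[
        (cutoffs["stratum"] == stratum) & (cutoffs["age_group"] == age_group)
    ]
    if not len(hit) or not np.isfinite(hit["cutoff_ng_ml"].iloc[0]):
        raise KeyError(f"no cut-off for cell (stratum={stratum}, age={age_group})")
    return float(hit["cutoff_ng_ml"].iloc[0])


def bootstrap_cutoff_stability(
    cohort: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
    **cutoff_kwargs,
) -> pd.DataFrame:
    """Percentile 95% CIs of every cut-off cell from ``B`` bootstrap
    resamples of participants (the published analysis used B = 2000).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    point = stratified_cutoffs(cohort, **cutoff_kwargs)
    draws = {i: [] for i in point.index}
    n = len(cohort)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = stratified_cutoffs(cohort.iloc[idx], **cutoff_kwargs)
        for i in point.index:
            draws[i].append(boot["cutoff_ng_ml"].iloc[i])
    out = point.copy()
    lo, hi = [], []
    for i in point.index:
        vals = np.asarray(draws[i], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals):
            lo.append(float(np.percentile(vals, 2.5)))
            hi.append(float(np.percentile(vals, 97.5)))
        else:
            lo.append(np.nan)
            hi.append(np.nan)
    out["ci_lo"] = lo
    out["ci_hi"] = hi
    return out
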