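"""Person-year rates, Cox proportional-hazards fits and interaction codings.

Incidence and prostate-cancer mortality are separate time scales: the
cohort schema carries (t_dx_years, dx_event) for diagnosis and
(t_death_years, pca_death_event) for disease-specific death, each with
its own follow-up.  Cox fits use Efron tie handling and expand
categorical covariates with an explicit "missing" level so incomplete
covariate data never drop participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

from .published import AGE_GROUPS

__all__ = [
    "RatesSummary",
    "CoxFit",
    "person_year_rates",
    "cox_fit",
    "interaction_analysis",
    "logrank",
    "rate_per_1000py",
    "OUTCOME_COLS",
]

OUTCOME_COLS = {
    "incidence": ("t_dx_years", "dx_event"),
    "mortality": ("t_death_years", "pca_death_event"),
}

#: default adjustment covariates (categorical; missing coded as a level)
DEFAULT_ADJUSTMENT = [
    "race",
    "bmi_class",
    "smoking",
    "family_history_pca",
    "prior_psa_tests",
    "enlarged_prostate",
    "diabetes",
]


def rate_per_1000py(n_events: float, person_years_thousands: float) -> float:
    """Event rate per 1,000 person-years from events and PYs in thousands."""
    return n_events / person_years_thousands


@dataclass
class RatesSummary:
    table: pd.DataFrame  # group, n, pct_n, n_events, pct_events, person_years_thousands, rate_per_1000_py


def person_year_rates(
    cohort: pd.DataFrame, grouping: str | None, outcome: str = "incidence"
) -> RatesSummary:
    """Events, person-years (thousands) and rates per 1,000 PYs by group.

    ``grouping=None`` gives the pooled cohort as a single row.
    """
    time_col, event_col = OUTCOME_COLS[outcome]
    if (cohort[time_col] < 0).any():
        raise ValueError("negative follow-up times")
    df = cohort.copy()
    df["_g"] = "overall" if grouping is None else df[grouping].astype(str)
    rows = []
    tot_n = len(df)
    tot_ev = df[event_col].sum()
    for g, sub in df.groupby("_g", sort=True):
        py = sub[time_col].sum() / 1000.0
        ev = int(sub[event_col].sum())
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "pct_n": 100.0 * len(sub) / tot_n,
                "n_events": ev,
                "pct_events": 100.0 * ev / tot_ev if tot_ev else np.nan,
                "person_years_thousands": py,
                "rate_per_1000_py": rate_per_1000py(ev, py) if py > 0 else np.nan,
            }
        )
    return RatesSummary(pd.DataFrame(rows))


@dataclass
class CoxFit:
    terms: pd.DataFrame  # term, log_hr, hr, ci_lo, ci_hi, p
    n: int
    n_events: int
    adjustment: list[str]
    penalized: bool = False  # ridge fallback used (sparse/separated level)

    def hr(self, term: str) -> float:
        return float(self.terms.set_index("term").at[term, "hr"])


def _design(
    cohort: pd.DataFrame,
    exposure: str | pd.Series,
    adjust: list[str] | None,
    time_col: str,
    event_col: str,
) -> tuple[pd.DataFrame, list[str]]:
    df = pd.DataFrame(
        {"T": cohort[time_col].to_numpy(), "E": cohort[event_col].to_numpy()}
    )
    if isinstance(exposure, str):
        exp_vals = cohort[exposure]
        exp_name = exposure
    else:
        exp_vals = exposure
        exp_name = exposure.name or "exposure"
    exp_terms: list[str]
    if pd.api.types.is_numeric_dtype(exp_vals) and exp_vals.nunique() > 4:
        if exp_vals.nunique() < 2:
            raise ValueError("exposure does not vary")
        df[exp_name] = exp_vals.to_numpy(dtype=float)
        exp_terms = [exp_name]
    else:
        cats = pd.Series(exp_vals).astype(str)
        levels = sorted(cats.unique())
        if len(levels) < 2:
            raise ValueError("exposure does not vary")
        dummies = pd.get_dummies(cats, prefix=exp_name, dtype=float)
        keep = [f"{exp_name}_{lv}" for lv in levels[1:]]
        df[keep] = dummies[keep].to_numpy()
        exp_terms = keep
    for cov in adjust or []:
        vals = cohort[cov]
        if pd.api.types.is_numeric_dtype(vals) and vals.nunique() > 6:
            df[cov] = vals.fillna(vals.median()).to_numpy(dtype=float)
            continue
        cats = vals.astype("object").where(vals.notna(), "missing").astype(str)
        dummies = pd.get_dummies(cats, prefix=cov, dtype=float)
        drop = dummies.columns[0]
        cols = [c for c in dummies.columns if c != drop and dummies[c].std() > 0]
        df[cols] = dummies[cols].to_numpy()
    return df, exp_terms


def cox_fit(
    cohort: pd.DataFrame,
    exposure: str | pd.Series,
    outcome: str = "incidence",
    adjust: list[str] | None = None,
    precision: float = 1e-9,
) -> CoxFit:
    """Multivariable Cox PH fit (Efron ties) returning HR, Wald 95% CI
    and p for every model term; the exposure's terms come first.

    ``precision`` is the Newton-Raphson stopping tolerance; the default
    suits cohort-scale fits, while tiny fixtures benchmarked against
    grid-search optima may need ~1e-14 (the stop rule includes the
    log-likelihood change, which is quadratic in the parameter error).
    """
    import warnings

    from lifelines.exceptions import ConvergenceError

    time_col, event_col = OUTCOME_COLS[outcome]
    df, exp_terms = _design(cohort, exposure, adjust, time_col, event_col)
    if df["E"].sum() < 1:
        raise ValueError("no events")
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph = CoxPHFitter()
            cph.fit(
                df,
                duration_col="T",
                event_col="E",
                fit_options={"precision": precision, "max_steps": 500},
            )
        except ConvergenceError:
            # monotone likelihood / quasi-separation in a sparse level:
            # stabilise with a light ridge penalty and flag the fit
            penalized = True
            cph = CoxPHFitter(penalizer=1e-3)
            cph.fit(
                df,
                duration_col="T",
                event_col="E",
                fit_options={"precision": precision, "max_steps": 500},
            )
    summ = cph.summary
    order = exp_terms + [t for t in summ.index if t not in exp_terms]
    terms = pd.DataFrame(
        {
            "term": order,
            "log_hr": summ.loc[order, "coef"].to_numpy(),
            "hr": summ.loc[order, "exp(coef)"].to_numpy(),
            "ci_lo": np.exp(summ.loc[order, "coef lower 95%"].to_numpy()),
            "ci_hi": np.exp(summ.loc[order, "coef upper 95%"].to_numpy()),
            "p": summ.loc[order, "p"].to_numpy(),
        }
    )
    return CoxFit(
        terms,
        n=len(df),
        n_events=int(df["E"].sum()),
        adjustment=list(adjust or []),
        penalized=penalized,
    )


# ---------------------------------------------------------------------------
# interaction codings

def _combo(cohort: pd.DataFrame) -> pd.Series:
    prs = cohort["prs_group"].astype(str)
    psa = np.where(cohort["psa_positive"].astype(bool), "PSA+", "PSA-")
    return pd.Series(prs.str.cat(psa, sep="/"), index=cohort.index, name="prs_psa")


COMBO_ORDER = ["low/PSA-", "low/PSA+", "high/PSA-", "high/PSA+"]


def interaction_analysis(
    cohort: pd.DataFrame,
    scheme: str = "age_stratified_4level",
    outcome: str = "incidence",
    adjust: list[str] | None = None,
) -> pd.DataFrame:
    """The two joint PRS x PSA positivity codings.

    ``age_stratified_4level``: within each age group, a 4-level factor
    {low/PSA-, low/PSA+, high/PSA-, high/PSA+} with low/PSA- as the
    within-stratum reference.  ``cross_age_16level``: one 16-level factor
    (4 combinations x 4 age groups) with low/PSA- aged <60 as the uniform
    reference.  Requires ``prs_group``, ``psa_positive`` and
    ``age_group`` columns.  Returns a tidy table of terms; reference
    levels appear with HR 1 and missing CI.
    """
    combo = _combo(cohort)
    rows = []
    if scheme == "age_stratified_4level":
        for ag in AGE_GROUPS:
            sub = cohort[cohort["age_group"].astype(str) == ag]
            if not len(sub):
                continue
            sub_combo = combo.loc[sub.index]
            levels = [lv for lv in COMBO_ORDER if (sub_combo == lv).any()]
            ref = levels[0]
            # relabel the reference so the dummy coding drops it
            relab = sub_combo.where(sub_combo != ref, "0_ref")
            fit = cox_fit(
                sub.assign(_combo=relab),
                exposure="_combo",
                outcome=outcome,
                adjust=adjust,
            )
            rows.append({"age_group": ag, "level": ref, "hr": 1.0,
                         "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan,
                         "reference": True})
            named = fit.terms.set_index("term")
            for lv in levels[1:]:
                term = f"_combo_{lv}"
                if term in named.index:
                    r = named.loc[term]
                    rows.append({"age_group": ag, "level": lv, "hr": r["hr"],
                                 "ci_lo": r["ci_lo"], "ci_hi": r["ci_hi"],
                                 "p": r["p"], "reference": False})
        return pd.DataFrame(rows)
    if scheme == "cross_age_16level":
        labels = cohort["age_group"].astype(str).str.cat(combo, sep=" ")
        ordered = [f"{ag} {lv}" for ag in AGE_GROUPS for lv in COMBO_ORDER]
        present = [lv for lv in ordered if (labels == lv).any()]
        ref = present[0]
        # put the uniform reference first so get_dummies drops it
        relab = labels.where(labels != ref, "0_ref")
        fit = cox_fit(
            cohort.assign(_combo16=relab),
            exposure="_combo16",
            outcome=outcome,
            adjust=adjust,
        )
        named = fit.terms.set_index("term")
        for lv in present:
            if lv == ref:
                rows.append({"level": lv, "hr": 1.0, "ci_lo": np.nan,
                             "ci_hi": np.nan, "p": np.nan, "reference": True})
            else:
                term = f"_combo16_{lv}"
                r = named.loc[term]
                rows.append({"level": lv, "hr": r["hr"], "ci_lo": r["ci_lo"],
                             "ci_hi": r["ci_hi"], "p": r["p"], "reference": False})
        out = pd.DataFrame(rows)
        out[["age_group", "level"]] = out["level"].str.split(" ", n=1, expand=True)
        return out[["age_group", "level", "hr", "ci_lo", "ci_hi", "p", "reference"]]
    raise ValueError(f"unknown interaction scheme {scheme!r}")


def logrank(cohort: pd.DataFrame, grouping: str, outcome: str = "incidence"):
    """Log-rank test across the levels of ``grouping``; returns
    (chi-square statistic, p)."""
    time_col, event_col = OUTCOME_COLS[outcome]
    groups = cohort[grouping].astype(str)
    if groups.nunique() < 2:
        raise ValueError("log-rank needs >=2 groups")
    res = multivariate_logrank_test(
        cohort[time_col], groups, cohort[event_col]
    )
    return float(res.test_statistic), float(res.p_value)
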