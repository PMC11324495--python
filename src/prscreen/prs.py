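"""Polygenic risk scores for prostate cancer.

Genotype I/O and control-major-allele imputation, per-SNP logistic
association, direction-consistent SNP validation, the four PRS variants
(unweighted / weighted x all / validated SNPs), ROC analysis with the
DeLong test for correlated AUCs, and dichotomisation of the cohort into
low-/high-PRS groups at the Youden-optimal score cut-off.

PRS variants
------------
PRS1  unweighted sum of risk-allele dosages over all panel SNPs
PRS2  unweighted sum over validated SNPs only
PRS3  dosages weighted by in-cohort univariate log-odds, all SNPs
PRS4  weighted sum over validated SNPs only
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "SNPPanel",
    "GenotypeMatrix",
    "PRSResult",
    "RocResult",
    "read_genotypes",
    "impute_missing",
    "per_snp_association",
    "validate_snps",
    "compute_prs",
    "roc_auc",
    "delong_compare",
    "select_and_dichotomize",
    "AlleleMismatchError",
]

PRS_VARIANTS = ("PRS1", "PRS2", "PRS3", "PRS4")


class AlleleMismatchError(ValueError):
    """Genotype file alleles do not match the SNP panel."""


@dataclass
class SNPPanel:
    """Ordered SNP metadata driving PRS construction.

    ``table`` columns: rsid, risk_allele, other_allele, published_beta,
    published_p, is_agent, plus (after fitting) fitted_beta, fitted_p,
    validated.
    """

    table: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.table["rsid"].duplicated().any():
            dupes = self.table.loc[self.table["rsid"].duplicated(), "rsid"]
            raise ValueError(f"duplicate rsids in panel: {sorted(set(dupes))}")
        self.table = self.table.reset_index(drop=True)

    @property
    def rsids(self) -> pd.Index:
        return pd.Index(self.table["rsid"])

    @classmethod
    def from_csv(cls, path, provenance: str = "file") -> "SNPPanel":
        return cls(pd.read_csv(path), provenance=provenance)


@dataclass
class GenotypeMatrix:
    """Participants x SNPs risk-allele dosage matrix.

    Entries are 0/1/2 risk-allele counts, NaN for missing.
    """

    participant_ids: pd.Index
    rsids: pd.Index
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.participant_ids), len(self.rsids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.participant_ids)} participants x {len(self.rsids)} SNPs"
            )

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.participant_ids, columns=self.rsids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


# ---------------------------------------------------------------------------
# I/O

def read_genotypes(path, panel: SNPPanel, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix, orienting dosages to each SNP's risk allele.

    ``tsv``: participants x SNPs table of {0,1,2,NA}, already counted in
    risk alleles; columns not in the panel are dropped with a warning.
    ``vcf``: hard-call GT records; the dosage is the count of the panel
    risk allele, so records where REF is the risk allele are flipped.
    Records whose {REF, ALT} do not match the panel alleles raise
    :class:`AlleleMismatchError` naming the offending rsids.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        unknown = [c for c in df.columns if c not in set(panel.rsids)]
        if unknown:
            warnings.warn(f"dropping {len(unknown)} rsids absent from panel: {unknown}")
            df = df.drop(columns=unknown)
        df = df.apply(pd.to_numeric, errors="coerce")
        keep = [r for r in panel.rsids if r in df.columns]
        df = df[keep]
        return GenotypeMatrix(df.index, pd.Index(keep), df.to_numpy(dtype=float))
    if format == "vcf":
        return _read_vcf(path, panel)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path, panel: SNPPanel) -> GenotypeMatrix:
    from cyvcf2 import VCF

    meta = panel.table.set_index("rsid")
    vcf = VCF(str(path))
    samples = pd.Index(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    mismatched: list[str] = []
    for var in vcf:
        rsid = var.ID
        if rsid not in meta.index:
            warnings.warn(f"dropping VCF record {rsid}: not in panel")
            continue
        risk = meta.at[rsid, "risk_allele"]
        other = meta.at[rsid, "other_allele"]
        alt = var.ALT[0] if var.ALT else None
        if {var.REF, alt} != {risk, other}:
            mismatched.append(rsid)
            continue
        # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        alt_count = np.array(
            [{0: 0.0, 1: 1.0, 3: 2.0}.get(g, np.nan) for g in var.gt_types]
        )
        cols[rsid] = alt_count if alt == risk else 2.0 - alt_count
    if mismatched:
        raise AlleleMismatchError(
            f"allele mismatch against panel for rsids: {mismatched}"
        )
    keep = [r for r in panel.rsids if r in cols]
    dos = np.column_stack([cols[r] for r in keep]) if keep else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, pd.Index(keep), dos)


# ---------------------------------------------------------------------------
# imputation

def impute_missing(G: GenotypeMatrix, is_control: np.ndarray) -> GenotypeMatrix:
    """Replace missing dosages with the homozygous-major-allele dosage,
    with the major allele determined among controls (cancer-free men).

    If the risk allele is the minor allele among controls the imputed
    dosage is 0 (homozygous for the other, major, allele); otherwise 2.
    Non-missing entries are never changed.
    """
    is_control = np.asarray(is_control, dtype=bool)
    if len(is_control) != len(G.participant_ids):
        raise ValueError("is_control length does not match participants")
    dos = G.dosages.copy()
    ctrl = dos[is_control]
    n_obs = (~np.isnan(ctrl)).sum(axis=0)
    bad = np.where(n_obs == 0)[0]
    if bad.size:
        raise ValueError(
            "no control genotypes to determine the major allele for SNPs: "
            f"{list(G.rsids[bad])}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        risk_freq = np.nanmean(ctrl, axis=0) / 2.0
    fill = np.where(risk_freq < 0.5, 0.0, 2.0)
    missing = np.isnan(dos)
    dos[missing] = np.broadcast_to(fill, dos.shape)[missing]
    return GenotypeMatrix(G.participant_ids, G.rsids, dos)


# ---------------------------------------------------------------------------
# per-SNP association

def _logit_fit(dosage: np.ndarray, y: np.ndarray):
    X = sm.add_constant(dosage)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        beta = float(res.params[1])
        se = float(res.bse[1])
        p = float(res.pvalues[1])
        converged = bool(res.mle_retvals.get("converged", True)) and np.isfinite(se)
        return beta, se, p, converged
    except Exception:
        return np.nan, np.nan, np.nan, False


def per_snp_association(G: GenotypeMatrix, y: np.ndarray) -> pd.DataFrame:
    """Univariate logistic regression of case status on each SNP's
    additive dosage; returns per-SNP log-OR, OR, SE and Wald p.

    SNPs with constant dosage, separation or non-convergence are flagged
    (``converged`` False, beta NaN).
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both cases and controls required")
    rows = []
    for j, rsid in enumerate(G.rsids):
        d = G.dosages[:, j]
        ok = ~np.isnan(d)
        dj, yj = d[ok], y[ok]
        if np.ptp(dj) == 0:
            rows.append((rsid, np.nan, np.nan, np.nan, np.nan, False))
            continue
        beta, se, p, conv = _logit_fit(dj, yj)
        rows.append((rsid, beta, np.exp(beta), se, p, conv))
    return pd.DataFrame(
        rows, columns=["rsid", "fitted_beta", "or_", "se", "fitted_p", "converged"]
    )


def validate_snps(panel: SNPPanel, assoc: pd.DataFrame, alpha: float = 0.05) -> SNPPanel:
    """Flag panel SNPs validated in-cohort: Wald p < alpha with a
    positive fitted log-OR under risk-allele coding (direction consistent
    with the published risk allele)."""
    merged = panel.table.merge(assoc, on="rsid", how="left", suffixes=("", "_fit"))
    if merged["fitted_beta"].isna().all() and len(merged):
        pass  # nothing converged; all unvalidated
    merged["validated"] = (
        (merged["fitted_p"] < alpha)
        & (merged["fitted_beta"] > 0)
        & merged["converged"].fillna(False).astype(bool)
    )
    return SNPPanel(merged, provenance=panel.provenance)


# ---------------------------------------------------------------------------
# PRS construction

def compute_prs(G: GenotypeMatrix, panel: SNPPanel, variant: str) -> pd.Series:
    """Compute one PRS variant for every participant.

    Requires a fully imputed matrix; PRS2/PRS4 need ``validated`` flags
    and PRS3/PRS4 need in-cohort ``fitted_beta`` on the panel.
    """
    if variant not in PRS_VARIANTS:
        raise ValueError(f"unknown PRS variant {variant!r}")
    if G.n_missing:
        raise ValueError("genotype matrix contains missing entries; impute first")
    tab = panel.table.set_index("rsid").loc[list(G.rsids)]
    if variant in ("PRS2", "PRS4"):
        if "validated" not in tab:
            raise ValueError(f"{variant} requires validated flags on the panel")
        mask = tab["validated"].to_numpy(dtype=bool)
    else:
        mask = np.ones(len(tab), dtype=bool)
    if variant in ("PRS3", "PRS4"):
        if "fitted_beta" not in tab:
            raise ValueError(f"{variant} requires fitted betas on the panel")
        w = tab["fitted_beta"].to_numpy(dtype=float)
        w = np.where(np.isfinite(w), w, 0.0)
    else:
        w = np.ones(len(tab))
    score = G.dosages[:, mask] @ w[mask]
    return pd.Series(score, index=G.participant_ids, name=variant)


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class RocResult:
    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    cutoff: float


def roc_auc(score, y) -> RocResult:
    """Empirical ROC of a score against a binary outcome.

    AUC is the Mann-Whitney statistic (ties counted 1/2).  The curve is
    evaluated at every unique score value with the positivity rule
    ``score > c``; the optimal cut-off maximises the Youden index
    sensitivity + specificity - 1, ties broken toward the smaller
    threshold (favouring sensitivity).
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, score))
    grid = np.unique(score)
    case, ctrl = np.sort(score[y == 1]), np.sort(score[y == 0])
    # sens(c) = P(case > c), spec(c) = P(ctrl <= c), via sorted counts
    sens = 1.0 - np.searchsorted(case, grid, side="right") / len(case)
    spec = np.searchsorted(ctrl, grid, side="right") / len(ctrl)
    youden = sens + spec - 1.0
    best = int(np.flatnonzero(youden == youden.max())[0])  # smallest threshold
    return RocResult(auc, grid, sens, spec, float(grid[best]))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(score: np.ndarray, y: np.ndarray):
    """Structural components (placements) of one ROC curve."""
    case = score[y == 1]
    ctrl = score[y == 0]
    m, n = len(case), len(ctrl)
    tx = _midrank(case)
    ty = _midrank(ctrl)
    tz = _midrank(np.concatenate([case, ctrl]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # per-case placements
    v10 = 1.0 - (tz[m:] - ty) / m  # per-control placements
    return auc, v01, v10


def delong_compare(score_a, score_b, y):
    """DeLong test for the difference of two correlated AUCs.

    Returns ``(auc_a - auc_b, variance_of_difference, two-sided p)``
    using the structural-components covariance estimator and a normal
    reference.  Identical scores give a difference of 0 and p = 1.
    """
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    y = np.asarray(y, dtype=int)
    if not (len(score_a) == len(score_b) == len(y)):
        raise ValueError("scores and outcome must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc_a, v01_a, v10_a = _delong_components(score_a, y)
    auc_b, v01_b, v10_b = _delong_components(score_b, y)
    m, n = len(v01_a), len(v10_a)
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    cov = s01 / m + s10 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = float(auc_a - auc_b)
    if var_diff <= 0:
        p = 1.0 if diff == 0 else 0.0
        return diff, max(var_diff, 0.0), p
    z = diff / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return diff, var_diff, p


def delong_auc_variance(score, y) -> float:
    """DeLong variance of a single AUC (for Wald CIs)."""
    score = np.asarray(score, dtype=float)
    y = np.asarray(y, dtype=int)
    _, v01, v10 = _delong_components(score, y)
    return float(np.var(v01, ddof=1) / len(v01) + np.var(v10, ddof=1) / len(v10))


# ---------------------------------------------------------------------------
# variant selection / dichotomisation

@dataclass
class PRSResult:
    variant: str
    scores: pd.Series
    auc: float
    auc_ci: tuple[float, float]
    n_snps: int
    cutoff: float = np.nan
    groups: pd.Series | None = None
    roc: RocResult | None = field(default=None, repr=False)


def prs_result(scores: pd.Series, y, variant: str, n_snps: int) -> PRSResult:
    """Bundle a score vector with its ROC summary."""
    roc = roc_auc(scores.to_numpy(), y)
    se = np.sqrt(delong_auc_variance(scores.to_numpy(), y))
    ci = (max(0.0, roc.auc - 1.96 * se), min(1.0, roc.auc + 1.96 * se))
    return PRSResult(variant, scores, roc.auc, ci, n_snps, roc=roc)


def select_and_dichotomize(results: dict[str, PRSResult]) -> PRSResult:
    """Select the PRS variant with the largest AUC and split the cohort
    at its Youden-optimal cut-off (high = score > cut-off).

    AUC ties are broken toward the variant with fewest SNPs, then toward
    the unweighted variant (lower variant number).
    """
    order = {v: i for i, v in enumerate(PRS_VARIANTS)}
    best = max(
        results.values(),
        key=lambda r: (r.auc, -r.n_snps, -order[r.variant]),
    )
    if best.roc is None:
        raise ValueError("selected PRSResult lacks ROC data")
    best.cutoff = best.roc.cutoff
    best.groups = pd.Series(
        np.where(best.scores.to_numpy() > best.cutoff, "high", "low"),
        index=best.scores.index,
        name="prs_group",
    )
    return best
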