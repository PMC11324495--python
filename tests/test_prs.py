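"""PRS module tests: genotype I/O and allele orientation, control-major
imputation, per-SNP logistic association against a profile-likelihood
oracle, SNP validation, the four score variants, ROC/Youden and the
DeLong test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prscreen.prs import (
    AlleleMismatchError,
    GenotypeMatrix,
    PRS_VARIANTS,
    SNPPanel,
    compute_prs,
    delong_auc_variance,
    delong_compare,
    impute_missing,
    per_snp_association,
    prs_result,
    read_genotypes,
    roc_auc,
    select_and_dichotomize,
    validate_snps,
)


def brute_force_auc(score, y):
    """O(n^2) Mann-Whitney pair counting, ties counted 1/2."""
    score = np.asarray(score, dtype=float)
    y = np.asarray(y, dtype=int)
    case, ctrl = score[y == 1], score[y == 0]
    total = sum(
        1.0 if a > b else (0.5 if a == b else 0.0) for a in case for b in ctrl
    )
    return total / (len(case) * len(ctrl))


def make_matrix(dosages, rsids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        pd.Index([f"P{i}" for i in range(n)]),
        pd.Index(rsids or [f"rs{j + 1}" for j in range(m)]),
        dosages,
    )


# ---------------------------------------------------------------------------
# I/O

class TestReadGenotypes:
    def test_tsv_with_missing(self, tmp_path, toy_panel):
        p = tmp_path / "g.tsv"
        p.write_text("id\trs1\trs2\nA\t0\t2\nB\t1\tNA\nC\t2\t0\n")
        G = read_genotypes(p, toy_panel, format="tsv")
        assert G.dosages.shape == (3, 2)
        assert G.n_missing == 1
        assert np.isnan(G.dosages[1, 1])

    def test_tsv_unknown_column_dropped_with_warning(self, tmp_path, toy_panel):
        p = tmp_path / "g.tsv"
        p.write_text("id\trs1\trs2\trs999\nA\t0\t2\t1\n")
        with pytest.warns(UserWarning, match="rs999"):
            G = read_genotypes(p, toy_panel, format="tsv")
        assert list(G.rsids) == ["rs1", "rs2"]

    @staticmethod
    def _write_vcf(path, records):
        header = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        )
        path.write_text(header + "".join(records))

    def test_vcf_allele_orientation(self, tmp_path, toy_panel):
        # rs1: REF is the risk allele -> dosage = 2 - alt count
        # rs2: ALT is the risk allele -> dosage = alt count
        p = tmp_path / "g.vcf"
        self._write_vcf(
            p,
            [
                "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\n",
                "1\t200\trs2\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t./.\n",
            ],
        )
        G = read_genotypes(p, toy_panel, format="vcf")
        frame = G.to_frame()
        np.testing.assert_array_equal(frame["rs1"].to_numpy(), [1.0, 0.0, 2.0])
        assert frame["rs2"].iloc[0] == 0.0 and frame["rs2"].iloc[1] == 1.0
        assert np.isnan(frame["rs2"].iloc[2])

    def test_vcf_orientation_enumeration(self, tmp_path):
        # oracle: enumerate GT x orientation; risk-allele dosage is the
        # count of the risk allele however REF/ALT are laid out
        gts = {"0/0": 0, "0/1": 1, "1/1": 2}
        for ref, alt, risk in [("A", "G", "A"), ("A", "G", "G")]:
            panel = SNPPanel(
                pd.DataFrame(
                    {
                        "rsid": ["rsX"],
                        "risk_allele": [risk],
                        "other_allele": ["G" if risk == "A" else "A"],
                        "published_beta": [0.1],
                        "published_p": [1e-8],
                        "is_agent": [False],
                    }
                )
            )
            for gt, alt_count in gts.items():
                expected = alt_count if alt == risk else 2 - alt_count
                p = tmp_path / f"g_{risk}_{gt.replace('/', '')}.vcf"
                self._write_vcf(
                    p,
                    [f"1\t100\trsX\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\t{gt}\t{gt}\n"],
                )
                G = read_genotypes(p, panel, format="vcf")
                assert G.dosages[0, 0] == expected, (risk, gt)

    def test_vcf_allele_mismatch_raises(self, tmp_path, toy_panel):
        p = tmp_path / "g.vcf"
        self._write_vcf(p, ["1\t100\trs1\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\n"])
        with pytest.raises(AlleleMismatchError, match="rs1"):
            read_genotypes(p, toy_panel, format="vcf")


# ---------------------------------------------------------------------------
# imputation

class TestImputeMissing:
    def test_risk_allele_minor_imputes_zero(self):
        G = make_matrix([[0], [0], [1], [np.nan]])
        out = impute_missing(G, [True, True, True, False])
        assert out.dosages[3, 0] == 0.0

    def test_risk_allele_major_imputes_two(self):
        # control dosages {2,2,1}: risk-allele frequency 5/6 -> major
        G = make_matrix([[2], [2], [1], [np.nan]])
        out = impute_missing(G, [True, True, True, False])
        assert out.dosages[3, 0] == 2.0

    def test_identity_when_no_missing(self):
        G = make_matrix([[0, 1], [2, 1]])
        out = impute_missing(G, [True, False])
        np.testing.assert_array_equal(out.dosages, G.dosages)

    def test_never_changes_observed_entries_and_clears_missing(self, small_cohort):
        _, genotypes = small_cohort
        obs = ~np.isnan(genotypes.dosages)
        is_control = np.arange(len(genotypes.participant_ids)) % 2 == 0
        out = impute_missing(genotypes, is_control)
        assert out.n_missing == 0
        np.testing.assert_array_equal(out.dosages[obs], genotypes.dosages[obs])

    def test_all_missing_controls_raises(self):
        G = make_matrix([[np.nan], [1.0]])
        with pytest.raises(ValueError, match="rs1"):
            impute_missing(G, [True, False])


# ---------------------------------------------------------------------------
# association + validation

def _profile_loglik_beta(counts_cases, counts_controls):
    """Oracle: univariate logistic MLE by 1-D profile-likelihood grid
    search, profiling out the intercept by bisection on its score."""
    from scipy.optimize import brentq

    x = np.array([0.0, 1.0, 2.0])
    n1 = np.asarray(counts_cases, float)
    n0 = np.asarray(counts_controls, float)

    def loglik(beta):
        def score_a(a):
            p = 1 / (1 + np.exp(-(a + beta * x)))
            return np.sum(n1) - np.sum((n1 + n0) * p)

        a = brentq(score_a, -30, 30)
        p = 1 / (1 + np.exp(-(a + beta * x)))
        return np.sum(n1 * np.log(p) + n0 * np.log(1 - p))

    grid = np.linspace(-3, 3, 2001)
    vals = [loglik(b) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    fine = np.linspace(b0 - 0.01, b0 + 0.01, 2001)
    vals = [loglik(b) for b in fine]
    return fine[int(np.argmax(vals))]


class TestPerSnpAssociation:
    def test_matches_profile_likelihood_oracle(self):
        cases = [10, 20, 30]
        controls = [30, 20, 10]
        dosage = np.repeat([0.0, 1.0, 2.0], [40, 40, 40])
        y = np.concatenate(
            [np.r_[np.ones(c), np.zeros(n)] for c, n in zip(cases, controls)]
        )
        G = make_matrix(dosage[:, None])
        res = per_snp_association(G, y)
        beta_oracle = _profile_loglik_beta(cases, controls)
        assert abs(res["fitted_beta"].iloc[0] - beta_oracle) < 1e-4
        assert abs(res["or_"].iloc[0] - np.exp(beta_oracle)) < 1e-3

    def test_balanced_null_table_gives_zero_beta(self):
        dosage = np.tile(np.repeat([0.0, 1.0, 2.0], 20), 2)
        y = np.r_[np.ones(60), np.zeros(60)]
        res = per_snp_association(make_matrix(dosage[:, None]), y)
        assert abs(res["fitted_beta"].iloc[0]) < 1e-8

    def test_constant_dosage_flagged(self):
        G = make_matrix(np.ones((40, 1)))
        y = np.r_[np.ones(20), np.zeros(20)]
        res = per_snp_association(G, y)
        assert not res["converged"].iloc[0]
        assert np.isnan(res["fitted_beta"].iloc[0])

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            per_snp_association(make_matrix(np.zeros((5, 1))), np.ones(5))


class TestValidateSnps:
    @staticmethod
    def _panel(n=1):
        return SNPPanel(
            pd.DataFrame(
                {
                    "rsid": [f"rs{i + 1}" for i in range(n)],
                    "risk_allele": "A",
                    "other_allele": "G",
                    "published_beta": 0.1,
                    "published_p": 1e-8,
                    "is_agent": False,
                }
            )
        )

    @pytest.mark.parametrize(
        "beta,p,expected",
        [(0.1, 0.03, True), (-0.1, 0.03, False), (0.1, 0.2, False)],
    )
    def test_direction_and_significance(self, beta, p, expected):
        assoc = pd.DataFrame(
            {"rsid": ["rs1"], "fitted_beta": [beta], "fitted_p": [p],
             "or_": [np.exp(beta)], "se": [0.05], "converged": [True]}
        )
        out = validate_snps(self._panel(), assoc, alpha=0.05)
        assert bool(out.table["validated"].iloc[0]) is expected

    def test_null_panel_validation_rate(self):
        # under the null, validated requires p < alpha AND positive
        # direction: expected rate alpha/2 = 2.5 per 100 SNPs
        rng = np.random.default_rng(21)
        counts = []
        for rep in range(3):
            n, m = 2_000, 100
            dos = rng.binomial(2, 0.3, size=(n, m)).astype(float)
            y = rng.binomial(1, 0.15, size=n)
            assoc = per_snp_association(make_matrix(dos), y)
            out = validate_snps(self._panel(m), assoc, alpha=0.05)
            counts.append(out.table["validated"].sum())
        assert 0.0 < np.mean(counts) < 7.0


# ---------------------------------------------------------------------------
# PRS construction

class TestComputePrs:
    @staticmethod
    def _fitted_panel():
        return SNPPanel(
            pd.DataFrame(
                {
                    "rsid": ["rs1", "rs2"],
                    "risk_allele": "A",
                    "other_allele": "G",
                    "published_beta": [0.1, 0.2],
                    "published_p": 1e-8,
                    "is_agent": False,
                    "fitted_beta": [0.1, 0.2],
                    "fitted_p": [0.01, 0.01],
                    "validated": [True, False],
                }
            )
        )

    def test_zero_dosages_zero_scores(self):
        G = make_matrix(np.zeros((3, 2)))
        panel = self._fitted_panel()
        for v in PRS_VARIANTS:
            assert (compute_prs(G, panel, v) == 0).all()

    def test_weighted_arithmetic(self):
        G = make_matrix(np.array([[1.0, 2.0]]))
        score = compute_prs(G, self._fitted_panel(), "PRS3")
        assert score.iloc[0] == pytest.approx(0.1 * 1 + 0.2 * 2)

    def test_missing_matrix_rejected(self):
        G = make_matrix(np.array([[np.nan, 1.0]]))
        with pytest.raises(ValueError, match="impute"):
            compute_prs(G, self._fitted_panel(), "PRS1")

    def test_weighted_without_betas_rejected(self):
        panel = self._fitted_panel()
        panel.table = panel.table.drop(columns=["fitted_beta"])
        with pytest.raises(ValueError):
            compute_prs(make_matrix(np.zeros((2, 2))), panel, "PRS3")

    @given(
        st.integers(min_value=0, max_value=10**6),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_prs1_minus_prs2_is_nonvalidated_sum(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 8)
        n = rng.integers(1, 20)
        dos = rng.integers(0, 3, size=(n, m)).astype(float)
        validated = rng.random(m) < 0.5
        panel = SNPPanel(
            pd.DataFrame(
                {
                    "rsid": [f"rs{j}" for j in range(m)],
                    "risk_allele": "A",
                    "other_allele": "G",
                    "published_beta": 0.1,
                    "published_p": 1e-8,
                    "is_agent": False,
                    "fitted_beta": rng.normal(0.1, 0.05, m),
                    "fitted_p": 0.01,
                    "validated": validated,
                }
            )
        )
        G = make_matrix(dos, rsids=[f"rs{j}" for j in range(m)])
        prs1 = compute_prs(G, panel, "PRS1")
        prs2 = compute_prs(G, panel, "PRS2")
        expected = dos[:, ~validated].sum(axis=1)
        np.testing.assert_allclose((prs1 - prs2).to_numpy(), expected)
        assert (prs1 >= prs2).all()


# ---------------------------------------------------------------------------
# ROC / DeLong

class TestRocAuc:
    def test_constant_score_auc_half(self):
        res = roc_auc(np.ones(10), np.r_[np.ones(4), np.zeros(6)])
        assert res.auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        score = np.r_[np.zeros(5), np.ones(5)]
        y = np.r_[np.zeros(5), np.ones(5)]
        res = roc_auc(score, y)
        assert res.auc == 1.0
        # Youden-optimal cut-off splits the classes: 0 <= c < 1
        assert 0.0 <= res.cutoff < 1.0

    def test_six_point_tie_matches_pair_counting(self):
        score = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0, 0, 1, 0, 1, 1])
        res = roc_auc(score, y)
        assert res.auc == pytest.approx(brute_force_auc(score, y))

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_auc_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 60)
        score = rng.integers(0, 8, size=n).astype(float)  # force ties
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        res = roc_auc(score, y)
        assert res.auc == pytest.approx(brute_force_auc(score, y))

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4))

    def test_youden_tie_breaks_to_smaller_threshold(self):
        # two thresholds achieve the same Youden index
        score = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 1, 1])
        res = roc_auc(score, y)
        assert res.cutoff == 1.0


class TestDeLong:
    def test_identical_scores_p_exactly_one(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=50)
        y = (rng.random(50) < 0.4).astype(int)
        diff, var, p = delong_compare(s, s, y)
        assert diff == 0.0 and p == 1.0

    def test_power_informative_vs_noise(self):
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(10):
            n = 2_000
            y = (rng.random(n) < 0.3).astype(int)
            informative = rng.normal(size=n) + 0.8 * y
            noise = rng.normal(size=n)
            _, _, p = delong_compare(informative, noise, y)
            rejections += p < 0.05
        assert rejections == 10

    def test_variance_against_bootstrap(self):
        # fixed toy set; bootstrap with 2,000 replicates as oracle
        rng = np.random.default_rng(2024)
        n = 400
        y = (rng.random(n) < 0.3).astype(int)
        score = rng.normal(size=n) + 0.8 * y
        v_delong = delong_auc_variance(score, y)
        from sklearn.metrics import roc_auc_score

        boots = []
        for _ in range(2_000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            boots.append(roc_auc_score(y[idx], score[idx]))
        v_boot = np.var(boots, ddof=1)
        assert abs(v_delong - v_boot) / v_boot < 0.10

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            delong_compare(np.zeros(3), np.zeros(4), np.array([0, 1, 0]))


# ---------------------------------------------------------------------------
# selection / dichotomisation

class TestSelectAndDichotomize:
    @staticmethod
    def _results(aucs, n_snps=(102, 80, 102, 80)):
        rng = np.random.default_rng(3)
        out = {}
        y = np.r_[np.ones(30), np.zeros(70)]
        for (v, auc), k in zip(aucs.items(), n_snps):
            score = pd.Series(rng.normal(size=100), index=range(100), name=v)
            res = prs_result(score, y, v, k)
            res.auc = auc  # published AUCs supplied directly
            out[v] = res
        return out

    def test_largest_auc_selected(self):
        res = self._results({"PRS1": 0.607, "PRS2": 0.614, "PRS3": 0.630, "PRS4": 0.631})
        assert select_and_dichotomize(res).variant == "PRS4"

    def test_tie_prefers_fewest_snps_then_unweighted(self):
        res = self._results({v: 0.6 for v in PRS_VARIANTS})
        assert select_and_dichotomize(res).variant == "PRS2"

    def test_groups_match_direct_threshold(self):
        rng = np.random.default_rng(4)
        y = (rng.random(300) < 0.3).astype(int)
        score = pd.Series(rng.normal(size=300) + y, index=range(300), name="PRS4")
        res = {"PRS4": prs_result(score, y, "PRS4", 80)}
        best = select_and_dichotomize(res)
        np.testing.assert_array_equal(
            best.groups.to_numpy(),
            np.where(score.to_numpy() > best.cutoff, "high", "low"),
        )


def test_weighted_beats_unweighted_on_heterogeneous_effects():
    """With heterogeneous true per-SNP effects the beta-weighted score
    should not lose discrimination relative to the unweighted one."""
    from prscreen.synthetic import SimConfig, simulate_cohort, simulate_panel

    auc2, auc4 = [], []
    for seed in range(20):
        cfg = SimConfig(
            n_participants=3_000, n_snps=40, logor_sd=0.06,
            missing_genotype_frac=0.0, seed=3_000 + seed,
        )
        panel, mafs = simulate_panel(cfg)
        cohort, G = simulate_cohort(cfg, panel, mafs)
        y = cohort["dx_event"].to_numpy(bool)
        assoc = per_snp_association(G, y)
        panel = validate_snps(panel, assoc)
        if panel.table["validated"].sum() == 0:
            continue
        for variant, acc in (("PRS2", auc2), ("PRS4", auc4)):
            acc.append(roc_auc(compute_prs(G, panel, variant), y).auc)
    assert np.mean(auc4) >= np.mean(auc2) - 0.005
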