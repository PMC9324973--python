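"""Tests of score computation, tail selection, and group characterization."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbgmet import (
    SimulationConfig,
    combine_sex_strata,
    compute_grs,
    expected_tail_difference,
    select_recall_groups,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_snp_weights,
    trajectory_differences,
)
from rbgmet.grs import (
    AlignmentReport,
    GroupAssignment,
    GrsResult,
    characterize_groups,
    fisher_comparison,
    welch_comparison,
)
from rbgmet.simulate import GenotypeMatrix, PhenotypeTable


def _geno(dosages, effect="A", other="G"):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n)],
        variants=pd.DataFrame(
            {
                "variant_id": [f"v{j}" for j in range(m)],
                "effect_allele": [effect] * m,
                "other_allele": [other] * m,
            }
        ),
        dosages=dosages,
    )


def _weights(ids, weights, effect="A", other="G"):
    return pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": [effect] * len(ids),
            "other_allele": [other] * len(ids),
            "weight": weights,
        }
    )


class TestComputeGrs:
    def test_zero_dosages_zero_score(self):
        g = _geno(np.zeros((4, 3)))
        res = compute_grs(g, _weights(["v0", "v1", "v2"], [0.5, 1.0, 2.0]))
        np.testing.assert_array_equal(res.scores["grs_raw"], 0.0)

    def test_single_term(self):
        g = _geno([[2.0]])
        res = compute_grs(g, _weights(["v0"], [0.5]))
        assert res.scores["grs_raw"].iloc[0] == 1.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 2, size=(5, 3))
        w = [0.3, -0.2, 1.1]
        res = compute_grs(_geno(d), _weights(["v0", "v1", "v2"], w))
        expected = [sum(w[i] * d[j, i] for i in range(3)) for j in range(5)]
        np.testing.assert_allclose(res.scores["grs_raw"], expected)

    def test_flipped_allele_counts_complement_dosage(self):
        # weight file counts G while the genotype file counted A: dosage -> 2-d
        g = _geno([[2.0], [0.0]])
        w = _weights(["v0"], [1.0], effect="G", other="A")
        res = compute_grs(g, w)
        np.testing.assert_allclose(res.scores["grs_raw"], [0.0, 2.0])
        assert res.report.n_flipped == 1

    def test_strand_flip_resolved_by_complement(self):
        # genotype counted T/other C; weights name A/G = the complements:
        # same variant read off the opposite strand, dosage used as-is
        g = _geno([[2.0], [1.0]], effect="T", other="C")
        w = _weights(["v0"], [1.0], effect="A", other="G")
        res = compute_grs(g, w)
        np.testing.assert_allclose(res.scores["grs_raw"], [2.0, 1.0])
        assert res.report.n_matched == 1 and res.report.n_flipped == 0

    def test_palindromic_mismatch_dropped_as_ambiguous(self):
        # weight alleles A/T are their own strand complement: against a
        # non-matching genotype pair the orientation is undecidable
        g = _geno(np.ones((3, 2)), effect="C", other="G")
        w = pd.DataFrame(
            {
                "variant_id": ["v0", "v1"],
                "effect_allele": ["A", "C"],
                "other_allele": ["T", "G"],
                "weight": [1.0, 1.0],
            }
        )
        with pytest.warns(UserWarning):
            res = compute_grs(g, w)
        # v1 matches directly; v0 is dropped
        assert res.report.n_matched == 1
        assert any("ambiguous" in reason for _, reason in res.report.dropped)

    def test_allele_mismatch_dropped_with_warning(self):
        g = _geno([[1.0], [1.0]], effect="A", other="G")
        w = _weights(["v0"], [1.0], effect="C", other="G")
        with pytest.warns(UserWarning), pytest.raises(ValueError, match="no variants matched"):
            compute_grs(g, w)

    def test_standardized_scores_have_unit_variance(self):
        rng = np.random.default_rng(1)
        res = compute_grs(_geno(rng.integers(0, 3, (50, 4)).astype(float)), _weights([f"v{j}" for j in range(4)], [0.1, 0.2, 0.3, 0.4]))
        z = res.scores["grs_z"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)


def _grs_result(scores, ids=None):
    ids = ids or [f"S{i:03d}" for i in range(len(scores))]
    scores = np.asarray(scores, dtype=float)
    z = (scores - scores.mean()) / (scores.std() or 1.0)
    return GrsResult(
        scores=pd.DataFrame({"sample_id": ids, "grs_raw": scores, "grs_z": z}),
        report=AlignmentReport(),
    )


class TestSelectRecallGroups:
    def test_tail_arithmetic(self):
        ga = select_recall_groups(_grs_result(range(10)), q=0.3)
        counts = ga.assignments["group"].value_counts()
        assert counts["low"] == 3 and counts["high"] == 3 and counts["unselected"] == 4

    def test_separation_without_ties(self):
        rng = np.random.default_rng(2)
        raw = _grs_result(rng.normal(size=101))
        ga = select_recall_groups(raw, q=0.25)
        merged = raw.scores.merge(ga.assignments, on="sample_id")
        assert merged.loc[merged["group"] == "high", "grs_raw"].min() > merged.loc[merged["group"] == "low", "grs_raw"].max()

    def test_all_ties_resolved_by_sample_id(self):
        ga = select_recall_groups(_grs_result([1.0] * 6), q=0.5)
        got = ga.assignments.set_index("sample_id")["group"]
        assert list(got.loc[["S000", "S001", "S002"]]) == ["low"] * 3
        assert list(got.loc[["S003", "S004", "S005"]]) == ["high"] * 3

    def test_too_small_selection_rejected(self):
        with pytest.raises(ValueError):
            select_recall_groups(_grs_result([1.0, 2.0]), q=0.3)

    def test_cap_takes_most_extreme(self):
        ga = select_recall_groups(_grs_result(range(20)), q=0.5, n_per_group=2)
        got = ga.assignments.set_index("sample_id")["group"]
        assert set(got[got == "low"].index) == {"S000", "S001"}
        assert set(got[got == "high"].index) == {"S018", "S019"}

    def test_simulated_tail_difference_matches_closed_form(self, study):
        """Standardized BMI difference between the 30% tails of a score with
        r2 = 0.06 should match 2*sqrt(r2)*phi(Phi^-1(0.7))/0.3."""
        groups = select_recall_groups(study.grs, q=0.3)  # full tails
        pheno = study.phenotypes.data.set_index("sample_id")
        low = pheno.loc[groups.ids("low"), "bmi"]
        high = pheno.loc[groups.ids("high"), "bmi"]
        sd = pheno["bmi"].std()
        d = (high.mean() - low.mean()) / sd
        expected = expected_tail_difference(0.3, 0.06)
        n = len(low)
        # MC standard error of a difference of two tail means (unit SD scale)
        se = math.sqrt(2.0 / n)
        assert abs(d - expected) < 3 * se


class TestCharacterizeGroups:
    def test_published_sex_table_or_and_p(self):
        # counts low (M=148, F=225) vs high (M=150, F=227) give OR ~ 1, p ~ 1
        table = np.array([[150, 227], [148, 225]])
        f = fisher_comparison(table)
        assert f["estimate"] == pytest.approx(1.00, abs=0.01)
        assert f["p"] == pytest.approx(1.00, abs=0.01)
        assert f["ci_low"] < 1.0 < f["ci_high"]

    def test_identical_groups_no_difference(self):
        x = np.concatenate([np.arange(20.0), np.arange(20.0)])
        pheno = PhenotypeTable(
            data=pd.DataFrame({"sample_id": [f"S{i}" for i in range(40)], "bmi": x})
        )
        ga = GroupAssignment(
            assignments=pd.DataFrame(
                {"sample_id": [f"S{i}" for i in range(40)], "group": ["low"] * 20 + ["high"] * 20}
            ),
            q=0.5,
        )
        out = characterize_groups(pheno, ga, continuous=("bmi",), categorical=())
        assert out["estimate"].iloc[0] == 0.0
        assert out["p_welch"].iloc[0] == pytest.approx(1.0)

    def test_welch_effect_equals_difference_of_means(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 45)
        w = welch_comparison(a, b)
        assert w["estimate"] == pytest.approx(b.mean() - a.mean(), abs=1e-14)
        # cross-check p against scipy's Welch test
        t = stats.ttest_ind(b, a, equal_var=False)
        assert w["p"] == pytest.approx(t.pvalue, rel=1e-10)

    def test_fisher_or_close_to_cross_product_on_balanced_table(self):
        table = np.array([[120, 180], [150, 160]])
        f = fisher_comparison(table)
        cross = (120 * 160) / (180 * 150)
        assert f["estimate"] == pytest.approx(cross, abs=0.005)

    def test_sex_combined_difference_from_stratified_summary(self):
        """Recombining sex-stratified summaries must reproduce the combined
        mean difference (oracle: direct concatenation)."""
        rng = np.random.default_rng(4)
        m_low, f_low = rng.normal(23.8, 3.5, 148), rng.normal(23.1, 3.8, 222)
        m_high, f_high = rng.normal(26.2, 4.7, 150), rng.normal(26.1, 5.6, 223)
        mean_low, sd_low = combine_sex_strata(
            [148, 222], [m_low.mean(), f_low.mean()], [m_low.std(ddof=1), f_low.std(ddof=1)]
        )
        all_low = np.concatenate([m_low, f_low])
        assert mean_low == pytest.approx(all_low.mean(), rel=1e-12)
        assert sd_low == pytest.approx(all_low.std(ddof=1), rel=1e-12)
        mean_high, _ = combine_sex_strata(
            [150, 223], [m_high.mean(), f_high.mean()], [m_high.std(ddof=1), f_high.std(ddof=1)]
        )
        assert mean_high - mean_low == pytest.approx(
            np.concatenate([m_high, f_high]).mean() - all_low.mean(), rel=1e-12
        )

    def test_shapiro_gate_labels_skewed_trait_rank_based(self):
        rng = np.random.default_rng(5)
        skewed = np.exp(rng.normal(0, 1.5, 300))
        pheno = PhenotypeTable(
            data=pd.DataFrame({"sample_id": [f"S{i}" for i in range(300)], "x": skewed})
        )
        ga = GroupAssignment(
            assignments=pd.DataFrame(
                {"sample_id": [f"S{i}" for i in range(300)], "group": ["low"] * 150 + ["high"] * 150}
            ),
            q=0.5,
        )
        out = characterize_groups(pheno, ga, continuous=("x",), categorical=())
        assert out["shapiro_w"].iloc[0] < 0.90
        assert out["primary_test"].iloc[0] == "wilcoxon"
        assert out["p"].iloc[0] == out["p_wilcoxon"].iloc[0]


class TestTrajectories:
    def _ga(self, n):
        return GroupAssignment(
            assignments=pd.DataFrame(
                {"sample_id": [f"S{i}" for i in range(n)], "group": ["low"] * (n // 2) + ["high"] * (n - n // 2)}
            ),
            q=0.5,
        )

    def test_single_time_point_single_row(self):
        rng = np.random.default_rng(6)
        series = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(20)], "age": 7.0, "bmi": rng.normal(17, 2, 20)}
        )
        out = trajectory_differences(series, self._ga(20))
        assert len(out) == 1 and out["age"].iloc[0] == 7.0

    def test_null_differences_fluctuate_around_zero(self):
        rng = np.random.default_rng(7)
        ages = [4.0, 8.0, 12.0, 16.0, 20.0, 24.0]
        frames = [
            pd.DataFrame({"sample_id": [f"S{i}" for i in range(400)], "age": a, "bmi": rng.normal(20, 3, 400)})
            for a in ages
        ]
        out = trajectory_differences(pd.concat(frames), self._ga(400))
        assert np.abs(out["estimate"]).max() < 1.0
        assert ((out["ci_low"] <= 0) & (out["ci_high"] >= 0)).mean() >= 0.5

    def test_ramped_profile_monotone_trend(self, study):
        import dataclasses

        from rbgmet import simulate_phenotypes, simulate_snp_weights

        cfg = dataclasses.replace(
            study.config,
            age_effect_profile={4.0: 0.1, 10.0: 0.4, 17.0: 0.7, 24.0: 1.0},
        )
        pheno = simulate_phenotypes(study.genotypes, study.weights, cfg)
        out = trajectory_differences(pheno.bmi_series, study.groups)
        d = out["estimate"].to_numpy() / out["estimate"].to_numpy()[-1]
        assert all(b > a for a, b in zip(d, d[1:]))
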