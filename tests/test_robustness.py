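"""Tests of the extended analyses: adjustment, resampling, clustering,
measured-BMI models, and diet post hoc tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbgmet.grs import GroupAssignment
from rbgmet.qc import MetaboliteMatrix
from rbgmet.robustness import (
    cluster_associated,
    diet_associations,
    fit_adjusted_group_model,
    fit_bmi_models,
    iterative_resampling,
)


def _groups(n_low, n_high, prefix="S"):
    ids = [f"{prefix}{i:04d}" for i in range(n_low + n_high)]
    return ids, GroupAssignment(
        assignments=pd.DataFrame({"sample_id": ids, "group": ["low"] * n_low + ["high"] * n_high}),
        q=0.3,
    )


def _tmat(arr, ids, names=None):
    names = names or [f"m{j}" for j in range(arr.shape[1])]
    return MetaboliteMatrix(data=pd.DataFrame(arr, index=ids, columns=names), state="transformed")


class TestAdjustedModel:
    def test_irrelevant_covariate_leaves_beta_unchanged(self):
        rng = np.random.default_rng(0)
        ids, ga = _groups(100, 100)
        g = np.r_[np.zeros(100), np.ones(100)]
        y = 0.4 * g + rng.normal(0, 1, 200)
        pheno = pd.DataFrame({"sample_id": ids, "noise": rng.normal(size=200)})
        vals = pd.Series(y, index=ids, name="m")
        adj = fit_adjusted_group_model(vals, ga, pheno, ["noise"])
        unadj = fit_adjusted_group_model(vals, ga, pheno, [])
        assert adj.effect("group")["estimate"] == pytest.approx(
            unadj.effect("group")["estimate"], abs=0.02
        )

    def test_confounder_adjustment_recovers_direct_effect(self):
        # confounder drives both group membership and metabolite
        rng = np.random.default_rng(1)
        n = 2000
        conf = rng.normal(size=n)
        group = (conf + rng.normal(size=n) > 0).astype(float)
        direct = 0.3
        y = direct * group + 0.8 * conf + rng.normal(size=n)
        ids = [f"S{i:04d}" for i in range(n)]
        ga = GroupAssignment(
            assignments=pd.DataFrame(
                {"sample_id": ids, "group": np.where(group == 1, "high", "low")}
            ),
            q=0.5,
        )
        pheno = pd.DataFrame({"sample_id": ids, "conf": conf})
        vals = pd.Series(y, index=ids, name="m")
        raw = fit_adjusted_group_model(vals, ga, pheno, []).effect("group")["estimate"]
        adj = fit_adjusted_group_model(vals, ga, pheno, ["conf"]).effect("group")["estimate"]
        assert abs(adj - direct) < abs(raw - direct)
        assert adj == pytest.approx(direct, abs=0.15)

    def test_weak_confounding_keeps_estimates_correlated(self, study):
        """With weak confounding, adjusted and unadjusted effects across the
        discoveries stay near-identical (correlation >= 0.99)."""
        pheno = study.recalled_phenotypes.data
        raw_b, adj_b = [], []
        for met in study.hit_ids:
            vals = study.qc.transformed.data[met]
            raw_b.append(fit_adjusted_group_model(vals, study.groups, pheno, []).effect("group")["estimate"])
            adj_b.append(
                fit_adjusted_group_model(vals, study.groups, pheno, ["social_class"]).effect("group")["estimate"]
            )
        r = np.corrcoef(raw_b, adj_b)[0, 1]
        assert r >= 0.99

    def test_collinear_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        ids, ga = _groups(30, 30)
        x = rng.normal(size=60)
        pheno = pd.DataFrame({"sample_id": ids, "a": x, "b": 2 * x})
        vals = pd.Series(rng.normal(size=60), index=ids, name="m")
        with pytest.warns(UserWarning, match="collinear"):
            res = fit_adjusted_group_model(vals, ga, pheno, ["a", "b"])
        assert "b" not in res.effects.index


class TestIterativeResampling:
    def test_threshold_unreachable_rejected(self):
        rng = np.random.default_rng(3)
        ids, ga = _groups(20, 20)
        tm = _tmat(rng.normal(size=(40, 3)), ids)
        with pytest.raises(ValueError, match="unreachable"):
            iterative_resampling(tm, ga, n_iterations=10, instance_threshold=20)

    def test_joint_bounded_by_components_and_deterministic(self):
        rng = np.random.default_rng(4)
        ids, ga = _groups(60, 60)
        arr = rng.normal(size=(120, 8))
        arr[:, 0] += np.r_[np.zeros(60), np.full(60, 0.8)]
        tm = _tmat(arr, ids)
        a = iterative_resampling(tm, ga, n_iterations=25, instance_threshold=5, seed=9)
        b = iterative_resampling(tm, ga, n_iterations=25, instance_threshold=5, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)
        t = a.table
        assert (t["joint"] <= np.minimum(t["discovery"], t["replication"])).all()
        assert (t["discovery"] <= 25).all()

    def test_null_gives_no_joint_instances(self):
        rng = np.random.default_rng(5)
        ids, ga = _groups(375, 375)
        tm = _tmat(rng.normal(size=(750, 10)), ids)
        res = iterative_resampling(tm, ga, n_iterations=50, instance_threshold=20, seed=1)
        assert res.table["joint"].sum() <= 2
        assert not res.table["robust"].any()

    def test_strong_effect_joint_saturates(self):
        # R^2 ~ 0.3 at 375/group: each half-sample is still overwhelmingly powered
        rng = np.random.default_rng(6)
        ids, ga = _groups(375, 375)
        g = np.r_[np.zeros(375), np.ones(375)]
        arr = rng.normal(size=(750, 4))
        arr[:, 0] = np.sqrt(0.3) * (g - 0.5) * 2 + np.sqrt(0.7) * rng.normal(size=750)
        tm = _tmat(arr, ids)
        res = iterative_resampling(tm, ga, n_iterations=100, instance_threshold=20, seed=2)
        assert res.table.loc[res.table["metabolite_id"] == "m0", "joint"].iloc[0] >= 95
        assert res.table.loc[res.table["metabolite_id"] == "m0", "robust"].iloc[0]

    def test_counts_rank_correlate_with_primary_p(self, study):
        """Joint-instance counts track the primary-analysis p ranking."""
        from rbgmet.association import model1_closed_form

        sub = study.qc.transformed.data[study.hit_ids]
        tm = MetaboliteMatrix(data=sub, state="transformed")
        res = iterative_resampling(tm, study.groups, n_iterations=40, instance_threshold=20, seed=3)
        sel = study.groups.assignments[study.groups.assignments["group"].isin(["low", "high"])]
        gmap = dict(zip(sel["sample_id"], sel["group"]))
        ids = [s for s in sel["sample_id"] if s in sub.index]
        g = np.array([1.0 if gmap[s] == "high" else 0.0 for s in ids])
        _, _, p, _ = model1_closed_form(sub.loc[ids].to_numpy(), g)
        rho = stats.spearmanr(-np.log10(p), res.table["joint"]).statistic
        assert rho > 0.6


class TestClustering:
    def test_uncorrelated_hits_all_singletons(self):
        rng = np.random.default_rng(7)
        ids = [f"S{i:04d}" for i in range(400)]
        tm = _tmat(rng.normal(size=(400, 6)), ids)
        ca = cluster_associated(tm)
        assert ca.n_clusters == 6
        assert len(ca.representatives()) == 6

    def test_planted_block_recovered(self, study):
        """The planted 11-member block among the 29 hits comes back as one
        cluster with its representative inside, and the full partition has
        15 clusters (11 + 4 + 2 + 12 singletons)."""
        tm = study.qc.transformed
        ca = cluster_associated(tm, study.hit_ids)
        t = ca.table.merge(
            study.truth.reset_index()[["metabolite_id", "cluster"]].rename(columns={"cluster": "true_cluster"}),
            on="metabolite_id",
        )
        # every planted multi-member cluster maps to exactly one found cluster
        for true_c, sub in t[t["true_cluster"].notna()].groupby("true_cluster"):
            assert sub["cluster"].nunique() == 1, f"planted cluster {true_c} split"
        sizes = t.groupby("cluster").size().sort_values(ascending=False).tolist()
        assert sizes[0] == 11
        assert ca.n_clusters == 15
        # representative of the big block is a member of it
        big = t[t["true_cluster"] == 1.0]
        assert t.loc[t["representative"] & t["metabolite_id"].isin(big["metabolite_id"])].shape[0] == 1

    def test_invariant_to_order_and_sign_flips(self):
        rng = np.random.default_rng(8)
        n = 300
        f = rng.normal(size=n)
        arr = np.column_stack(
            [f + 0.3 * rng.normal(size=n) for _ in range(3)]
            + [rng.normal(size=n) for _ in range(3)]
        )
        ids = [f"S{i:04d}" for i in range(n)]
        tm1 = _tmat(arr, ids)
        ca1 = cluster_associated(tm1)
        # flip signs of two columns and permute column order
        arr2 = arr.copy()
        arr2[:, 0] *= -1
        arr2[:, 4] *= -1
        perm = [5, 2, 0, 3, 1, 4]
        tm2 = MetaboliteMatrix(
            data=pd.DataFrame(arr2[:, perm], index=ids, columns=[f"m{j}" for j in perm]),
            state="transformed",
        )
        ca2 = cluster_associated(tm2)

        def partition(ca):
            t = ca.table
            return {frozenset(sub["metabolite_id"]) for _, sub in t.groupby("cluster")}

        assert partition(ca1) == partition(ca2)

    def test_constant_metabolite_excluded_with_warning(self):
        rng = np.random.default_rng(9)
        ids = [f"S{i:04d}" for i in range(50)]
        arr = np.column_stack([rng.normal(size=50), np.zeros(50), rng.normal(size=50)])
        tm = _tmat(arr, ids)
        with pytest.warns(UserWarning, match="constant"):
            ca = cluster_associated(tm)
        assert "m1" not in set(ca.table["metabolite_id"])


class TestBmiModels:
    def _data(self, slope_low, slope_high, n=400, seed=10):
        rng = np.random.default_rng(seed)
        ids, ga = _groups(n // 2, n // 2)
        g = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        bmi = rng.normal(25, 4, n) + 1.5 * g
        sex = rng.choice(["M", "F"], n)
        age = rng.normal(24.5, 0.8, n)
        slope = np.where(g == 0, slope_low, slope_high)
        y = slope * bmi + 0.2 * (sex == "M") + rng.normal(0, 1, n)
        pheno = pd.DataFrame({"sample_id": ids, "bmi": bmi, "sex": sex, "age": age})
        return pd.Series(y, index=ids, name="m"), ga, pheno

    def test_interaction_null_p_uniform(self):
        """With a common BMI slope the interaction p value is uniform."""
        ps = []
        for seed in range(60):
            y, ga, pheno = self._data(0.1, 0.1, n=200, seed=seed)
            res = fit_bmi_models(y, ga, pheno, mode="interaction")
            ps.append(res.interaction_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_interaction_detected_vs_f_oracle(self):
        """Product-term t-test agrees with the nested-model F test."""
        import statsmodels.api as sm

        y, ga, pheno = self._data(0.05, 0.25, n=600, seed=99)
        res = fit_bmi_models(y, ga, pheno, mode="interaction")
        # brute-force nested F
        df = pheno.set_index("sample_id")
        g = (ga.assignments.set_index("sample_id").loc[df.index, "group"] == "high").astype(float)
        X0 = sm.add_constant(
            pd.DataFrame(
                {"bmi": df["bmi"], "g": g, "sex": (df["sex"] == "M").astype(float), "age": df["age"]}
            )
        )
        X1 = X0.copy()
        X1["bmi:g"] = X0["bmi"] * g
        f0 = sm.OLS(y.loc[df.index], X0).fit()
        f1 = sm.OLS(y.loc[df.index], X1).fit()
        fres = f1.compare_f_test(f0)
        assert res.interaction_p == pytest.approx(fres[1], rel=1e-6)
        assert res.interaction_p < 0.01

    def test_interaction_reduces_to_additive_when_constrained(self):
        y, ga, pheno = self._data(0.15, 0.15, n=300, seed=5)
        add = fit_bmi_models(y, ga, pheno, mode="additive")
        inter = fit_bmi_models(y, ga, pheno, mode="interaction")
        # additive model == interaction model with the product coefficient at 0:
        # dropping a near-zero product term barely moves the BMI effect
        assert inter.effects.loc["bmi:group", "p"] > 0.05
        assert add.effect("bmi")["estimate"] == pytest.approx(
            inter.effect("bmi")["estimate"], abs=0.05
        )

    def test_per_group_slopes(self):
        y, ga, pheno = self._data(0.05, 0.3, n=800, seed=12)
        out = fit_bmi_models(y, ga, pheno, mode="per_group")
        assert out["low"].effect("bmi")["estimate"] == pytest.approx(0.05, abs=0.05)
        assert out["high"].effect("bmi")["estimate"] == pytest.approx(0.3, abs=0.05)

    def test_directional_concordance_under_mediation(self, study):
        """Generated under score -> BMI -> metabolite, the measured-BMI
        effect sign agrees with the group-effect sign for nearly all hits."""
        from rbgmet.association import fit_model1

        pheno = study.recalled_phenotypes.data
        agree = 0
        for met in study.hit_ids:
            vals = study.qc.transformed.data[met]
            grp_sign = np.sign(fit_model1(vals, study.groups).effect)
            bmi_sign = np.sign(
                fit_bmi_models(vals, study.groups, pheno, mode="additive").effect("bmi")["estimate"]
            )
            agree += grp_sign == bmi_sign
        assert agree / len(study.hit_ids) >= 14 / 15


class TestDietAssociations:
    def _pheno(self, n, link=0.0, sex_link=0.0, seed=20):
        rng = np.random.default_rng(seed)
        ids = [f"S{i:04d}" for i in range(n)]
        sex = rng.choice(["M", "F"], n, p=[0.4, 0.6])
        latent = rng.normal(size=n) + sex_link * (sex == "M")
        pref = np.clip(np.digitize(latent, [-1.2, -0.4, 0.4, 1.2]) + 1, 1, 5)
        met = link * pref + sex_link * (sex == "M") + rng.normal(size=n)
        pheno = pd.DataFrame({"sample_id": ids, "sex": sex, "pref_fish": pref})
        tm = MetaboliteMatrix(data=pd.DataFrame({"pfos": met}, index=ids), state="transformed")
        return ids, pheno, tm

    def test_null_preference_group_p_roughly_uniform(self):
        ps = []
        for seed in range(40):
            ids, pheno, tm = self._pheno(300, seed=seed)
            ga = GroupAssignment(
                assignments=pd.DataFrame({"sample_id": ids, "group": ["low"] * 150 + ["high"] * 150}),
                q=0.3,
            )
            out = diet_associations(pheno, ga, tm, ["pref_fish"], ["pfos"])
            ps.append(out["group_tests"]["p_wilcoxon"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_link_recovered_and_attenuated_by_adjustment(self):
        """A sex-confounded preference-metabolite link attenuates once sex
        enters the model."""
        ids, pheno, tm = self._pheno(800, link=0.25, sex_link=0.8, seed=42)
        ga = GroupAssignment(
            assignments=pd.DataFrame({"sample_id": ids, "group": ["low"] * 400 + ["high"] * 400}),
            q=0.3,
        )
        out = diet_associations(pheno, ga, tm, ["pref_fish"], ["pfos"])
        row = out["metabolite_tests"].iloc[0]
        assert row["slope"] > 0 and row["p"] < 1e-4
        assert abs(row["slope_adjusted"]) < abs(row["slope"])

    def test_constant_preference_skipped(self):
        ids, pheno, tm = self._pheno(100, seed=1)
        pheno["pref_fish"] = 3
        ga = GroupAssignment(
            assignments=pd.DataFrame({"sample_id": ids, "group": ["low"] * 50 + ["high"] * 50}),
            q=0.3,
        )
        with pytest.warns(UserWarning, match="constant"):
            out = diet_associations(pheno, ga, tm, ["pref_fish"], ["pfos"])
        assert out["group_tests"].empty
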