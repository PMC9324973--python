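#!/usr/bin/env python
"""Robustness of the primary associations.

Runs the split-half resampling over the transformed panel's discoveries,
collapses correlated hits into representative clusters, relates the
representatives to measured BMI, and tests dietary preferences."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from rbgmet.association import fit_model1, run_associations, summarize_associations
from rbgmet.qc import MetaboliteMatrix
from rbgmet.robustness import (
    cluster_associated,
    diet_associations,
    fit_adjusted_group_model,
    fit_bmi_models,
    iterative_resampling,
)


def main() -> None:
    s = common.get_study()
    qc = common.get_qc()
    rd = common.results_dir()
    results = run_associations(qc.transformed, qc.presence_absence, qc.raw_filtered, s.groups)
    hits = summarize_associations(results)["hits"]
    hit_ids = hits.loc[hits["model"] == "model1", "metabolite_id"].tolist()
    pheno = s.recalled_phenotypes.data

    # confounder adjustment: social class alongside group
    raw_b, adj_b = [], []
    for met in hit_ids:
        vals = qc.transformed.data[met]
        raw_b.append(fit_model1(vals, s.groups).effect)
        adj_b.append(fit_adjusted_group_model(vals, s.groups, pheno, ["social_class"]).effect("group")["estimate"])
    r = np.corrcoef(raw_b, adj_b)[0, 1]
    print(f"adjusted vs unadjusted group effects over {len(hit_ids)} discoveries: r = {r:.3f}")

    # split-half resampling on the discoveries
    sub = MetaboliteMatrix(data=qc.transformed.data[hit_ids], state="transformed")
    res = iterative_resampling(sub, s.groups, n_iterations=100, instance_threshold=20, seed=common.SEED)
    res.table.to_csv(rd / "06_resampling.tsv", sep="\t", index=False)
    print(f"robust (>= 20 joint discovery+replication instances of 100): "
          f"{int(res.table['robust'].sum())}/{len(res.table)}")

    # redundancy clustering with representatives
    ca = cluster_associated(qc.transformed, hit_ids)
    ca.table.to_csv(rd / "06_clusters.tsv", sep="\t", index=False)
    sizes = ca.table.groupby("cluster").size().sort_values(ascending=False)
    print(f"clusters among discoveries: {ca.n_clusters} (largest {sizes.iloc[0]}, "
          f"{int((sizes == 1).sum())} singletons)")

    # measured-BMI models for the representatives
    rows = []
    for met in ca.representatives():
        add = fit_bmi_models(qc.transformed.data[met], s.groups, pheno, mode="additive")
        inter = fit_bmi_models(qc.transformed.data[met], s.groups, pheno, mode="interaction")
        grp_sign = np.sign(fit_model1(qc.transformed.data[met], s.groups).effect)
        bmi = add.effect("bmi")
        rows.append(
            {
                "metabolite_id": met,
                "bmi_beta": bmi["estimate"],
                "p": bmi["p"],
                "interaction_p": inter.interaction_p,
                "concordant_with_group_effect": bool(np.sign(bmi["estimate"]) == grp_sign),
            }
        )
    bmi_tab = pd.DataFrame(rows)
    bmi_tab.to_csv(rd / "06_bmi_models.tsv", sep="\t", index=False, float_format="%.4g")
    print(f"representatives associated with measured BMI (p < 0.05): "
          f"{int((bmi_tab['p'] < 0.05).sum())}/{len(bmi_tab)}; "
          f"directionally concordant: {int(bmi_tab['concordant_with_group_effect'].sum())}/{len(bmi_tab)}")

    # diet post hoc tests on the first few representatives
    diet = diet_associations(pheno, s.groups, qc.transformed,
                             ["pref_fish", "pref_fruit", "pref_veg"], ca.representatives()[:3])
    diet["group_tests"].to_csv(rd / "06_diet_group.tsv", sep="\t", index=False, float_format="%.4g")
    diet["metabolite_tests"].to_csv(rd / "06_diet_metabolites.tsv", sep="\t", index=False, float_format="%.4g")
    print("diet preferences vs group (Wilcoxon p): "
          + ", ".join(f"{r.preference}={r.p_wilcoxon:.2f}" for r in diet["group_tests"].itertuples()))
    print(f"\nwrote resampling/cluster/BMI-model/diet tables under {rd}")


if __name__ == "__main__":
    main()
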