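"""Shared fixtures: a study-scale synthetic cohort generated once per session.

The cohort mirrors the design the pipeline targets: an eligible pool of
1,250 genotyped individuals with samples, a 940-variant weighted score
explaining 6% of BMI variance, recall of the full 30% tails (375 per
group), and a 1,216-metabolite metabolome on the recalled samples with 29
planted BMI effects (cluster sizes 11 + 4 + 2 + 12 singletons, 25 negative
/ 4 positive).
"""

from __future__ import annotations

import dataclasses
from types import SimpleNamespace

import pytest
from hypothesis import settings

from rbgmet import (
    SimulationConfig,
    compute_grs,
    default_metabolome_spec,
    select_recall_groups,
    simulate_genotypes,
    simulate_metabolome,
    simulate_phenotypes,
    simulate_snp_weights,
)
from rbgmet.qc import MetaboliteMatrix, run_qc
from rbgmet.simulate import PhenotypeTable

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study():
    """Full synthetic study: cohort, score, recall groups, metabolome, QC."""
    cfg = SimulationConfig(n_individuals=1250, n_snps=940, r2_grs_bmi=0.06, seed=STUDY_SEED)
    weights = simulate_snp_weights(cfg)
    geno = simulate_genotypes(cfg, weights)
    pheno = simulate_phenotypes(geno, weights, cfg)
    grs = compute_grs(geno, weights)
    groups = select_recall_groups(grs, q=0.3)  # full tails: 375 per group
    recalled = sorted(groups.ids("low") + groups.ids("high"))

    spec = default_metabolome_spec(n_samples_hint=len(recalled), seed=12345)
    sub_pheno = PhenotypeTable(
        data=pheno.data[pheno.data["sample_id"].isin(recalled)].reset_index(drop=True)
    )
    metab = simulate_metabolome(sub_pheno, dataclasses.replace(cfg, metabolite_spec=spec))
    qcres = run_qc(
        MetaboliteMatrix(data=metab.abundance, state="raw"),
        metab.annotation,
        impute_method="median",
        seed=5,
    )
    truth = metab.truth.set_index("metabolite_id")
    hit_ids = truth.index[truth["r2_met_bmi"].abs() > 0].tolist()
    hit_ids_m1 = [m for m in hit_ids if m in qcres.transformed.data.columns]
    return SimpleNamespace(
        config=cfg,
        weights=weights,
        genotypes=geno,
        phenotypes=pheno,
        recalled_phenotypes=sub_pheno,
        grs=grs,
        groups=groups,
        metabolome=metab,
        qc=qcres,
        truth=truth,
        hit_ids=hit_ids_m1,
    )
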