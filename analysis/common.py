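"""Shared study construction for the numbered analysis drivers.

Every driver rebuilds the same deterministic synthetic study in memory
(seed 2024): an eligible pool of 1,250 with a 940-variant weighted score
explaining 6% of BMI variance, recall of the full 30% tails (375 per
group), and a 1,216-metabolite panel on the recalled samples with 29
planted BMI effects. Large intermediates stay in memory; drivers write
only summary tables under results/.
"""

from __future__ import annotations

import dataclasses
import functools
from pathlib import Path
from types import SimpleNamespace

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

SEED = 2024
RESULTS = Path(__file__).resolve().parent.parent / "results"

AGE_PROFILE = {0.5: 0.0, 4.0: 0.05, 7.0: 0.25, 10.0: 0.45, 13.0: 0.75, 17.0: 0.85, 20.0: 0.95, 24.0: 1.0}


@functools.lru_cache(maxsize=1)
def get_study() -> SimpleNamespace:
    cfg = SimulationConfig(
        n_individuals=1250,
        n_snps=940,
        r2_grs_bmi=0.06,
        age_effect_profile=tuple(AGE_PROFILE.items()),  # hashable; rebuilt below
        seed=SEED,
    )
    cfg = dataclasses.replace(cfg, age_effect_profile=dict(AGE_PROFILE))
    weights = simulate_snp_weights(cfg)
    geno = simulate_genotypes(cfg, weights)
    pheno = simulate_phenotypes(geno, weights, cfg)
    grs = compute_grs(geno, weights)
    groups = select_recall_groups(grs, q=0.3)  # full tails: 375 per group
    recalled = sorted(groups.ids("low") + groups.ids("high"))
    spec = default_metabolome_spec(n_samples_hint=len(recalled), seed=SEED + 1)
    sub = PhenotypeTable(data=pheno.data[pheno.data["sample_id"].isin(recalled)].reset_index(drop=True))
    metab = simulate_metabolome(sub, dataclasses.replace(cfg, metabolite_spec=spec))
    return SimpleNamespace(
        config=cfg,
        weights=weights,
        genotypes=geno,
        phenotypes=pheno,
        recalled_phenotypes=sub,
        grs=grs,
        groups=groups,
        metabolome=metab,
        truth=metab.truth.set_index("metabolite_id"),
    )


@functools.lru_cache(maxsize=1)
def get_qc():
    s = get_study()
    return run_qc(
        MetaboliteMatrix(data=s.metabolome.abundance, state="raw"),
        s.metabolome.annotation,
        impute_method="median",
        seed=SEED + 2,
    )


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
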