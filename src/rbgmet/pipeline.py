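"""End-to-end orchestration: score -> recall -> characterize -> QC ->
association -> power -> robustness, with a reconciling run manifest.

A run starts either from files (genotypes + weights + phenotypes +
abundances + annotation) or from a synthetic configuration, in which case
the generator writes the same files first so the whole file interface is
exercised. A single global seed fans out to per-stage seeds derived from
stage names, so each stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import grs as grsmod
from . import io, power, qc, robustness, simulate

log = logging.getLogger("rbgmet")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2^31 from the global seed."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; round-trips through YAML."""

    out_dir: str = "results/run"
    seed: int = 0
    # inputs: either paths ...
    genotypes: str | None = None
    weights: str | None = None
    phenotypes: str | None = None
    abundance: str | None = None
    annotation: str | None = None
    # ... or a synthetic cohort
    synthetic: dict | None = None
    n_metabolites_synthetic: int | None = None  # None -> study-scale 1216
    recall_fraction: float = 0.3
    n_per_group: int | None = None
    miss_threshold: float = 0.20
    presence_min: int = 11
    sample_miss_threshold: float = 0.5
    outlier_sd: float = 5.0
    impute_method: str = "forest"
    alpha: float = 0.05
    resampling_iterations: int = 100
    cluster_cut: float = 0.5
    run_robustness: bool = True

    def validate(self) -> None:
        if not 0.0 < self.recall_fraction <= 0.5:
            raise ValueError("recall_fraction must be in (0, 0.5]")
        if not 0.0 <= self.miss_threshold < 1.0:
            raise ValueError("miss_threshold must be in [0, 1)")
        if self.presence_min < 1:
            raise ValueError("presence_min must be >= 1")
        if self.impute_method not in ("forest", "median"):
            raise ValueError("impute_method must be 'forest' or 'median'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.synthetic is None and not all(
            (self.genotypes, self.weights, self.phenotypes, self.abundance, self.annotation)
        ):
            raise ValueError("provide either `synthetic` or all five input paths")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Stage-by-stage record counts; ``complete`` only when every stage ran
    and the counts reconcile."""

    config_hash: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)
    complete: bool = False

    def record(self, stage: str, n_in: int, n_out: int, **extra) -> None:
        self.stages.append({"stage": stage, "n_in": n_in, "n_out": n_out, **extra})
        log.info("stage %-16s in=%d out=%d %s", stage, n_in, n_out, extra or "")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.manifest = manifest


def _synthetic_inputs(cfg: RunConfig, out: Path) -> dict[str, Path]:
    """Generate the synthetic cohort and write every input file.

    The metabolome is generated *after* recall on the recalled samples only
    (a recall study assays only the recalled samples), so the generator's
    intended QC dispositions refer to the assayed set.
    """
    sim_kwargs = dict(cfg.synthetic or {})
    specs = sim_kwargs.pop("metabolite_spec", None)
    scfg = simulate.SimulationConfig(seed=stage_seed(cfg.seed, "simulate"), **sim_kwargs)
    weights = simulate.simulate_snp_weights(scfg)
    geno = simulate.simulate_genotypes(scfg, weights)
    pheno = simulate.simulate_phenotypes(geno, weights, scfg)

    grs_res = grsmod.compute_grs(geno, weights)
    groups = grsmod.select_recall_groups(grs_res, cfg.recall_fraction, n_per_group=cfg.n_per_group)
    recalled = sorted(groups.ids("low") + groups.ids("high"))
    if specs is None:
        specs = simulate.default_metabolome_spec(
            n_samples_hint=len(recalled), seed=stage_seed(cfg.seed, "metabolome-spec")
        )
    sub_pheno = simulate.PhenotypeTable(
        data=pheno.data[pheno.data["sample_id"].isin(recalled)].reset_index(drop=True),
        bmi_series=pheno.bmi_series,
    )
    scfg_m = dataclasses.replace(scfg, metabolite_spec=tuple(specs))
    metab = simulate.simulate_metabolome(sub_pheno, scfg_m)

    paths = {
        "genotypes": out / "genotypes.tsv",
        "weights": out / "weights.tsv",
        "phenotypes": out / "phenotypes.csv",
        "bmi_series": out / "bmi_series.csv",
        "abundance": out / "abundance.csv",
        "annotation": out / "annotation.csv",
        "truth": out / "generator_truth.tsv",
    }
    io.write_dosage_tsv(geno, paths["genotypes"])
    io.write_weights_tsv(weights, paths["weights"])
    io.write_phenotypes_csv(pheno, paths["phenotypes"], series_path=paths["bmi_series"])
    io.write_abundance_csv(metab.abundance, paths["abundance"])
    io.write_annotation_csv(metab.annotation, paths["annotation"])
    metab.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute every stage, writing all artifacts under ``cfg.out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    from . import __version__

    manifest = RunManifest(config_hash=cfg.digest(), seed=cfg.seed, version=__version__)
    stage = "inputs"
    try:
        if cfg.synthetic is not None:
            paths = _synthetic_inputs(cfg, out)
        else:
            paths = {
                "genotypes": Path(cfg.genotypes),
                "weights": Path(cfg.weights),
                "phenotypes": Path(cfg.phenotypes),
                "abundance": Path(cfg.abundance),
                "annotation": Path(cfg.annotation),
            }
        geno = io.read_genotypes(paths["genotypes"])
        weights = io.read_weights_tsv(paths["weights"])
        pheno = io.read_phenotypes_csv(paths["phenotypes"], series_path=paths.get("bmi_series"))
        abundance = io.read_abundance_csv(paths["abundance"])
        annotation = io.read_annotation_csv(paths["annotation"])
        manifest.record("inputs", len(geno.samples), len(geno.samples), n_metabolites=abundance.shape[1])

        stage = "grs"
        grs_res = grsmod.compute_grs(geno, weights)
        grs_res.scores.to_csv(out / "grs.tsv", sep="\t", index=False)
        manifest.record(
            "grs",
            len(geno.samples),
            len(grs_res.scores),
            n_variants_matched=grs_res.report.n_matched,
            n_flipped=grs_res.report.n_flipped,
            n_dropped=len(grs_res.report.dropped),
        )

        stage = "recall"
        groups = grsmod.select_recall_groups(grs_res, cfg.recall_fraction, n_per_group=cfg.n_per_group)
        groups.assignments.to_csv(out / "groups.tsv", sep="\t", index=False)
        n_recalled = len(groups.ids("low")) + len(groups.ids("high"))
        manifest.record("recall", len(grs_res.scores), n_recalled, q=cfg.recall_fraction)

        stage = "characterize"
        chars = grsmod.characterize_groups(pheno, groups)
        chars.to_csv(out / "group_characteristics.tsv", sep="\t", index=False)
        if pheno.bmi_series is not None:
            traj = grsmod.trajectory_differences(pheno.bmi_series, groups)
            traj.to_csv(out / "bmi_trajectory.tsv", sep="\t", index=False)
        manifest.record("characterize", n_recalled, len(chars))

        stage = "qc"
        raw = qc.MetaboliteMatrix(data=abundance, state="raw")
        qcres = qc.run_qc(
            raw,
            annotation,
            miss_threshold=cfg.miss_threshold,
            presence_min=cfg.presence_min,
            sample_miss_threshold=cfg.sample_miss_threshold,
            outlier_sd=cfg.outlier_sd,
            impute_method=cfg.impute_method,
            seed=stage_seed(cfg.seed, "impute"),
        )
        qcres.plan.table.to_csv(out / "qc_plan.tsv", sep="\t", index=False)
        qcres.transformed.data.to_csv(out / "metabolites_transformed.tsv", sep="\t")
        qcres.presence_absence.to_csv(out / "metabolites_pa.tsv", sep="\t")
        disposition_counts = qcres.plan.table["disposition"].value_counts().to_dict()
        with open(out / "qc_report.json", "w") as fh:
            json.dump(
                {
                    "n_samples_in": int(abundance.shape[0]),
                    "n_samples_retained": len(qcres.retained_samples),
                    "dispositions": disposition_counts,
                },
                fh,
                indent=2,
            )
        manifest.record(
            "qc",
            abundance.shape[0],
            len(qcres.retained_samples),
            **{f"n_{k}": int(v) for k, v in disposition_counts.items()},
        )

        stage = "association"
        results = assoc.run_associations(qcres.transformed, qcres.presence_absence, qcres.raw_filtered, groups)
        results.to_csv(out / "associations.tsv", sep="\t", index=False)
        summary = assoc.summarize_associations(results, alpha=cfg.alpha)
        summary["hits"].to_csv(out / "hits.tsv", sep="\t", index=False)
        summary["volcano"].to_csv(out / "volcano.tsv", sep="\t", index=False)
        manifest.record(
            "association",
            int(results.shape[0]),
            int(results.shape[0]),
            n_hits=int((results["p_adjusted"] < cfg.alpha).sum()),
        )

        stage = "power"
        chars_bmi = chars[chars["variable"] == "bmi"]
        if len(chars_bmi):
            sd_ref = power.pooled_cohort_sd(
                *_cohort_sds(pheno.data)
            )
            d_bmi = power.standardized_bmi_difference(
                float(chars_bmi["mean_low"].iloc[0]), float(chars_bmi["mean_high"].iloc[0]), sd_ref
            )
            n_pg = min(len(groups.ids("low")), len(groups.ids("high")))
            spec = power.DesignPowerSpec(n_per_group=n_pg, r2_met_bmi=0.2, alpha=cfg.alpha, d_bmi=abs(d_bmi))
            grid = np.round(np.arange(0.01, 0.41, 0.01), 2)
            curve = pd.DataFrame({"r2_met_bmi": grid, "power": power.power_curve(spec, grid)})
            curve.to_csv(out / "power_curve.tsv", sep="\t", index=False)
            min_r2 = power.min_r2_for_power(0.8, spec)
            with open(out / "power.json", "w") as fh:
                json.dump(
                    {
                        "d_bmi": d_bmi,
                        "n_per_group": n_pg,
                        "power_at_r2_0.20": power.analytic_power(spec),
                        "min_r2_for_80pct": min_r2,
                    },
                    fh,
                    indent=2,
                )
            manifest.record("power", n_pg, len(curve))

        stage = "robustness"
        if cfg.run_robustness:
            hits_m1 = summary["hits"]
            hit_ids = hits_m1.loc[hits_m1["model"] == "model1", "metabolite_id"].tolist()
            resr = robustness.iterative_resampling(
                qcres.transformed,
                groups,
                n_iterations=cfg.resampling_iterations,
                seed=stage_seed(cfg.seed, "resampling"),
            )
            resr.table.to_csv(out / "resampling.tsv", sep="\t", index=False)
            if len(hit_ids) >= 2:
                clus = robustness.cluster_associated(qcres.transformed, hit_ids, cut_threshold=cfg.cluster_cut)
                clus.table.to_csv(out / "clusters.tsv", sep="\t", index=False)
                bmi_rows = []
                for met in clus.representatives():
                    res = robustness.fit_bmi_models(
                        qcres.transformed.data[met], groups, pheno.data, mode="additive"
                    )
                    row = res.effect("bmi")
                    bmi_rows.append(
                        {
                            "metabolite_id": met,
                            "bmi_beta": row["estimate"],
                            "ci_low": row["ci_low"],
                            "ci_high": row["ci_high"],
                            "p": row["p"],
                        }
                    )
                pd.DataFrame(bmi_rows).to_csv(out / "bmi_models.tsv", sep="\t", index=False)
            manifest.record("robustness", int(qcres.transformed.data.shape[1]), int(len(resr.table)))
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        manifest.to_json(out / "manifest.json")
        raise StageError(stage, manifest, exc) from exc

    manifest.complete = True
    manifest.to_json(out / "manifest.json")
    return manifest


def _cohort_sds(pheno: pd.DataFrame) -> tuple[float, float]:
    """Full-cohort BMI SD per sex (male, female)."""
    m = pheno.loc[pheno["sex"] == "M", "bmi"].std(ddof=1)
    f = pheno.loc[pheno["sex"] == "F", "bmi"].std(ddof=1)
    if np.isnan(m) or np.isnan(f):
        s = pheno["bmi"].std(ddof=1)
        return float(s), float(s)
    return float(m), float(f)


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Schema-check every input file and cross-check sample ids.

    Returns a findings table (file, finding); empty when all checks pass.
    Never raises on malformed content — failures are findings.
    """
    findings: list[dict] = []
    loaded: dict[str, object] = {}
    readers = {
        "genotypes": io.read_genotypes,
        "weights": io.read_weights_tsv,
        "phenotypes": lambda p: io.read_phenotypes_csv(p),
        "abundance": io.read_abundance_csv,
        "annotation": io.read_annotation_csv,
    }
    for key, reader in readers.items():
        path = paths.get(key)
        if path is None:
            continue
        if not Path(path).exists():
            findings.append({"file": str(path), "finding": f"{key}: file not found"})
            continue
        try:
            loaded[key] = reader(path)
        except Exception as exc:  # noqa: BLE001
            findings.append({"file": str(path), "finding": f"{key}: {exc}"})

    if paths.get("abundance") is not None and Path(paths["abundance"]).exists():
        try:
            raw = pd.read_csv(paths["abundance"], index_col="sample_id", dtype=str)
        except Exception:  # noqa: BLE001 - reader finding already recorded
            raw = None
        cell_findings = []
        if raw is not None:
            for col in raw.columns:
                bad = raw[col].dropna()[~raw[col].dropna().str.match(r"^-?\d+(\.\d+)?([eE][+-]?\d+)?$")]
                for sample, val in bad.items():
                    cell_findings.append(
                        {
                            "file": str(paths["abundance"]),
                            "finding": f"non-numeric cell at row {sample!r}, column {col!r}: {val!r}",
                        }
                    )
        if cell_findings:
            # the cell-level findings subsume the generic reader failure
            findings = [f for f in findings if not f["finding"].startswith("abundance:")]
            findings.extend(cell_findings)
    if "genotypes" in loaded and "phenotypes" in loaded:
        gset = set(loaded["genotypes"].samples)
        pset = set(loaded["phenotypes"].data["sample_id"])
        if gset != pset:
            only_g = sorted(gset - pset)[:10]
            only_p = sorted(pset - gset)[:10]
            findings.append(
                {
                    "file": str(paths["phenotypes"]),
                    "finding": f"sample-id mismatch: genotypes-only={only_g}, phenotypes-only={only_p}",
                }
            )
    if "abundance" in loaded and "annotation" in loaded:
        aset = set(loaded["abundance"].columns)
        nset = set(loaded["annotation"]["metabolite_id"])
        if not aset.issubset(nset):
            findings.append(
                {
                    "file": str(paths["annotation"]),
                    "finding": f"metabolites lacking annotation: {sorted(aset - nset)[:10]}",
                }
            )
    return pd.DataFrame(findings, columns=["file", "finding"])
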