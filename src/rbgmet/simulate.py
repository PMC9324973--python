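"""Synthetic cohorts with a GRS -> BMI -> metabolome causal chain.

The generator produces the three inputs the analysis pipeline consumes —
genotype dosages with SNP weights, a phenotype table, and a raw metabolite
abundance matrix with annotation — under a fully specified causal model:

    GRS (weighted sum of ~940 independent dosages)
      -> BMI   (GRS explains a configurable fraction ``r2_grs_bmi`` of variance)
      -> each metabolite (BMI explains a signed fraction ``r2_met_bmi``),
         with correlated residual clusters and MCAR or left-censored
         missingness on a log-normal peak-area scale.

Because every structural parameter is known, downstream stages (recall-group
selection, QC dispositions, association effect sizes, power) have exact
ground truth to recover in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its domain."""


_ALLELES = np.array(list("ACGT"))

# Superpathway labels used for annotation; "Xenobiotics" marks exogenous
# compounds, everything else is endogenous.
XENOBIOTIC_SUPERPATHWAY = "Xenobiotics"
_ENDOGENOUS_SUPERPATHWAYS = (
    "Lipid",
    "Amino Acid",
    "Nucleotide",
    "Carbohydrate",
    "Cofactors and Vitamins",
    "Peptide",
    "Energy",
    "Partially Characterized Molecules",
)


@dataclass(frozen=True)
class MetaboliteSpec:
    """Generative recipe for one metabolite.

    ``r2_met_bmi`` is a *signed* fraction: its magnitude is the share of
    (log-scale) metabolite variance explained by BMI, its sign the direction
    of the BMI effect. ``missing_frac`` cells are masked after generation,
    either uniformly at random (``mcar``) or from the bottom of the abundance
    distribution (``left``, detection-limit censoring).
    """

    name: str
    superpathway: str = "Lipid"
    subpathway: str = ""
    xenobiotic: bool = False
    r2_met_bmi: float = 0.0
    cluster: int | None = None
    missing_frac: float = 0.0
    mechanism: str = "mcar"  # "mcar" | "left"

    def validate(self) -> None:
        if not 0.0 <= abs(self.r2_met_bmi) <= 1.0:
            raise ConfigurationError(
                f"{self.name}: |r2_met_bmi| must be in [0,1], got {self.r2_met_bmi}"
            )
        if not 0.0 <= self.missing_frac < 1.0:
            raise ConfigurationError(
                f"{self.name}: missing_frac must be in [0,1), got {self.missing_frac}"
            )
        if self.mechanism not in ("mcar", "left"):
            raise ConfigurationError(
                f"{self.name}: unknown missingness mechanism {self.mechanism!r}"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a young-adult cohort: BMI mean/SD per sex match the
    full age-24 cohort values (male 24.9 (4.44), female 25.0 (5.42) kg/m^2),
    the score uses 940 independent variants, and the GRS explains 6% of BMI
    variance (a free parameter of the design; 0.06 reproduces the observed
    standardized 30%-tail BMI difference of ~0.56 SD).
    """

    n_individuals: int = 2500
    n_snps: int = 940
    maf_range: tuple[float, float] = (0.05, 0.5)
    r2_grs_bmi: float = 0.06
    bmi_mean: tuple[float, float] = (24.9, 25.0)  # (male, female) kg/m^2
    bmi_sd: tuple[float, float] = (4.44, 5.42)  # (male, female) kg/m^2
    p_male: float = 0.4
    age_mean: float = 24.5
    age_sd: float = 0.8
    metabolite_spec: tuple[MetaboliteSpec, ...] = ()
    cluster_rho: float = 0.6
    # optional map age (years) -> multiplicative scaling of the GRS effect
    # on BMI; drives the age-increasing divergence of the recall groups.
    age_effect_profile: Mapping[float, float] | None = None
    # latent shift of ordinal diet preference per unit covariate; used by
    # the post hoc diet analyses.
    diet_sex_effect: float = 0.0
    social_class_levels: tuple[str, ...] = ("I", "II", "III", "IV", "V")
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if not 0.0 <= self.r2_grs_bmi < 1.0:
            raise ConfigurationError(f"r2_grs_bmi must be in [0,1), got {self.r2_grs_bmi}")
        if not 0.0 <= self.cluster_rho < 1.0:
            raise ConfigurationError(f"cluster_rho must be in [0,1), got {self.cluster_rho}")
        for spec in self.metabolite_spec:
            spec.validate()
            if abs(spec.r2_met_bmi) + (self.cluster_rho if spec.cluster is not None else 0.0) > 1.0:
                raise ConfigurationError(
                    f"{spec.name}: structural variance components exceed 1 "
                    f"(|r2|={abs(spec.r2_met_bmi)}, cluster_rho={self.cluster_rho})"
                )


@dataclass
class GenotypeMatrix:
    """Per-sample effect-allele dosages for a set of variants.

    ``dosages`` is samples x variants, values in [0, 2], no missing entries.
    ``variants`` carries id, counted (effect) allele and other allele.
    """

    samples: list[str]
    variants: pd.DataFrame  # columns: variant_id, effect_allele, other_allele
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.dosages.size and (np.isnan(self.dosages).any()):
            raise ValueError("dosages must not contain missing values")


@dataclass
class PhenotypeTable:
    """Cross-sectional phenotypes plus an optional longitudinal BMI series.

    ``data`` columns: sample_id, sex ("M"/"F"), age, bmi, weight, height,
    fat_mass, lean_mass, whr, pref_fish, pref_fruit, pref_veg, social_class.
    ``bmi_series`` (optional) is long-format: sample_id, age, bmi.
    """

    data: pd.DataFrame
    bmi_series: pd.DataFrame | None = None


def simulate_snp_weights(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a published-GWAS-style weight table for ``config.n_snps`` variants.

    Weights are positive per-allele BMI effects (kg/m^2 per effect allele);
    alleles are two distinct bases per variant. Returns columns
    variant_id, effect_allele, other_allele, weight.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_snps
    first = rng.integers(0, 4, size=n)
    offset = rng.integers(1, 4, size=n)
    effect = _ALLELES[first]
    other = _ALLELES[(first + offset) % 4]
    weights = np.abs(rng.normal(0.0, 0.02, size=n)) + 1e-3
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1:05d}" for i in range(n)],
            "effect_allele": effect,
            "other_allele": other,
            "weight": weights,
        }
    )


def simulate_genotypes(config: SimulationConfig, variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Draw dosages Binomial(2, MAF) independently per variant.

    Variants are simulated independent (no linkage disequilibrium): the score
    the design assumes uses near-independent genome-wide significant variants,
    so LD would add nothing downstream. Deterministic under ``config.seed``.
    """
    config.validate()
    if variants is None:
        variants = simulate_snp_weights(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 102]))
    n, m = config.n_individuals, len(variants)
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)
    samples = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(
        samples=samples,
        variants=variants[["variant_id", "effect_allele", "other_allele"]].reset_index(drop=True),
        dosages=dosages,
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    config: SimulationConfig,
) -> PhenotypeTable:
    """Generate phenotypes downstream of the weighted score.

    BMI = mu_sex + sd_sex * (sqrt(r2) * GRS_z + sqrt(1 - r2) * e) so that the
    score explains ``r2_grs_bmi`` of within-sex BMI variance. Weight is
    BMI x height^2 with sex-specific heights; fat/lean mass and waist-hip
    ratio are linear in BMI plus noise. If ``age_effect_profile`` is set,
    a longitudinal BMI series applies the per-age scaling of the genetic
    effect (the recall groups then diverge with age).
    """
    config.validate()
    w = weights.set_index("variant_id").loc[genotypes.variants["variant_id"], "weight"].to_numpy()
    if len(w) != genotypes.dosages.shape[1]:
        raise ConfigurationError("weights do not align with genotype variants")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 103]))
    n = len(genotypes.samples)
    grs_raw = genotypes.dosages @ w
    grs_z = _standardize(grs_raw) if n > 1 else np.zeros(n)

    male = rng.random(n) < config.p_male
    sex = np.where(male, "M", "F")
    age = rng.normal(config.age_mean, config.age_sd, size=n)

    r2 = config.r2_grs_bmi
    mu = np.where(male, config.bmi_mean[0], config.bmi_mean[1])
    sd = np.where(male, config.bmi_sd[0], config.bmi_sd[1])
    e = rng.normal(size=n)
    bmi = mu + sd * (math.sqrt(r2) * grs_z + math.sqrt(1.0 - r2) * e)
    bmi = np.maximum(bmi, 12.0)  # physiological floor

    height = np.where(male, rng.normal(1.78, 0.06, n), rng.normal(1.64, 0.06, n))
    weight_kg = bmi * height**2
    fat = np.maximum(0.6 * bmi + np.where(male, -3.0, 4.0) + rng.normal(0, 3.0, n), 1.0)
    lean = np.maximum(np.where(male, 57.0, 41.0) + 0.35 * (bmi - 25.0) + rng.normal(0, 4.0, n), 20.0)
    whr = np.clip(np.where(male, 0.85, 0.77) + 0.004 * (bmi - 25.0) + rng.normal(0, 0.04, n), 0.5, 1.2)

    def ordinal_pref(shift: np.ndarray) -> np.ndarray:
        latent = rng.normal(size=n) + shift
        return np.clip(np.digitize(latent, [-1.2, -0.4, 0.4, 1.2]) + 1, 1, 5)

    sex_shift = config.diet_sex_effect * male.astype(float)
    prefs = {
        "pref_fish": ordinal_pref(sex_shift),
        "pref_fruit": ordinal_pref(np.zeros(n)),
        "pref_veg": ordinal_pref(np.zeros(n)),
    }
    social = rng.choice(config.social_class_levels, size=n, p=_class_probs(len(config.social_class_levels)))

    data = pd.DataFrame(
        {
            "sample_id": genotypes.samples,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "height": height,
            "weight": weight_kg,
            "fat_mass": fat,
            "lean_mass": lean,
            "whr": whr,
            **prefs,
            "social_class": social,
        }
    )

    series = None
    if config.age_effect_profile is not None:
        rows = []
        for a, scale in sorted(config.age_effect_profile.items()):
            mu_a = _child_bmi_mean(a)
            sd_a = 1.3 + 0.15 * a
            e_a = rng.normal(size=n)
            s2 = min(max(scale, 0.0) ** 2 * r2, 1.0)
            bmi_a = mu_a + sd_a * (math.sqrt(s2) * grs_z + math.sqrt(1.0 - s2) * e_a)
            rows.append(pd.DataFrame({"sample_id": genotypes.samples, "age": a, "bmi": bmi_a}))
        series = pd.concat(rows, ignore_index=True)

    return PhenotypeTable(data=data, bmi_series=series)


def _child_bmi_mean(age: float) -> float:
    # crude reference curve: dip in childhood, rise through adolescence
    if age <= 6:
        return 16.0
    return min(16.0 + 0.5 * (age - 6.0), 25.0)


def _class_probs(k: int) -> np.ndarray:
    p = np.linspace(1.5, 0.5, k)
    return p / p.sum()


@dataclass
class SyntheticMetabolome:
    """Raw abundance matrix plus annotation and generative ground truth.

    ``abundance``: samples x metabolites, log-normal peak-area scale, NaN for
    masked cells. ``truth`` records per metabolite the intended QC disposition
    and the structural parameters, for use as a test oracle.
    """

    abundance: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame


def simulate_metabolome(phenotypes: PhenotypeTable, config: SimulationConfig) -> SyntheticMetabolome:
    """Generate metabolites causally downstream of BMI.

    Per metabolite, on the latent log scale:

        z = sign * sqrt(|r2|) * BMI_z + sqrt(1-|r2|) * (sqrt(rho)*F_c + sqrt(1-rho)*eps)

    where F_c is a shared per-cluster factor (within-cluster residual
    correlation ``cluster_rho``) and abundance = exp(log(1e6) + z), a
    log-normal peak-area scale. Missing cells are masked in *exact* counts
    (round(missing_frac * n)): uniformly for MCAR, from the lowest values
    for left-censoring, so the generated missingness pattern — and hence the
    intended QC disposition — is deterministic given the seed.
    """
    config.validate()
    specs = config.metabolite_spec
    if not specs:
        raise ConfigurationError("metabolite_spec must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104]))
    n = len(phenotypes.data)
    bmi_z = _standardize(phenotypes.data["bmi"].to_numpy())

    cluster_ids = sorted({s.cluster for s in specs if s.cluster is not None})
    factors = {c: rng.normal(size=n) for c in cluster_ids}
    rho = config.cluster_rho

    cols, ann_rows, truth_rows = {}, [], []
    for spec in specs:
        r2 = abs(spec.r2_met_bmi)
        sign = -1.0 if spec.r2_met_bmi < 0 else 1.0
        eps = rng.normal(size=n)
        if spec.cluster is not None:
            resid = math.sqrt(rho) * factors[spec.cluster] + math.sqrt(1.0 - rho) * eps
        else:
            resid = eps
        z = sign * math.sqrt(r2) * bmi_z + math.sqrt(1.0 - r2) * resid
        abund = np.exp(math.log(1e6) + z)

        n_miss = int(round(spec.missing_frac * n))
        mask = np.zeros(n, dtype=bool)
        if n_miss > 0:
            if spec.mechanism == "left":
                mask[np.argsort(abund, kind="stable")[:n_miss]] = True
            else:
                mask[rng.choice(n, size=n_miss, replace=False)] = True
        vals = abund.copy()
        vals[mask] = np.nan
        cols[spec.name] = vals

        ann_rows.append(
            {
                "metabolite_id": spec.name,
                "superpathway": spec.superpathway,
                "subpathway": spec.subpathway,
                "xenobiotic": spec.xenobiotic,
            }
        )
        truth_rows.append(
            {
                "metabolite_id": spec.name,
                "r2_met_bmi": spec.r2_met_bmi,
                "cluster": spec.cluster,
                "missing_frac": spec.missing_frac,
                "mechanism": spec.mechanism,
                "n_missing": n_miss,
                "intended_disposition": _intended_disposition(spec, n, n_miss),
            }
        )

    abundance = pd.DataFrame(cols, index=phenotypes.data["sample_id"].to_numpy())
    abundance.index.name = "sample_id"
    return SyntheticMetabolome(
        abundance=abundance,
        annotation=pd.DataFrame(ann_rows),
        truth=pd.DataFrame(truth_rows),
    )


def _intended_disposition(spec: MetaboliteSpec, n: int, n_miss: int, miss_threshold: float = 0.20, presence_min: int = 11) -> str:
    """The QC disposition the generated missingness pattern implies."""
    frac = n_miss / n if n else 0.0
    if frac <= miss_threshold:
        return "continuous"
    if not spec.xenobiotic:
        return "excluded"
    if n - n_miss < presence_min:
        return "excluded"
    return "presence_absence"


def expected_tail_difference(q: float, r2: float) -> float:
    """Expected standardized difference in a downstream trait between the
    upper and lower ``q``-tails of a standard-normal score explaining ``r2``
    of the trait's variance.

    The mean of the upper q-tail of N(0,1) is phi(Phi^-1(1-q))/q; selection on
    the score shifts the trait by sqrt(r2) times the score shift, hence

        d = 2 * sqrt(r2) * phi(Phi^-1(1-q)) / q.
    """
    if not 0.0 < q <= 0.5:
        raise ValueError(f"tail fraction q must be in (0, 0.5], got {q}")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must be in [0,1], got {r2}")
    tail_mean = stats.norm.pdf(stats.norm.ppf(1.0 - q)) / q
    return 2.0 * math.sqrt(r2) * tail_mean


# ---------------------------------------------------------------------------
# Default study-scale metabolome composition
# ---------------------------------------------------------------------------

def default_metabolome_spec(
    n_clean_endogenous: int = 895,
    n_highmiss_endogenous: int = 205,
    n_clean_xenobiotic: int = 10,
    n_pa_xenobiotic: int = 68,
    n_rare_xenobiotic: int = 38,
    n_hits: int = 29,
    hit_r2_range: tuple[float, float] = (0.17, 0.32),
    n_samples_hint: int = 750,
    seed: int = 12345,
) -> tuple[MetaboliteSpec, ...]:
    """Compose a study-scale metabolome recipe (defaults: 1,216 metabolites,
    of which 905 end up continuous, 68 presence/absence, 243 excluded).

    The first ``n_hits`` clean endogenous metabolites carry true BMI effects
    in ``hit_r2_range`` with the cluster structure one block of 11, one of 4,
    one of 2 and 12 singletons (15 clusters), 25 negative / 4 positive.
    One presence/absence xenobiotic gets a left-censored BMI effect so the
    binary model has a true signal. ``n_samples_hint`` only guards the
    rare-xenobiotic present-count (< 11 of that many samples).
    """
    rng = np.random.default_rng(seed)
    specs: list[MetaboliteSpec] = []

    # planted cluster structure among the hits, scaled from the default
    # 29-hit layout 11 + 4 + 2 + 12 singletons (15 clusters)
    sizes: list[int] = []
    if n_hits >= 6:
        sizes.append(max(2, round(n_hits * 11 / 29)))
        sizes.append(max(2, round(n_hits * 4 / 29)))
        if n_hits >= 17:
            sizes.append(2)
    elif n_hits >= 2:
        sizes.append(2)
    while sum(sizes) > n_hits:
        sizes[0] -= 1
    sizes += [1] * (n_hits - sum(sizes))
    cluster_of: list[int | None] = []
    for cid, size in enumerate(sizes, start=1):
        cluster_of.extend([cid if size > 1 else None] * size)
    # mostly BMI-decreasing effects, a small positive minority (the size-2
    # block plus trailing singletons when the layout allows)
    signs = [-1.0] * n_hits
    n_pos = round(n_hits * 4 / 29)
    if n_hits >= 17 and n_pos >= 2:
        start_third = sizes[0] + sizes[1]
        signs[start_third] = signs[start_third + 1] = +1.0
        n_pos -= 2
    for j in range(n_pos):
        signs[n_hits - 1 - j] = +1.0
    lo, hi = hit_r2_range
    hit_r2 = rng.uniform(lo, hi, size=n_hits)

    idx = 0
    for k in range(n_clean_endogenous):
        idx += 1
        sp = _ENDOGENOUS_SUPERPATHWAYS[k % len(_ENDOGENOUS_SUPERPATHWAYS)]
        if k < n_hits:
            specs.append(
                MetaboliteSpec(
                    name=f"M{idx:04d}",
                    superpathway=sp,
                    xenobiotic=False,
                    r2_met_bmi=float(signs[k] * hit_r2[k]),
                    cluster=cluster_of[k],
                    missing_frac=float(rng.uniform(0.0, 0.05)),
                    mechanism="mcar",
                )
            )
        else:
            specs.append(
                MetaboliteSpec(
                    name=f"M{idx:04d}",
                    superpathway=sp,
                    xenobiotic=False,
                    missing_frac=float(rng.uniform(0.0, 0.15)),
                    mechanism="mcar",
                )
            )
    for _ in range(n_highmiss_endogenous):
        idx += 1
        specs.append(
            MetaboliteSpec(
                name=f"M{idx:04d}",
                superpathway=_ENDOGENOUS_SUPERPATHWAYS[idx % len(_ENDOGENOUS_SUPERPATHWAYS)],
                xenobiotic=False,
                missing_frac=float(rng.uniform(0.25, 0.60)),
                mechanism="mcar" if rng.random() < 0.5 else "left",
            )
        )
    for _ in range(n_clean_xenobiotic):
        idx += 1
        specs.append(
            MetaboliteSpec(
                name=f"M{idx:04d}",
                superpathway=XENOBIOTIC_SUPERPATHWAY,
                xenobiotic=True,
                missing_frac=float(rng.uniform(0.0, 0.10)),
                mechanism="mcar",
            )
        )
    for j in range(n_pa_xenobiotic):
        idx += 1
        # one binary-model signal: left-censored at the median with a latent
        # BMI effect of R^2 = 0.3, which under a ~0.56 SD group contrast
        # yields a detection odds ratio near 0.6
        r2 = -0.30 if j == 0 else 0.0
        specs.append(
            MetaboliteSpec(
                name=f"M{idx:04d}",
                superpathway=XENOBIOTIC_SUPERPATHWAY,
                xenobiotic=True,
                r2_met_bmi=r2,
                missing_frac=0.5 if j == 0 else float(rng.uniform(0.30, 0.80)),
                mechanism="left",
            )
        )
    for _ in range(n_rare_xenobiotic):
        idx += 1
        # present in fewer than 11 samples
        n_present = int(rng.integers(1, 11))
        specs.append(
            MetaboliteSpec(
                name=f"M{idx:04d}",
                superpathway=XENOBIOTIC_SUPERPATHWAY,
                xenobiotic=True,
                missing_frac=1.0 - n_present / n_samples_hint,
                mechanism="left",
            )
        )
    return tuple(specs)
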