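"""Weighted genetic risk score, extreme-tail recall, and group characterization.

The score is the weighted sum of BMI-increasing allele dosages over a set of
near-independent variants; recall groups are the top and bottom q-tails of
the score distribution (the design's exposure contrast). Group
characterization reproduces the descriptive comparison table: Welch t for
continuous traits (with a Wilcoxon alternative gated on Shapiro-Wilk W),
Fisher's exact test for categorical ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix, PhenotypeTable

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class AlignmentReport:
    """Bookkeeping of how weight variants were matched to genotype columns."""

    n_matched: int = 0
    n_flipped: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (variant, reason)


@dataclass
class GrsResult:
    """Per-sample raw and cohort-standardized score."""

    scores: pd.DataFrame  # columns: sample_id, grs_raw, grs_z
    report: AlignmentReport


@dataclass
class GroupAssignment:
    """Low/high/unselected recall labels at tail fraction ``q``."""

    assignments: pd.DataFrame  # columns: sample_id, group
    q: float

    def ids(self, group: str) -> list[str]:
        return self.assignments.loc[self.assignments["group"] == group, "sample_id"].tolist()


def compute_grs(genotypes: GenotypeMatrix, weights: pd.DataFrame, allele_policy: str = "flip") -> GrsResult:
    """raw score_j = sum_i w_i * g_ij over variants matched between the
    genotype file and the weight table, dosages aligned to the effect allele.

    If the genotype file counts the non-effect allele, the dosage is flipped
    (2 - d). Variants whose alleles match neither directly nor via strand
    complement are dropped with a warning; strand-ambiguous (A/T, C/G)
    mismatches are likewise dropped. The standardized score is a z-score over
    all scored samples.
    """
    if allele_policy not in ("flip", "strict"):
        raise ValueError(f"unknown allele_policy {allele_policy!r}")
    geno_idx = {v: j for j, v in enumerate(genotypes.variants["variant_id"])}
    report = AlignmentReport()
    n = len(genotypes.samples)
    raw = np.zeros(n)
    for row in weights.itertuples(index=False):
        j = geno_idx.get(row.variant_id)
        if j is None:
            report.dropped.append((row.variant_id, "absent from genotypes"))
            continue
        counted = genotypes.variants["effect_allele"].iat[j]
        other = genotypes.variants["other_allele"].iat[j]
        dos = genotypes.dosages[:, j]
        aligned = _align_dosage(row, counted, other, dos, allele_policy, report)
        if aligned is None:
            continue
        raw += float(row.weight) * aligned
        report.n_matched += 1
    if report.n_matched == 0:
        raise ValueError("no variants matched between genotypes and weights")
    sd = raw.std()
    z = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)
    return GrsResult(
        scores=pd.DataFrame({"sample_id": genotypes.samples, "grs_raw": raw, "grs_z": z}),
        report=report,
    )


def _align_dosage(row, counted: str, other: str, dos: np.ndarray, policy: str, report: AlignmentReport) -> np.ndarray | None:
    eff, oth = str(row.effect_allele), str(getattr(row, "other_allele", "") or "")
    if eff == counted and (not oth or oth == other):
        return dos
    if eff == other and (not oth or oth == counted):
        if policy == "strict":
            report.dropped.append((row.variant_id, "allele flip under strict policy"))
            return None
        report.n_flipped += 1
        return 2.0 - dos
    # strand flip: relabel both alleles by their complements; palindromic
    # (A/T, C/G) pairs are indistinguishable from an allele flip and dropped
    ceff, coth = _COMPLEMENT.get(eff, "?"), _COMPLEMENT.get(oth, "?")
    if oth and coth == eff:
        report.dropped.append((row.variant_id, "strand-ambiguous alleles"))
        warnings.warn(f"{row.variant_id}: strand-ambiguous alleles dropped")
        return None
    if ceff == counted and (not oth or coth == other):
        return dos
    if ceff == other and (not oth or coth == counted):
        if policy == "strict":
            report.dropped.append((row.variant_id, "allele flip under strict policy"))
            return None
        report.n_flipped += 1
        return 2.0 - dos
    report.dropped.append((row.variant_id, f"allele mismatch {eff}/{oth} vs {counted}/{other}"))
    warnings.warn(f"{row.variant_id}: allele mismatch, variant dropped")
    return None


def select_recall_groups(grs: GrsResult, q: float, n_per_group: int | None = None) -> GroupAssignment:
    """floor(q*n) lowest scores -> "low", floor(q*n) highest -> "high",
    rest "unselected". Ties at a boundary break by ascending sample id.

    ``n_per_group`` optionally caps each group at the most extreme scores
    within its tail (a recall study often assays fewer samples than the full
    tails contain).
    """
    if not 0.0 < q <= 0.5:
        raise ValueError(f"recall fraction q must be in (0, 0.5], got {q}")
    df = grs.scores
    n = len(df)
    k = int(math.floor(q * n))
    if k < 1:
        raise ValueError(f"q*n = {q * n:.3f} selects no samples")
    if n_per_group is not None:
        if n_per_group < 1 or n_per_group > k:
            raise ValueError(f"n_per_group must be in [1, floor(q*n)={k}]")
    order = np.lexsort((df["sample_id"].to_numpy(), df["grs_raw"].to_numpy()))
    group = np.array(["unselected"] * n, dtype=object)
    kk = n_per_group if n_per_group is not None else k
    low_pool, high_pool = order[:k], order[n - k:]
    group[low_pool[:kk]] = "low"
    group[high_pool[len(high_pool) - kk:]] = "high"
    return GroupAssignment(
        assignments=pd.DataFrame({"sample_id": df["sample_id"], "group": group}),
        q=q,
    )


# ---------------------------------------------------------------------------
# Group characterization
# ---------------------------------------------------------------------------

def welch_comparison(low: np.ndarray, high: np.ndarray, alpha: float = 0.05) -> dict:
    """Welch two-sample difference high - low with Satterthwaite df CI/p."""
    n1, n2 = len(low), len(high)
    m1, m2 = low.mean(), high.mean()
    v1, v2 = low.var(ddof=1), high.var(ddof=1)
    se = math.sqrt(v1 / n1 + v2 / n2)
    df = (v1 / n1 + v2 / n2) ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    diff = m2 - m1
    t = diff / se if se > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), df) if se > 0 else 1.0
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return {
        "estimate": diff,
        "ci_low": diff - tcrit * se,
        "ci_high": diff + tcrit * se,
        "se": se,
        "df": df,
        "p": p,
    }


def fisher_comparison(table: np.ndarray, alpha: float = 0.05) -> dict:
    """Fisher exact test on a 2x2 table [[high&1, high&0], [low&1, low&0]]:
    conditional-MLE odds ratio, exact CI, two-sided p."""
    res = stats.contingency.odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=1 - alpha)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {"estimate": res.statistic, "ci_low": ci.low, "ci_high": ci.high, "p": p}


def combine_sex_strata(ns: np.ndarray, means: np.ndarray, sds: np.ndarray) -> tuple[float, float]:
    """Combined mean and SD of strata given per-stratum n, mean, SD.

    Combined variance pools within-stratum variance and between-stratum
    spread: ((sum (n_i-1) s_i^2 + sum n_i (m_i - m)^2) / (N - 1)).
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    N = ns.sum()
    m = float((ns * means).sum() / N)
    ss = ((ns - 1) * sds**2).sum() + (ns * (means - m) ** 2).sum()
    return m, float(math.sqrt(ss / (N - 1)))


DEFAULT_CONTINUOUS = ("age", "bmi", "weight", "fat_mass", "lean_mass", "whr")
DEFAULT_CATEGORICAL = ("sex",)


def characterize_groups(
    phenotypes: PhenotypeTable,
    groups: GroupAssignment,
    continuous: tuple[str, ...] | None = None,
    categorical: tuple[str, ...] | None = None,
    shapiro_gate: float = 0.90,
) -> pd.DataFrame:
    """Descriptive comparison of the recall groups (low group is reference).

    Continuous traits: Welch t difference with CI and p, plus a Wilcoxon
    rank-sum p and the Shapiro-Wilk W of the pooled trait; the primary test
    is labelled rank-based iff W < ``shapiro_gate``. Categorical traits:
    Fisher exact conditional-MLE OR with exact CI (binary) or the exact /
    simulated p over the full table.
    """
    continuous = tuple(c for c in (continuous or DEFAULT_CONTINUOUS) if c in phenotypes.data.columns)
    categorical = tuple(c for c in (categorical or DEFAULT_CATEGORICAL) if c in phenotypes.data.columns)
    df = phenotypes.data.merge(groups.assignments, on="sample_id")
    low = df[df["group"] == "low"]
    high = df[df["group"] == "high"]
    rows = []
    for var in continuous:
        x1 = low[var].dropna().to_numpy(dtype=float)
        x2 = high[var].dropna().to_numpy(dtype=float)
        if len(x1) < 2 or len(x2) < 2:
            warnings.warn(f"{var}: fewer than 2 observations per group, skipped")
            continue
        pooled = np.concatenate([x1, x2])
        if pooled.std() == 0:
            warnings.warn(f"{var}: constant variable, comparison skipped")
            continue
        w = welch_comparison(x1, x2)
        mw = stats.mannwhitneyu(x2, x1, alternative="two-sided")
        sw = stats.shapiro(pooled if len(pooled) <= 4999 else np.random.default_rng(0).choice(pooled, 4999, replace=False))
        primary = "wilcoxon" if sw.statistic < shapiro_gate else "welch"
        rows.append(
            {
                "variable": var,
                "kind": "continuous",
                "n_low": len(x1),
                "mean_low": x1.mean(),
                "sd_low": x1.std(ddof=1),
                "n_high": len(x2),
                "mean_high": x2.mean(),
                "sd_high": x2.std(ddof=1),
                "estimate": w["estimate"],
                "ci_low": w["ci_low"],
                "ci_high": w["ci_high"],
                "p_welch": w["p"],
                "p_wilcoxon": mw.pvalue,
                "shapiro_w": sw.statistic,
                "primary_test": primary,
                "p": mw.pvalue if primary == "wilcoxon" else w["p"],
            }
        )
    for var in categorical:
        levels = sorted(df[var].dropna().unique())
        if len(levels) < 2:
            warnings.warn(f"{var}: constant variable, comparison skipped")
            continue
        if len(levels) == 2:
            ref = levels[0]
            table = np.array(
                [
                    [(high[var] == ref).sum(), (high[var] != ref).sum()],
                    [(low[var] == ref).sum(), (low[var] != ref).sum()],
                ]
            )
            f = fisher_comparison(table)
            rows.append(
                {
                    "variable": f"{var}={ref}",
                    "kind": "binary",
                    "n_low": len(low),
                    "mean_low": (low[var] == ref).mean(),
                    "sd_low": np.nan,
                    "n_high": len(high),
                    "mean_high": (high[var] == ref).mean(),
                    "sd_high": np.nan,
                    "estimate": f["estimate"],
                    "ci_low": f["ci_low"],
                    "ci_high": f["ci_high"],
                    "p_welch": np.nan,
                    "p_wilcoxon": np.nan,
                    "shapiro_w": np.nan,
                    "primary_test": "fisher",
                    "p": f["p"],
                }
            )
        else:
            table = np.array(
                [[(high[var] == lv).sum() for lv in levels], [(low[var] == lv).sum() for lv in levels]]
            )
            # Freeman-Halton exact is infeasible for large tables; use the
            # chi2-free Monte Carlo exact p via scipy when the table is small
            try:
                _, p = stats.fisher_exact(table)
            except ValueError:
                p = stats.chi2_contingency(table)[1]
            rows.append(
                {
                    "variable": var,
                    "kind": "categorical",
                    "n_low": len(low),
                    "mean_low": np.nan,
                    "sd_low": np.nan,
                    "n_high": len(high),
                    "mean_high": np.nan,
                    "sd_high": np.nan,
                    "estimate": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_welch": np.nan,
                    "p_wilcoxon": np.nan,
                    "shapiro_w": np.nan,
                    "primary_test": "fisher",
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def trajectory_differences(bmi_series: pd.DataFrame, groups: GroupAssignment, value: str = "bmi") -> pd.DataFrame:
    """Per-age Welch difference (high - low) with 95% CI, ordered by age."""
    if bmi_series is None or bmi_series.empty:
        raise ValueError("longitudinal series is empty")
    df = bmi_series.merge(groups.assignments, on="sample_id")
    rows = []
    for age, sub in sorted(df.groupby("age"), key=lambda kv: kv[0]):
        x1 = sub.loc[sub["group"] == "low", value].dropna().to_numpy(dtype=float)
        x2 = sub.loc[sub["group"] == "high", value].dropna().to_numpy(dtype=float)
        if len(x1) < 2 or len(x2) < 2:
            warnings.warn(f"age {age}: a group is empty or too small, skipped")
            continue
        w = welch_comparison(x1, x2)
        rows.append(
            {
                "age": age,
                "n_low": len(x1),
                "n_high": len(x2),
                "estimate": w["estimate"],
                "ci_low": w["ci_low"],
                "ci_high": w["ci_high"],
                "p": w["p"],
            }
        )
    return pd.DataFrame(rows)
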