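"""Two-model metabolome-wide association against recall group.

Model 1: linear regression of each rank-inverse-normal transformed
metabolite on recall group (low = 0, high = 1); with a binary regressor the
OLS slope is exactly the difference of group means and the classical t-based
inference coincides with the pooled-variance two-sample t-test. Model 2:
logistic regression of each presence/absence trait on recall group. p values
are Benjamini-Hochberg adjusted separately per model family, and effect
sizes are complemented by the log2 median fold change on the raw scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grs import GroupAssignment
from .qc import MetaboliteMatrix


@dataclass
class AssociationResult:
    """One metabolite, one model."""

    metabolite_id: str
    model: str  # "model1" | "model2"
    effect: float  # beta (SD units) for model1; OR for model2
    ci_low: float
    ci_high: float
    p: float
    r2: float  # R^2 (model1) or variance-function pseudo-R^2 (model2)
    n_low: int
    n_high: int
    log2_fc: float = math.nan
    p_adjusted: float = math.nan
    flagged: str = ""  # e.g. "separation" for a degenerate logistic fit


def _group_vector(values: pd.Series | pd.DataFrame, groups: GroupAssignment) -> tuple[np.ndarray, np.ndarray]:
    """Align a sample-indexed vector with the low/high assignment; returns
    (y, g) with g coded low=0 / high=1."""
    sel = groups.assignments[groups.assignments["group"].isin(["low", "high"])]
    ids = [s for s in sel["sample_id"] if s in values.index]
    y = values.loc[ids].to_numpy(dtype=float)
    gmap = dict(zip(sel["sample_id"], sel["group"]))
    g = np.array([1.0 if gmap[s] == "high" else 0.0 for s in ids])
    return y, g


def fit_model1(values: pd.Series, groups: GroupAssignment, name: str | None = None, alpha: float = 0.05) -> AssociationResult:
    """OLS metabolite ~ group with group coded low=0/high=1.

    beta equals mean(high) - mean(low) exactly; SE/p are the classical OLS
    (= pooled-variance two-sample t) quantities; R^2 is the variance in the
    transformed metabolite explained by group.
    """
    y, g = _group_vector(values, groups)
    if len(np.unique(g)) < 2:
        raise ValueError("both recall groups must be present")
    X = sm.add_constant(g)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=alpha)[1]
    return AssociationResult(
        metabolite_id=name or str(values.name),
        model="model1",
        effect=float(fit.params[1]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues[1]),
        r2=float(fit.rsquared),
        n_low=int((g == 0).sum()),
        n_high=int((g == 1).sum()),
    )


def model1_closed_form(matrix: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-group OLS over metabolite columns.

    For a 0/1 regressor, beta = mean1 - mean0, se^2 = s_pooled^2 (1/n0 + 1/n1),
    t = beta/se with df = n - 2, and R^2 = t^2 / (t^2 + df). Identical to the
    per-metabolite OLS fit; used in resampling and null-simulation loops.
    Returns (beta, se, p, r2).
    """
    g = np.asarray(g, dtype=float)
    m0, m1 = matrix[g == 0], matrix[g == 1]
    n0, n1 = len(m0), len(m1)
    beta = m1.mean(axis=0) - m0.mean(axis=0)
    ss = ((m0 - m0.mean(axis=0)) ** 2).sum(axis=0) + ((m1 - m1.mean(axis=0)) ** 2).sum(axis=0)
    df = n0 + n1 - 2
    s2 = ss / df
    se = np.sqrt(s2 * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    r2 = t**2 / (t**2 + df)
    return beta, se, p, r2


def fit_model2(values: pd.Series, groups: GroupAssignment, name: str | None = None, alpha: float = 0.05) -> AssociationResult:
    """Logistic regression presence ~ group; OR = exp(coefficient), Wald CI.

    Complete separation (a group all-present or all-absent) cannot support a
    finite MLE: the result is flagged and carries the Fisher exact p instead
    of an OR.
    """
    y, g = _group_vector(values, groups)
    nm = name or str(values.name)
    if len(np.unique(y)) < 2:
        raise ValueError(f"{nm}: outcome has a single level")
    n_low, n_high = int((g == 0).sum()), int((g == 1).sum())
    pres_low, pres_high = y[g == 0].sum(), y[g == 1].sum()
    separated = pres_low in (0, n_low) or pres_high in (0, n_high)
    if separated:
        table = np.array([[pres_high, n_high - pres_high], [pres_low, n_low - pres_low]]).astype(int)
        _, p = stats.fisher_exact(table)
        return AssociationResult(
            metabolite_id=nm,
            model="model2",
            effect=math.nan,
            ci_low=math.nan,
            ci_high=math.nan,
            p=float(p),
            r2=math.nan,
            n_low=n_low,
            n_high=n_high,
            flagged="separation",
        )
    X = sm.add_constant(g)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    ci = fit.conf_int(alpha=alpha)[1]
    return AssociationResult(
        metabolite_id=nm,
        model="model2",
        effect=float(math.exp(fit.params[1])),
        ci_low=float(math.exp(ci[0])),
        ci_high=float(math.exp(ci[1])),
        p=float(fit.pvalues[1]),
        r2=_pseudo_r2_variance(y, fit.fittedvalues),
        n_low=n_low,
        n_high=n_high,
    )


def _pseudo_r2_variance(y: np.ndarray, mu: np.ndarray) -> float:
    # Variance-function-based pseudo-R^2 for a Bernoulli GLM:
    #   R^2_V = 1 - sum((y - mu_i)^2 / V(mu_i)) / sum((y - mu_0)^2 / V(mu_0))
    # with V(mu) = mu(1 - mu) and mu_0 the null (intercept-only) fit = mean(y).
    mu0 = y.mean()
    num = np.sum((y - mu) ** 2 / (mu * (1.0 - mu)))
    den = np.sum((y - mu0) ** 2 / (mu0 * (1.0 - mu0)))
    return float(1.0 - num / den)


def log2_median_fold_change(raw: MetaboliteMatrix, groups: GroupAssignment) -> pd.Series:
    """log2(median_high / median_low) per metabolite on the raw
    (untransformed, unimputed) scale, over observed cells only.

    NaN marks an undefined value (a zero median or a group with no observed
    cells) — a value state, not an error.
    """
    if raw.state != "raw":
        raise ValueError("fold change uses the raw matrix")
    low_ids = [s for s in groups.ids("low") if s in raw.data.index]
    high_ids = [s for s in groups.ids("high") if s in raw.data.index]
    med_low = raw.data.loc[low_ids].median(axis=0, skipna=True)
    med_high = raw.data.loc[high_ids].median(axis=0, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(med_high.to_numpy() / med_low.to_numpy())
    fc = np.where(np.isfinite(fc), fc, np.nan)
    return pd.Series(fc, index=raw.data.columns, name="log2_fc")


def bh_adjust(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1).

    Applied separately per model family by the callers.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_associations(
    transformed: MetaboliteMatrix,
    presence_absence: pd.DataFrame,
    raw: MetaboliteMatrix,
    groups: GroupAssignment,
) -> pd.DataFrame:
    """Fit Model 1 on every transformed metabolite and Model 2 on every
    presence/absence trait; BH-adjust per family; attach fold changes.

    Returns one row per metabolite per model with Table-2-style columns.
    """
    results: list[AssociationResult] = []
    for met in transformed.data.columns:
        results.append(fit_model1(transformed.data[met], groups, name=met))
    for met in presence_absence.columns:
        col = presence_absence[met]
        if col.nunique() < 2:
            warnings.warn(f"{met}: single-level presence/absence trait skipped")
            continue
        results.append(fit_model2(col, groups, name=met))

    df = pd.DataFrame([vars(r) for r in results])
    for fam in ("model1", "model2"):
        mask = df["model"] == fam
        if mask.any():
            df.loc[mask, "p_adjusted"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    fc = log2_median_fold_change(raw, groups)
    df["log2_fc"] = df["metabolite_id"].map(fc)
    return df


def summarize_associations(results: pd.DataFrame, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Discovery table (BH p < alpha, sorted ascending) and a volcano table
    pairing log2 fold change with -log10 p."""
    hits = results[results["p_adjusted"] < alpha].sort_values("p_adjusted").reset_index(drop=True)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(results["p"].to_numpy())
    volcano = pd.DataFrame(
        {
            "metabolite_id": results["metabolite_id"],
            "model": results["model"],
            "log2_fc": results["log2_fc"],
            "neg_log10_p": neglog,
            "significant": (results["p_adjusted"] < alpha),
        }
    )
    return {"hits": hits, "volcano": volcano}
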