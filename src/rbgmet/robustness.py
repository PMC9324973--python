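"""Extended analyses: confounder adjustment, split-half resampling,
redundancy clustering, measured-BMI models, and diet post hoc tests.

These probe the robustness of the primary recall-group associations:

* refit the group model with measured confounders as fixed effects;
* assess internal reproducibility by repeatedly splitting the sample into
  discovery and replication halves (an association is "robust" when it
  passes BH in the discovery half and replicates with concordant sign at
  nominal significance in enough iterations);
* collapse correlated hits into clusters (average-linkage on 1 - |rho|)
  each summarized by a representative metabolite;
* relate hits to measured BMI with additive, interaction and per-group
  models;
* test ordinal dietary preferences against recall group and against
  individual metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .association import bh_adjust, model1_closed_form
from .grs import GroupAssignment
from .qc import MetaboliteMatrix


# ---------------------------------------------------------------------------
# Confounder-adjusted group model
# ---------------------------------------------------------------------------

def _design_with_covariates(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Expand categorical covariates to indicator contrasts (reference =
    most frequent level); drop collinear columns with a warning."""
    cols = {}
    for cov in covariates:
        s = df[cov]
        if s.dtype.kind in "ifu" and s.nunique() > 5:
            cols[cov] = s.astype(float)
        else:
            levels = s.value_counts().index.tolist()
            ref = levels[0]
            for lv in levels[1:]:
                cols[f"{cov}[{lv}]"] = (s == lv).astype(float)
    X = pd.DataFrame(cols, index=df.index)
    # rank check: drop columns that add no rank
    keep: list[str] = []
    for c in X.columns:
        trial = X[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), trial])) == len(keep) + 2:
            keep.append(c)
        else:
            warnings.warn(f"covariate column {c} is collinear and was dropped")
    return X[keep]


@dataclass
class ExtendedModelResult:
    """Coefficient summary of one extended linear model."""

    metabolite_id: str
    formula: str
    effects: pd.DataFrame  # index = term; columns: estimate, ci_low, ci_high, p
    interaction_p: float | None = None

    def effect(self, term: str) -> pd.Series:
        return self.effects.loc[term]


def _ols_summary(y: np.ndarray, X: pd.DataFrame, alpha: float = 0.05):
    Xc = sm.add_constant(X)
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=alpha)
    eff = pd.DataFrame(
        {
            "estimate": fit.params,
            "ci_low": ci[0] if isinstance(ci, pd.DataFrame) else ci[:, 0],
            "ci_high": ci[1] if isinstance(ci, pd.DataFrame) else ci[:, 1],
            "p": fit.pvalues,
        }
    )
    return fit, eff


def fit_adjusted_group_model(
    values: pd.Series,
    groups: GroupAssignment,
    phenotypes: pd.DataFrame,
    covariates: list[str],
    name: str | None = None,
) -> ExtendedModelResult:
    """metabolite ~ group + covariates (group coded low=0/high=1)."""
    sel = groups.assignments[groups.assignments["group"].isin(["low", "high"])]
    df = phenotypes.merge(sel, on="sample_id").set_index("sample_id")
    ids = [s for s in df.index if s in values.index]
    df = df.loc[ids]
    y = values.loc[ids].to_numpy(dtype=float)
    X = _design_with_covariates(df, covariates)
    X.insert(0, "group", (df["group"] == "high").astype(float))
    _, eff = _ols_summary(y, X)
    return ExtendedModelResult(
        metabolite_id=name or str(values.name),
        formula="metabolite ~ group + " + " + ".join(covariates),
        effects=eff,
    )


# ---------------------------------------------------------------------------
# Two-step iterative resampling
# ---------------------------------------------------------------------------

@dataclass
class ResamplingResult:
    """Per-metabolite discovery/replication instance counts."""

    table: pd.DataFrame  # metabolite_id, discovery, replication, joint, robust
    n_iterations: int
    instance_threshold: int


def iterative_resampling(
    transformed: MetaboliteMatrix,
    groups: GroupAssignment,
    n_iterations: int = 100,
    split: float = 0.5,
    discovery_alpha: float = 0.05,
    replication_alpha: float = 0.05,
    instance_threshold: int = 20,
    seed: int = 0,
) -> ResamplingResult:
    """Split-half discovery/replication resampling.

    Each iteration splits the recalled samples into discovery and replication
    halves, stratified by group. A metabolite scores a *discovery* instance
    when its discovery-half group model passes BH < ``discovery_alpha``
    (BH within the half, across metabolites), a *replication* instance when
    the replication half gives nominal p < ``replication_alpha`` with a
    concordant effect sign, and a *joint* instance when both hold in the
    same iteration. ``robust`` flags joint >= ``instance_threshold``.
    """
    if n_iterations < instance_threshold:
        raise ValueError(
            f"threshold {instance_threshold} unreachable with {n_iterations} iterations"
        )
    if transformed.state != "transformed":
        raise ValueError("resampling expects the transformed matrix")
    sel = groups.assignments[groups.assignments["group"].isin(["low", "high"])]
    ids = [s for s in sel["sample_id"] if s in transformed.data.index]
    gmap = dict(zip(sel["sample_id"], sel["group"]))
    g = np.array([1.0 if gmap[s] == "high" else 0.0 for s in ids])
    mat = transformed.data.loc[ids].to_numpy(dtype=float)
    idx_low, idx_high = np.where(g == 0)[0], np.where(g == 1)[0]
    k_low, k_high = int(round(split * len(idx_low))), int(round(split * len(idx_high)))
    if min(k_low, k_high, len(idx_low) - k_low, len(idx_high) - k_high) < 4:
        raise ValueError("each group must contribute >= 4 samples per half-split")

    rng = np.random.default_rng(seed)
    m = mat.shape[1]
    disc = np.zeros(m, dtype=int)
    repl = np.zeros(m, dtype=int)
    joint = np.zeros(m, dtype=int)
    for _ in range(n_iterations):
        pl = rng.permutation(idx_low)
        ph = rng.permutation(idx_high)
        half1 = np.concatenate([pl[:k_low], ph[:k_high]])
        half2 = np.concatenate([pl[k_low:], ph[k_high:]])
        b1, _, p1, _ = model1_closed_form(mat[half1], g[half1])
        b2, _, p2, _ = model1_closed_form(mat[half2], g[half2])
        disc_hit = bh_adjust(p1) < discovery_alpha
        repl_hit = (p2 < replication_alpha) & (np.sign(b1) == np.sign(b2))
        disc += disc_hit
        repl += repl_hit
        joint += disc_hit & repl_hit
    table = pd.DataFrame(
        {
            "metabolite_id": transformed.data.columns,
            "discovery": disc,
            "replication": repl,
            "joint": joint,
            "robust": joint >= instance_threshold,
        }
    )
    return ResamplingResult(table=table, n_iterations=n_iterations, instance_threshold=instance_threshold)


# ---------------------------------------------------------------------------
# Redundancy clustering with representative metabolites
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Cluster label per metabolite plus one representative per cluster."""

    table: pd.DataFrame  # metabolite_id, cluster, representative (bool)

    @property
    def n_clusters(self) -> int:
        return self.table["cluster"].nunique()

    def representatives(self) -> list[str]:
        t = self.table
        return t.loc[t["representative"], "metabolite_id"].tolist()


def cluster_associated(
    transformed: MetaboliteMatrix,
    metabolites: list[str] | None = None,
    corr_method: str = "spearman",
    linkage: str = "average",
    cut_threshold: float = 0.5,
) -> ClusterAssignment:
    """Group correlated hits: distance 1 - |rho|, agglomerative tree cut at
    ``cut_threshold``; each cluster's representative is the member most
    correlated (|r|) with the cluster's first principal component
    (singletons represent themselves). Invariant to column order and to
    sign flips of whole metabolites.
    """
    data = transformed.data[metabolites] if metabolites is not None else transformed.data
    constant = data.columns[data.std(axis=0) == 0]
    if len(constant):
        warnings.warn(f"constant metabolites excluded from clustering: {list(constant)}")
        data = data.drop(columns=list(constant))
    if data.shape[1] < 2:
        raise ValueError("clustering needs >= 2 non-constant metabolites")
    corr = data.corr(method=corr_method).to_numpy()
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    labels = hierarchy.fcluster(Z, t=cut_threshold, criterion="distance")

    # stable relabelling by first occurrence in column order
    order: dict[int, int] = {}
    relabelled = []
    for lab in labels:
        order.setdefault(lab, len(order) + 1)
        relabelled.append(order[lab])
    labels = np.array(relabelled)

    rep = np.zeros(len(labels), dtype=bool)
    cols = list(data.columns)
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        if len(members) == 1:
            rep[members[0]] = True
            continue
        block = data.iloc[:, members].to_numpy(dtype=float)
        block = (block - block.mean(axis=0)) / block.std(axis=0)
        # first principal component of the member block
        u, s, vt = np.linalg.svd(block - block.mean(axis=0), full_matrices=False)
        pc1 = u[:, 0] * s[0]
        cors = np.abs([np.corrcoef(block[:, j], pc1)[0, 1] for j in range(block.shape[1])])
        rep[members[int(np.argmax(cors))]] = True
    return ClusterAssignment(
        table=pd.DataFrame({"metabolite_id": cols, "cluster": labels, "representative": rep})
    )


# ---------------------------------------------------------------------------
# Measured-BMI models
# ---------------------------------------------------------------------------

def fit_bmi_models(
    values: pd.Series,
    groups: GroupAssignment,
    phenotypes: pd.DataFrame,
    mode: str = "additive",
    name: str | None = None,
) -> ExtendedModelResult | dict[str, ExtendedModelResult]:
    """Relate a metabolite to measured BMI alongside recall group.

    ``additive``:    metabolite ~ BMI + group + sex + age
    ``interaction``: metabolite ~ BMI * group + sex + age (reports the
                     product-term p and per-group BMI slopes)
    ``per_group``:   metabolite ~ BMI + sex + age within each group
    """
    if mode not in ("additive", "interaction", "per_group"):
        raise ValueError(f"unknown mode {mode!r}")
    nm = name or str(values.name)
    sel = groups.assignments[groups.assignments["group"].isin(["low", "high"])]
    df = phenotypes.merge(sel, on="sample_id").set_index("sample_id")
    ids = [s for s in df.index if s in values.index]
    df = df.loc[ids]
    y = values.loc[ids].to_numpy(dtype=float)
    male = (df["sex"] == "M").astype(float)
    gi = (df["group"] == "high").astype(float)
    base = pd.DataFrame({"bmi": df["bmi"].astype(float), "group": gi, "sex": male, "age": df["age"].astype(float)})

    if mode == "per_group":
        out: dict[str, ExtendedModelResult] = {}
        for gname in ("low", "high"):
            sub = df["group"] == gname
            if sub.sum() < 5:
                raise ValueError(f"group {gname}: degenerate design")
            Xg = base.loc[sub.to_numpy(), ["bmi", "sex", "age"]]
            _, eff = _ols_summary(y[sub.to_numpy()], Xg)
            out[gname] = ExtendedModelResult(nm, "metabolite ~ BMI + sex + age", eff)
        return out

    X = base.copy()
    if mode == "interaction":
        X["bmi:group"] = X["bmi"] * X["group"]
    if np.linalg.matrix_rank(sm.add_constant(X.to_numpy())) < X.shape[1] + 1:
        raise ValueError("degenerate design matrix")
    _, eff = _ols_summary(y, X)
    formula = "metabolite ~ BMI " + ("* group" if mode == "interaction" else "+ group") + " + sex + age"
    return ExtendedModelResult(
        metabolite_id=nm,
        formula=formula,
        effects=eff,
        interaction_p=float(eff.loc["bmi:group", "p"]) if mode == "interaction" else None,
    )


# ---------------------------------------------------------------------------
# Diet post hoc tests
# ---------------------------------------------------------------------------

def diet_associations(
    phenotypes: pd.DataFrame,
    groups: GroupAssignment,
    transformed: MetaboliteMatrix,
    preferences: list[str],
    metabolites: list[str],
) -> dict[str, pd.DataFrame]:
    """Ordinal diet preferences vs recall group and vs metabolites.

    Returns two tables: ``group_tests`` (Wilcoxon rank-sum of each ordinal
    preference between groups) and ``metabolite_tests`` (OLS slope of each
    metabolite on each preference, unadjusted and adjusted for sex + group).
    """
    sel = groups.assignments[groups.assignments["group"].isin(["low", "high"])]
    df = phenotypes.merge(sel, on="sample_id").set_index("sample_id")
    group_rows, met_rows = [], []
    for pref in preferences:
        x = df[pref].astype(float)
        if x.nunique() < 2:
            warnings.warn(f"{pref}: constant preference skipped")
            continue
        lowv = x[df["group"] == "low"]
        highv = x[df["group"] == "high"]
        mw = stats.mannwhitneyu(highv, lowv, alternative="two-sided")
        group_rows.append(
            {
                "preference": pref,
                "median_low": lowv.median(),
                "median_high": highv.median(),
                "p_wilcoxon": mw.pvalue,
            }
        )
        for met in metabolites:
            ids = [s for s in df.index if s in transformed.data.index]
            y = transformed.data.loc[ids, met].to_numpy(dtype=float)
            sub = df.loc[ids]
            X0 = pd.DataFrame({"pref": sub[pref].astype(float)}, index=sub.index)
            _, eff0 = _ols_summary(y, X0)
            X1 = X0.copy()
            X1["sex"] = (sub["sex"] == "M").astype(float)
            X1["group"] = (sub["group"] == "high").astype(float)
            _, eff1 = _ols_summary(y, X1)
            met_rows.append(
                {
                    "preference": pref,
                    "metabolite_id": met,
                    "slope": eff0.loc["pref", "estimate"],
                    "p": eff0.loc["pref", "p"],
                    "slope_adjusted": eff1.loc["pref", "estimate"],
                    "p_adjusted_model": eff1.loc["pref", "p"],
                }
            )
    return {
        "group_tests": pd.DataFrame(group_rows),
        "metabolite_tests": pd.DataFrame(met_rows),
    }
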