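"""Metabolite preprocessing: classification, sample QC, imputation, scaling.

The flow mirrors untargeted-metabolomics practice for peak-area data:

1. sample QC (missingness and principal-component outliers);
2. per-metabolite disposition: endogenous metabolites with more than 20%
   missing cells are excluded; xenobiotics with more than 20% missing become
   presence/absence traits unless detected in fewer than 11 samples (then
   excluded); everything else stays continuous;
3. imputation of the continuous block (iterative forest, or median);
4. rank-based inverse-normal transformation (Blom offsets) per metabolite.

Presence/absence traits are coded 1 = detected, 0 = not detected, from the
*raw* (pre-imputation) matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites abundance matrix with a QC state tag.

    States: ``raw`` (positive peak areas, NaN = missing) -> ``filtered`` ->
    ``imputed`` (no NaN) -> ``transformed`` (each column ~ N(0,1)).
    """

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in ("raw", "filtered", "imputed", "transformed"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state in ("raw", "filtered"):
            with np.errstate(invalid="ignore"):
                if (self.data.to_numpy(dtype=float) <= 0).any():
                    raise ValueError("raw abundances must be positive where present")
        if self.state in ("imputed", "transformed") and self.data.isna().any().any():
            raise ValueError(f"{self.state} matrix must have no missing cells")

    @property
    def missing_fraction(self) -> pd.Series:
        return self.data.isna().mean(axis=0)


@dataclass
class QcPlan:
    """Per-metabolite disposition with reason codes.

    ``table`` columns: metabolite_id, disposition (continuous |
    presence_absence | excluded), missing_frac, n_present, reason.
    """

    table: pd.DataFrame
    miss_threshold: float
    presence_min: int

    def ids(self, disposition: str) -> list[str]:
        t = self.table
        return t.loc[t["disposition"] == disposition, "metabolite_id"].tolist()


def classify_metabolites(
    matrix: MetaboliteMatrix,
    annotation: pd.DataFrame,
    miss_threshold: float = 0.20,
    presence_min: int = 11,
) -> QcPlan:
    """Disposition every metabolite by missingness and xenobiotic status.

    Missingness strictly greater than ``miss_threshold`` triggers the rule
    (exactly 20% missing is retained as continuous).
    """
    if matrix.state != "raw":
        raise ValueError(f"classification expects a raw matrix, got {matrix.state!r}")
    ann = annotation.set_index("metabolite_id")
    missing_ann = [m for m in matrix.data.columns if m not in ann.index]
    if missing_ann:
        raise KeyError(f"annotation missing for metabolites: {missing_ann[:5]}")
    n = len(matrix.data)
    rows = []
    for met in matrix.data.columns:
        col = matrix.data[met]
        n_present = int(col.notna().sum())
        frac = 1.0 - n_present / n
        xeno = bool(ann.at[met, "xenobiotic"])
        if frac <= miss_threshold:
            disp, reason = "continuous", "missingness within threshold"
        elif not xeno:
            disp, reason = "excluded", f"non-xenobiotic with >{miss_threshold:.0%} missing"
        elif n_present < presence_min:
            disp, reason = "excluded", f"xenobiotic present in <{presence_min} samples"
        else:
            disp, reason = "presence_absence", f"xenobiotic with >{miss_threshold:.0%} missing"
        rows.append(
            {
                "metabolite_id": met,
                "disposition": disp,
                "missing_frac": frac,
                "n_present": n_present,
                "xenobiotic": xeno,
                "reason": reason,
            }
        )
    return QcPlan(table=pd.DataFrame(rows), miss_threshold=miss_threshold, presence_min=presence_min)


def sample_qc(
    matrix: MetaboliteMatrix,
    sample_miss_threshold: float = 0.5,
    outlier_sd: float = 5.0,
    n_pcs: int = 2,
) -> tuple[list[str], pd.DataFrame]:
    """Exclude samples with extreme missingness or PCA outliers.

    A sample is dropped if its missing fraction exceeds
    ``sample_miss_threshold`` or it lies beyond ``outlier_sd`` standard
    deviations on any of the first ``n_pcs`` principal components of the
    (median-imputed, standardized) log-abundance matrix. Defaults are chosen
    so that clean data lose no samples. Returns (retained ids, report).
    """
    if matrix.state != "raw":
        raise ValueError("sample QC expects a raw matrix")
    data = matrix.data
    miss = data.isna().mean(axis=1)
    report = pd.DataFrame({"sample_id": data.index, "missing_frac": miss.to_numpy()})
    report["fail_missingness"] = report["missing_frac"] > sample_miss_threshold

    logx = np.log(data.to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(logx, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    filled = np.where(np.isnan(logx), med, logx)
    sd = filled.std(axis=0)
    sd[sd == 0] = 1.0
    zs = (filled - filled.mean(axis=0)) / sd
    from sklearn.decomposition import PCA

    k = min(n_pcs, zs.shape[0] - 1, zs.shape[1])
    pcs = PCA(n_components=k, random_state=0).fit_transform(zs)
    pc_fail = np.zeros(len(data), dtype=bool)
    for j in range(pcs.shape[1]):
        col = pcs[:, j]
        s = col.std()
        if s > 0:
            pc_fail |= np.abs(col - col.mean()) > outlier_sd * s
        report[f"pc{j + 1}"] = col
    report["fail_pca"] = pc_fail
    report["retained"] = ~(report["fail_missingness"] | report["fail_pca"])
    retained = report.loc[report["retained"], "sample_id"].tolist()
    if not retained:
        raise ValueError("sample QC excluded every sample")
    return retained, report


def impute_missing(matrix: MetaboliteMatrix, method: str = "forest", seed: int = 0) -> MetaboliteMatrix:
    """Fill missing cells of a continuous-block matrix; observed cells are
    left untouched.

    ``forest`` is an iterative ensemble-regression imputer (each incomplete
    metabolite regressed on the others over a few rounds) run on the log
    scale and exponentiated back; seed-deterministic. ``median`` fills each
    column with its observed median (deterministic fallback).
    """
    if method not in ("forest", "median"):
        raise ValueError(f"unknown imputation method {method!r}")
    data = matrix.data
    fully_missing = data.columns[data.isna().all(axis=0)]
    if len(fully_missing):
        raise ValueError(f"fully missing metabolites should have been excluded: {list(fully_missing)[:5]}")
    if not data.isna().any().any():
        return MetaboliteMatrix(data=data.copy(), state="imputed")
    if method == "median":
        out = data.fillna(data.median(axis=0))
        return MetaboliteMatrix(data=out, state="imputed")

    from sklearn.ensemble import ExtraTreesRegressor
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    logx = np.log(data.to_numpy(dtype=float))
    imputer = IterativeImputer(
        estimator=ExtraTreesRegressor(n_estimators=10, random_state=seed, n_jobs=1),
        max_iter=5,
        random_state=seed,
        sample_posterior=False,
        keep_empty_features=True,
    )
    filled = imputer.fit_transform(logx)
    out = np.exp(filled)
    # observed cells byte-identical to input
    obs = ~np.isnan(logx)
    outv = np.where(obs, data.to_numpy(dtype=float), out)
    return MetaboliteMatrix(data=pd.DataFrame(outv, index=data.index, columns=data.columns), state="imputed")


def rank_inverse_normal(values: np.ndarray | pd.Series, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse-normal transform.

    y_i = Phi^-1((rank_i - c) / (n - 2c + 1)) with c = 3/8 (so the
    denominator is n + 1/4); ties get average ranks. Strictly monotone on
    tie-free input; requires n >= 3 and no missing values.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("rank-based INT requires complete data")
    n = len(x)
    if n < 3:
        raise ValueError(f"rank-based INT needs n >= 3, got {n}")
    ranks = stats.rankdata(x, method="average")
    return ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))


def transform_matrix(matrix: MetaboliteMatrix, offset: float = 3.0 / 8.0) -> MetaboliteMatrix:
    """Apply the rank-based INT column-wise to an imputed matrix."""
    if matrix.state != "imputed":
        raise ValueError("transformation expects an imputed matrix")
    out = {c: rank_inverse_normal(matrix.data[c].to_numpy(), offset=offset) for c in matrix.data.columns}
    return MetaboliteMatrix(data=pd.DataFrame(out, index=matrix.data.index), state="transformed")


def to_presence_absence(matrix: MetaboliteMatrix, plan: QcPlan) -> pd.DataFrame:
    """0/1 detection table for the presence/absence-dispositioned metabolites
    (from the raw matrix: detected = observed cell)."""
    if matrix.state != "raw":
        raise ValueError("presence/absence coding uses the raw matrix")
    pa_ids = plan.ids("presence_absence")
    return matrix.data[pa_ids].notna().astype(int)


@dataclass
class QcResult:
    """Everything downstream of QC: the Model-1 and Model-2 inputs."""

    transformed: MetaboliteMatrix  # continuous block, INT-transformed
    presence_absence: pd.DataFrame  # 0/1 detection table
    raw_filtered: MetaboliteMatrix  # raw values, QC-retained samples, all analyzed metabolites
    plan: QcPlan
    retained_samples: list[str]
    sample_report: pd.DataFrame


def run_qc(
    matrix: MetaboliteMatrix,
    annotation: pd.DataFrame,
    miss_threshold: float = 0.20,
    presence_min: int = 11,
    sample_miss_threshold: float = 0.5,
    outlier_sd: float = 5.0,
    impute_method: str = "forest",
    seed: int = 0,
) -> QcResult:
    """Full preprocessing: sample QC -> disposition -> impute -> transform."""
    retained, sample_report = sample_qc(
        matrix, sample_miss_threshold=sample_miss_threshold, outlier_sd=outlier_sd
    )
    filtered = MetaboliteMatrix(data=matrix.data.loc[retained], state="raw")
    plan = classify_metabolites(filtered, annotation, miss_threshold=miss_threshold, presence_min=presence_min)
    cont = MetaboliteMatrix(data=filtered.data[plan.ids("continuous")], state="raw")
    imputed = impute_missing(cont, method=impute_method, seed=seed)
    transformed = transform_matrix(imputed)
    pa = to_presence_absence(filtered, plan)
    analyzed = plan.ids("continuous") + plan.ids("presence_absence")
    return QcResult(
        transformed=transformed,
        presence_absence=pa,
        raw_filtered=MetaboliteMatrix(data=filtered.data[analyzed], state="raw"),
        plan=plan,
        retained_samples=retained,
        sample_report=sample_report,
    )
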