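"""Per-CpG association of methylation with current smoking.

Each CpG's beta value is regressed on a current-vs-never smoker indicator
adjusted for age and cell composition (immune-cell proportion in buccal and
cervical samples, lymphoid proportion in blood).  Ex-smokers and
alternative exposures are excluded at this discovery stage.  P values come
from the t distribution with residual degrees of freedom, and family-wise
error is controlled per tissue by step-down Holm adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .deconvolution import CellFractions
from .io_formats import BetaMatrix, SampleSheet

__all__ = [
    "EwasResult",
    "EwasError",
    "fit_cpg",
    "run_ewas",
    "holm_adjust",
    "significant_sites",
    "write_ewas_result",
    "read_ewas_result",
]

# chi-square(1) median, for the genomic-inflation diagnostic
_CHI2_MEDIAN = stats.chi2.ppf(0.5, 1)

SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}


class EwasError(ValueError):
    pass


@dataclass
class EwasResult:
    """Per-CpG effect estimates for one tissue.

    ``table`` columns: effect (beta-scale current-vs-never difference), se,
    p, p_holm, n, flag.  ``lambda_gc`` is the median-chi-square inflation
    factor; ~1 under the null.
    """

    table: pd.DataFrame
    tissue: str
    lambda_gc: float = np.nan
    covariates: tuple[str, ...] = ("age", "composition")

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["p_holm"] < alpha]


def _design_matrix(
    sheet: SampleSheet,
    fractions: CellFractions,
    sample_ids,
    composition_covariate: str,
    extra_covariates: pd.DataFrame | None = None,
) -> np.ndarray:
    smoking = sheet.column("smoking_type", sample_ids)
    age = sheet.column("age", sample_ids).to_numpy(dtype=float)
    if composition_covariate == "immune_proportion":
        comp = fractions.immune_proportion.reindex(sample_ids).to_numpy(dtype=float)
    elif composition_covariate == "lymphoid_proportion":
        comp = fractions.lymphoid_proportion.reindex(sample_ids).to_numpy(dtype=float)
    else:
        raise EwasError(
            "composition_covariate must be 'immune_proportion' or "
            f"'lymphoid_proportion', got {composition_covariate!r}"
        )
    current = (smoking == "current").to_numpy(dtype=float)
    cols = [np.ones(len(sample_ids)), current, age, comp]
    names = ["intercept", "current", "age", composition_covariate]
    if extra_covariates is not None:
        extra = extra_covariates.reindex(sample_ids)
        cols.extend(extra[c].to_numpy(dtype=float) for c in extra.columns)
        names.extend(map(str, extra.columns))
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise EwasError("missing covariate values for some samples")
    _check_collinearity(X, names)
    return X

def _check_collinearity(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        centered = X[:, 1:] - X[:, 1:].mean(axis=0)
        sd = centered.std(axis=0)
        degenerate = [names[i + 1] for i in np.flatnonzero(sd < 1e-12)]
        if degenerate:
            raise EwasError(f"constant covariate(s): {degenerate}")
        corr = np.corrcoef(centered, rowvar=False)
        i, j = divmod(int(np.argmax(np.abs(np.triu(corr, 1)))), corr.shape[1])
        raise EwasError(
            f"collinear covariates: {names[i + 1]!r} and {names[j + 1]!r}"
        )


def _ols_rows(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OLS of every row of Y on the shared design X.

    Returns (effect, se, p, n) for the column-1 coefficient.  Rows with
    missing values are refit complete-case; constant rows get p = 1.
    """
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T  # k x n

    effect = np.full(Y.shape[0], np.nan)
    se = np.full(Y.shape[0], np.nan)
    pval = np.full(Y.shape[0], np.nan)
    nused = np.full(Y.shape[0], n, dtype=int)

    complete = ~np.isnan(Y).any(axis=1)
    if complete.any():
        Yc = Y[complete]
        B = Yc @ H.T  # rows x k
        resid = Yc - B @ X.T
        dof = n - k
        s2 = (resid**2).sum(axis=1) / dof
        se_c = np.sqrt(s2 * XtX_inv[1, 1])
        eff_c = B[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = eff_c / se_c
        p_c = 2.0 * stats.t.sf(np.abs(tstat), dof)
        effect[complete] = eff_c
        se[complete] = se_c
        pval[complete] = p_c

    for i in np.flatnonzero(~complete):
        y = Y[i]
        mask = ~np.isnan(y)
        ni = int(mask.sum())
        nused[i] = ni
        if ni <= k:
            continue
        Xi = X[mask]
        XtX_inv_i = np.linalg.inv(Xi.T @ Xi)
        b = XtX_inv_i @ Xi.T @ y[mask]
        resid = y[mask] - Xi @ b
        s2 = (resid**2).sum() / (ni - k)
        se_i = float(np.sqrt(s2 * XtX_inv_i[1, 1]))
        effect[i] = b[1]
        se[i] = se_i
        with np.errstate(divide="ignore", invalid="ignore"):
            pval[i] = 2.0 * stats.t.sf(abs(b[1] / se_i), ni - k) if se_i > 0 else 1.0

    return effect, se, pval, nused


def fit_cpg(
    beta_row: pd.Series,
    sheet: SampleSheet,
    fractions: CellFractions,
    composition_covariate: str = "immune_proportion",
    min_per_group: int = 10,
    extra_covariates: pd.DataFrame | None = None,
) -> tuple[float, float, float]:
    """Fit one CpG; returns (effect, se, p) for the current-smoker term."""
    sample_ids = beta_row.index
    _check_group_sizes(sheet, sample_ids, min_per_group)
    X = _design_matrix(
        sheet, fractions, sample_ids, composition_covariate, extra_covariates
    )
    Y = beta_row.to_numpy(dtype=float)[None, :]
    if np.nanstd(Y) < 1e-12:
        return 0.0, np.nan, 1.0
    eff, se, p, _ = _ols_rows(Y, X)
    return float(eff[0]), float(se[0]), float(p[0])


def _check_group_sizes(sheet, sample_ids, min_per_group):
    smoking = sheet.column("smoking_type", sample_ids)
    counts = smoking.value_counts()
    for grp in ("never", "current"):
        if counts.get(grp, 0) < min_per_group:
            raise EwasError(
                f"need >= {min_per_group} samples per smoking group, "
                f"got {int(counts.get(grp, 0))} {grp!r}"
            )


def run_ewas(
    beta: BetaMatrix,
    sheet: SampleSheet,
    fractions: CellFractions,
    tissue: str,
    composition_covariate: str | None = None,
    min_per_group: int = 10,
    extra_covariates: pd.DataFrame | None = None,
) -> EwasResult:
    """EWAS over all CpGs of one tissue, with Holm adjustment per tissue.

    Only never and current smokers enter the fit.  ``composition_covariate``
    defaults to lymphoid proportion for blood and immune proportion
    otherwise.
    """
    if composition_covariate is None:
        composition_covariate = (
            "lymphoid_proportion" if tissue == "blood" else "immune_proportion"
        )
    records = sheet.data
    keep = records[
        (records["tissue"] == tissue)
        & records["smoking_type"].isin(["never", "current"])
    ]["sample_id"]
    keep = [s for s in keep if s in set(beta.sample_ids)]
    if not keep:
        raise EwasError(f"no never/current samples for tissue {tissue!r}")
    _check_group_sizes(sheet, pd.Index(keep), min_per_group)
    X = _design_matrix(
        sheet, fractions, pd.Index(keep), composition_covariate, extra_covariates
    )
    Y = beta.data[keep].to_numpy(dtype=float)

    effect, se, pval, nused = _ols_rows(Y, X)
    flag = np.where(np.isnan(pval), "fit_failed", "")
    constant = np.nanstd(Y, axis=1) < 1e-12
    effect[constant] = 0.0
    se[constant] = np.nan
    pval[constant] = 1.0
    flag = np.where(constant, "constant", flag)

    tested = ~np.isnan(pval)
    p_holm = np.full_like(pval, np.nan)
    if tested.any():
        p_holm[tested] = holm_adjust(pval[tested])

    chi2 = stats.chi2.isf(pval[tested], 1)
    lambda_gc = float(np.median(chi2) / _CHI2_MEDIAN) if tested.any() else np.nan

    table = pd.DataFrame(
        {
            "effect": effect,
            "se": se,
            "p": pval,
            "p_holm": p_holm,
            "n": nused,
            "flag": flag,
        },
        index=beta.cpg_ids,
    )
    n_failed = int((flag == "fit_failed").sum())
    if n_failed:
        warnings.warn(f"{n_failed} CpGs could not be fitted", stacklevel=2)
    return EwasResult(
        table=table,
        tissue=tissue,
        lambda_gc=lambda_gc,
        covariates=("age", composition_covariate),
    )


def holm_adjust(pvals) -> np.ndarray:
    """Step-down Holm–Bonferroni adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise EwasError("holm_adjust expects a 1-D p-value vector")
    if np.isnan(p).any():
        raise EwasError("NaN p-values are not allowed in holm_adjust")
    if ((p < 0) | (p > 1)).any():
        raise EwasError("p-values must lie in [0,1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def significant_sites(
    results: dict[str, EwasResult] | list[EwasResult],
    alpha: float = 0.05,
    annotation: pd.Series | None = None,
) -> list[str]:
    """Union of Holm-significant CpGs across tissues, minus sex chromosomes.

    Sex-chromosome CpGs are removed only when an annotation is supplied;
    CpGs absent from the annotation are retained with a warning.
    """
    if isinstance(results, dict):
        results = list(results.values())
    if not results:
        raise EwasError("no EWAS results supplied")
    hits: set[str] = set()
    for res in results:
        hits.update(res.significant(alpha))
    if annotation is not None:
        unannotated = sorted(c for c in hits if c not in annotation.index)
        if unannotated:
            warnings.warn(
                f"{len(unannotated)} significant CpGs missing from annotation; retained",
                stacklevel=2,
            )
        hits = {
            c
            for c in hits
            if c in unannotated or annotation.get(c) not in SEX_CHROMOSOMES
        }
    return sorted(hits)


def write_ewas_result(res: EwasResult, path) -> None:
    out = res.table.copy()
    out.insert(0, "tissue", res.tissue)
    out.insert(0, "cpg_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ewas_result(path) -> EwasResult:
    raw = pd.read_csv(path, sep="\t", dtype={"cpg_id": str}, na_values=["NA"])
    raw["flag"] = raw["flag"].fillna("") if "flag" in raw else ""
    tissue = raw["tissue"].iloc[0] if len(raw) else ""
    table = raw.set_index("cpg_id").drop(columns=["tissue"])
    return EwasResult(table=table, tissue=tissue)
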