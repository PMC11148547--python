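"""Compartment-specific delta-beta by intercept extrapolation.

For each CpG, beta values are regressed on cell composition separately in
current smokers and never smokers.  The two lines evaluated at immune-cell
proportion 0 give the group means in a pure epithelial population, and at
proportion 1 in a pure immune population; their differences are the
epithelial and immune delta-beta estimates.  Blood replaces immune
proportion with lymphoid proportion (1 - myeloid), so proportion 1 yields
the lymphoid and proportion 0 the myeloid delta-beta.  Stacking the six
tissue-compartment estimates per CpG yields the delta-beta feature matrix
that clustering consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolution import CellFractions
from .io_formats import BetaMatrix, SampleSheet

__all__ = [
    "DELTA_COLUMNS",
    "GroupLine",
    "DeltaBetaProfile",
    "ExtrapolationError",
    "fit_group_lines",
    "delta_beta",
    "build_delta_matrix",
    "write_delta_matrix",
    "read_delta_matrix",
]

# fixed column order of the cross-tissue delta-beta feature matrix
DELTA_COLUMNS = (
    "epithelial_buccal",
    "immune_buccal",
    "epithelial_cervical",
    "immune_cervical",
    "lymphoid_blood",
    "myeloid_blood",
)

MIN_N_PER_GROUP = 20
SPREAD_MIN = 0.2


class ExtrapolationError(ValueError):
    pass


@dataclass
class GroupLine:
    """Least-squares line of beta on composition for one smoking group."""

    group: str
    intercept: float
    slope: float
    n: int
    resid_sd: float
    se_at0: float
    se_at1: float

    def at(self, f: float) -> float:
        return self.intercept + self.slope * f

    def se_at(self, f: float) -> float:
        if f == 0.0:
            return self.se_at0
        if f == 1.0:
            return self.se_at1
        raise ExtrapolationError("standard errors are tracked at f=0 and f=1 only")


@dataclass
class DeltaBetaProfile:
    """Per-CpG six-vector of compartment-specific smoking effects.

    ``values`` holds unclipped estimates (NaN where a tissue is missing);
    ``se`` the matching standard errors.  Reported values are clipped to
    [-1, 1] on write only.
    """

    values: pd.DataFrame
    se: pd.DataFrame

    def __post_init__(self) -> None:
        for df in (self.values, self.se):
            if list(df.columns) != list(DELTA_COLUMNS):
                raise ExtrapolationError(
                    f"delta matrix columns must be {list(DELTA_COLUMNS)}"
                )

    @property
    def clipped(self) -> pd.DataFrame:
        return self.values.clip(-1.0, 1.0)


def _line_stats(y: np.ndarray, f: np.ndarray) -> tuple[float, float, float, float, float]:
    """Closed-form simple regression: intercept, slope, resid SD, SE at 0 and 1."""
    n = len(y)
    fbar = f.mean()
    ybar = y.mean()
    sxx = ((f - fbar) ** 2).sum()
    slope = ((f - fbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * fbar
    resid = y - intercept - slope * f
    dof = n - 2
    s2 = (resid**2).sum() / dof if dof > 0 else np.nan
    se0 = np.sqrt(s2 * (1.0 / n + fbar**2 / sxx))
    se1 = np.sqrt(s2 * (1.0 / n + (1.0 - fbar) ** 2 / sxx))
    return intercept, slope, float(np.sqrt(s2)), float(se0), float(se1)


def fit_group_lines(
    beta_row: pd.Series | np.ndarray,
    f: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    min_n: int = MIN_N_PER_GROUP,
    spread_min: float = SPREAD_MIN,
) -> dict[str, GroupLine]:
    """One least-squares line of beta on composition per smoking group.

    Extrapolation to the pure compartments is fragile when a group is small
    or its composition values barely vary, so groups below ``min_n`` samples
    or ``spread_min`` composition range are rejected.
    """
    y = np.asarray(beta_row, dtype=float)
    fv = np.asarray(f, dtype=float)
    gv = np.asarray(groups)
    if not (len(y) == len(fv) == len(gv)):
        raise ExtrapolationError("beta, composition and group vectors must align")
    out: dict[str, GroupLine] = {}
    for grp in pd.unique(gv):
        mask = (gv == grp) & ~np.isnan(y) & ~np.isnan(fv)
        n = int(mask.sum())
        if n < min_n:
            raise ExtrapolationError(
                f"group {grp!r} has {n} usable samples, need >= {min_n}"
            )
        spread = fv[mask].max() - fv[mask].min()
        if spread < spread_min:
            raise ExtrapolationError(
                f"composition range too narrow for extrapolation in group {grp!r} "
                f"(spread {spread:.3f} < {spread_min})"
            )
        intercept, slope, rsd, se0, se1 = _line_stats(y[mask], fv[mask])
        out[str(grp)] = GroupLine(
            group=str(grp),
            intercept=intercept,
            slope=slope,
            n=n,
            resid_sd=rsd,
            se_at0=se0,
            se_at1=se1,
        )
    return out


def delta_beta(
    beta_row,
    f,
    groups,
    at: float,
    case: str = "current",
    control: str = "never",
    **fit_kwargs,
) -> float:
    """Delta-beta at a pure compartment: case line minus control line at ``at``.

    ``at=0`` extrapolates to the compartment absent from the composition
    covariate (epithelial, or myeloid in blood); ``at=1`` to the compartment
    the covariate measures (immune, or lymphoid).
    """
    if at not in (0.0, 1.0, 0, 1):
        raise ExtrapolationError("delta-beta is defined at f=0 or f=1")
    lines = fit_group_lines(beta_row, f, groups, **fit_kwargs)
    for grp in (case, control):
        if grp not in lines:
            raise ExtrapolationError(f"group {grp!r} absent from data")
    return lines[case].at(float(at)) - lines[control].at(float(at))


def _lines_matrix(
    Y: np.ndarray, f: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise simple regression of Y (CpG x sample) on f, NaN-aware.

    Returns (intercept, slope, var_at0, var_at1) per row.
    """
    valid = ~np.isnan(Y)
    n = valid.sum(axis=1).astype(float)
    F = np.where(valid, f[None, :], 0.0)
    Yz = np.where(valid, Y, 0.0)
    fbar = F.sum(axis=1) / n
    ybar = Yz.sum(axis=1) / n
    fc = np.where(valid, f[None, :] - fbar[:, None], 0.0)
    yc = np.where(valid, Y - ybar[:, None], 0.0)
    sxx = (fc**2).sum(axis=1)
    slope = (fc * yc).sum(axis=1) / sxx
    intercept = ybar - slope * fbar
    resid = np.where(valid, Y - intercept[:, None] - slope[:, None] * f[None, :], 0.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = (resid**2).sum(axis=1) / dof
        var0 = s2 * (1.0 / n + fbar**2 / sxx)
        var1 = s2 * (1.0 / n + (1.0 - fbar) ** 2 / sxx)
    return intercept, slope, var0, var1


def build_delta_matrix(
    datasets: dict[str, tuple[BetaMatrix, SampleSheet, CellFractions]],
    cpg_list,
    min_n: int = MIN_N_PER_GROUP,
    spread_min: float = SPREAD_MIN,
) -> DeltaBetaProfile:
    """Assemble the cross-tissue delta-beta feature matrix for ``cpg_list``.

    ``datasets`` maps tissue name to its (beta, sheet, fractions) triple.
    Buccal and cervical contribute epithelial (f=0) and immune (f=1)
    columns against immune proportion; blood contributes myeloid (f=0) and
    lymphoid (f=1) columns against lymphoid proportion.  Columns of absent
    tissues are NaN.
    """
    cpg_list = list(cpg_list)
    if not cpg_list:
        raise ExtrapolationError("cpg_list is empty")
    if not datasets:
        raise ExtrapolationError("no tissue datasets supplied")
    index = pd.Index(cpg_list, name="cpg_id")
    values = pd.DataFrame(np.nan, index=index, columns=list(DELTA_COLUMNS))
    ses = pd.DataFrame(np.nan, index=index, columns=list(DELTA_COLUMNS))

    column_map = {
        "buccal": {0.0: "epithelial_buccal", 1.0: "immune_buccal"},
        "cervical": {0.0: "epithelial_cervical", 1.0: "immune_cervical"},
        "blood": {0.0: "myeloid_blood", 1.0: "lymphoid_blood"},
    }

    for tissue, (beta, sheet, fractions) in datasets.items():
        if tissue not in column_map:
            raise ExtrapolationError(f"unknown tissue {tissue!r}")
        present = [c for c in cpg_list if c in set(beta.cpg_ids)]
        if not present:
            continue
        sample_ids = beta.sample_ids
        smoking = sheet.column("smoking_type", sample_ids)
        if tissue == "blood":
            f_all = fractions.lymphoid_proportion.reindex(sample_ids).to_numpy(float)
        else:
            f_all = fractions.immune_proportion.reindex(sample_ids).to_numpy(float)

        stats_by_group = {}
        for grp in ("never", "current"):
            mask = (smoking == grp).to_numpy() & ~np.isnan(f_all)
            n = int(mask.sum())
            if n < min_n:
                raise ExtrapolationError(
                    f"{tissue}: group {grp!r} has {n} samples, need >= {min_n}"
                )
            spread = f_all[mask].max() - f_all[mask].min()
            if spread < spread_min:
                raise ExtrapolationError(
                    f"{tissue}: composition range too narrow for extrapolation "
                    f"in group {grp!r} (spread {spread:.3f} < {spread_min})"
                )
            Y = beta.data.loc[present, sample_ids[mask]].to_numpy(float)
            stats_by_group[grp] = _lines_matrix(Y, f_all[mask])

        (i_n, s_n, v0_n, v1_n) = stats_by_group["never"]
        (i_c, s_c, v0_c, v1_c) = stats_by_group["current"]
        d0 = i_c - i_n
        d1 = (i_c + s_c) - (i_n + s_n)
        se0 = np.sqrt(v0_c + v0_n)
        se1 = np.sqrt(v1_c + v1_n)
        values.loc[present, column_map[tissue][0.0]] = d0
        values.loc[present, column_map[tissue][1.0]] = d1
        ses.loc[present, column_map[tissue][0.0]] = se0
        ses.loc[present, column_map[tissue][1.0]] = se1

    return DeltaBetaProfile(values=values, se=ses)


def write_delta_matrix(profile: DeltaBetaProfile, path) -> None:
    out = profile.clipped.copy()
    for col in DELTA_COLUMNS:
        out[f"se_{col}"] = profile.se[col]
    out.insert(0, "cpg_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NA")


def read_delta_matrix(path) -> DeltaBetaProfile:
    raw = pd.read_csv(path, sep="\t", dtype={"cpg_id": str}, na_values=["NA"])
    raw = raw.set_index("cpg_id")
    values = raw[list(DELTA_COLUMNS)].astype(float)
    se = raw[[f"se_{c}" for c in DELTA_COLUMNS]].astype(float)
    se.columns = list(DELTA_COLUMNS)
    return DeltaBetaProfile(values=values, se=se)
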