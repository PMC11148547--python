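"""Reference-based cell-type deconvolution of bulk methylation profiles.

Per-sample compartment fractions are estimated by non-negative least
squares against a reference matrix of pure-compartment mean beta values,
then renormalised to sum to one.  A two-level (tissue compartments ->
immune subtypes) variant rescales subtype estimates to the level-1 immune
fraction, and blood subtype fractions aggregate into myeloid / lymphoid
lineages (lymphoid = 1 - myeloid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_formats import BetaMatrix, FormatError

__all__ = [
    "ReferenceMatrix",
    "CellFractions",
    "DeconvolutionError",
    "estimate_fractions",
    "aggregate_lineages",
    "hierarchical_fractions",
    "read_reference",
    "write_reference",
    "read_fractions",
    "write_fractions",
]

MYELOID_SUBTYPES = ("monocyte", "neutrophil", "eosinophil")

# below this many shared CpGs the least-squares problem is considered fragile
MIN_SHARED_CPGS = 30


class DeconvolutionError(ValueError):
    pass


@dataclass
class ReferenceMatrix:
    """Pure-compartment mean beta profiles: CpG x compartment."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise DeconvolutionError("reference needs at least two compartments")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
            raise DeconvolutionError("reference values must be finite and in [0,1]")

    @property
    def compartments(self) -> pd.Index:
        return self.data.columns


@dataclass
class CellFractions:
    """Per-sample compartment proportions (rows sum to 1 over estimated compartments)."""

    data: pd.DataFrame

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def immune_proportion(self) -> pd.Series:
        """Fraction of immune cells; the x-axis of every extrapolation fit."""
        if "immune" in self.data.columns:
            return self.data["immune"].rename("immune_proportion")
        subtypes = [c for c in self.data.columns if c in MYELOID_SUBTYPES]
        if subtypes:  # blood-style table: everything is immune
            return pd.Series(1.0, index=self.data.index, name="immune_proportion")
        raise DeconvolutionError("no 'immune' compartment in fractions")

    @property
    def lymphoid_proportion(self) -> pd.Series:
        """Lymphoid share of blood, defined as 1 - (myeloid proportion)."""
        if "lymphoid" in self.data.columns:
            return self.data["lymphoid"].rename("lymphoid_proportion")
        missing = [c for c in MYELOID_SUBTYPES if c not in self.data.columns]
        if missing:
            raise DeconvolutionError(
                f"cannot derive lymphoid proportion: missing subtypes {missing}"
            )
        myeloid = self.data[list(MYELOID_SUBTYPES)].sum(axis=1)
        return (1.0 - myeloid).rename("lymphoid_proportion")


def _solve_sample(R: np.ndarray, b: np.ndarray, robust: bool) -> np.ndarray:
    mask = ~np.isnan(b)
    w, _ = nnls(R[mask], b[mask])
    if robust:
        # Huber-weighted IRLS around the NNLS solution
        for _ in range(10):
            resid = b[mask] - R[mask] @ w
            scale = max(1.4826 * np.median(np.abs(resid)), 1e-8)
            hw = np.minimum(1.0, 1.345 * scale / np.maximum(np.abs(resid), 1e-12))
            sw = np.sqrt(hw)
            w_new, _ = nnls(R[mask] * sw[:, None], b[mask] * sw)
            if np.allclose(w_new, w, atol=1e-8):
                w = w_new
                break
            w = w_new
    total = w.sum()
    if total <= 1e-12:
        return np.full_like(w, 1.0 / len(w))
    return w / total


def estimate_fractions(
    beta: BetaMatrix, ref: ReferenceMatrix, robust: bool = False
) -> CellFractions:
    """Estimate compartment fractions per sample.

    Solves ``min ||b - R w||^2 subject to w >= 0`` on the CpGs shared
    between the bulk matrix and the reference, then normalises ``w`` to sum
    to one.  ``robust=True`` enables Huber-weighted iterative reweighting.
    """
    shared = ref.data.index.intersection(beta.cpg_ids)
    if len(shared) == 0:
        raise DeconvolutionError("no shared CpGs between beta matrix and reference")
    if len(shared) < MIN_SHARED_CPGS:
        warnings.warn(
            f"only {len(shared)} CpGs shared with reference; "
            "fraction estimates may be unstable",
            stacklevel=2,
        )
    R = ref.data.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise DeconvolutionError("reference is rank-deficient on the shared CpGs")
    B = beta.data.loc[shared].to_numpy(dtype=float)
    out = np.empty((B.shape[1], R.shape[1]))
    for j in range(B.shape[1]):
        out[j] = _solve_sample(R, B[:, j], robust)
    return CellFractions(
        pd.DataFrame(out, index=beta.sample_ids, columns=ref.compartments)
    )


def aggregate_lineages(fractions: CellFractions) -> CellFractions:
    """Collapse blood immune subtypes into myeloid / lymphoid lineages.

    Myeloid is the sum of monocyte, neutrophil and eosinophil fractions;
    lymphoid is its complement.
    """
    missing = [c for c in MYELOID_SUBTYPES if c not in fractions.data.columns]
    if missing:
        raise DeconvolutionError(f"missing myeloid constituent subtypes: {missing}")
    out = fractions.data.copy()
    out["myeloid"] = out[list(MYELOID_SUBTYPES)].sum(axis=1)
    out["lymphoid"] = 1.0 - out["myeloid"]
    return CellFractions(out)


def hierarchical_fractions(
    beta: BetaMatrix,
    ref_level1: ReferenceMatrix,
    ref_level2: ReferenceMatrix,
    immune_label: str = "immune",
    robust: bool = False,
) -> CellFractions:
    """Two-level deconvolution: tissue compartments, then immune subtypes.

    Level-2 subtype fractions are estimated on the bulk profile (jointly
    with the non-immune level-1 compartments, so their signal does not leak
    into the subtype weights), normalised among themselves, and rescaled so
    they sum to the level-1 immune fraction of each sample.
    """
    if immune_label not in ref_level1.compartments:
        raise DeconvolutionError(
            f"level-1 reference lacks an {immune_label!r} compartment"
        )
    level1 = estimate_fractions(beta, ref_level1, robust=robust)
    non_immune = [c for c in ref_level1.compartments if c != immune_label]
    shared = ref_level1.data.index.intersection(ref_level2.data.index)
    combined_ref = ReferenceMatrix(
        pd.concat(
            [ref_level1.data.loc[shared, non_immune], ref_level2.data.loc[shared]],
            axis=1,
        )
    )
    combined = estimate_fractions(beta, combined_ref, robust=robust)
    raw_sub = combined.data[list(ref_level2.compartments)]
    sub_total = raw_sub.sum(axis=1)
    norm_sub = raw_sub.div(sub_total.where(sub_total > 0, 1.0), axis=0)
    immune_total = level1.data[immune_label]
    scaled = norm_sub.mul(immune_total, axis=0)
    out = pd.concat([level1.data.drop(columns=[immune_label]), scaled], axis=1)
    out[immune_label] = immune_total
    return CellFractions(out)


def write_reference(ref: ReferenceMatrix, path) -> None:
    out = ref.data.copy()
    out.insert(0, "cpg_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_reference(path) -> ReferenceMatrix:
    raw = pd.read_csv(path, sep="\t", dtype={"cpg_id": str})
    if "cpg_id" not in raw.columns:
        raise FormatError(f"{path}: first column must be 'cpg_id'")
    return ReferenceMatrix(raw.set_index("cpg_id").astype(float))


def write_fractions(fractions: CellFractions, path) -> None:
    out = fractions.data.copy()
    try:
        out["immune_proportion"] = fractions.immune_proportion
    except DeconvolutionError:
        pass
    try:
        out["lymphoid_proportion"] = fractions.lymphoid_proportion
    except DeconvolutionError:
        pass
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, index=False, float_format="%.6f")


def read_fractions(path) -> CellFractions:
    raw = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in raw.columns:
        raise FormatError(f"{path}: first column must be 'sample_id'")
    raw = raw.set_index("sample_id").astype(float)
    # derived columns are recomputed from the base compartments when those
    # are present; an externally supplied file may carry only the derived ones
    if "immune" in raw.columns:
        raw = raw.drop(columns=["immune_proportion"], errors="ignore")
    elif "immune_proportion" in raw.columns:
        raw = raw.rename(columns={"immune_proportion": "immune"})
    if "lymphoid" in raw.columns or all(c in raw.columns for c in MYELOID_SUBTYPES):
        raw = raw.drop(columns=["lymphoid_proportion"], errors="ignore")
    elif "lymphoid_proportion" in raw.columns:
        raw = raw.rename(columns={"lymphoid_proportion": "lymphoid"})
    return CellFractions(raw)
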