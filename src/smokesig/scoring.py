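"""Mean-methylation signature scores with cell-composition correction.

The raw score of a sample for a CpG set is the mean beta over the set's
members present in the matrix.  Because that mean tracks cell composition
as much as exposure, a correction fits, per smoking type, a line of score
against immune-cell proportion and moves every sample to the pure target
compartment: the sample's residual from its type's line is added to the
line's value at immune proportion 0 (pure epithelial; for the epithelial
sets) or 1 (pure immune; for the immune set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, CpGSet, SampleSheet

__all__ = [
    "CorrectionModel",
    "ScoringError",
    "mean_score",
    "fit_correction",
    "correct_scores",
    "score_table",
    "write_score_table",
]

MIN_N_PER_TYPE = 10
SPREAD_MIN = 0.1


class ScoringError(ValueError):
    pass


@dataclass
class CorrectionModel:
    """Per-type score-vs-composition lines and the target proportion f*."""

    lines: dict[str, tuple[float, float]]  # type -> (intercept, slope)
    target_f: float

    def predict(self, type_: str, f) -> np.ndarray:
        if type_ not in self.lines:
            raise ScoringError(f"no correction line fitted for type {type_!r}")
        intercept, slope = self.lines[type_]
        return intercept + slope * np.asarray(f, dtype=float)

    def at_target(self, type_: str) -> float:
        intercept, slope = self.lines[type_]
        return intercept + slope * self.target_f


def mean_score(beta: BetaMatrix, cpg_set: CpGSet) -> tuple[pd.Series, pd.Series]:
    """Per-sample mean beta over the set members present in the matrix.

    Missing per-sample values are skipped; returns (score, coverage) where
    coverage is the fraction of set members that entered each sample's mean.
    """
    present = [c for c in cpg_set.cpgs if c in set(beta.cpg_ids)]
    if not present:
        raise ScoringError(
            f"no members of set {cpg_set.name!r} present in the beta matrix"
        )
    sub = beta.data.loc[present]
    score = sub.mean(axis=0, skipna=True).rename(cpg_set.name)
    coverage = (sub.notna().sum(axis=0) / len(cpg_set.cpgs)).rename("coverage")
    return score, coverage


def fit_correction(
    scores: pd.Series,
    f: pd.Series,
    types: pd.Series,
    target_f: float,
    min_n: int = MIN_N_PER_TYPE,
    spread_min: float = SPREAD_MIN,
) -> CorrectionModel:
    """Fit one score-vs-composition line per smoking type.

    Every type present in ``types`` gets its own line; the target
    proportion f* (0 for epithelial sets, 1 for the immune set) is where
    corrected scores will be read off.
    """
    if target_f not in (0.0, 1.0):
        raise ScoringError("target_f must be 0 (epithelial) or 1 (immune)")
    df = pd.DataFrame({"y": scores, "f": f, "t": types}).dropna()
    lines: dict[str, tuple[float, float]] = {}
    for type_, grp in df.groupby("t", sort=True):
        if len(grp) < min_n:
            raise ScoringError(
                f"type {type_!r} has {len(grp)} samples, need >= {min_n}"
            )
        spread = grp["f"].max() - grp["f"].min()
        if spread < spread_min:
            raise ScoringError(
                f"composition range too narrow for type {type_!r} "
                f"(spread {spread:.3f} < {spread_min})"
            )
        slope, intercept = np.polyfit(grp["f"], grp["y"], 1)
        lines[str(type_)] = (float(intercept), float(slope))
    return CorrectionModel(lines=lines, target_f=float(target_f))


def correct_scores(
    scores: pd.Series,
    f: pd.Series,
    types: pd.Series,
    model: CorrectionModel,
) -> pd.Series:
    """Move each sample's score to the pure target compartment.

    corrected = line_t(f*) + (y - line_t(f)): the residual from the
    sample's own type line is carried to the line's value at the target
    proportion.  Values are not clipped; the caller flags out-of-range ones.
    """
    missing = sorted(set(types.dropna().unique()) - set(model.lines))
    if missing:
        raise ScoringError(f"no correction line fitted for type(s) {missing}")
    out = pd.Series(np.nan, index=scores.index, name=scores.name)
    for type_ in types.dropna().unique():
        mask = (types == type_).to_numpy()
        resid = scores[mask] - model.predict(str(type_), f[mask])
        out[mask] = model.at_target(str(type_)) + resid
    return out


def score_table(
    beta: BetaMatrix,
    sets: list[CpGSet],
    fractions_f: pd.Series,
    sheet: SampleSheet,
    corrected: bool = True,
    min_n: int = MIN_N_PER_TYPE,
    spread_min: float = SPREAD_MIN,
) -> pd.DataFrame:
    """Long-format score table: one row per sample x set.

    ``fractions_f`` is the composition covariate on the score's x-axis
    (immune proportion for buccal/cervical/saliva, lymphoid proportion for
    blood).  Columns: sample_id, set, raw, corrected, f, type, coverage,
    out_of_range.
    """
    types = sheet.column("smoking_type", beta.sample_ids)
    f = fractions_f.reindex(beta.sample_ids)
    frames = []
    for s in sets:
        raw, coverage = mean_score(beta, s)
        block = pd.DataFrame(
            {
                "sample_id": beta.sample_ids,
                "set": s.name,
                "raw": raw.to_numpy(),
                "f": f.to_numpy(),
                "type": types.to_numpy(),
                "coverage": coverage.to_numpy(),
            }
        )
        if corrected:
            model = fit_correction(
                raw, f, types, target_f=s.target_fraction,
                min_n=min_n, spread_min=spread_min,
            )
            corr = correct_scores(raw, f, types, model)
            block["corrected"] = corr.to_numpy()
            block["out_of_range"] = ((corr < 0) | (corr > 1)).to_numpy().astype(int)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6f", na_rep="NA")
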