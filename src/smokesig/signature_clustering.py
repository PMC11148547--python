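"""Clustering of delta-beta profiles into signature archetypes.

Agglomerative (Ward, Euclidean) clustering of the per-CpG six-vector of
compartment-specific smoking effects, followed by rule-based labelling of
cluster mean profiles into the four archetypes: epithelial hypomethylation
(both exposed and distal epithelium), immune hypomethylation (all immune
lineages), and hypermethylation confined to distal (cervical) or proximal
(buccal) epithelium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .cell_specific import DELTA_COLUMNS, DeltaBetaProfile
from .io_formats import CpGSet

__all__ = [
    "ClusterResult",
    "ClusteringError",
    "cluster_delta_matrix",
    "label_archetypes",
    "select_k",
]

LABEL_TAU = 0.02


class ClusteringError(ValueError):
    pass


@dataclass
class ClusterResult:
    """Cluster assignments plus per-cluster mean profiles and labels."""

    assignments: pd.Series  # cpg -> cluster id
    means: pd.DataFrame  # cluster id x six delta columns
    labels: dict[int, str]  # cluster id -> archetype label
    k: int
    silhouette: float
    imputed: pd.Index = field(default_factory=lambda: pd.Index([]))

    def label_of(self, cpg: str) -> str:
        return self.labels[int(self.assignments[cpg])]

    @property
    def cpg_labels(self) -> pd.Series:
        return self.assignments.map(lambda c: self.labels[int(c)]).rename("label")

    def to_cpg_sets(self) -> list[CpGSet]:
        """Export labelled clusters as signature sets for scoring."""
        sets = []
        for cid, label in self.labels.items():
            if label.startswith("unlabeled"):
                continue
            members = tuple(self.assignments.index[self.assignments == cid])
            compartment = "immune" if label.startswith("immune") else "epithelial"
            sets.append(CpGSet(name=label, cpgs=members, target_compartment=compartment))
        return sets


def _prepare(matrix: pd.DataFrame | DeltaBetaProfile) -> tuple[pd.DataFrame, pd.Index]:
    if isinstance(matrix, DeltaBetaProfile):
        matrix = matrix.values
    if list(matrix.columns) != list(DELTA_COLUMNS):
        raise ClusteringError(f"expected columns {list(DELTA_COLUMNS)}")
    # deterministic regardless of input row order
    matrix = matrix.sort_index()
    imputed = matrix.index[matrix.isna().any(axis=1)]
    return matrix.fillna(0.0), imputed


def cluster_delta_matrix(
    matrix: pd.DataFrame | DeltaBetaProfile,
    k: int = 4,
    tau: float = LABEL_TAU,
) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering of delta-beta profiles.

    Missing entries (tissues without data) are imputed as zero — no
    evidence of effect — and the affected CpGs flagged.  Cluster ids are
    renumbered by their lexicographically smallest member, so the result is
    independent of input row order.
    """
    X_df, imputed = _prepare(matrix)
    n = len(X_df)
    if not 1 <= k <= n:
        raise ClusteringError(f"k={k} outside valid range 1..{n}")
    X = X_df.to_numpy(dtype=float)
    if k == 1:
        raw = np.zeros(n, dtype=int)
    else:
        raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)

    # stable renumbering: order clusters by their smallest CpG id
    order = sorted(range(k), key=lambda c: X_df.index[raw == c].min())
    remap = {old: new for new, old in enumerate(order)}
    assignments = pd.Series(
        [remap[c] for c in raw], index=X_df.index, name="cluster"
    )
    means = (
        X_df.groupby(assignments).mean().reindex(range(k))
    )
    means.index.name = "cluster"
    if 2 <= k < n:
        sil = float(silhouette_score(X, assignments.to_numpy()))
    else:
        sil = np.nan
    labels = label_archetypes(means, tau=tau)
    return ClusterResult(
        assignments=assignments,
        means=means,
        labels=labels,
        k=k,
        silhouette=sil,
        imputed=imputed,
    )


def select_k(
    matrix: pd.DataFrame | DeltaBetaProfile, k_range=range(2, 9), tau: float = LABEL_TAU
) -> ClusterResult:
    """Pick k by silhouette over ``k_range`` and return the best clustering."""
    best: ClusterResult | None = None
    for k in k_range:
        res = cluster_delta_matrix(matrix, k=k, tau=tau)
        if best is None or (res.silhouette > best.silhouette):
            best = res
    assert best is not None
    return best


def _classify_profile(profile: pd.Series, tau: float) -> str:
    epi_b = profile["epithelial_buccal"]
    imm_b = profile["immune_buccal"]
    epi_c = profile["epithelial_cervical"]
    imm_c = profile["immune_cervical"]
    lym = profile["lymphoid_blood"]
    mye = profile["myeloid_blood"]
    immune_means = (imm_b, imm_c, lym, mye)
    epithelial_means = (epi_b, epi_c)
    if (
        epi_b < -tau
        and epi_c < -tau
        and all(abs(v) <= tau for v in immune_means)
    ):
        return "epithelial_hypoM"
    if all(v < -tau for v in immune_means) and all(
        abs(v) <= tau for v in epithelial_means
    ):
        return "immune_hypoM"
    if epi_c > tau and abs(epi_b) <= tau:
        return "distal_epithelial_hyperM"
    if epi_b > tau and abs(epi_c) <= tau:
        return "proximal_epithelial_hyperM"
    return "unlabeled"


def label_archetypes(means: pd.DataFrame, tau: float = LABEL_TAU) -> dict[int, str]:
    """Map cluster mean profiles to archetype labels by sign-pattern rules.

    A cluster is an archetype when its effects exceed ``tau`` in that
    archetype's compartments and stay within ``tau`` elsewhere; anything
    else is ``unlabeled``.  Two clusters mapping to one archetype keep both,
    with a numeric suffix and a warning.
    """
    labels: dict[int, str] = {}
    seen: dict[str, int] = {}
    for cid, profile in means.iterrows():
        label = _classify_profile(profile, tau)
        count = seen.get(label, 0)
        if count and label != "unlabeled":
            warnings.warn(
                f"archetype {label!r} matched by more than one cluster", stacklevel=2
            )
            labels[int(cid)] = f"{label}_{count + 1}"
        elif count and label == "unlabeled":
            labels[int(cid)] = f"unlabeled_{count + 1}"
        else:
            labels[int(cid)] = label
        seen[label] = count + 1
    return labels


def write_cluster_result(res: ClusterResult, path, summary_path=None) -> None:
    out = pd.DataFrame(
        {
            "cpg_id": res.assignments.index,
            "cluster": res.assignments.to_numpy(),
            "label": res.cpg_labels.to_numpy(),
            "imputed": res.assignments.index.isin(res.imputed).astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False)
    if summary_path is not None:
        summary = res.means.copy()
        summary["size"] = res.assignments.value_counts().reindex(summary.index).fillna(0).astype(int)
        summary["label"] = [res.labels[int(c)] for c in summary.index]
        summary.insert(0, "cluster", summary.index)
        summary.to_csv(summary_path, sep="\t", index=False, float_format="%.6f")
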