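"""Hierarchical clustering of dCt profiles and genomic clustering of hits.

Hierarchical clustering uses Euclidean distance with complete linkage
(the maximum pairwise distance between clusters), which guarantees
monotone merge heights.  Items are sorted lexicographically by id before
clustering so the result does not depend on input order; remaining
distance ties are resolved by scipy's deterministic agglomeration order.

Genomic clustering groups significantly altered miRNAs that share a
chromosome (whole-chromosome granularity — the annotation carries no
base-pair coordinates) and reports strand makeup and the fraction of
members sharing the majority direction of change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import CtMatrix, MiRNAAnnotation

__all__ = [
    "Dendrogram",
    "GenomicCluster",
    "hierarchical_cluster",
    "genomic_clusters",
    "heatmap_export",
]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over items (assays or samples)."""

    items: tuple[str, ...]  # lexicographically sorted clustering input order
    linkage: np.ndarray  # scipy linkage matrix
    axis: Literal["assays", "samples"]

    def __post_init__(self) -> None:
        h = self.heights
        if len(h) > 1 and np.any(np.diff(h) < -1e-12):
            raise ValueError("complete-linkage heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.items[i] for i in hierarchy.leaves_list(self.linkage)]


@dataclass(frozen=True)
class GenomicCluster:
    """Co-localised significant miRNAs on one chromosome (>= 2 members)."""

    chromosome: str
    members: tuple[str, ...]
    strands: tuple[str, ...]
    directions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a genomic cluster needs at least 2 members")

    @property
    def concordance(self) -> float:
        """Fraction of members sharing the majority direction of change."""
        counts = pd.Series(self.directions).value_counts()
        return float(counts.iloc[0] / len(self.directions))


def _cluster_axis(matrix: pd.DataFrame, axis: Literal["assays", "samples"]) -> Dendrogram:
    # rows = items to cluster
    data = matrix.T if axis == "assays" else matrix
    data = data.sort_index()
    if data.shape[0] < 2:
        raise ValueError(f"need at least 2 {axis} to cluster")
    if data.isna().any().any():
        raise ValueError("hierarchical clustering requires complete cases")
    Z = hierarchy.linkage(pdist(data.to_numpy(dtype=float), metric="euclidean"),
                          method="complete")
    return Dendrogram(items=tuple(data.index), linkage=Z, axis=axis)


def hierarchical_cluster(
    delta: CtMatrix, axis: Literal["assays", "samples", "both"] = "both"
) -> dict[str, Dendrogram]:
    """Complete-linkage / Euclidean clustering of a dCt matrix.

    Returns a dict with keys ``assays`` and/or ``samples``.
    """
    if delta.stage != "delta_ct":
        raise ValueError("hierarchical_cluster expects a delta_ct matrix")
    axes = ("assays", "samples") if axis == "both" else (axis,)
    if not set(axes) <= {"assays", "samples"}:
        raise ValueError(f"unknown axis {axis!r}")
    return {a: _cluster_axis(delta.values, a) for a in axes}


def genomic_clusters(
    significant: Sequence[Mapping] | pd.DataFrame,
    annotations: Sequence[MiRNAAnnotation],
) -> list[GenomicCluster]:
    """Group significant miRNAs sharing a chromosome (>= 2 members).

    ``significant`` is an iterable of records (or a DataFrame) with at
    least ``assay_id`` and ``direction`` fields; assays without a
    chromosome annotation are skipped with a warning.
    """
    if isinstance(significant, pd.DataFrame):
        records = significant.to_dict("records")
    else:
        records = [dict(r) for r in significant]
    ann = {a.assay_id: a for a in annotations}
    by_chrom: dict[str, list[tuple[str, str, str]]] = {}
    for rec in records:
        assay = rec.get("assay_id") or rec.get("mirna")
        a = ann.get(assay)
        if a is None or not a.chromosome:
            warnings.warn(f"no chromosome annotation for {assay!r}; skipped", stacklevel=2)
            continue
        by_chrom.setdefault(a.chromosome, []).append(
            (assay, a.strand, str(rec["direction"]))
        )
    out = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom])
        if len(members) < 2:
            continue
        out.append(
            GenomicCluster(
                chromosome=chrom,
                members=tuple(m[0] for m in members),
                strands=tuple(m[1] for m in members),
                directions=tuple(m[2] for m in members),
            )
        )
    return out


def heatmap_export(
    delta: CtMatrix,
    dendrograms: dict[str, Dendrogram],
    path: str | Path,
) -> tuple[Path, Path]:
    """Write the leaf-ordered dCt matrix as TSV plus a rendered heatmap.

    ``path`` is the TSV destination; the PNG goes next to it.  The TSV is
    the testable artifact — a pure permutation of the input values.
    """
    path = Path(path)
    ordered = delta.values
    if "samples" in dendrograms:
        ordered = ordered.loc[dendrograms["samples"].leaf_order]
    if "assays" in dendrograms:
        ordered = ordered.loc[:, dendrograms["assays"].leaf_order]
    ordered.to_csv(path, sep="\t")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.12 * ordered.shape[1]), max(3, 0.3 * ordered.shape[0]))
    )
    im = ax.pcolormesh(ordered.to_numpy(dtype=float), cmap="RdBu_r")
    ax.set_yticks(np.arange(ordered.shape[0]) + 0.5, ordered.index, fontsize=6)
    ax.set_xticks([])
    ax.set_xlabel("miRNA assays (dendrogram leaf order)")
    fig.colorbar(im, ax=ax, label="dCt")
    png = path.with_suffix(".png")
    fig.savefig(png, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path, png
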