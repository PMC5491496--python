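"""Group-specific differential co-expression networks.

Pairwise Pearson correlations are computed on global-mean-centred Ct
values separately within each diagnostic group.  A pair (i, j) is an edge
of the *case-specific* network iff

1. r_case > r_sig                (significant positive case correlation),
2. -r_sig < r_control < r_sig    (no significant control correlation), and
3. r_case - r_control > r_gap    (the correlation is group-specific),

with strict inequalities; the *control-specific* network applies the
mirrored criteria.  The default r_sig = 0.7 is the conventional rounding
of the critical correlation at alpha = 0.05 for group sizes around 9-11
(see :func:`critical_r`); criterion 2 as stated also excludes strong
*positive* control correlations, which criterion 3 makes partially
redundant — the literal rule is kept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CtMatrix, SampleInfo, samples_to_frame

__all__ = [
    "CorrelationMatrices",
    "DiffCoexprNetwork",
    "pairwise_pearson",
    "critical_r",
    "select_differential_edges",
    "degree_summary",
    "export_network",
    "import_network",
]

Direction = Literal["case_specific", "control_specific"]


@dataclass(frozen=True)
class CorrelationMatrices:
    """Symmetric per-group Pearson correlation matrices over assays."""

    r_case: pd.DataFrame
    r_control: pd.DataFrame
    n_case: int
    n_control: int
    excluded_assays: tuple[str, ...] = ()  # zero variance within a group

    def __post_init__(self) -> None:
        if not self.r_case.index.equals(self.r_control.index):
            raise ValueError("correlation matrices are not aligned")


@dataclass(frozen=True)
class DiffCoexprNetwork:
    """Undirected network of group-specifically co-expressed miRNAs."""

    direction: Direction
    graph: nx.Graph
    r_sig: float
    r_gap: float
    n_pairs_tested: int
    n_pairs_skipped: int = 0

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float, float]]:
        return sorted(
            (min(u, v), max(u, v), d["r_case"], d["r_control"])
            for u, v, d in self.graph.edges(data=True)
        )


def pairwise_pearson(
    centered: CtMatrix, samples: Sequence[SampleInfo]
) -> CorrelationMatrices:
    """All-pairs Pearson r per group on globally centred Ct values.

    Assays must be complete within each group; an assay with zero variance
    in a group has undefined correlations and is excluded with a warning.
    """
    if centered.stage != "global_centered":
        raise ValueError("pairwise_pearson expects a global_centered matrix")
    meta = samples_to_frame(samples)
    groups = {
        g: [s for s in centered.samples if meta.at[s, "group"] == g]
        for g in ("case", "control")
    }
    for g, members in groups.items():
        if len(members) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")

    values = centered.values
    if values.isna().any().any():
        raise ValueError("pairwise_pearson requires complete assays; filter first")

    excluded: set[str] = set()
    for g, members in groups.items():
        sd = values.loc[members].std(axis=0, ddof=1)
        zero = sd.index[sd == 0]
        if len(zero):
            warnings.warn(
                f"{len(zero)} zero-variance assays in group {g!r} excluded "
                f"from correlation: {list(zero)[:5]}",
                stacklevel=2,
            )
            excluded.update(zero)
    keep = [a for a in centered.assays if a not in excluded]

    def corr(members: list[str]) -> pd.DataFrame:
        r = np.corrcoef(values.loc[members, keep].to_numpy(dtype=float), rowvar=False)
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        return pd.DataFrame(r, index=keep, columns=keep)

    return CorrelationMatrices(
        r_case=corr(groups["case"]),
        r_control=corr(groups["control"]),
        n_case=len(groups["case"]),
        n_control=len(groups["control"]),
        excluded_assays=tuple(sorted(excluded)),
    )


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significantly different from 0 at the two-sided level.

    Inverts the t statistic t = r sqrt((n-2)/(1-r^2)) at the two-sided
    critical value with df = n - 2:  r* = t_c / sqrt(df + t_c^2).
    """
    if n < 4:
        raise ValueError("critical_r requires n >= 4")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    df = n - 2
    t_c = stats.t.ppf(1 - alpha / 2.0, df)
    return float(t_c / np.sqrt(df + t_c**2))


def select_differential_edges(
    corr: CorrelationMatrices,
    direction: Direction,
    r_sig: float = 0.7,
    r_gap: float = 0.8,
) -> DiffCoexprNetwork:
    """Build the group-specific differential co-expression network."""
    if r_gap <= 0:
        raise ValueError("r_gap must be positive")
    if direction not in ("case_specific", "control_specific"):
        raise ValueError(f"unknown direction {direction!r}")

    rc = corr.r_case.to_numpy()
    rk = corr.r_control.to_numpy()
    if direction == "case_specific":
        hi, lo = rc, rk
    else:
        hi, lo = rk, rc
    sel = (hi > r_sig) & (lo > -r_sig) & (lo < r_sig) & ((hi - lo) > r_gap)

    assays = list(corr.r_case.index)
    g = nx.Graph()
    iu, ju = np.triu_indices(len(assays), k=1)
    hits = sel[iu, ju]
    for i, j in zip(iu[hits], ju[hits]):
        g.add_edge(
            assays[i],
            assays[j],
            r_case=float(rc[i, j]),
            r_control=float(rk[i, j]),
        )
    return DiffCoexprNetwork(
        direction=direction,
        graph=g,
        r_sig=r_sig,
        r_gap=r_gap,
        n_pairs_tested=int(len(iu)),
    )


def degree_summary(net: DiffCoexprNetwork, hub_quantile: float = 0.9) -> dict:
    """Per-node degrees, (min, max, median), and hub list (top decile)."""
    degrees = dict(net.graph.degree())
    if not degrees:
        return {"degrees": {}, "min": None, "max": None, "median": None, "hubs": []}
    vals = np.array(sorted(degrees.values()))
    cut = float(np.quantile(vals, hub_quantile))
    hubs = sorted(n for n, d in degrees.items() if d >= cut)
    return {
        "degrees": {n: int(d) for n, d in sorted(degrees.items())},
        "min": int(vals.min()),
        "max": int(vals.max()),
        "median": float(np.median(vals)),
        "hubs": hubs,
    }


def export_network(
    net: DiffCoexprNetwork, path: str | Path, format: Literal["graphml", "edge_tsv"]
) -> Path:
    """Write the network as GraphML or a TSV edge list (node, node, r's)."""
    path = Path(path)
    if format == "graphml":
        g = net.graph.copy()
        g.graph.update(
            direction=net.direction, r_sig=net.r_sig, r_gap=net.r_gap
        )
        for n in g.nodes:
            g.nodes[n]["label"] = str(n)
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        rows = [
            {"source": u, "target": v, "r_case": rc, "r_control": rk}
            for u, v, rc, rk in net.edges
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "r_case", "r_control"])
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def import_network(path: str | Path, format: Literal["graphml", "edge_tsv"]) -> DiffCoexprNetwork:
    """Re-read an exported network (round-trip counterpart of export)."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        meta = g.graph
        out = nx.Graph()
        for u, v, d in g.edges(data=True):
            out.add_edge(str(u), str(v), r_case=float(d["r_case"]), r_control=float(d["r_control"]))
        return DiffCoexprNetwork(
            direction=meta.get("direction", "case_specific"),
            graph=out,
            r_sig=float(meta.get("r_sig", 0.7)),
            r_gap=float(meta.get("r_gap", 0.8)),
            n_pairs_tested=0,
        )
    elif format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for r in df.itertuples():
            g.add_edge(str(r.source), str(r.target), r_case=float(r.r_case), r_control=float(r.r_control))
        return DiffCoexprNetwork(
            direction="case_specific", graph=g, r_sig=0.7, r_gap=0.8, n_pairs_tested=0
        )
    raise ValueError(f"unknown format {format!r}")
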