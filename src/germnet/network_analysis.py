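"""Thresholded interaction graphs and main-graph topology statistics.

Edges come from a STRING-style table with per-channel evidence scores on a
0-1000 integer scale.  Selected channels are combined with a noisy-OR,
1 - prod(1 - s_c), without any prior correction, and an edge is kept when
the combined score reaches the high-confidence threshold (0.700, inclusive).
The "main graph" is the largest connected component; characteristic path
length is averaged over unordered connected node pairs within it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import stats_core
from .errors import ArgumentError, InsufficientDataError

DEFAULT_THRESHOLD = 0.700
DEFAULT_CHANNELS = ("experiments", "databases", "fusion")
_EPS = 1e-9  # float guard for the inclusive score threshold


@dataclass
class MainGraphStats:
    n_total: int
    n_main: int
    fraction: float
    char_path_length: float
    avg_neighbors: float
    shortest_path_histogram: dict[int, int] = field(default_factory=dict)
    degree_histogram: dict[int, int] = field(default_factory=dict)
    powerlaw_slope: float | None = None
    powerlaw_r2: float | None = None
    degenerate: bool = False  # main graph too small for a path length

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_main": self.n_main,
            "fraction": self.fraction,
            "char_path_length": self.char_path_length,
            "avg_neighbors": self.avg_neighbors,
            "shortest_path_histogram": {
                str(k): v for k, v in sorted(self.shortest_path_histogram.items())
            },
            "degree_histogram": {
                str(k): v for k, v in sorted(self.degree_histogram.items())
            },
            "powerlaw_slope": self.powerlaw_slope,
            "powerlaw_r2": self.powerlaw_r2,
            "degenerate": self.degenerate,
        }


def load_edge_table(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Load a STRING-style TSV (protein1, protein2, channel columns,
    combined_score; integer scores 0-1000)."""
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source, sep="\t")


def combined_score(
    channel_scores: Mapping[str, float], channels: Sequence[str] = DEFAULT_CHANNELS
) -> float:
    """Noisy-OR combination over the selected evidence channels."""
    p_no = 1.0
    for c in channels:
        s = channel_scores.get(c, 0.0)
        if not 0.0 <= s <= 1.0:
            raise ArgumentError(f"channel score out of [0,1]: {c}={s}")
        p_no *= 1.0 - s
    return 1.0 - p_no


def build_graph(
    edges: pd.DataFrame,
    gene_set: Iterable[str],
    score_threshold: float = DEFAULT_THRESHOLD,
    channels: Sequence[str] = DEFAULT_CHANNELS,
) -> nx.Graph:
    """Interaction graph over ``gene_set`` (isolates included as nodes).

    An edge is kept iff both endpoints are in the gene set and the noisy-OR
    combined score of the selected channels is >= ``score_threshold``.
    """
    genes = set(gene_set)
    for c in channels:
        if c not in edges.columns:
            raise ArgumentError(f"unknown evidence channel {c!r}")
    g = nx.Graph()
    g.add_nodes_from(genes)
    if genes and len(edges):
        sub = edges[edges["protein1"].isin(genes) & edges["protein2"].isin(genes)]
        if len(sub):
            scores = np.ones(len(sub))
            for c in channels:
                scores *= 1.0 - sub[c].to_numpy(dtype=float) / 1000.0
            scores = 1.0 - scores
            keep = sub[scores >= score_threshold - _EPS]
            for a, b in zip(keep["protein1"], keep["protein2"]):
                if a != b:
                    g.add_edge(a, b)
    return g


def main_graph(graph: nx.Graph) -> nx.Graph:
    """Largest connected component; size ties broken by the component whose
    lexicographically smallest member sorts first."""
    if graph.number_of_nodes() == 0:
        return nx.Graph()
    comp = max(
        nx.connected_components(graph), key=lambda c: (len(c), _rev_min(c))
    )
    return graph.subgraph(comp).copy()


class _rev_min:
    """Orders components so that, at equal size, the one with the smallest
    minimum node wins under max()."""

    def __init__(self, component):
        self.key = min(str(n) for n in component)

    def __lt__(self, other):  # larger under max() == smaller key
        return self.key > other.key


def graph_stats(graph: nx.Graph) -> MainGraphStats:
    """Topology summary of the main graph of ``graph``.

    Characteristic path length and the shortest-path histogram cover the
    unordered connected node pairs of the main graph (BFS distances);
    avg_neighbors is the mean degree.  A single-node (or empty) main graph
    has no defined path length and is reported as 0 with ``degenerate=True``.
    """
    n_total = graph.number_of_nodes()
    mg = main_graph(graph)
    n_main = mg.number_of_nodes()
    fraction = n_main / n_total if n_total else 0.0

    degree_histogram: dict[int, int] = {}
    for _, d in mg.degree():
        degree_histogram[d] = degree_histogram.get(d, 0) + 1

    # ordered pairs (distances are symmetric), halved to unordered counts
    sp_hist: dict[int, int] = {}
    total_dist = 0
    n_pairs = 0
    for node, dists in nx.all_pairs_shortest_path_length(mg):
        for other, dist in dists.items():
            if other is node or other == node:
                continue
            sp_hist[dist] = sp_hist.get(dist, 0) + 1
            total_dist += dist
            n_pairs += 1
    sp_hist = {k: v // 2 for k, v in sp_hist.items()}
    n_pairs //= 2
    total_dist //= 2
    degenerate = n_main < 2
    cpl = total_dist / n_pairs if n_pairs else 0.0
    avg_neighbors = (
        2.0 * mg.number_of_edges() / n_main if n_main else 0.0
    )

    slope = r2 = None
    try:
        slope, r2 = powerlaw_fit(degree_histogram)
    except InsufficientDataError:
        pass

    return MainGraphStats(
        n_total=n_total,
        n_main=n_main,
        fraction=fraction,
        char_path_length=cpl,
        avg_neighbors=avg_neighbors,
        shortest_path_histogram=sp_hist,
        degree_histogram=degree_histogram,
        powerlaw_slope=slope,
        powerlaw_r2=r2,
        degenerate=degenerate,
    )


def powerlaw_fit(degree_histogram: Mapping[int, int]) -> tuple[float, float]:
    """Least-squares line on (log10 k, log10 n(k)); returns (slope, r2).

    Degree 0 and zero-count bins are excluded; at least 3 distinct degrees
    with positive counts are required.
    """
    pts = [(k, n) for k, n in degree_histogram.items() if k > 0 and n > 0]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"power-law fit needs >= 3 support points, got {len(pts)}"
        )
    x = np.log10([k for k, _ in pts])
    y = np.log10([n for _, n in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(r2)


def main_fraction_point(
    gene_set: Iterable[str],
    edges: pd.DataFrame,
    score_threshold: float = DEFAULT_THRESHOLD,
    channels: Sequence[str] = DEFAULT_CHANNELS,
) -> tuple[int, float]:
    """(main-graph size, main-graph node fraction) for one individual."""
    g = build_graph(edges, gene_set, score_threshold, channels)
    mg = main_graph(g)
    n_total = g.number_of_nodes()
    n_main = mg.number_of_nodes()
    return n_main, (n_main / n_total if n_total else 0.0)


def compare_groups(
    group_a: Sequence[MainGraphStats],
    group_b: Sequence[MainGraphStats],
    metric: Literal["neighbor_counts", "n_main", "fraction"],
    test: Literal["ks", "mwu"],
) -> float:
    """Two-group comparison: KS on pooled per-node neighbor counts, or a
    Mann-Whitney U on per-individual scalars."""

    def values(group):
        if metric == "neighbor_counts":
            out = []
            for s in group:
                for k, n in s.degree_histogram.items():
                    out.extend([k] * n)
            return out
        if metric == "n_main":
            return [s.n_main for s in group]
        if metric == "fraction":
            return [s.fraction for s in group]
        raise ArgumentError(f"unknown metric {metric!r}")

    xa, xb = values(group_a), values(group_b)
    if test == "ks":
        return stats_core.ks_two_sample(xa, xb).pvalue
    if test == "mwu":
        return stats_core.mann_whitney_exact(xa, xb, two_sided=True).pvalue
    raise ArgumentError(f"unknown test {test!r}")
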