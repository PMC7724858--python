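"""Pathway gene sets: GMT loading, per-individual overlap counts,
hypergeometric top-k ranking, and cross-individual shared pathways.

The published ranking criterion for "top 10 pathways" is unstated; pathways
are ranked here by hypergeometric upper-tail p against a background of all
genes in the database union (count-based ranking is available via
``by="count"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from . import stats_core
from .errors import ArgumentError, FormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayDB:
    pathways: Mapping[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    @property
    def background_size(self) -> int:
        return len(self.background)

    def genes(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    overlap_count: int
    pathway_size: int
    p_value: float
    rank: int


def load_gmt(text: str, background: Iterable[str] | None = None) -> PathwayDB:
    """Parse GMT text (id <tab> description <tab> genes...).

    The enrichment background defaults to the union of all member genes.
    """
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line {lineno}: expected >= 3 columns")
        pid, desc, genes = parts[0], parts[1], frozenset(g for g in parts[2:] if g)
        if not genes:
            raise FormatError(f"GMT line {lineno}: empty gene set")
        pathways[pid] = (desc, genes)
    if background is None:
        bg: set[str] = set()
        for _, gs in pathways.values():
            bg |= gs
    else:
        bg = set(background)
        for pid, (_, gs) in pathways.items():
            if not gs <= bg:
                bg |= gs
    return PathwayDB(pathways=pathways, background=frozenset(bg))


def write_gmt(db: PathwayDB) -> str:
    lines = []
    for pid, (desc, genes) in db.pathways.items():
        lines.append("\t".join([pid, desc, *sorted(genes)]))
    return "\n".join(lines) + ("\n" if lines else "")


def pathway_counts(gene_set: Iterable[str], db: PathwayDB) -> dict[str, int]:
    """Exact overlap size between the query gene set and every pathway."""
    q = set(gene_set)
    return {pid: len(q & genes) for pid, (_, genes) in db.pathways.items()}


def rank_pathways(
    gene_set: Iterable[str],
    db: PathwayDB,
    k: int = 10,
    by: Literal["pvalue", "count"] = "pvalue",
) -> list[EnrichmentRow]:
    """Top-k pathways for a query gene set.

    p-values are hypergeometric upper tails with N = background size,
    K = pathway size, n = |query ∩ background|.  Ties sort by descending
    overlap, then pathway id.  Query genes outside the background are
    dropped (logged).
    """
    if k < 1:
        raise ArgumentError("k must be >= 1")
    q = set(gene_set)
    dropped = q - db.background
    if dropped:
        logger.info("dropping %d query genes absent from background", len(dropped))
    q &= db.background
    n = len(q)
    if n > db.background_size:
        raise ArgumentError("query larger than background")
    rows = []
    for pid, (_, genes) in db.pathways.items():
        overlap = len(q & genes)
        p = stats_core.hypergeom_tail(overlap, len(genes), n, db.background_size)
        rows.append((p, -overlap, pid, len(genes)))
    if by == "pvalue":
        rows.sort()
    elif by == "count":
        rows.sort(key=lambda r: (r[1], r[0], r[2]))
    else:
        raise ArgumentError(f"unknown ranking criterion {by!r}")
    return [
        EnrichmentRow(
            pathway_id=pid,
            overlap_count=-neg_overlap,
            pathway_size=size,
            p_value=p,
            rank=i + 1,
        )
        for i, (p, neg_overlap, pid, size) in enumerate(rows[:k])
    ]


def shared_top(
    rankings: Sequence[Sequence[EnrichmentRow]], k: int = 10
) -> set[str]:
    """Pathways present in every individual's top-k ranking."""
    if not rankings:
        raise ArgumentError("need at least one ranking")
    sets = [{row.pathway_id for row in ranking[:k]} for ranking in rankings]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out
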