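"""SNV detection from per-position pileups.

The caller tests, at each sufficiently covered position, the most frequent
non-reference base against an idealised all-reference sample of equal depth
with a one-sided Fisher exact test: observed (alt, ref) vs ideal (0, depth).
This table construction is a documented reconstruction of the published
procedure, which states only the null hypothesis ("all bases identical to
the reference") and the threshold (p < 0.01 at depth >= 10).

Germline variants are calls made in blood or para-cancer tissue; somatic
variants are calls made in cancer tissue that are absent from the matched
para-cancer sample *and* adequately covered there, so absence is evidenced
rather than an artifact of missing coverage.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from . import stats_core
from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
PILEUP_COLUMNS = ["CHROM", "POS", "REF", "DEPTH", "A", "C", "G", "T"]

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_DEPTH = 10
HOM_FRACTION = 0.85  # allele fraction at/above which a call is homozygous


class VariantKey(NamedTuple):
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass(frozen=True)
class PileupColumn:
    """Base counts at one 1-based genomic position."""

    chrom: str
    pos: int
    ref: str
    depth: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref not in BASES:
            raise DataError(f"reference base {self.ref!r} at {self.chrom}:{self.pos}")
        if self.depth < 0:
            raise DataError(f"negative depth at {self.chrom}:{self.pos}")
        if sum(self.counts.get(b, 0) for b in BASES) != self.depth:
            raise DataError(
                f"base counts do not sum to depth at {self.chrom}:{self.pos}"
            )


@dataclass
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    p_value: float
    zygosity: str  # het | hom
    origin: str = "unclassified"  # germline | somatic | unclassified

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


def call_snv(
    column: PileupColumn,
    alpha: float = DEFAULT_ALPHA,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> VariantCall | None:
    """Call an SNV at one position, or return None.

    Positions below ``min_depth`` are filtered. Only the single most frequent
    non-reference base is tested (ties broken alphabetically); the variant is
    called iff the one-sided Fisher p of [[alt, depth-alt], [0, depth]] is
    below ``alpha``.
    """
    if not 0 < alpha < 1:
        raise DataError(f"alpha must be in (0,1), got {alpha}")
    d = column.depth
    if d < min_depth:
        return None
    alts = [(column.counts.get(b, 0), b) for b in BASES if b != column.ref]
    # most frequent non-reference base; ties broken alphabetically
    a = max(c for c, _ in alts)
    alt = min(b for c, b in alts if c == a)
    if a == 0:
        return None
    p = stats_core.fisher_exact([[a, d - a], [0, d]], alternative="one_sided")
    if p >= alpha:
        return None
    zygosity = "hom" if a / d >= HOM_FRACTION else "het"
    return VariantCall(column.chrom, column.pos, column.ref, alt, a, d, p, zygosity)


def read_pileup(source: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read a pileup TSV (CHROM, POS 1-based, REF, DEPTH, A, C, G, T)."""
    df = pd.read_csv(source, sep="\t", dtype={"CHROM": str})
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pileup table missing columns {missing}")
    return df[PILEUP_COLUMNS]


def iter_columns(pileup: pd.DataFrame) -> Iterable[PileupColumn]:
    for row in pileup.itertuples(index=False):
        yield PileupColumn(
            chrom=str(row.CHROM),
            pos=int(row.POS),
            ref=str(row.REF),
            depth=int(row.DEPTH),
            counts={b: int(getattr(row, b)) for b in BASES},
        )


def call_sample(
    pileup: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[VariantCall]:
    """Call SNVs over a whole pileup table, which must be sorted by
    (CHROM, POS) without duplicate positions."""
    keys = list(zip(pileup["CHROM"].astype(str), pileup["POS"].astype(int)))
    if keys != sorted(keys):
        raise FormatError("pileup must be sorted by (CHROM, POS)")
    if len(set(keys)) != len(keys):
        raise FormatError("pileup contains duplicate positions")
    calls = []
    for col in iter_columns(pileup):
        call = call_snv(col, alpha=alpha, min_depth=min_depth)
        if call is not None:
            calls.append(call)
    return calls


def germline_set(calls: Sequence[VariantCall]) -> set[VariantKey]:
    """Mark calls from a non-cancer (blood/para) sample as germline."""
    for c in calls:
        c.origin = "germline"
    return {c.key for c in calls}


def somatic_set(
    cancer_calls: Sequence[VariantCall],
    para_calls: Sequence[VariantCall],
    para_pileup: pd.DataFrame,
    min_para_depth: int = DEFAULT_MIN_DEPTH,
) -> set[VariantKey]:
    """Cancer-only calls whose absence in the para-cancer sample is covered.

    A cancer call is somatic iff no call exists at the same (chrom,pos,ref,alt)
    in the para-cancer sample AND the para-cancer depth at that position is at
    least ``min_para_depth``.
    """
    para_keys = {c.key for c in para_calls}
    depth_by_pos = {
        (str(r.CHROM), int(r.POS)): int(r.DEPTH)
        for r in para_pileup.itertuples(index=False)
    }
    out: set[VariantKey] = set()
    for call in cancer_calls:
        if call.key in para_keys:
            continue
        pos_key = (call.chrom, call.pos)
        if pos_key not in depth_by_pos:
            raise DataError(
                f"para-cancer pileup has no coverage record at {call.chrom}:{call.pos}"
            )
        if depth_by_pos[pos_key] < min_para_depth:
            continue
        call.origin = "somatic"
        out.add(call.key)
    return out


def shared_germline(sets: Sequence[set[VariantKey]]) -> set[VariantKey]:
    """Exact intersection of germline key sets across individuals."""
    if not sets:
        raise DataError("need at least one germline set")
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def crossref_catalog(
    variants: Iterable[VariantKey],
    catalog: pd.DataFrame | str | Path,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Left-join variants against a local variant catalog.

    The catalog is a TSV with columns CHROM, POS, REF, ALT, CLASSIFICATION.
    Returns per-variant annotations and a summary with the count of variants
    whose classification is not "benign" (case-insensitive) and the fraction
    of variants present in the catalog at all.
    """
    if not isinstance(catalog, pd.DataFrame):
        rows = []
        for i, line in enumerate(Path(catalog).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                logger.warning("skipping malformed catalog line %d", i)
                continue
            try:
                rows.append((parts[0], int(parts[1]), parts[2], parts[3], parts[4]))
            except ValueError:
                logger.warning("skipping malformed catalog line %d", i)
        catalog = pd.DataFrame(
            rows, columns=["CHROM", "POS", "REF", "ALT", "CLASSIFICATION"]
        )
    lookup = {
        VariantKey(str(r.CHROM), int(r.POS), str(r.REF), str(r.ALT)): str(
            r.CLASSIFICATION
        )
        for r in catalog.itertuples(index=False)
    }
    variants = list(variants)
    records = []
    for key in variants:
        cls = lookup.get(key)
        records.append(
            {
                "CHROM": key.chrom,
                "POS": key.pos,
                "REF": key.ref,
                "ALT": key.alt,
                "in_catalog": cls is not None,
                "classification": cls,
            }
        )
    ann = pd.DataFrame(
        records,
        columns=["CHROM", "POS", "REF", "ALT", "in_catalog", "classification"],
    )
    n = len(variants)
    present = int(ann["in_catalog"].sum()) if n else 0
    non_benign = (
        int(
            (
                ann["in_catalog"]
                & (ann["classification"].str.lower() != "benign")
            ).sum()
        )
        if n
        else 0
    )
    summary = {
        "n_variants": n,
        "n_in_catalog": present,
        "present_fraction": present / n if n else 0.0,
        "non_benign_count": non_benign,
    }
    return ann, summary


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternate read count">
##INFO=<ID=FETP,Number=1,Type=Float,Description="Fisher exact test p-value">
##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity (het/hom)">
##INFO=<ID=ORIGIN,Number=1,Type=String,Description="germline/somatic/unclassified">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Sequence[VariantCall], reference_name: str = "ref") -> str:
    """Render calls as minimal VCF 4.2 text. Calls must be sorted."""
    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        raise FormatError("calls must be sorted by (chrom, pos)")
    records = []
    for c in calls:
        info = (
            f"DP={c.depth};AC={c.alt_count};FETP={c.p_value:.6g};"
            f"ZYG={c.zygosity};ORIGIN={c.origin}"
        )
        records.append(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")
    meta, columns = VCF_HEADER.rsplit("#CHROM", 1)
    return meta + f"##reference={reference_name}\n" + "#CHROM" + columns + "".join(records)


def read_vcf(text: str) -> list[VariantCall]:
    """Parse VCF text produced by :func:`write_vcf` back into calls."""
    calls = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, pos, _id, ref, alt, _q, _f, info = line.split("\t")
        fields = dict(kv.split("=", 1) for kv in info.split(";"))
        calls.append(
            VariantCall(
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                alt=alt,
                alt_count=int(fields["AC"]),
                depth=int(fields["DP"]),
                p_value=float(fields["FETP"]),
                zygosity=fields["ZYG"],
                origin=fields["ORIGIN"],
            )
        )
    return calls
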