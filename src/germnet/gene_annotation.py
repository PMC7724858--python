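"""refFlat gene models and coding-consequence annotation.

Coordinates follow the UCSC convention: transcript/CDS/exon intervals are
0-based half-open; variant positions arriving from pileups are 1-based and
converted on entry.  A variant's consequence is collapsed over transcripts
by maximum severity (stop changes > nonsynonymous > synonymous > noncoding),
and the nonsynonymous bucket (including stop gain/loss) feeds the network
stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .errors import DataError, FormatError
from .variant_calling import VariantKey

logger = logging.getLogger(__name__)

SEVERITY = {
    "stop_gain": 3,
    "stop_loss": 3,
    "nonsynonymous": 2,
    "synonymous": 1,
    "noncoding": 0,
}

NONSYN_CONSEQUENCES = frozenset({"nonsynonymous", "stop_gain", "stop_loss"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class GeneModel:
    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise FormatError(f"exon list mismatch for {self.transcript_id}")
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not self.tx_start <= s < e <= self.tx_end:
                raise FormatError(f"exon outside transcript in {self.transcript_id}")
        if list(self.exon_starts) != sorted(self.exon_starts):
            raise FormatError(f"exons not sorted in {self.transcript_id}")

    def cds_positions(self) -> list[int]:
        """Genomic 0-based positions of the CDS in genomic (ascending) order."""
        out = []
        for s, e in zip(self.exon_starts, self.exon_ends):
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            out.extend(range(lo, hi))
        return out

    @property
    def codable(self) -> bool:
        n = len(self.cds_positions())
        return n > 0 and n % 3 == 0


@dataclass(frozen=True)
class AnnotatedVariant:
    key: VariantKey
    gene_name: str | None
    consequence: str
    ref_aa: str | None = None
    alt_aa: str | None = None


def parse_refflat(text: str) -> list[GeneModel]:
    """Parse refFlat text: 11 tab-separated columns, coordinate lists
    comma-separated with an optional trailing comma."""
    models = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 11:
            raise FormatError(
                f"refFlat line {lineno}: expected 11 columns, got {len(parts)}"
            )
        try:
            exon_count = int(parts[8])
            starts = tuple(int(x) for x in parts[9].strip(",").split(",") if x != "")
            ends = tuple(int(x) for x in parts[10].strip(",").split(",") if x != "")
            model = GeneModel(
                gene_name=parts[0],
                transcript_id=parts[1],
                chrom=parts[2],
                strand=parts[3],
                tx_start=int(parts[4]),
                tx_end=int(parts[5]),
                cds_start=int(parts[6]),
                cds_end=int(parts[7]),
                exon_starts=starts,
                exon_ends=ends,
            )
        except ValueError as exc:
            raise FormatError(f"refFlat line {lineno}: {exc}") from exc
        if len(starts) != exon_count or len(ends) != exon_count:
            raise FormatError(f"refFlat line {lineno}: exon count mismatch")
        if not model.codable:
            logger.warning(
                "transcript %s has CDS length not divisible by 3; flagged non-codable",
                model.transcript_id,
            )
        models.append(model)
    return models


def write_refflat(models: Iterable[GeneModel]) -> str:
    lines = []
    for m in models:
        lines.append(
            "\t".join(
                [
                    m.gene_name,
                    m.transcript_id,
                    m.chrom,
                    m.strand,
                    str(m.tx_start),
                    str(m.tx_end),
                    str(m.cds_start),
                    str(m.cds_end),
                    str(len(m.exon_starts)),
                    "".join(f"{s}," for s in m.exon_starts),
                    "".join(f"{e}," for e in m.exon_ends),
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def _transcript_consequence(
    key: VariantKey, model: GeneModel, seq: str
) -> tuple[str, str | None, str | None]:
    """Consequence of the variant within one codable transcript."""
    g0 = key.pos - 1  # 1-based pileup coordinate -> 0-based genomic
    cds = model.cds_positions()
    if g0 not in set(cds):
        return "noncoding", None, None
    if model.strand == "-":
        cds = cds[::-1]
    idx = cds.index(g0)
    codon_idx = idx // 3
    codon_genomic = cds[codon_idx * 3 : codon_idx * 3 + 3]

    def fetch(base_at_variant: str) -> str:
        bases = []
        for p in codon_genomic:
            b = base_at_variant if p == g0 else seq[p]
            bases.append(b.translate(_COMPLEMENT) if model.strand == "-" else b)
        return "".join(bases)

    ref_codon = fetch(key.ref)
    alt_codon = fetch(key.alt)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous", ref_aa, alt_aa
    if alt_aa == "*":
        return "stop_gain", ref_aa, alt_aa
    if ref_aa == "*":
        return "stop_loss", ref_aa, alt_aa
    return "nonsynonymous", ref_aa, alt_aa


def consequence(
    variant: VariantKey,
    models: Sequence[GeneModel],
    genome: Mapping[str, str] | str,
) -> AnnotatedVariant:
    """Annotate one variant against all overlapping codable transcripts,
    collapsing to the maximum-severity consequence."""
    seq = genome if isinstance(genome, str) else genome[variant.chrom]
    g0 = variant.pos - 1
    if not 0 <= g0 < len(seq):
        raise DataError(f"variant position {variant.pos} outside genome")
    if seq[g0].upper() != variant.ref:
        raise DataError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"genome has {seq[g0]!r}, variant claims {variant.ref!r}"
        )
    best: tuple[int, str, str | None, str | None, str | None] = (
        -1,
        "noncoding",
        None,
        None,
        None,
    )
    for model in models:
        if model.chrom != variant.chrom or not (model.tx_start <= g0 < model.tx_end):
            continue
        if not model.codable:
            continue
        cons, ref_aa, alt_aa = _transcript_consequence(variant, model, seq)
        score = SEVERITY[cons]
        if score > best[0]:
            best = (score, cons, model.gene_name, ref_aa, alt_aa)
    if best[0] < 0:
        return AnnotatedVariant(variant, None, "noncoding")
    _, cons, gene, ref_aa, alt_aa = best
    if cons == "noncoding":
        # inside a transcript but outside every CDS exon
        return AnnotatedVariant(variant, gene, "noncoding", ref_aa, alt_aa)
    return AnnotatedVariant(variant, gene, cons, ref_aa, alt_aa)


def annotate_all(
    variants: Iterable[VariantKey],
    models: Sequence[GeneModel],
    genome: Mapping[str, str] | str,
) -> list[AnnotatedVariant]:
    return [consequence(v, models, genome) for v in variants]


def nonsynonymous_genes(annotated: Iterable[AnnotatedVariant]) -> set[str]:
    """Unique gene names of variants with a protein-altering consequence."""
    return {
        a.gene_name
        for a in annotated
        if a.consequence in NONSYN_CONSEQUENCES and a.gene_name is not None
    }
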