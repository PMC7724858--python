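"""Deterministic synthetic inputs for every pipeline stage.

Because the study data behind this pipeline were never deposited, each
input — genome, gene models, pileups with planted variants, a scale-free
interaction network with a planted dense module, pathway gene sets, and a
case-control cohort with a designed exposure odds ratio — is generated from
a single seed.  One global seed expands into per-stage child seeds by fixed
offsets so each stage can be regenerated independently.

All distributions here are stand-ins at toy scale: the read model is
binomial sampling on Poisson depths (no indels, no linkage, no population
allele frequencies), the network is preferential attachment plus a planted
Erdős–Rényi module, and exposures are independent Bernoulli draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ArgumentError, DataError, SizingError
from .gene_annotation import GeneModel, write_refflat

BASES = np.array(["A", "C", "G", "T"])

# fixed child-seed offsets, one per generation stage
STAGE_OFFSETS = {
    "genome": 1,
    "truth": 2,
    "pileup_blood": 3,
    "pileup_para": 4,
    "pileup_cancer": 5,
    "ppi": 6,
    "pathways": 7,
    "cohort": 8,
    "gene_sets": 9,
}


def child_seed(seed: int, stage: str, index: int = 0) -> int:
    if stage not in STAGE_OFFSETS:
        raise ArgumentError(f"unknown stage {stage!r}")
    return seed * 1000 + STAGE_OFFSETS[stage] * 100 + index


@dataclass
class SimulationConfig:
    seed: int = 42
    genome_length: int = 60000
    n_genes: int = 20
    depth_mean: float = 30.0
    error_rate: float = 0.005
    het_fraction: float = 0.5
    n_germline: int = 60
    n_somatic: int = 20
    cancer_fraction: float = 0.3  # tumor-purity surrogate for somatic sites
    ppi_nodes: int = 300
    ppi_attach: int = 2
    planted_module_size: int = 30
    n_gene_universe: int = 1000
    cohort_sizes: tuple[int, int] = (200, 200)
    exposure_probs: tuple[float, float] = (0.3, 0.15)

    def __post_init__(self) -> None:
        probs = [self.error_rate, self.het_fraction, self.cancer_fraction,
                 *self.exposure_probs]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ArgumentError("all probabilities must lie in [0, 1]")
        counts = [self.genome_length, self.n_genes, self.n_germline,
                  self.n_somatic, self.ppi_nodes, self.planted_module_size,
                  *self.cohort_sizes]
        if any(c < 0 for c in counts):
            raise ArgumentError("all counts must be >= 0")
        if self.n_germline + self.n_somatic > self.genome_length:
            raise ArgumentError("more planted variants than genome positions")

    @property
    def true_or(self) -> float:
        p1, p0 = self.exposure_probs
        return (p1 / (1 - p1)) / (p0 / (1 - p0))


@dataclass
class GroundTruth:
    germline_sites: list[tuple[int, str, str, str]] = field(default_factory=list)
    somatic_sites: list[tuple[int, str, str, float]] = field(default_factory=list)
    planted_module_genes: set[str] = field(default_factory=set)
    true_or: float = 1.0

    def __post_init__(self) -> None:
        g = {p for p, *_ in self.germline_sites}
        s = {p for p, *_ in self.somatic_sites}
        if g & s:
            raise DataError("germline and somatic positions must be disjoint")

    def to_json(self) -> str:
        return json.dumps(
            {
                "germline_sites": self.germline_sites,
                "somatic_sites": self.somatic_sites,
                "planted_module_genes": sorted(self.planted_module_genes),
                "true_or": self.true_or,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            germline_sites=[tuple(t) for t in d["germline_sites"]],
            somatic_sites=[tuple(t) for t in d["somatic_sites"]],
            planted_module_genes=set(d["planted_module_genes"]),
            true_or=d["true_or"],
        )


def default_gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# genome + gene models

def synth_genome(config: SimulationConfig) -> tuple[str, list[GeneModel]]:
    """Random genome with non-overlapping gene models on one chromosome.

    Every model has 1-3 exons, a CDS that is a multiple of 3 and starts with
    ATG in transcript orientation, and a random strand.  Genes are laid out
    sequentially; sizes are bounded so the stated precondition
    (genome_length >= 300 * n_genes) always leaves room.
    """
    if config.genome_length < 300 * config.n_genes:
        raise SizingError(
            f"genome of {config.genome_length} bases cannot fit "
            f"{config.n_genes} genes (need >= {300 * config.n_genes})"
        )
    rng = np.random.default_rng(child_seed(config.seed, "genome"))
    genome = rng.choice(BASES, size=config.genome_length).tolist()

    models: list[GeneModel] = []
    cursor = 0
    for i in range(config.n_genes):
        cursor += int(rng.integers(10, 31))  # intergenic gap
        n_exons = int(rng.integers(1, 4))
        n_codons = int(rng.integers(30, 61))
        coding = 3 * n_codons
        # split coding bases over exons, each at least 30
        sizes = [30] * n_exons
        for _ in range(coding - 30 * n_exons):
            sizes[int(rng.integers(0, n_exons))] += 1
        introns = [int(rng.integers(20, 41)) for _ in range(n_exons - 1)]
        span = coding + sum(introns)
        if cursor + span > config.genome_length:
            raise SizingError("genes cannot fit in the requested genome length")
        strand = "+" if rng.random() < 0.5 else "-"
        exon_starts, exon_ends = [], []
        p = cursor
        for j, sz in enumerate(sizes):
            exon_starts.append(p)
            exon_ends.append(p + sz)
            p += sz
            if j < n_exons - 1:
                p += introns[j]
        tx_start, tx_end = cursor, cursor + span
        # plant the start codon (transcript orientation)
        if strand == "+":
            genome[tx_start], genome[tx_start + 1], genome[tx_start + 2] = "A", "T", "G"
        else:
            genome[tx_end - 3], genome[tx_end - 2], genome[tx_end - 1] = "C", "A", "T"
        models.append(
            GeneModel(
                gene_name=f"G{i + 1:04d}",
                transcript_id=f"T{i + 1:04d}",
                chrom="chr1",
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=tx_start,
                cds_end=tx_end,
                exon_starts=tuple(exon_starts),
                exon_ends=tuple(exon_ends),
            )
        )
        cursor = tx_end
    return "".join(genome), models


# ---------------------------------------------------------------------------
# planted variants + pileups

def synth_truth(
    config: SimulationConfig,
    genome: str,
    models: Sequence[GeneModel] | None = None,
    coding_only: bool = False,
    index: int = 0,
) -> GroundTruth:
    """Plant germline and somatic SNV sites at distinct positions.

    ``coding_only`` restricts sites to CDS positions of the supplied models
    (useful when downstream consequence annotation should see coding hits).
    ``index`` varies the child seed so several individuals can get distinct
    private truths.
    """
    rng = np.random.default_rng(child_seed(config.seed, "truth", index))
    if coding_only:
        if not models:
            raise ArgumentError("coding_only requires gene models")
        pool = sorted({p + 1 for m in models if m.codable for p in m.cds_positions()})
    else:
        pool = range(1, len(genome) + 1)
    n_total = config.n_germline + config.n_somatic
    if n_total > len(pool):
        raise SizingError("not enough candidate positions for planted variants")
    positions = rng.choice(np.asarray(pool), size=n_total, replace=False)

    def alt_for(ref: str) -> str:
        others = [b for b in "ACGT" if b != ref]
        return others[int(rng.integers(0, 3))]

    germline = []
    for pos in positions[: config.n_germline]:
        ref = genome[int(pos) - 1]
        zyg = "het" if rng.random() < config.het_fraction else "hom"
        germline.append((int(pos), ref, alt_for(ref), zyg))
    somatic = []
    for pos in positions[config.n_germline:]:
        ref = genome[int(pos) - 1]
        somatic.append((int(pos), ref, alt_for(ref), config.cancer_fraction))
    return GroundTruth(
        germline_sites=sorted(germline),
        somatic_sites=sorted(somatic),
        true_or=config.true_or,
    )


def synth_pileup(
    genome: str,
    truth: GroundTruth,
    config: SimulationConfig,
    tissue: str,
    index: int = 0,
) -> pd.DataFrame:
    """Per-position pileup table for one tissue of one individual.

    Depth is Poisson(depth_mean).  Non-variant sites read reference with
    probability 1 - error_rate, otherwise a uniformly random other base.
    Germline sites carry alt reads at probability 0.5 (het) or 1.0 (hom) in
    every tissue; somatic sites carry alt reads at their cancer fraction in
    cancer tissue only.
    """
    if tissue not in ("blood", "para", "cancer"):
        raise ArgumentError(f"unknown tissue {tissue!r}")
    length = len(genome)
    for pos, *_ in [*truth.germline_sites, *truth.somatic_sites]:
        if not 1 <= pos <= length:
            raise DataError(f"planted position {pos} outside genome")
    rng = np.random.default_rng(child_seed(config.seed, f"pileup_{tissue}", index))

    ref_idx = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    ref_idx = lut[ref_idx]

    depth = rng.poisson(config.depth_mean, size=length)
    counts = np.zeros((length, 4), dtype=np.int64)
    n_err = rng.binomial(depth, config.error_rate)
    err_split = rng.multinomial(n_err, [1 / 3] * 3)
    counts[np.arange(length), ref_idx] = depth - n_err
    # scatter the error reads onto the three non-reference bases
    for r in range(4):
        mask = ref_idx == r
        others = [b for b in range(4) if b != r]
        counts[np.ix_(mask, others)] += err_split[mask]

    overrides: list[tuple[int, str, str, float]] = [
        (pos, ref, alt, 1.0 if zyg == "hom" else 0.5)
        for pos, ref, alt, zyg in truth.germline_sites
    ]
    if tissue == "cancer":
        overrides += [
            (pos, ref, alt, frac) for pos, ref, alt, frac in truth.somatic_sites
        ]
    base_to_idx = {b: i for i, b in enumerate("ACGT")}
    for pos, ref, alt, p_alt in overrides:
        d = int(depth[pos - 1])
        a = int(rng.binomial(d, p_alt))
        row = np.zeros(4, dtype=np.int64)
        row[base_to_idx[alt]] = a
        row[base_to_idx[ref]] = d - a
        counts[pos - 1] = row

    return pd.DataFrame(
        {
            "CHROM": "chr1",
            "POS": np.arange(1, length + 1),
            "REF": BASES[ref_idx],
            "DEPTH": depth,
            "A": counts[:, 0],
            "C": counts[:, 1],
            "G": counts[:, 2],
            "T": counts[:, 3],
        }
    )


# ---------------------------------------------------------------------------
# interaction network

def synth_ppi(
    config: SimulationConfig, gene_names: Sequence[str]
) -> tuple[pd.DataFrame, set[str]]:
    """Scale-free interaction table with a planted dense module.

    Growth is preferential attachment (``ppi_attach`` edges per new node);
    the planted module adds internal edges with probability 0.5.  Every kept
    edge gets an 'experiments' score drawn Uniform(0.7, 0.95) (other
    channels 0), so the combined score clears the 0.700 threshold.
    """
    if config.ppi_attach >= config.ppi_nodes:
        raise ArgumentError("ppi_attach must be smaller than ppi_nodes")
    if config.ppi_nodes > len(gene_names):
        raise ArgumentError("not enough gene names for the requested network")
    seed = child_seed(config.seed, "ppi")
    rng = np.random.default_rng(seed)
    names = list(gene_names[: config.ppi_nodes])
    g = nx.barabasi_albert_graph(config.ppi_nodes, config.ppi_attach, seed=seed)
    edges = {(names[min(u, v)], names[max(u, v)]) for u, v in g.edges()}

    if config.planted_module_size > config.ppi_nodes:
        raise ArgumentError("planted module larger than network")
    planted_idx = rng.choice(
        config.ppi_nodes, size=config.planted_module_size, replace=False
    )
    planted = {names[i] for i in planted_idx}
    ordered = sorted(planted)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if rng.random() < 0.5:
                edges.add((min(a, b), max(a, b)))

    rows = []
    for a, b in sorted(edges):
        score = int(round(rng.uniform(0.7, 0.95) * 1000))
        rows.append(
            {
                "protein1": a,
                "protein2": b,
                "experiments": score,
                "databases": 0,
                "fusion": 0,
                "combined_score": score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein1",
            "protein2",
            "experiments",
            "databases",
            "fusion",
            "combined_score",
        ],
    ), planted


# ---------------------------------------------------------------------------
# pathways

def synth_pathways(
    gene_names: Sequence[str],
    planted_module_genes: Iterable[str],
    n_pathways: int = 10,
    seed: int = 0,
    size_range: tuple[int, int] = (30, 50),
    module_overlap: float = 0.6,
) -> str:
    """GMT text with two focal pathways and random fillers.

    Pathway 1 (PI3K_AKT_LIKE) contains every planted-module gene plus random
    fillers; pathway 2 (CANCER_LIKE) overlaps the planted module partially
    (``module_overlap`` of it); the rest are random gene sets.
    """
    if n_pathways < 2:
        raise ArgumentError("need at least 2 pathways")
    rng = np.random.default_rng(child_seed(seed, "pathways"))
    planted = sorted(set(planted_module_genes))
    universe = list(gene_names)
    lo, hi = size_range

    def fillers(exclude: set[str], n: int) -> list[str]:
        pool = [g for g in universe if g not in exclude]
        if n > len(pool):
            raise ArgumentError("gene universe too small for pathway sizes")
        return [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]

    lines = []
    size1 = max(int(rng.integers(lo, hi + 1)), len(planted) + 5)
    genes1 = planted + fillers(set(planted), size1 - len(planted))
    lines.append("\t".join(["PI3K_AKT_LIKE", "synthetic focal pathway 1", *genes1]))

    n_core = int(round(module_overlap * len(planted)))
    core = (
        [planted[i] for i in rng.choice(len(planted), size=n_core, replace=False)]
        if planted
        else []
    )
    size2 = max(int(rng.integers(lo, hi + 1)), len(core) + 5)
    genes2 = core + fillers(set(core), size2 - len(core))
    lines.append("\t".join(["CANCER_LIKE", "synthetic focal pathway 2", *genes2]))

    for i in range(3, n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        genes = fillers(set(), size)
        lines.append("\t".join([f"PWY{i:02d}", f"random pathway {i}", *genes]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# individuals and cohort

def synth_individual_gene_sets(
    config: SimulationConfig,
    gene_names: Sequence[str],
    planted_module_genes: Iterable[str],
    n_familial: int = 10,
    n_control: int = 10,
    set_size: int = 40,
    module_take: int = 25,
) -> list[tuple[str, str, set[str]]]:
    """Per-individual variant-gene sets: familial individuals draw most of
    their genes from the planted module, controls draw at random."""
    rng = np.random.default_rng(child_seed(config.seed, "gene_sets"))
    planted = sorted(set(planted_module_genes))
    universe = list(gene_names)
    out = []
    for i in range(n_familial):
        take = min(module_take, len(planted))
        genes = set(
            planted[j] for j in rng.choice(len(planted), size=take, replace=False)
        )
        pool = [g for g in universe if g not in genes]
        extra = set_size - len(genes)
        genes |= {pool[j] for j in rng.choice(len(pool), size=extra, replace=False)}
        out.append((f"FAM{i + 1:02d}", "familial_patient", genes))
    for i in range(n_control):
        genes = {
            universe[j]
            for j in rng.choice(len(universe), size=set_size, replace=False)
        }
        out.append((f"CTL{i + 1:02d}", "control", genes))
    return out


def synth_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Case-control cohort with Bernoulli exposures at the configured
    per-arm probabilities (columns: id, status, exposure)."""
    n_cases, n_controls = config.cohort_sizes
    if n_cases <= 0 or n_controls <= 0:
        raise ArgumentError("cohort sizes must be positive")
    p_case, p_control = config.exposure_probs
    rng = np.random.default_rng(child_seed(config.seed, "cohort"))
    exp_cases = rng.random(n_cases) < p_case
    exp_controls = rng.random(n_controls) < p_control
    ids = [f"case{i + 1:05d}" for i in range(n_cases)] + [
        f"ctrl{i + 1:05d}" for i in range(n_controls)
    ]
    status = ["case"] * n_cases + ["control"] * n_controls
    exposure = np.where(
        np.concatenate([exp_cases, exp_controls]), "yes", "no"
    )
    return pd.DataFrame({"id": ids, "status": status, "exposure": exposure})


# ---------------------------------------------------------------------------
# file emission

def write_fasta(genome: str, name: str = "chr1", width: int = 70) -> str:
    body = "\n".join(genome[i : i + width] for i in range(0, len(genome), width))
    return f">{name}\n{body}\n"


def read_fasta(text: str) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            seqs[current] = []
        elif current is not None:
            seqs[current].append(line.strip())
    return {k: "".join(v).upper() for k, v in seqs.items()}


def simulate_all(
    config: SimulationConfig,
    outdir: str | Path,
    n_seq_individuals: int = 2,
) -> dict:
    """Generate and write every pipeline input under ``outdir``.

    Sequenced individuals get blood/para/cancer pileups with a shared
    germline core (the first individual's germline sites) plus private
    sites; network-level individuals get gene sets via
    :func:`synth_individual_gene_sets`.
    Returns a manifest of written paths plus the ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, models = synth_genome(config)
    (outdir / "genome.fa").write_text(write_fasta(genome))
    (outdir / "genes.refflat").write_text(write_refflat(models))

    pileup_dir = outdir / "pileups"
    pileup_dir.mkdir(exist_ok=True)
    truths = []
    core = synth_truth(config, genome, models, coding_only=True, index=0)
    n_core = max(1, config.n_germline // 2)
    for i in range(n_seq_individuals):
        private = synth_truth(config, genome, models, coding_only=True, index=i + 1)
        core_positions = {p for p, *_ in core.germline_sites[:n_core]}
        merged_germ = core.germline_sites[:n_core] + [
            s for s in private.germline_sites if s[0] not in core_positions
        ]
        germ_positions = {p for p, *_ in merged_germ}
        somatic = [s for s in private.somatic_sites if s[0] not in germ_positions]
        truth = GroundTruth(
            germline_sites=sorted(merged_germ),
            somatic_sites=sorted(somatic),
            true_or=config.true_or,
        )
        truths.append(truth)
        for tissue in ("blood", "para", "cancer"):
            df = synth_pileup(genome, truth, config, tissue, index=i)
            df.to_csv(pileup_dir / f"IND{i + 1:02d}_{tissue}.tsv", sep="\t", index=False)

    gene_names = default_gene_names(config.n_gene_universe)
    edges, planted = synth_ppi(config, gene_names)
    edges.to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False)
    gmt = synth_pathways(gene_names, planted, n_pathways=25, seed=config.seed)
    (outdir / "pathways.gmt").write_text(gmt)

    gene_sets = synth_individual_gene_sets(config, gene_names, planted)
    (outdir / "gene_sets.json").write_text(
        json.dumps(
            [
                {"id": i, "label": lab, "genes": sorted(genes)}
                for i, lab, genes in gene_sets
            ],
            indent=1,
        )
    )

    cohort = synth_cohort(config)
    cohort.to_csv(outdir / "cohort.csv", index=False)

    truth_all = GroundTruth(
        germline_sites=truths[0].germline_sites if truths else [],
        somatic_sites=truths[0].somatic_sites if truths else [],
        planted_module_genes=planted,
        true_or=config.true_or,
    )
    (outdir / "truth.json").write_text(truth_all.to_json())
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=1))
    return {
        "outdir": str(outdir),
        "n_seq_individuals": n_seq_individuals,
        "planted_module_genes": sorted(planted),
        "truths": truths,
        "shared_core_size": n_core,
    }
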