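"""Deterministic synthetic genomes, annotations and mutation ladders.

Everything the rest of the toolkit needs for testing and benchmarking is
generated here, reproducibly from an integer seed: i.i.d. genomes with a
chosen GC content, non-overlapping gene/CDS annotations, uniform
substitution mutants, and exact site planting for off-target fixtures.

The mutation ladder is *coupled*: one uniform variate and one alternative
base are drawn per position, independently of the rate ``r``, and a
position is substituted whenever its variate falls below ``r``.  The
mutation set at a lower rate is therefore an exact subset of the set at
any higher rate (same seed), so monotonicity of downstream statistics
along a ladder holds deterministically, not just in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._seq import decode, encode, revcomp
from .genome_io import Contig, Feature, Genome

_BASES = "ACGT"


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a synthetic genome; defaults emulate a desk-scale
    small-prokaryote test case (single 50 kb contig, balanced GC, 25
    non-overlapping genes of 0.3-1.5 kb separated by 0.1-0.4 kb)."""

    n_contigs: int = 1
    contig_len: int = 50_000
    gc_fraction: float = 0.5
    n_genes: int = 25
    gene_len: tuple[int, int] = (300, 1500)
    intergenic: tuple[int, int] = (100, 400)
    strand_ratio: float = 0.5
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0,1]")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must be in [0,1)")
        if self.gene_len[0] > self.gene_len[1] or self.gene_len[0] <= 0:
            raise ValueError("bad gene_len range")
        if self.intergenic[0] > self.intergenic[1] or self.intergenic[0] < 0:
            raise ValueError("bad intergenic range")


def random_genome(spec: SimSpec) -> Genome:
    """i.i.d. bases with P(G)+P(C) = gc_fraction; seed-reproducible."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs = []
    for i in range(spec.n_contigs):
        codes = rng.choice(4, size=spec.contig_len, p=p).astype(np.uint8)
        contigs.append(Contig(id=f"sim{i + 1}", seq=decode(codes)))
    return Genome(name=f"sim_seed{spec.seed}", contigs=contigs)


def random_annotation(genome: Genome, spec: SimSpec) -> list[Feature]:
    """Non-overlapping gene+CDS pairs packed left to right.

    Genes are placed sequentially with random lengths and intergenic gaps,
    round-robin across contigs; locus tags run LOC0001, LOC0002, ...
    Raises ValueError naming the achievable maximum when the request does
    not fit.
    """
    rng = np.random.default_rng(spec.seed + 1)
    features: list[Feature] = []
    cursors = {c.id: int(rng.integers(spec.intergenic[0], spec.intergenic[1] + 1))
               for c in genome.contigs}
    placed = 0
    contig_cycle = [c for c in genome.contigs]
    ci = 0
    stuck = 0
    while placed < spec.n_genes and stuck < len(contig_cycle):
        contig = contig_cycle[ci % len(contig_cycle)]
        ci += 1
        glen = int(rng.integers(spec.gene_len[0], spec.gene_len[1] + 1))
        gap = int(rng.integers(spec.intergenic[0], spec.intergenic[1] + 1))
        start = cursors[contig.id]
        if start + glen > contig.length:
            stuck += 1
            continue
        stuck = 0
        placed += 1
        end = start + glen
        cursors[contig.id] = end + gap
        strand = "+" if rng.random() < spec.strand_ratio else "-"
        locus = f"LOC{placed:04d}"
        features.append(
            Feature(
                feature_id=f"gene_{locus}",
                locus_id=locus,
                contig_id=contig.id,
                start=start,
                end=end,
                strand=strand,
                ftype="gene",
            )
        )
        features.append(
            Feature(
                feature_id=f"cds_{locus}",
                locus_id=locus,
                contig_id=contig.id,
                start=start,
                end=end,
                strand=strand,
                ftype="CDS",
                parent_id=f"gene_{locus}",
            )
        )
    if placed < spec.n_genes:
        raise ValueError(
            f"cannot place {spec.n_genes} genes in {genome.total_length} bp; "
            f"achievable maximum with this spec is {placed}"
        )
    return features


def mutate(genome: Genome, r: float, seed: int) -> Genome:
    """Uniform substitutions at per-base rate ``r``, coupled across rates.

    Each position draws (once, rate-independently) a uniform variate and a
    replacement offset; the base is substituted iff the variate < r, by
    one of the three other bases chosen uniformly.  Non-ACGT bases are
    left untouched.
    """
    if not (0.0 <= r < 1.0):
        raise ValueError("mutation rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    contigs = []
    for contig in genome.contigs:
        enc = encode(contig.seq)
        u = rng.random(contig.length)
        alt = rng.integers(1, 4, size=contig.length).astype(np.uint8)
        hit = (u < r) & (enc < 4)
        out = enc.copy()
        out[hit] = (out[hit] + alt[hit]) % 4
        contigs.append(Contig(id=contig.id, seq=decode(out)))
    return Genome(name=f"{genome.name}_r{r:g}", contigs=contigs)


def plant_site(
    genome: Genome,
    sequence: str,
    position: int,
    strand: str = "+",
    contig_id: str | None = None,
) -> Genome:
    """Overwrite genome sequence with ``sequence`` at ``position``.

    On strand '-', the reverse complement is written so the planted site
    reads as ``sequence`` on the minus strand.  Used to build duplications
    and controlled near-matches for off-target fixtures.
    """
    sequence = sequence.upper()
    contig_id = contig_id or genome.contigs[0].id
    contig = genome[contig_id]
    if position < 0 or position + len(sequence) > contig.length:
        raise ValueError(
            f"planted site [{position},{position + len(sequence)}) outside "
            f"contig {contig_id} of length {contig.length}"
        )
    insert = revcomp(sequence) if strand == "-" else sequence
    seq = contig.seq[:position] + insert + contig.seq[position + len(insert):]
    contigs = [
        Contig(id=c.id, seq=seq) if c.id == contig_id else c for c in genome.contigs
    ]
    return Genome(name=genome.name, contigs=contigs)


def mutation_ladder(genome: Genome, rates: list[float], seed: int) -> list[Genome]:
    """Coupled mutants of one genome at each rate (shared seed)."""
    return [mutate(genome, r, seed) for r in rates]
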