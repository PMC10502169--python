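"""Guide-library portability across related genomes.

A guide "transfers" to another genome when its spacer occurs there
perfectly (Hamming distance 0) adjacent to a valid PAM, on either strand.
For a library of ``n`` guides the per-genome summary reports the matched
fraction and the number of guides with two or more perfect sites (each a
perfect off-target).  Genome relatedness is expressed as average
nucleotide identity (ANI), either supplied from metadata or estimated
natively with a bottom-s MinHash sketch over canonical k-mers using the
Mash distance formula ``ANI = 1 + ln(2J/(1+J))/k``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd

from .genome_io import Genome, ValidationError
from .offtarget_search import iter_windows

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PortabilityResult:
    """Per-genome library match summary."""

    genome_name: str
    n_guides: int
    n_matched: int
    n_multi: int
    ani_estimate: float | None = None
    ani_provided: float | None = None

    @property
    def fraction_matched(self) -> float:
        return self.n_matched / self.n_guides


def _spacers(library) -> list[str]:
    guides = getattr(library, "guides", library)
    spacers = [g if isinstance(g, str) else g.spacer for g in guides]
    if not spacers:
        raise ValidationError("empty guide library")
    lengths = {len(s) for s in spacers}
    if len(lengths) != 1:
        raise ValidationError(f"mixed spacer lengths in library: {sorted(lengths)}")
    return [s.upper() for s in spacers]


def match_library(library, genome: Genome, pam: str) -> PortabilityResult:
    """Count library guides with >=1 (matched) and >=2 (multi-site)
    perfect spacer+PAM occurrences in ``genome``, either strand."""
    spacers = _spacers(library)
    L = len(spacers[0])
    counts: Counter[str] = Counter()
    for _contig, _start, _strand, spacer, _pam in iter_windows(genome, pam, L):
        if spacer is not None:
            counts[spacer] += 1
    n_matched = sum(1 for s in spacers if counts[s] >= 1)
    n_multi = sum(1 for s in spacers if counts[s] >= 2)
    return PortabilityResult(
        genome_name=genome.name,
        n_guides=len(spacers),
        n_matched=n_matched,
        n_multi=n_multi,
    )


# --------------------------------------------------------------------------
# MinHash sketching / ANI


@dataclass(frozen=True)
class KmerSketch:
    """Bottom-s MinHash sketch over canonical k-mers."""

    k: int
    sketch_size: int
    seed: int
    hashes: np.ndarray  # sorted uint64, length <= sketch_size


def _splitmix64(x: np.ndarray) -> np.ndarray:
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    from ._seq import encode

    enc = encode(seq).astype(np.uint64)
    m = len(seq) - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = (enc >= 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    fwd = np.zeros(m, dtype=np.uint64)
    rc = np.zeros(m, dtype=np.uint64)
    b = enc & np.uint64(3)
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | b[i : i + m]
    for i in range(k - 1, -1, -1):
        rc = (rc << np.uint64(2)) | (np.uint64(3) - b[i : i + m])
    return np.minimum(fwd, rc)[valid]


def sketch(genome: Genome | str, k: int, sketch_size: int, seed: int = 0) -> KmerSketch:
    """Bottom-``sketch_size`` MinHash of the canonical k-mer set.

    Canonical = the lexicographic minimum of a k-mer and its reverse
    complement (2-bit encoded), so a sequence and its reverse complement
    sketch identically.  k must lie in [11, 31]; k-mers spanning non-ACGT
    bases are skipped, and sequences shorter than k give an empty sketch
    with a warning.
    """
    if not (11 <= k <= 31):
        raise ValueError(f"k must be in [11, 31], got {k}")
    seqs = [c.seq for c in genome.contigs] if isinstance(genome, Genome) else [genome]
    codes = [
        _canonical_kmer_codes(s, k) for s in seqs if len(s) >= k
    ]
    if not codes or all(len(c) == 0 for c in codes):
        log.warning("sequence shorter than k=%d: empty sketch", k)
        return KmerSketch(k=k, sketch_size=sketch_size, seed=seed,
                          hashes=np.empty(0, dtype=np.uint64))
    allcodes = np.unique(np.concatenate(codes))
    hashes = np.unique(_splitmix64(allcodes ^ np.uint64(seed)))
    return KmerSketch(
        k=k, sketch_size=sketch_size, seed=seed, hashes=hashes[:sketch_size]
    )


def estimate_ani(a: KmerSketch, b: KmerSketch) -> float | None:
    """Mash-style ANI estimate from two compatible sketches.

    Jaccard similarity J is estimated on the bottom-s sketch of the union;
    ANI = 1 + ln(2J/(1+J))/k, clamped to (0, 1].  Returns None when the
    sketches share nothing (identity below the sketch's resolution).
    """
    if a.k != b.k or a.seed != b.seed:
        raise ValidationError(
            f"incompatible sketches: k {a.k}/{b.k}, seed {a.seed}/{b.seed}"
        )
    if len(a.hashes) == 0 or len(b.hashes) == 0:
        return None
    s = min(a.sketch_size, b.sketch_size)
    merged = np.union1d(a.hashes, b.hashes)[:s]
    shared = np.intersect1d(merged, np.intersect1d(a.hashes, b.hashes)).size
    if shared == 0:
        return None
    j = shared / len(merged)
    ani = 1.0 + math.log(2.0 * j / (1.0 + j)) / a.k
    return min(1.0, max(ani, 1e-12))


def portability_series(
    library,
    genomes: list[Genome],
    pam: str,
    reference: Genome | None = None,
    ani_table: dict[str, float] | None = None,
    k: int = 16,
    sketch_size: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Match the library against each genome; one row per genome.

    When ``reference`` is given, ANI of each genome to the reference is
    estimated by MinHash; user-provided ANI values (``ani_table``, keyed
    by genome name) are carried through in their own column.  Rows are
    sorted by descending ANI (estimate, falling back to provided).
    """
    if not genomes:
        raise ValidationError("at least one genome required")
    _spacers(library)  # validates non-empty + single length
    ref_sketch = sketch(reference, k, sketch_size, seed) if reference is not None else None
    rows = []
    for g in genomes:
        res = match_library(library, g, pam)
        ani_est = None
        if ref_sketch is not None:
            ani_est = estimate_ani(ref_sketch, sketch(g, k, sketch_size, seed))
        ani_prov = (ani_table or {}).get(g.name)
        rows.append(
            {
                "genome": g.name,
                "n_guides": res.n_guides,
                "n_matched": res.n_matched,
                "fraction": res.fraction_matched,
                "n_multi": res.n_multi,
                "ani_estimate": ani_est,
                "ani_provided": ani_prov,
            }
        )
    df = pd.DataFrame(rows)
    sort_key = df["ani_estimate"].fillna(df["ani_provided"]).fillna(-1.0)
    df = df.iloc[np.argsort(-sort_key.to_numpy(), kind="stable")].reset_index(drop=True)
    return df
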