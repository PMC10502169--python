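"""Mismatch-bounded genome search for spacer+PAM sites.

Two independent routes find every genomic window that (a) carries a valid
PAM and (b) lies within a Hamming-distance budget of a query spacer:

* :func:`find_sites` — a pigeonhole seed-and-extend search over a
  :class:`SeedIndex` of all PAM-adjacent windows.  The spacer is cut into
  disjoint PAM-proximal slices of length ``seed_len``; a site with at most
  ``m`` mismatches must match at least one of any ``m+1`` disjoint slices
  exactly, so looking up ``m+1`` slices and verifying candidates is exact.
* :func:`brute_force_scan` — a vectorised exhaustive window scan, kept as
  the reference implementation.

Conventions: the PAM sits 3' of the spacer (SpCas9 layout).  Hit
coordinates span the full spacer+PAM footprint on the forward genomic
strand, 0-based half-open, for both orientations.  Mismatch positions are
numbered 1..spacer_len from the 5' (PAM-distal) end, so PAM-proximal
mismatches carry high indices.  IUPAC codes are honoured in the PAM
*pattern* only; ambiguity codes in the genome never match, and windows
whose spacer part contains non-ACGT bases are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seq import IUPAC_SETS, encode, pam_code_sets, revcomp
from .genome_io import Genome

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OffTargetHit:
    """One genomic site within the mismatch budget of a spacer.

    ``start``/``strand`` locate the full spacer+PAM window on the forward
    strand; ``mismatch_positions`` are 1-based from the spacer's 5' end.
    """

    contig_id: str
    start: int
    strand: str
    mismatch_positions: tuple[int, ...]
    pam_seq: str

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


@dataclass
class SeedIndex:
    """All PAM-adjacent windows of a genome, keyed by spacer slices.

    ``windows`` holds one (contig_id, start, strand) triple per window;
    ``slice_maps[i]`` maps the i-th PAM-proximal ``seed_len``-mer of a
    window's spacer to window indices.  ``n_slices`` disjoint slices are
    available, so searches up to ``n_slices - 1`` mismatches are exact.
    """

    pam: str
    spacer_len: int
    seed_len: int
    windows: list[tuple[str, int, str]] = field(default_factory=list)
    slice_maps: list[dict[str, list[int]]] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def n_slices(self) -> int:
        return len(self.slice_maps)

    def slice_bounds(self, i: int) -> tuple[int, int]:
        """Oriented-spacer coordinates of slice i (0 = PAM-proximal)."""
        end = self.spacer_len - i * self.seed_len
        return end - self.seed_len, end


def _pam_positions(enc: np.ndarray, pam: str, strand: str) -> np.ndarray:
    """Offsets where the PAM pattern (or its reverse complement for the
    minus strand) matches forward-strand encoded sequence."""
    if strand == "+":
        codes = pam_code_sets(pam)
    else:
        codes = pam_code_sets(revcomp(pam))
    P = len(pam)
    n = len(enc) - P + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mask = np.ones(n, dtype=bool)
    for j, allowed in enumerate(codes):
        mask &= np.isin(enc[j : j + n], allowed)
    return np.nonzero(mask)[0]


def iter_windows(genome: Genome, pam: str, spacer_len: int):
    """Yield (contig_id, window_start, strand, oriented_spacer, pam_seq)
    for every PAM-adjacent window with a clean ACGT spacer.

    Also yields excluded windows as (..., None, pam_seq) so callers can
    count them.
    """
    L, P = spacer_len, len(pam)
    W = L + P
    for contig in genome.contigs:
        if contig.length < W:
            log.warning(
                "contig %s shorter than spacer+PAM (%d < %d); skipped",
                contig.id, contig.length, W,
            )
            continue
        enc = encode(contig.seq)
        clean = enc < 4
        # plus strand: spacer at [s, s+L), PAM at [s+L, s+L+P)
        for p in _pam_positions(enc, pam, "+"):
            s = int(p) - L
            if s < 0:
                continue
            spacer = contig.seq[s : s + L]
            ok = bool(clean[s : s + L].all())
            yield contig.id, s, "+", spacer if ok else None, contig.seq[s + L : s + L + P]
        # minus strand: PAM (revcomp pattern) at [s, s+P), spacer at [s+P, s+P+L)
        for p in _pam_positions(enc, pam, "-"):
            s = int(p)
            if s + W > contig.length:
                continue
            ok = bool(clean[s + P : s + P + L].all())
            spacer = revcomp(contig.seq[s + P : s + P + L])
            yield contig.id, s, "-", spacer if ok else None, revcomp(contig.seq[s : s + P])


def build_index(genome: Genome, pam: str, spacer_len: int, seed_len: int) -> SeedIndex:
    """Index every PAM-adjacent window under its PAM-proximal spacer slices.

    ``seed_len`` must lie in [4, spacer_len]; ``spacer_len // seed_len``
    disjoint slices are stored, bounding the exact mismatch budget usable
    at query time.
    """
    if not (4 <= seed_len <= spacer_len):
        raise ValueError(f"seed_len must be in [4, {spacer_len}], got {seed_len}")
    for c in pam:
        if c not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {c!r} in PAM {pam!r}")
    n_slices = spacer_len // seed_len
    idx = SeedIndex(pam=pam, spacer_len=spacer_len, seed_len=seed_len,
                    slice_maps=[{} for _ in range(n_slices)])
    for contig_id, start, strand, spacer, _pam_seq in iter_windows(genome, pam, spacer_len):
        if spacer is None:
            idx.n_excluded += 1
            continue
        wid = len(idx.windows)
        idx.windows.append((contig_id, start, strand))
        for i in range(n_slices):
            a, b = idx.slice_bounds(i)
            idx.slice_maps[i].setdefault(spacer[a:b], []).append(wid)
    if idx.n_excluded:
        log.info("%d windows excluded for non-ACGT bases", idx.n_excluded)
    return idx


def _window_oriented_seqs(
    genome: Genome, contig_id: str, start: int, strand: str, spacer_len: int, pam_len: int
) -> tuple[str, str]:
    """(oriented spacer, oriented PAM) of a window from its coordinates."""
    seq = genome[contig_id].seq
    W = spacer_len + pam_len
    if strand == "+":
        return seq[start : start + spacer_len], seq[start + spacer_len : start + W]
    return (
        revcomp(seq[start + pam_len : start + W]),
        revcomp(seq[start : start + pam_len]),
    )


def find_sites(
    spacer: str,
    index: SeedIndex,
    genome: Genome,
    max_mismatches: int,
) -> list[OffTargetHit]:
    """All PAM-adjacent sites within ``max_mismatches`` of ``spacer``.

    Exactness requires ``max_mismatches + 1`` disjoint seed slices, i.e.
    ``seed_len <= spacer_len // (max_mismatches + 1)``; other
    configurations are rejected.
    """
    spacer = spacer.upper()
    if len(spacer) != index.spacer_len:
        raise ValueError(
            f"spacer length {len(spacer)} != index spacer_len {index.spacer_len}"
        )
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if index.n_slices < max_mismatches + 1:
        raise ValueError(
            f"seed_len {index.seed_len} provides {index.n_slices} disjoint slices; "
            f"{max_mismatches + 1} needed for an exact search at "
            f"{max_mismatches} mismatches (pigeonhole)"
        )
    cand: set[int] = set()
    for i in range(max_mismatches + 1):
        a, b = index.slice_bounds(i)
        cand.update(index.slice_maps[i].get(spacer[a:b], ()))
    hits = []
    L, P = index.spacer_len, len(index.pam)
    for wid in sorted(cand):
        contig_id, start, strand = index.windows[wid]
        site, pam_seq = _window_oriented_seqs(genome, contig_id, start, strand, L, P)
        mis = []
        for i in range(L):
            if site[i] != spacer[i]:
                mis.append(i + 1)
                if len(mis) > max_mismatches:
                    break
        if len(mis) <= max_mismatches:
            hits.append(
                OffTargetHit(
                    contig_id=contig_id,
                    start=start,
                    strand=strand,
                    mismatch_positions=tuple(mis),
                    pam_seq=pam_seq,
                )
            )
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return hits


def brute_force_scan(
    spacer: str,
    genome: Genome,
    pam: str,
    max_mismatches: int,
) -> list[OffTargetHit]:
    """Exhaustive reference scan of every window on both strands.

    Vectorised with numpy but independent of the seed index: per contig it
    computes the Hamming profile of all windows in O(genome x spacer_len)
    and thresholds it.
    """
    spacer = spacer.upper()
    L, P = len(spacer), len(pam)
    W = L + P
    sp = encode(spacer)
    sp_rc = encode(revcomp(spacer))
    hits: list[OffTargetHit] = []
    for contig in genome.contigs:
        if contig.length < W:
            continue
        enc = encode(contig.seq)
        n = contig.length - W + 1
        clean = (enc < 4).astype(np.int16)

        for strand in ("+", "-"):
            mm = np.zeros(n, dtype=np.int16)
            ok = np.ones(n, dtype=bool)
            if strand == "+":
                # spacer at [s, s+L)
                for i in range(L):
                    seg = enc[i : i + n]
                    mm += seg != sp[i]
                    ok &= seg < 4
                for j, allowed in enumerate(pam_code_sets(pam)):
                    ok &= np.isin(enc[L + j : L + j + n], allowed)
            else:
                # oriented spacer position i sits at genomic offset P + L-1-i,
                # holding the complement of spacer[i]; compare against the
                # reverse complement encoding directly.
                for i in range(L):
                    seg = enc[P + i : P + i + n]
                    mm += seg != sp_rc[i]
                    ok &= seg < 4
                for j, allowed in enumerate(pam_code_sets(revcomp(pam))):
                    ok &= np.isin(enc[j : j + n], allowed)
            sel = np.nonzero(ok & (mm <= max_mismatches))[0]
            for s in sel.tolist():
                site, pam_seq = _window_oriented_seqs(
                    genome, contig.id, s, strand, L, P
                )
                mis = tuple(i + 1 for i in range(L) if site[i] != spacer[i])
                hits.append(
                    OffTargetHit(
                        contig_id=contig.id,
                        start=s,
                        strand=strand,
                        mismatch_positions=mis,
                        pam_seq=pam_seq,
                    )
                )
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return hits
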