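"""Guide enumeration, scoring, ranking and the end-to-end design pipeline.

For every target region the designer enumerates all PAM-adjacent windows
with a full-length spacer, searches the whole genome for off-target sites
within the mismatch budget, scores each candidate twice —

* an off-target positional score: each off-target site contributes
  ``sum(1.2**p)`` over its mismatch positions ``p`` (1..L from the 5' end),
  so sites whose mismatches crowd the PAM-proximal end (where mismatches
  are least tolerated, hence the site least likely to cut) score highest;
* a folding accessibility score: the fraction of spacer bases left
  unpaired in a maximum base-pairing secondary structure of
  spacer+scaffold (Nussinov dynamic programming, Watson-Crick plus G:U
  wobble pairs, minimum hairpin loop of 3);

— and selects the top ``n_guides`` per locus.  Candidates with a
perfect-match off-target elsewhere in the genome are disqualified from
normal ranking: they fill remaining slots only when too few clean
candidates exist, flagged in the scoring log, and the locus is recorded in
the shortfall report with its clean-candidate count.
"""

from __future__ import annotations

import logging
import tarfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import IUPAC_SETS, encode, revcomp
from .genome_io import (
    Genome,
    AnnotationStore,
    ValidationError,
    write_fasta,
    write_guides_csv,
)
from .offtarget_search import (
    OffTargetHit,
    SeedIndex,
    brute_force_scan,
    build_index,
    find_sites,
)
from .region_select import (
    RegionSpec,
    TargetRegion,
    extract_regions,
    validate_spec,
)

log = logging.getLogger(__name__)

#: Canonical hybrid single-guide scaffold (crRNA:tracrRNA fusion) appended
#: 3' of the spacer when predicting folding.  Editable via GuideParams.
DEFAULT_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

STRAND_FILTERS = ("any", "coding", "template")


@dataclass(frozen=True)
class GuideParams:
    """Design parameters; defaults follow common SpCas9 practice."""

    pam: str = "NGG"
    spacer_len: int = 20
    max_mismatches: int = 4
    n_guides: int = 3
    strand_filter: str = "any"
    scaffold_seq: str = DEFAULT_SCAFFOLD

    def __post_init__(self) -> None:
        if self.spacer_len < 10:
            raise ValidationError("spacer_len must be >= 10")
        if self.n_guides < 1:
            raise ValidationError("n_guides must be >= 1")
        if self.max_mismatches < 0:
            raise ValidationError("max_mismatches must be >= 0")
        if self.strand_filter not in STRAND_FILTERS:
            raise ValidationError(f"strand_filter must be one of {STRAND_FILTERS}")
        bad = set(self.pam.upper()) - set(IUPAC_SETS)
        if bad or not self.pam:
            raise ValidationError(f"PAM {self.pam!r} is not valid IUPAC")
        object.__setattr__(self, "pam", self.pam.upper())
        scaffold = self.scaffold_seq.upper().replace("U", "T")
        object.__setattr__(self, "scaffold_seq", scaffold)


@dataclass
class GuideCandidate:
    """A spacer+PAM instance; scores filled in by the pipeline.

    ``start``/``end`` span the full spacer+PAM window on the forward
    genomic strand (end - start == spacer_len + |PAM|).
    """

    locus_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    spacer: str
    pam_observed: str
    name: str = ""
    offtargets: list[OffTargetHit] = field(default_factory=list)
    offtarget_score: float = 0.0
    fold_score: float = 0.0
    rank: int = 0
    perfect_offtarget: bool = False


@dataclass
class GuideLibrary:
    """Selected guides plus the per-locus shortfall report."""

    guides: list[GuideCandidate]
    shortfall: dict[str, int]
    params: GuideParams


# --------------------------------------------------------------------------
# enumeration


def enumerate_pam_sites(seq: str, pam: str) -> list[tuple[int, str]]:
    """Every PAM occurrence in ``seq`` as (offset, strand), ascending.

    Offsets index the forward representation of ``seq`` for both strands
    (a minus-strand occurrence means the reverse complement of the PAM
    pattern matches at that offset).  IUPAC codes are interpreted in the
    pattern only; ambiguous genome bases never match.
    """
    seq = seq.upper()
    out: list[tuple[int, str]] = []
    P = len(pam)
    rc_pam = revcomp(pam)
    for o in range(len(seq) - P + 1):
        window = seq[o : o + P]
        if all(b in IUPAC_SETS.get(p, ()) and b in "ACGT" for p, b in zip(pam, window)):
            out.append((o, "+"))
        if all(b in IUPAC_SETS.get(p, ()) and b in "ACGT" for p, b in zip(rc_pam, window)):
            out.append((o, "-"))
    return out


def candidates_in_region(
    region: TargetRegion, genome: Genome, params: GuideParams
) -> list[GuideCandidate]:
    """Unscored candidates whose spacer+PAM lie wholly inside the region.

    The spacer sits 5' of the PAM on the candidate strand.  Spacers with
    non-ACGT bases are dropped (logged).  ``strand_filter`` is interpreted
    relative to the locus strand: 'coding' keeps guides whose spacer reads
    on the locus's sense strand, 'template' the opposite.
    """
    L, P = params.spacer_len, len(params.pam)
    if region.length < L + P:
        return []
    contig_seq = genome[region.contig_id].seq
    fwd = contig_seq[region.start : region.end]
    out: list[GuideCandidate] = []
    for offset, strand in enumerate_pam_sites(fwd, params.pam):
        if strand == "+":
            s = region.start + offset - L
            if s < region.start:
                continue
            win_start, win_end = s, region.start + offset + P
            spacer = contig_seq[s : s + L]
            pam_obs = contig_seq[s + L : s + L + P]
        else:
            win_start = region.start + offset
            win_end = win_start + P + L
            if win_end > region.end:
                continue
            spacer = revcomp(contig_seq[win_start + P : win_end])
            pam_obs = revcomp(contig_seq[win_start : win_start + P])
        if any(b not in "ACGT" for b in spacer):
            log.debug("candidate at %s:%d dropped: ambiguous spacer", region.contig_id, win_start)
            continue
        if params.strand_filter == "coding" and strand != region.strand:
            continue
        if params.strand_filter == "template" and strand == region.strand:
            continue
        out.append(
            GuideCandidate(
                locus_id=region.locus_id or region.name,
                contig_id=region.contig_id,
                start=win_start,
                end=win_end,
                strand=strand,
                spacer=spacer,
                pam_observed=pam_obs,
            )
        )
    out.sort(key=lambda c: (c.start, c.strand))
    return out


# --------------------------------------------------------------------------
# scoring


def score_offtargets(candidate: GuideCandidate, hits: list[OffTargetHit]) -> float:
    """CCTop-style positional off-target score.

    Each hit contributes ``sum(1.2**p)`` over its 1-based mismatch
    positions; a perfect-match hit contributes 0 and flags the candidate
    as disqualified from clean ranking.  Hits must already exclude the
    on-target site.
    """
    candidate.offtargets = list(hits)
    candidate.perfect_offtarget = any(h.n_mismatches == 0 for h in hits)
    score = 0.0
    for h in hits:
        score += sum(1.2 ** p for p in h.mismatch_positions)
    candidate.offtarget_score = score
    return score


# base codes that can pair: Watson-Crick + G:U wobble
_PAIRABLE = np.zeros((5, 5), dtype=bool)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _PAIRABLE[_a, _b] = True

_MIN_LOOP = 3  # minimum unpaired bases in a hairpin loop


def nussinov_max_pairs(seq: str) -> tuple[int, set[int]]:
    """Maximum base-pairing structure of an RNA/DNA sequence.

    Returns (number of pairs, set of paired positions) for one maximum
    structure chosen by a deterministic traceback (prefer leaving the
    3'-most base unpaired; otherwise pair it with the smallest partner).
    Pairing rule: Watson-Crick + G:U, loop >= 3 unpaired bases.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    if n == 0:
        return 0, set()
    enc = encode(s)
    pairable = _PAIRABLE[np.ix_(enc, enc)]
    # M is N padded by one zero row/column on each side so that the
    # empty-span lookups N[i, i-1] and N[j+1, j] read 0 without wrapping:
    # N[i, j] == M[i+1, j+1].
    M = np.zeros((n + 2, n + 2), dtype=np.int32)
    idx0 = np.arange(n)
    for l in range(_MIN_LOOP + 1, n):
        i = idx0[: n - l]
        j = i + l
        best = M[i + 1, j].copy()  # N[i, j-1]: j unpaired
        dk = np.arange(l - _MIN_LOOP)
        kk = i[:, None] + dk[None, :]
        jj = j[:, None]
        left = M[i[:, None] + 1, kk]  # N[i, k-1]
        inner = M[kk + 2, jj]  # N[k+1, j-1]
        pm = pairable[kk, jj]
        cand = np.where(pm, left + inner + 1, -1).max(axis=1)
        M[i + 1, j + 1] = np.maximum(best, cand)
    N = M[1 : n + 1, 1 : n + 1]

    paired: set[int] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= _MIN_LOOP:
            continue
        if N[i, j] == N[i, j - 1]:
            stack.append((i, j - 1))
            continue
        target = N[i, j]
        for k in range(i, j - _MIN_LOOP):
            if not pairable[k, j]:
                continue
            left = N[i, k - 1] if k > i else 0
            if left + 1 + N[k + 1, j - 1] == target:
                paired.update((k, j))
                if k > i:
                    stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
    return int(N[0, n - 1]), paired


def score_folding(spacer: str, scaffold: str) -> float:
    """Fraction of spacer bases unpaired in a maximum-pairing structure of
    spacer+scaffold; 1.0 = fully accessible spacer (best)."""
    spacer = spacer.upper().replace("U", "T")
    scaffold = scaffold.upper().replace("U", "T")
    full = spacer + scaffold
    if len(full) < 4:
        raise ValidationError("spacer+scaffold must be at least 4 nt")
    _, paired = nussinov_max_pairs(full)
    if not spacer:
        return 1.0
    unpaired = sum(1 for i in range(len(spacer)) if i not in paired)
    return unpaired / len(spacer)


# --------------------------------------------------------------------------
# selection


def _rank_key(c: GuideCandidate):
    # fewer off-target sites, then mismatches concentrated PAM-proximal
    # (larger positional score), then more accessible spacer, then
    # coordinate for determinism.
    return (
        len(c.offtargets),
        -c.offtarget_score,
        -c.fold_score,
        c.contig_id,
        c.start,
        c.strand,
    )


def rank_and_select(candidates: list[GuideCandidate], params: GuideParams) -> GuideLibrary:
    """Pick the top ``n_guides`` per locus.

    Clean candidates (no perfect-match off-target) fill ranks first;
    flagged candidates are used only when clean ones run out.  Loci with
    fewer than ``n_guides`` clean candidates enter the shortfall map with
    their clean count.
    """
    by_locus: dict[str, list[GuideCandidate]] = {}
    for c in candidates:
        by_locus.setdefault(c.locus_id, []).append(c)
    guides: list[GuideCandidate] = []
    shortfall: dict[str, int] = {}
    for locus in sorted(by_locus):
        cands = by_locus[locus]
        clean = sorted((c for c in cands if not c.perfect_offtarget), key=_rank_key)
        flagged = sorted((c for c in cands if c.perfect_offtarget), key=_rank_key)
        chosen = clean[: params.n_guides]
        if len(chosen) < params.n_guides:
            shortfall[locus] = len(clean)
            chosen += flagged[: params.n_guides - len(chosen)]
        for r, c in enumerate(chosen, 1):
            c.rank = r
            c.name = f"{locus}_T{r}"
            guides.append(c)
    return GuideLibrary(guides=guides, shortfall=shortfall, params=params)


# --------------------------------------------------------------------------
# end-to-end pipeline


def _write_report(path: Path, report, library: GuideLibrary) -> None:
    with open(path, "w") as fh:
        fh.write("# design report\n")
        if report.warnings:
            fh.write("\n## warnings\n")
            for w in report.warnings:
                fh.write(f"{w}\n")
        fh.write("\n## loci below requested guide count\n")
        if not library.shortfall:
            fh.write("(none)\n")
        for locus, count in sorted(library.shortfall.items()):
            fh.write(f"{locus}\tclean_guides_found={count}\n")
        fh.write("\n## loci skipped during region extraction\n")
        if not report.skipped:
            fh.write("(none)\n")
        for locus, reason in report.skipped:
            fh.write(f"{locus}\t{reason}\n")


def _write_scoring_log(path: Path, candidates: list[GuideCandidate]) -> None:
    cols = [
        "name", "locus", "contig", "start", "end", "strand", "spacer", "pam",
        "n_offtargets", "offtarget_score", "fold_score", "perfect_offtarget",
        "selected", "rank",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            fh.write(
                "\t".join(
                    [
                        c.name or f"{c.contig_id}:{c.start}{c.strand}",
                        c.locus_id, c.contig_id, str(c.start + 1), str(c.end),
                        c.strand, c.spacer, c.pam_observed,
                        str(len(c.offtargets)), f"{c.offtarget_score:.4f}",
                        f"{c.fold_score:.4f}", str(c.perfect_offtarget),
                        str(bool(c.name)), str(c.rank or ""),
                    ]
                )
                + "\n"
            )


def design(
    genome: Genome,
    store: AnnotationStore,
    loci: list[str] | None,
    region_spec: RegionSpec,
    params: GuideParams,
    out_prefix: str | Path | None = None,
    make_bundle: bool = False,
) -> tuple[GuideLibrary, dict[str, Path]]:
    """Run the full pipeline: regions -> candidates -> genome-wide
    off-target search -> scoring -> per-locus selection -> output files.

    Output bundle (when ``out_prefix`` given): ``<prefix>.results.csv``
    (selected guides), ``<prefix>.target_regions.fa``,
    ``<prefix>.report.txt`` (shortfall + skipped loci) and
    ``<prefix>.scoring.log`` (statistics for every scored candidate).
    """
    violations = validate_spec(region_spec)
    if violations:
        raise ValidationError("invalid region spec: " + "; ".join(violations))
    regions, report = extract_regions(genome, store, loci, region_spec)
    if not regions:
        raise ValidationError(
            "no target regions resolved; check loci, feature type and offsets "
            f"(skipped: {report.skipped[:5]}...)"
        )

    L, P = params.spacer_len, len(params.pam)
    seed_len = L // (params.max_mismatches + 1)
    index: SeedIndex | None = None
    if seed_len >= 4:
        index = build_index(genome, params.pam, L, seed_len)

    all_candidates: list[GuideCandidate] = []
    site_cache: dict[str, list[OffTargetHit]] = {}
    fold_cache: dict[str, float] = {}
    for region in regions:
        for cand in candidates_in_region(region, genome, params):
            if cand.spacer in site_cache:
                hits = site_cache[cand.spacer]
            else:
                if index is not None:
                    hits = find_sites(cand.spacer, index, genome, params.max_mismatches)
                else:
                    hits = brute_force_scan(
                        cand.spacer, genome, params.pam, params.max_mismatches
                    )
                site_cache[cand.spacer] = hits
            own = (cand.contig_id, cand.start, cand.strand)
            score_offtargets(
                cand,
                [h for h in hits if (h.contig_id, h.start, h.strand) != own],
            )
            if cand.spacer not in fold_cache:
                fold_cache[cand.spacer] = score_folding(cand.spacer, params.scaffold_seq)
            cand.fold_score = fold_cache[cand.spacer]
            all_candidates.append(cand)

    library = rank_and_select(all_candidates, params)
    # loci whose regions produced no candidate at all still owe a report entry
    loci_with_regions = {r.locus_id or r.name for r in regions}
    loci_with_cands = {c.locus_id for c in all_candidates}
    for locus in sorted(loci_with_regions - loci_with_cands):
        library.shortfall.setdefault(locus, 0)
        report.add(locus, "no PAM-adjacent window fits the region")

    paths: dict[str, Path] = {}
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths["results"] = Path(f"{prefix}.results.csv")
        write_guides_csv(library, paths["results"])
        paths["target_regions"] = Path(f"{prefix}.target_regions.fa")
        write_fasta(regions, paths["target_regions"])
        paths["report"] = Path(f"{prefix}.report.txt")
        _write_report(paths["report"], report, library)
        paths["scoring_log"] = Path(f"{prefix}.scoring.log")
        _write_scoring_log(paths["scoring_log"], all_candidates)
        if make_bundle:
            paths["bundle"] = Path(f"{prefix}.tar.gz")
            with tarfile.open(paths["bundle"], "w:gz") as tf:
                for key in ("results", "target_regions", "report", "scoring_log"):
                    tf.add(paths[key], arcname=paths[key].name)
    return library, paths
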