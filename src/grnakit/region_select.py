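"""Feature-relative region selection.

The region grammar anchors both endpoints of a target region to reference
points of an annotated feature (its start or its end, in the feature's own
5'->3' frame) with signed base-pair offsets: negative offsets point
upstream of the anchor, positive downstream, and offset 0 is the anchor
base itself.  A resolved region is half-open ``[resolve(start_anchor +
start_offset), resolve(end_anchor + end_offset))`` in genomic coordinates,
reverse-complemented for minus-strand features so extracted sequence always
reads 5'->3' relative to the feature.

Typical uses: ``(feature_start-500 .. feature_start+0)`` extracts promoter
regions for CRISPRa/promoter libraries; ``(feature_start+0 ..
feature_end+0)`` is the feature itself; asymmetric specs produce homology
arms for repair templates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._seq import revcomp
from .genome_io import AnnotationStore, Feature, Genome

log = logging.getLogger(__name__)

LIMIT_MODES = ("coding_only", "noncoding_only", "both")
ANCHORS = ("feature_start", "feature_end")


@dataclass(frozen=True)
class RegionSpec:
    """Anchor/offset grammar for one batch of target regions."""

    limit_mode: str = "both"
    start_anchor: str = "feature_start"
    start_offset: int = 0
    end_anchor: str = "feature_end"
    end_offset: int = 0
    feature_type: str = "CDS"


@dataclass(frozen=True)
class TargetRegion:
    """A resolved genomic interval plus its (strand-corrected) sequence."""

    name: str
    contig_id: str
    start: int
    end: int
    strand: str
    seq: str
    locus_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExtractionReport:
    """Per-run record of loci that yielded no region, with reasons."""

    skipped: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, locus: str, reason: str) -> None:
        self.skipped.append((locus, reason))

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        log.warning(message)


def validate_spec(spec: RegionSpec) -> list[str]:
    """Return every incompatibility in the spec (empty list = valid).

    The canonical conflict: restricting to coding regions while asking for
    sequence upstream of the feature — the requested region cannot contain
    any of the feature's own coding sequence.
    """
    violations: list[str] = []
    if spec.limit_mode not in LIMIT_MODES:
        violations.append(f"unknown limit_mode {spec.limit_mode!r}")
    if spec.start_anchor not in ANCHORS:
        violations.append(f"unknown start_anchor {spec.start_anchor!r}")
    if spec.end_anchor not in ANCHORS:
        violations.append(f"unknown end_anchor {spec.end_anchor!r}")
    if violations:
        return violations
    if spec.limit_mode == "coding_only" and (
        (spec.start_anchor == "feature_start" and spec.start_offset < 0)
        or (spec.end_anchor == "feature_start" and spec.end_offset < 0)
    ):
        violations.append(
            "upstream region incompatible with coding-only limiting"
        )
    if spec.start_anchor == spec.end_anchor:
        if spec.start_offset == spec.end_offset:
            violations.append("empty region: start and end resolve to the same point")
        elif spec.start_offset > spec.end_offset:
            violations.append("inverted region: start offset beyond end offset")
    return violations


def resolve_region(
    feature: Feature, spec: RegionSpec, contig_length: int
) -> tuple[int, int] | str:
    """Map the spec onto one feature; returns (start, end) genomic interval
    or a string reason when the feature must be skipped.

    Anchors live in the feature's 5'->3' frame: on the plus strand
    ``feature_start`` is the genomic start and offsets increase rightward;
    on the minus strand ``feature_start`` is the genomic *end* and upstream
    (negative) offsets extend toward larger genomic coordinates.  Intervals
    are clamped to the contig.
    """

    def anchor_pos(anchor: str, offset: int) -> int:
        if feature.strand == "+":
            base = feature.start if anchor == "feature_start" else feature.end
            return base + offset
        base = feature.end if anchor == "feature_start" else feature.start
        return base - offset

    p_start = anchor_pos(spec.start_anchor, spec.start_offset)
    p_end = anchor_pos(spec.end_anchor, spec.end_offset)
    lo, hi = (p_start, p_end) if feature.strand == "+" else (p_end, p_start)
    if hi <= lo:
        return "empty or inverted region"
    clamped_lo, clamped_hi = max(0, lo), min(contig_length, hi)
    if (clamped_lo, clamped_hi) != (lo, hi):
        log.info(
            "region for %s clamped from [%d,%d) to [%d,%d)",
            feature.feature_id, lo, hi, clamped_lo, clamped_hi,
        )
    if clamped_hi <= clamped_lo:
        return "region entirely outside contig"
    return clamped_lo, clamped_hi


def _coding_union(
    store: AnnotationStore, contig_id: str, start: int, end: int,
    report: ExtractionReport | None = None,
) -> list[tuple[int, int]]:
    """Merged union of coding intervals overlapping [start,end), clipped.

    'Coding' means CDS-type features; annotations with no CDS at all fall
    back to gene-type features (warned once per call site).
    """
    ctype = "CDS"
    if not store.by_type("CDS"):
        ctype = "gene"
        if store.by_type("gene") and report is not None:
            report.warn("annotation has no CDS features; using gene features as coding")
    ivs = sorted(
        (max(f.start, start), min(f.end, end))
        for f in store.overlapping(contig_id, start, end, ftype=ctype)
    )
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if s >= e:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def limit_regions(
    interval: tuple[str, int, int],
    store: AnnotationStore,
    mode: str,
    report: ExtractionReport | None = None,
) -> list[tuple[int, int]]:
    """Restrict a genomic interval to its coding / non-coding parts.

    Returns disjoint, sorted sub-intervals whose union is exactly the
    set-intersection (coding_only) or set-difference (noncoding_only) of
    the interval with the union of coding features; mode='both' returns the
    interval unchanged.
    """
    contig_id, start, end = interval
    if mode == "both":
        return [(start, end)]
    coding = _coding_union(store, contig_id, start, end, report)
    if mode == "coding_only":
        return coding
    if mode == "noncoding_only":
        out: list[tuple[int, int]] = []
        cursor = start
        for s, e in coding:
            if s > cursor:
                out.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < end:
            out.append((cursor, end))
        return out
    raise ValueError(f"unknown limit mode {mode!r}")


def extract_regions(
    genome: Genome,
    store: AnnotationStore,
    loci: list[str] | None,
    spec: RegionSpec,
) -> tuple[list[TargetRegion], ExtractionReport]:
    """Resolve the spec for every requested locus and slice out sequence.

    ``loci`` empty/None targets every locus in the store (genome-scale).
    Unknown loci and loci whose region resolves empty are recorded in the
    report, never fatal.  Output order is deterministic: locus sort, then
    genomic coordinate; minus-strand sequences are reverse-complemented.
    """
    report = ExtractionReport()
    known = set(store.list_loci())
    if not loci:
        targets = store.list_loci()
    else:
        targets = []
        seen = set()
        for l in loci:
            if l in seen:
                continue
            seen.add(l)
            if l not in known:
                report.add(l, "locus not found in annotation")
            else:
                targets.append(l)
        targets.sort()

    regions: list[TargetRegion] = []
    for locus in targets:
        feats = [f for f in store.by_locus(locus) if f.ftype == spec.feature_type]
        if not feats:
            report.add(locus, f"no feature of type {spec.feature_type!r}")
            continue
        n_for_locus = 0
        multi = len(feats) > 1
        for fi, feat in enumerate(feats, 1):
            contig = genome[feat.contig_id]
            resolved = resolve_region(feat, spec, contig.length)
            if isinstance(resolved, str):
                report.add(locus, f"{feat.feature_id}: {resolved}")
                continue
            lo, hi = resolved
            subs = limit_regions((feat.contig_id, lo, hi), store, spec.limit_mode, report)
            if not subs:
                report.add(
                    locus,
                    f"{feat.feature_id}: nothing left after {spec.limit_mode} limiting",
                )
                continue
            if feat.strand == "-":
                subs = sorted(subs)
            for si, (s, e) in enumerate(subs, 1):
                name = locus
                if multi:
                    name += f".f{fi}"
                if len(subs) > 1:
                    name += f".r{si}"
                raw = contig.seq[s:e]
                seq = revcomp(raw) if feat.strand == "-" else raw
                regions.append(
                    TargetRegion(
                        name=name,
                        contig_id=feat.contig_id,
                        start=s,
                        end=e,
                        strand=feat.strand,
                        seq=seq,
                        locus_id=locus,
                    )
                )
                n_for_locus += 1
        if n_for_locus == 0 and not any(l == locus for l, _ in report.skipped):
            report.add(locus, "no region resolved")
    return regions, report
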