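"""Genome and annotation I/O.

Parses FASTA, GenBank and GFF3 into an in-memory :class:`Genome` plus a
queryable :class:`AnnotationStore`, and writes the FASTA/BED/CSV outputs the
rest of the toolkit produces.

Coordinate conventions
----------------------
Internally every interval is **0-based, half-open** ``[start, end)``.
GFF3, GenBank and the guide CSV are 1-based inclusive on disk; BED is
0-based half-open.  All conversions happen at the parse/write boundary and
nowhere else.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from ._seq import IUPAC_DNA, is_iupac_dna

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """The file is not syntactically usable (empty, wrong format...)."""


class ValidationError(ValueError):
    """The file parsed but violates a semantic requirement."""


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence; sequences are upper-cased on ingest."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("contig id must be non-empty")
        if not self.seq:
            raise ValidationError(f"contig {self.id!r}: empty sequence")
        if not self.seq.isupper():
            object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - IUPAC_DNA
        if bad:
            raise ValidationError(
                f"contig {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class Genome:
    """An ordered collection of contigs with unique ids."""

    name: str
    contigs: list[Contig]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValidationError(f"genome {self.name!r} has no contigs")
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate contig ids: {dups}")
        self._by_id = {c.id: c for c in self.contigs}

    def __getitem__(self, contig_id: str) -> Contig:
        return self._by_id[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._by_id

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)


@dataclass(frozen=True)
class Feature:
    """A strand-aware annotation interval (internal 0-based half-open)."""

    feature_id: str
    locus_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    ftype: str
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.feature_id!r}: bad interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"feature {self.feature_id!r}: strand {self.strand!r}")
        if not self.ftype:
            raise ValidationError(f"feature {self.feature_id!r}: empty ftype")

    @property
    def length(self) -> int:
        return self.end - self.start


class AnnotationStore:
    """Features indexed by locus id, feature type and genomic interval.

    The interval index is an :class:`intervaltree.IntervalTree` per contig;
    overlap queries return exactly the features overlapping the half-open
    query interval.
    """

    def __init__(self, features: Iterable[Feature]):
        self.features: list[Feature] = list(features)
        self._by_locus: dict[str, list[Feature]] = {}
        self._by_type: dict[str, list[Feature]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features:
            self._by_locus.setdefault(f.locus_id, []).append(f)
            self._by_type.setdefault(f.ftype, []).append(f)
            self._trees.setdefault(f.contig_id, IntervalTree()).addi(f.start, f.end, f)

    def __len__(self) -> int:
        return len(self.features)

    def list_loci(self) -> list[str]:
        return sorted(self._by_locus)

    def list_feature_types(self) -> list[str]:
        return sorted(self._by_type)

    def by_locus(self, locus_id: str) -> list[Feature]:
        return sorted(
            self._by_locus.get(locus_id, []),
            key=lambda f: (f.contig_id, f.start, f.end, f.ftype),
        )

    def by_type(self, ftype: str) -> list[Feature]:
        return sorted(
            self._by_type.get(ftype, []),
            key=lambda f: (f.contig_id, f.start, f.end, f.locus_id),
        )

    def overlapping(
        self, contig_id: str, start: int, end: int, ftype: str | None = None
    ) -> list[Feature]:
        """Features overlapping [start, end) on ``contig_id``."""
        tree = self._trees.get(contig_id)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if ftype is not None:
            hits = [f for f in hits if f.ftype == ftype]
        return sorted(hits, key=lambda f: (f.start, f.end, f.ftype, f.feature_id))


def build_store(features: Iterable[Feature]) -> AnnotationStore:
    return AnnotationStore(features)


# --------------------------------------------------------------------------
# input handling

def _open_text(path: str | Path) -> io.TextIOBase:
    """Open plain, .gz, or single-member .zip files as text."""
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    if path.suffix == ".zip":
        zf = zipfile.ZipFile(path)
        names = zf.namelist()
        if len(names) != 1:
            raise FormatError(
                f"{path}: compressed archives must contain exactly one file "
                f"(found {len(names)})"
            )
        return io.TextIOWrapper(zf.open(names[0]))
    return open(path, "rt")


def parse_fasta(path: str | Path, name: str | None = None) -> Genome:
    """Parse a (possibly gzip/zip-compressed) FASTA file into a Genome.

    Contig ids are the header tokens up to the first whitespace; sequence is
    upper-cased; non-IUPAC characters or duplicate ids raise
    :class:`ValidationError`, an empty file raises :class:`FormatError`.
    """
    path = Path(path)
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    contigs = [Contig(id=r.id, seq=str(r.seq)) for r in records]
    return Genome(name=name or path.stem, contigs=contigs)


_GENBANK_SKIP_TYPES = {"source"}

# locus-id precedence when keying features; GenBank qualifiers and GFF3
# attributes are looked up in this order.
_LOCUS_KEYS = ("locus_tag", "gene", "ID", "protein_id")


def _locus_from_qualifiers(quals: dict, fallback: str) -> str:
    for key in _LOCUS_KEYS:
        if key in quals and quals[key]:
            v = quals[key]
            return v[0] if isinstance(v, (list, tuple)) else str(v)
    return fallback


def parse_genbank(path: str | Path, name: str | None = None) -> tuple[Genome, list[Feature]]:
    """Parse a GenBank flat file into a Genome plus its features.

    GenBank 1-based inclusive locations become 0-based half-open;
    ``join()`` locations are split into one Feature per span, all sharing a
    ``parent_id``.  Records without sequence are rejected with a pointer to
    the FASTA+GFF3 route.
    """
    path = Path(path)
    try:
        with _open_text(path) as fh:
            records = list(SeqIO.parse(fh, "genbank"))
    except ValueError as exc:
        raise FormatError(
            f"{path}: unparseable GenBank record ({exc}); if the file carries "
            "no ORIGIN sequence, provide the genome as FASTA plus a GFF3 "
            "annotation file instead"
        ) from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records found")

    contigs: list[Contig] = []
    features: list[Feature] = []
    counter = 0
    for rec in records:
        try:
            seq = str(rec.seq)
        except Exception:
            seq = ""
        if not seq:
            raise FormatError(
                f"{path}: record {rec.id!r} carries no sequence (no ORIGIN); "
                "provide the genome as FASTA plus a GFF3 annotation file instead"
            )
        contigs.append(Contig(id=rec.id, seq=seq))
        for feat in rec.features:
            if feat.type in _GENBANK_SKIP_TYPES:
                continue
            counter += 1
            fid = f"{feat.type}_{counter}"
            locus = _locus_from_qualifiers(feat.qualifiers, fallback=fid)
            strand = "-" if feat.location.strand == -1 else "+"
            parts = list(feat.location.parts)
            if len(parts) == 1:
                features.append(
                    Feature(
                        feature_id=fid,
                        locus_id=locus,
                        contig_id=rec.id,
                        start=int(feat.location.start),
                        end=int(feat.location.end),
                        strand=strand,
                        ftype=feat.type,
                    )
                )
            else:
                # join(): one Feature per span sharing the parent id.
                for i, part in enumerate(sorted(parts, key=lambda p: int(p.start)), 1):
                    features.append(
                        Feature(
                            feature_id=f"{fid}.part{i}",
                            locus_id=locus,
                            contig_id=rec.id,
                            start=int(part.start),
                            end=int(part.end),
                            strand=strand,
                            ftype=feat.type,
                            parent_id=fid,
                        )
                    )
    genome = Genome(name=name or path.stem, contigs=contigs)
    return genome, features


def parse_gff3(path: str | Path, genome: Genome) -> list[Feature]:
    """Parse GFF3 annotations against an already-loaded genome.

    Uses an in-memory gffutils database; column 4/5 coordinates (1-based
    inclusive) become 0-based half-open.  Features on contigs absent from
    the genome, or extending past a contig end, raise
    :class:`ValidationError` naming every offender.
    """
    path = Path(path)
    with _open_text(path) as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"{path}: empty GFF3 file")
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    bad_seqids: set[str] = set()
    out_of_range: list[str] = []
    features: list[Feature] = []
    for f in db.all_features():
        if f.seqid not in genome:
            bad_seqids.add(f.seqid)
            continue
        start, end = f.start - 1, f.end
        if end > genome[f.seqid].length or start < 0:
            out_of_range.append(f"{f.id}@{f.seqid}:{f.start}-{f.end}")
            continue
        attrs = {k: list(v) for k, v in f.attributes.items()}
        locus = _locus_from_qualifiers(attrs, fallback=f.id)
        parent = attrs.get("Parent", [None])[0]
        strand = f.strand if f.strand in ("+", "-") else "+"
        features.append(
            Feature(
                feature_id=f.id,
                locus_id=locus,
                contig_id=f.seqid,
                start=start,
                end=end,
                strand=strand,
                ftype=f.featuretype,
            parent_id=parent,
            )
        )
    if bad_seqids:
        raise ValidationError(
            "GFF3 seqids absent from genome: " + ", ".join(sorted(bad_seqids))
        )
    if out_of_range:
        raise ValidationError(
            "GFF3 features beyond contig end: " + ", ".join(out_of_range)
        )
    return features


def load_genome(
    fasta: str | Path | None = None,
    gff3: str | Path | None = None,
    genbank: str | Path | None = None,
    name: str | None = None,
) -> tuple[Genome, AnnotationStore]:
    """Load a genome from either a GenBank file or a FASTA+GFF3 pair.

    When both routes are supplied the GFF3 annotations win (GFF is the
    preferred annotation source, GenBank conversion being lossy for complex
    eukaryote structure) and a warning is logged.
    """
    if genbank is not None and fasta is None:
        genome, feats = parse_genbank(genbank, name=name)
        return genome, build_store(feats)
    if fasta is None:
        raise ValueError("provide either genbank= or fasta= (+ gff3=)")
    genome = parse_fasta(fasta, name=name)
    feats: list[Feature] = []
    if genbank is not None and gff3 is not None:
        log.warning("both GenBank and GFF3 annotations supplied; using GFF3")
    if gff3 is not None:
        feats = parse_gff3(gff3, genome)
    elif genbank is not None:
        _, feats = parse_genbank(genbank, name=name)
    return genome, build_store(feats)


# --------------------------------------------------------------------------
# writers


def write_fasta(records: Sequence, path: str | Path) -> None:
    """Write objects with ``.name`` and ``.seq`` attributes as FASTA."""
    recs = [
        SeqRecord(Seq(r.seq), id=r.name if hasattr(r, "name") else r.id, description="")
        for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_bed(features: Sequence[Feature], path: str | Path) -> None:
    """BED6: 0-based half-open, name column = feature_id."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.contig_id}\t{f.start}\t{f.end}\t{f.feature_id}\t.\t{f.strand}\n"
            )


def parse_bed(path: str | Path) -> list[Feature]:
    """Read BED back into Features (ftype 'region')."""
    feats = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            contig, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else f"{contig}:{start}-{end}"
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            feats.append(
                Feature(
                    feature_id=name,
                    locus_id=name,
                    contig_id=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    ftype="region",
                )
            )
    return feats


def write_gff3(features: Sequence[Feature], path: str | Path) -> None:
    """Normalized GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.feature_id}", f"locus_tag={f.locus_id}"]
            if f.parent_id:
                attrs.append(f"Parent={f.parent_id}")
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "grnakit",
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


GUIDE_CSV_COLUMNS = ["name", "contig", "start", "end", "strand", "spacer", "pam"]


def write_guides_csv(library, path: str | Path) -> None:
    """Guide CSV with 1-based inclusive coordinates.

    Accepts a GuideLibrary or any iterable of guide candidates.
    """
    guides = getattr(library, "guides", library)
    rows = [
        {
            "name": g.name,
            "contig": g.contig_id,
            "start": g.start + 1,
            "end": g.end,
            "strand": g.strand,
            "spacer": g.spacer,
            "pam": g.pam_observed,
        }
        for g in guides
    ]
    pd.DataFrame(rows, columns=GUIDE_CSV_COLUMNS).to_csv(path, index=False)


@dataclass(frozen=True)
class GuideRecord:
    """A guide row read back from a results CSV (internal coordinates)."""

    name: str
    contig_id: str
    start: int
    end: int
    strand: str
    spacer: str
    pam_observed: str


def read_guides_csv(path: str | Path) -> list[GuideRecord]:
    df = pd.read_csv(path, dtype={c: str for c in ("name", "contig", "strand", "spacer", "pam")})
    missing = set(GUIDE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing guide CSV columns {sorted(missing)}")
    return [
        GuideRecord(
            name=r["name"],
            contig_id=r["contig"],
            start=int(r["start"]) - 1,
            end=int(r["end"]),
            strand=r["strand"],
            spacer=r["spacer"],
            pam_observed=r["pam"],
        )
        for r in df.to_dict("records")
    ]


# --------------------------------------------------------------------------
# preprocessed store directory


def save_store(genome: Genome, store: AnnotationStore, outdir: str | Path) -> Path:
    """Serialize genome + annotations as FASTA + normalized GFF3 + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recs = [SeqRecord(Seq(c.seq), id=c.id, description="") for c in genome.contigs]
    SeqIO.write(recs, str(outdir / "genome.fa"), "fasta")
    write_gff3(store.features, outdir / "annotations.gff3")
    manifest = {
        "name": genome.name,
        "contigs": [{"id": c.id, "length": c.length} for c in genome.contigs],
        "loci": store.list_loci(),
        "feature_types": store.list_feature_types(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_store(indir: str | Path) -> tuple[Genome, AnnotationStore]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    genome = parse_fasta(indir / "genome.fa", name=manifest["name"])
    feats = parse_gff3(indir / "annotations.gff3", genome)
    return genome, build_store(feats)
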