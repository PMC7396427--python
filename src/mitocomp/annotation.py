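"""Mitogenome annotation data model and file I/O.

Coordinates follow the convention used in mitogenome annotation tables:
1-based, inclusive, on a (usually) circular chromosome.  A feature whose
``end`` is numerically smaller than its ``start`` spans the replication
origin of a circular genome and is stored as a single record.

Strands are written ``+`` / ``-``; GenBank ``complement(...)`` locations
map to ``-``.  Feature categories are the five classes relevant to a
metazoan mitogenome: protein-coding genes (PCG), tRNAs, rRNAs, the
control region, and a catch-all ``other``.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CATEGORIES = ("PCG", "tRNA", "rRNA", "control_region", "other")
STRANDS = ("+", "-")

#: canonical column order of the annotation TSV dialect
TSV_COLUMNS = ("gene", "strand", "start", "end", "category", "start_codon", "stop_codon")

_RRNA_PREFIXES = ("12s", "16s", "rrn")


class AnnotationError(ValueError):
    """Malformed annotation content or unparsable annotation input."""


def infer_category(name: str) -> str:
    """Guess a feature category from its name (used when the TSV lacks a
    category column).  ``trn*`` -> tRNA, ``12S``/``16S``/``rrn*`` -> rRNA,
    names mentioning a control region -> control_region, otherwise PCG."""
    low = name.strip().lower()
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith(_RRNA_PREFIXES):
        return "rRNA"
    if "control" in low or "d-loop" in low or re.search(r"\bcr\b", low):
        return "control_region"
    return "PCG"


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated genomic feature.

    ``end < start`` is permitted only for origin-spanning features on a
    circular genome.  Start/stop codons are stored verbatim as annotated
    (they are *not* validated against any sequence: published tables
    sometimes print strand-inconsistent triplets).
    """

    name: str
    category: str
    strand: str
    start: int
    end: int
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise AnnotationError(f"unknown category {self.category!r} for {self.name!r}")
        if self.strand not in STRANDS:
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise AnnotationError(f"coordinates are 1-based; got ({self.start}, {self.end}) for {self.name!r}")
        if (self.start_codon or self.stop_codon) and self.category != "PCG":
            raise AnnotationError(f"start/stop codons only allowed for PCGs ({self.name!r})")

    @property
    def spans_origin(self) -> bool:
        return self.end < self.start

    def span_length(self, genome_length: int, circular: bool = True) -> int:
        """Feature length in bp under 1-based inclusive coordinates."""
        if not self.spans_origin:
            return self.end - self.start + 1
        if not circular:
            raise AnnotationError(f"{self.name!r}: end < start on a linear genome")
        return genome_length - self.start + 1 + self.end

    def positions(self, genome_length: int) -> Iterator[int]:
        """Yield the 1-based genomic positions covered, 5'->3' on the
        plus strand (origin-spanning features wrap past ``genome_length``)."""
        if not self.spans_origin:
            yield from range(self.start, self.end + 1)
        else:
            yield from range(self.start, genome_length + 1)
            yield from range(1, self.end + 1)


@dataclass
class MitogenomeAnnotation:
    """An ordered set of features on one (circular) genome.

    Records are kept sorted by start coordinate; duplicate feature names
    are disambiguated by suffixing ``_2``, ``_3``, ... in start order so
    that downstream gene-order analysis sees unique labels.
    """

    genome_id: str
    genome_length: int
    records: list[AnnotationRecord] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise AnnotationError("genome_length must be positive")
        self.records = sorted(self.records, key=lambda r: (r.start, r.end))
        for rec in self.records:
            if rec.start > self.genome_length or rec.end > self.genome_length:
                raise AnnotationError(
                    f"feature {rec.name!r} ({rec.start}, {rec.end}) outside [1, {self.genome_length}]"
                )
            if rec.spans_origin and not self.circular:
                raise AnnotationError(f"origin-spanning feature {rec.name!r} on a linear genome")
        self.records = _deduplicate_names(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self.records)

    def by_category(self, category: str) -> list[AnnotationRecord]:
        return [r for r in self.records if r.category == category]

    def census(self) -> dict[str, int]:
        """Feature counts per category."""
        out: dict[str, int] = {}
        for rec in self.records:
            out[rec.category] = out.get(rec.category, 0) + 1
        return out

    def get(self, name: str) -> AnnotationRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)


def _deduplicate_names(records: Sequence[AnnotationRecord]) -> list[AnnotationRecord]:
    seen: set[str] = set()
    out: list[AnnotationRecord] = []
    for rec in records:
        name = rec.name
        if name in seen:
            n = 2
            while f"{name}_{n}" in seen:
                n += 1
                if n > len(records) + 1:
                    raise AnnotationError(f"cannot deduplicate feature name {rec.name!r}")
            name = f"{name}_{n}"
            rec = replace(rec, name=name)
        seen.add(name)
        out.append(rec)
    return out


@dataclass
class GenomeSequence:
    """A nucleotide sequence over {A,C,G,T,N} with a circularity flag."""

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.residues:
            raise AnnotationError("empty sequence")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    def fragment(self, start: int, end: int) -> str:
        """1-based inclusive subsequence; wraps the origin when end < start
        on a circular sequence."""
        n = len(self.residues)
        if not 1 <= start <= n or not 1 <= end <= n:
            raise AnnotationError(f"fragment ({start}, {end}) outside [1, {n}]")
        if end >= start:
            return self.residues[start - 1 : end]
        if not self.circular:
            raise AnnotationError("end < start on a linear sequence")
        return self.residues[start - 1 :] + self.residues[:end]

    def feature_sequence(self, record: AnnotationRecord) -> str:
        """Coding-strand sequence of a feature (reverse complement for
        minus-strand records)."""
        frag = self.fragment(record.start, record.end)
        if record.strand == "-":
            return str(Seq(frag).reverse_complement())
        return frag


# ---------------------------------------------------------------------------
# annotation TSV dialect


def _open_text(source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def read_annotation_tsv(
    source: str | Path | IO[str],
    genome_length: int,
    circular: bool = True,
    genome_id: str = "genome",
) -> MitogenomeAnnotation:
    """Read the tab-separated annotation dialect.

    Required columns: gene, strand, start, end.  Optional: category
    (inferred from the name when absent), start_codon, stop_codon.
    Coordinates are 1-based inclusive; a Unicode minus in the strand
    column is accepted and normalised to ASCII ``-``.
    """
    handle, close = _open_text(source)
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise AnnotationError("no records: empty annotation stream")
        fields = [f.strip().lower() for f in reader.fieldnames]
        for required in ("gene", "strand", "start", "end"):
            if required not in fields:
                raise AnnotationError(f"missing required column {required!r}")
        records: list[AnnotationRecord] = []
        for lineno, row in enumerate(reader, start=2):
            row = {(k or "").strip().lower(): (v or "").strip() for k, v in row.items()}
            name = row.get("gene", "")
            if not name:
                continue
            try:
                start = int(row["start"])
                end = int(row["end"])
            except (KeyError, ValueError) as exc:
                raise AnnotationError(f"line {lineno}: bad coordinates for {name!r}") from exc
            for coord in (start, end):
                if not 1 <= coord <= genome_length:
                    raise AnnotationError(
                        f"line {lineno}: coordinate {coord} outside [1, {genome_length}] for {name!r}"
                    )
            strand = row["strand"].replace("−", "-").replace("–", "-") or "+"
            category = row.get("category") or infer_category(name)
            try:
                records.append(
                    AnnotationRecord(
                        name=name,
                        category=category,
                        strand=strand,
                        start=start,
                        end=end,
                        start_codon=row.get("start_codon") or None,
                        stop_codon=row.get("stop_codon") or None,
                    )
                )
            except AnnotationError as exc:
                raise AnnotationError(f"line {lineno}: {exc}") from exc
        if not records:
            raise AnnotationError("no records")
        return MitogenomeAnnotation(
            genome_id=genome_id, genome_length=genome_length, records=records, circular=circular
        )
    finally:
        if close:
            handle.close()


def write_annotation_tsv(annotation: MitogenomeAnnotation, sink: str | Path | IO[str]) -> None:
    """Write the canonical TSV form (header + one sorted record per line)."""
    handle, close = _open_text(sink, "w")
    try:
        handle.write("\t".join(TSV_COLUMNS) + "\n")
        for rec in annotation.records:
            handle.write(
                "\t".join(
                    [
                        rec.name,
                        rec.strand,
                        str(rec.start),
                        str(rec.end),
                        rec.category,
                        rec.start_codon or "",
                        rec.stop_codon or "",
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# GenBank and FASTA

_GENBANK_TYPE_TO_CATEGORY = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control_region",
}
_CATEGORY_TO_GENBANK_TYPE = {
    "PCG": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "control_region": "D-loop",
    "other": "misc_feature",
}


def _feature_name(feat: SeqFeature, default: str) -> str:
    for key in ("gene", "product", "locus_tag", "note"):
        if key in feat.qualifiers and feat.qualifiers[key]:
            return str(feat.qualifiers[key][0])
    return default


def read_genbank(source: str | Path | IO[str]) -> tuple[GenomeSequence, MitogenomeAnnotation]:
    """Read one GenBank flat-file record into a sequence + annotation pair.

    ``complement(...)`` locations become minus-strand records; ``join(...)``
    locations across the origin become single origin-spanning records.
    """
    handle, close = _open_text(source)
    try:
        rec = SeqIO.read(handle, "genbank")
    finally:
        if close:
            handle.close()
    try:
        residues = str(rec.seq)
    except Exception as exc:  # undefined sequence content
        raise AnnotationError("GenBank record has no ORIGIN sequence") from exc
    if not residues:
        raise AnnotationError("GenBank record has no ORIGIN sequence")
    circular = rec.annotations.get("topology", "circular") == "circular"
    n = len(residues)

    records: list[AnnotationRecord] = []
    counter = 0
    for feat in rec.features:
        if feat.type not in _GENBANK_TYPE_TO_CATEGORY and feat.type != "misc_feature":
            continue
        counter += 1
        if feat.type == "misc_feature":
            name = _feature_name(feat, f"misc_{counter}")
            category = infer_category(name)
            if category == "PCG":
                category = "other"
        else:
            category = _GENBANK_TYPE_TO_CATEGORY[feat.type]
            name = _feature_name(feat, f"{feat.type}_{counter}")
        strand = "-" if feat.location.strand == -1 else "+"
        parts = feat.location.parts
        if len(parts) == 2 and int(parts[0].end) == n and int(parts[1].start) == 0:
            start, end = int(parts[0].start) + 1, int(parts[1].end)  # origin-spanning join
        else:
            start, end = int(feat.location.start) + 1, int(feat.location.end)
        if end > n or start > n:
            raise AnnotationError(f"feature {name!r} beyond sequence length {n}")
        codon_start = feat.qualifiers.get("start_codon", [None])[0]
        codon_stop = feat.qualifiers.get("stop_codon", [None])[0]
        if category != "PCG":
            codon_start = codon_stop = None
        records.append(
            AnnotationRecord(
                name=name, category=category, strand=strand, start=start, end=end,
                start_codon=codon_start, stop_codon=codon_stop,
            )
        )
    if not records:
        logger.warning("GenBank record %s has no mappable features", rec.id)
    sequence = GenomeSequence(id=rec.id or "genome", residues=residues, circular=circular)
    annotation = MitogenomeAnnotation(
        genome_id=rec.id or "genome", genome_length=n, records=records, circular=circular
    )
    return sequence, annotation


def write_genbank(
    sequence: GenomeSequence, annotation: MitogenomeAnnotation, sink: str | Path | IO[str]
) -> None:
    """Write a sequence + annotation pair as a GenBank flat file."""
    seqrec = SeqRecord(
        Seq(sequence.residues),
        id=annotation.genome_id[:16] or "genome",
        name=re.sub(r"\W", "_", annotation.genome_id)[:16] or "genome",
        description=f"{annotation.genome_id} mitochondrial genome",
    )
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular" if annotation.circular else "linear"
    n = annotation.genome_length
    for rec in annotation.records:
        strand = -1 if rec.strand == "-" else 1
        if rec.spans_origin:
            loc = CompoundLocation(
                [SimpleLocation(rec.start - 1, n, strand), SimpleLocation(0, rec.end, strand)]
            )
        else:
            loc = SimpleLocation(rec.start - 1, rec.end, strand)
        qualifiers: dict[str, list[str]] = {"gene": [rec.name]}
        if rec.start_codon:
            qualifiers["start_codon"] = [rec.start_codon]
        if rec.stop_codon:
            qualifiers["stop_codon"] = [rec.stop_codon]
        seqrec.features.append(
            SeqFeature(loc, type=_CATEGORY_TO_GENBANK_TYPE[rec.category], qualifiers=qualifiers)
        )
    handle, close = _open_text(sink, "w")
    try:
        SeqIO.write([seqrec], handle, "genbank")
    finally:
        if close:
            handle.close()


def read_fasta(source: str | Path | IO[str], circular: bool = True) -> GenomeSequence:
    handle, close = _open_text(source)
    try:
        rec = SeqIO.read(handle, "fasta")
    finally:
        if close:
            handle.close()
    return GenomeSequence(id=rec.id, residues=str(rec.seq), circular=circular)


def write_fasta(sequence: GenomeSequence, sink: str | Path | IO[str]) -> None:
    handle, close = _open_text(sink, "w")
    try:
        SeqIO.write([SeqRecord(Seq(sequence.residues), id=sequence.id, description="")], handle, "fasta")
    finally:
        if close:
            handle.close()
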