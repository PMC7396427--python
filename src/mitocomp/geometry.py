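"""Circular-genome feature geometry.

Lengths, intergenic spacers, overlaps, noncoding regions, and putative
control-region identification for an annotated (usually circular)
mitogenome.  Adjacency is defined purely by start-coordinate order around
the circle — geometry is strand-agnostic — and the spacer between two
consecutive features is ``next.start - prev.end - 1`` (negative values
are overlaps), which reproduces published "intergenic region" columns
exactly under 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .annotation import AnnotationRecord, AnnotationError, GenomeSequence, MitogenomeAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpacerRecord:
    """Signed gap between two features adjacent on the circle (bp).

    Negative ``gap`` means the two features overlap by ``-gap`` bases.
    """

    prev_name: str
    next_name: str
    gap: int


@dataclass(frozen=True)
class NoncodingRegion:
    """A maximal run of positions covered by no feature."""

    start: int
    end: int
    length: int
    flanking: tuple[str, str]


@dataclass(frozen=True)
class ControlRegionCall:
    """Result of putative control-region identification."""

    region: NoncodingRegion
    at_fraction: float | None = None
    passes_threshold: bool | None = None


def feature_length(record: AnnotationRecord, genome_length: int, circular: bool = True) -> int:
    """Length in bp of a feature under 1-based inclusive coordinates;
    ``end < start`` wraps the origin on a circular genome."""
    if record.start > genome_length or record.end > genome_length:
        raise AnnotationError(f"{record.name!r} outside [1, {genome_length}]")
    return record.span_length(genome_length, circular=circular)


def spacers(annotation: MitogenomeAnnotation) -> list[SpacerRecord]:
    """Signed gaps between consecutive features in start order.

    Circular genomes get one spacer per feature (including the wrap-around
    pair last -> first); linear genomes get one fewer.
    """
    recs = annotation.records
    if len(recs) < 2:
        raise AnnotationError("need at least 2 features to compute spacers")
    if recs != sorted(recs, key=lambda r: (r.start, r.end)):
        logger.warning("records not sorted by start; sorting internally")
        recs = sorted(recs, key=lambda r: (r.start, r.end))
    out = []
    for prev, nxt in zip(recs, recs[1:]):
        out.append(SpacerRecord(prev.name, nxt.name, nxt.start - prev.end - 1))
    if annotation.circular:
        last, first = recs[-1], recs[0]
        out.append(
            SpacerRecord(last.name, first.name, first.start + annotation.genome_length - last.end - 1)
        )
    return out


def overlaps(annotation: MitogenomeAnnotation) -> list[SpacerRecord]:
    """Adjacent-pair overlaps (spacers with gap < 0), sorted by overlap
    size descending.  Non-adjacent containment, if any, is logged as a
    warning but not counted."""
    result = sorted((s for s in spacers(annotation) if s.gap < 0), key=lambda s: s.gap)
    _warn_nonadjacent_containment(annotation)
    return result


def _covered(record: AnnotationRecord, genome_length: int) -> set[int]:
    return set(record.positions(genome_length))


def _warn_nonadjacent_containment(annotation: MitogenomeAnnotation) -> None:
    recs = annotation.records
    for i, a in enumerate(recs):
        for b in recs[i + 2 :]:  # skip adjacent pair; crude but n is ~40
            if b is recs[-1] and a is recs[0]:
                continue
            ia = _covered(a, annotation.genome_length)
            ib = _covered(b, annotation.genome_length)
            if ia & ib:
                logger.warning("non-adjacent features %s and %s intersect", a.name, b.name)


def _wrap(pos: int, genome_length: int) -> int:
    return (pos - 1) % genome_length + 1


def noncoding_regions(
    annotation: MitogenomeAnnotation, include_cr_feature: bool = True
) -> list[NoncodingRegion]:
    """Positive spacers as noncoding regions.

    With ``include_cr_feature=False`` annotated control-region features are
    themselves treated as noncoding: they are removed before spacers are
    recomputed, which merges each with its flanking gaps into one region
    (published counts of "noncoding regions" often use this convention).
    """
    if include_cr_feature:
        ann = annotation
    else:
        kept = [r for r in annotation.records if r.category != "control_region"]
        if not kept:
            raise AnnotationError("annotation contains only control-region features")
        ann = MitogenomeAnnotation(
            genome_id=annotation.genome_id,
            genome_length=annotation.genome_length,
            records=kept,
            circular=annotation.circular,
        )
    regions = []
    for sp in spacers(ann):
        if sp.gap <= 0:
            continue
        prev = ann.get(sp.prev_name)
        nxt = ann.get(sp.next_name)
        regions.append(
            NoncodingRegion(
                start=_wrap(prev.end + 1, ann.genome_length),
                end=_wrap(nxt.start - 1 if nxt.start > 1 else ann.genome_length, ann.genome_length),
                length=sp.gap,
                flanking=(sp.prev_name, sp.next_name),
            )
        )
    return regions


def identify_control_region(
    annotation: MitogenomeAnnotation,
    sequence: GenomeSequence | None = None,
    at_threshold: float = 0.60,
) -> ControlRegionCall:
    """Longest noncoding region as the putative control region.

    Control-region features already annotated are treated as noncoding for
    this purpose.  When a sequence is supplied the region's A+T fraction is
    reported and checked against ``at_threshold`` (default 0.60); a
    candidate below threshold is still returned, with a warning.
    Ties are broken toward the lower start coordinate.
    """
    regions = noncoding_regions(annotation, include_cr_feature=False)
    if not regions:
        raise AnnotationError("no noncoding region: features tile the whole genome")
    best = max(regions, key=lambda r: (r.length, -r.start))
    if sequence is None:
        return ControlRegionCall(region=best)
    frag = sequence.fragment(best.start, best.end)
    at = sum(frag.count(b) for b in "AT") / len(frag)
    ok = at >= at_threshold
    if not ok:
        logger.warning(
            "best noncoding candidate (%d-%d) has AT fraction %.3f below threshold %.2f",
            best.start, best.end, at, at_threshold,
        )
    return ControlRegionCall(region=best, at_fraction=at, passes_threshold=ok)


def geometry_report(annotation: MitogenomeAnnotation) -> pd.DataFrame:
    """Per-feature table: size and intergenic spacer to the next feature
    (mirrors the layout of published mitogenome annotation tables)."""
    gap_after = {s.prev_name: s.gap for s in spacers(annotation)}
    rows = []
    for rec in annotation.records:
        rows.append(
            {
                "gene": rec.name,
                "strand": rec.strand,
                "start": rec.start,
                "end": rec.end,
                "size_bp": feature_length(rec, annotation.genome_length, annotation.circular),
                "category": rec.category,
                "start_codon": rec.start_codon or "",
                "stop_codon": rec.stop_codon or "",
                "intergenic": gap_after.get(rec.name, pd.NA),
            }
        )
    return pd.DataFrame(rows)
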