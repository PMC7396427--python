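"""Base composition, strand skews, codon counting, RSCU and amino-acid
usage under explicit genetic codes.

Two conventions matter throughout and are kept explicit:

* **Skews** are the classic strand-asymmetry statistics,
  GC-skew = (G - C)/(G + C) and AT-skew = (A - T)/(A + T).  They are
  invariant under common scaling, so printed percentages are valid inputs.

* **Genetic codes** play two separable roles.  The *label code* assigns
  each codon its amino acid (what a published codon table prints in
  parentheses); the *family code* defines the synonymous families that
  form RSCU denominators.  Published mitogenome codon tables sometimes mix
  the two — e.g. labelling AGA/AGG as serine (invertebrate mitochondrial
  code) while computing RSCU within standard-code families — so every
  operation takes the code it needs as an argument.  Codes are built from
  the NCBI translation tables (via Biopython) or user-supplied mappings.

Stop codons are counted, carry their own synonymous family ('*') in RSCU,
and stay in the denominator of amino-acid usage percentages (reported as
their own row).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .annotation import AnnotationError, GenomeSequence, MitogenomeAnnotation

logger = logging.getLogger(__name__)

BASES = "TCAG"  # classic codon-table order: TTT ... GGG
#: the 64 DNA codons in canonical (TTT..GGG) order
CODONS: tuple[str, ...] = tuple("".join(c) for c in itertools.product(BASES, repeat=3))

STOP = "*"


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.425 -> 0.43 at 2 digits), the convention
    of most published tables, unlike Python's banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def dna_to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def rna_to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# base composition and skews


@dataclass(frozen=True)
class BaseComposition:
    """Counts of A/C/G/T plus anything else (``other``, excluded from
    percentages)."""

    counts: Mapping[str, int]
    other: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percent(self, base: str) -> float:
        return 100.0 * self.counts[base] / self.total

    @property
    def at_percent(self) -> float:
        return self.percent("A") + self.percent("T")

    @property
    def gc_percent(self) -> float:
        return self.percent("G") + self.percent("C")


@dataclass(frozen=True)
class SkewPair:
    """GC- and AT-skew; ``None`` when a denominator is zero."""

    gc_skew: float | None
    at_skew: float | None


def base_composition(residues: str) -> BaseComposition:
    """Tally A/C/G/T in a sequence; other characters are counted apart and
    excluded from percentages."""
    if not residues:
        raise AnnotationError("empty sequence")
    up = residues.upper()
    counts = {b: up.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise AnnotationError("sequence contains no A/C/G/T")
    return BaseComposition(counts=counts, other=len(up) - total)


def skew(x: float, y: float) -> float:
    """(x - y)/(x + y); the GC-skew for (G, C), the AT-skew for (A, T).

    Scale-invariant, so counts and percentages give the same value.
    """
    if x < 0 or y < 0:
        raise ValueError("skew inputs must be non-negative")
    if x + y == 0:
        raise ZeroDivisionError("skew undefined: x + y = 0")
    return (x - y) / (x + y)


def skew_pair(comp: BaseComposition) -> SkewPair:
    def safe(a: str, b: str) -> float | None:
        try:
            return skew(comp.counts[a], comp.counts[b])
        except ZeroDivisionError:
            return None

    return SkewPair(gc_skew=safe("G", "C"), at_skew=safe("A", "T"))


def composition_report(
    sequence: GenomeSequence, annotation: MitogenomeAnnotation, decimals: bool = True
) -> pd.DataFrame:
    """Per-feature base composition and skews, plus aggregate rows.

    Minus-strand features are reported on their coding strand (reverse
    complement).  Aggregates: ``PCGs`` (all protein-coding sequences
    concatenated, coding strand), ``CRs`` (control regions concatenated),
    and ``genome`` (the whole plus strand).  Percentages are rounded
    half-up to 2 decimals and skews to 3 unless ``decimals=False``.
    """
    if len(sequence) != annotation.genome_length:
        raise AnnotationError("sequence length does not match annotation genome_length")

    def row(name: str, category: str, strand: str, seq: str) -> dict:
        comp = base_composition(seq)
        sk = skew_pair(comp)
        fmt2 = (lambda v: round_half_up(v, 2)) if decimals else (lambda v: v)
        fmt3 = (lambda v: None if v is None else round_half_up(v, 3)) if decimals else (lambda v: v)
        return {
            "name": name,
            "category": category,
            "strand": strand,
            "length_bp": len(seq),
            "T_pct": fmt2(comp.percent("T")),
            "C_pct": fmt2(comp.percent("C")),
            "A_pct": fmt2(comp.percent("A")),
            "G_pct": fmt2(comp.percent("G")),
            "AT_pct": fmt2(comp.at_percent),
            "GC_pct": fmt2(comp.gc_percent),
            "gc_skew": fmt3(sk.gc_skew),
            "at_skew": fmt3(sk.at_skew),
        }

    rows = []
    pcg_parts: list[str] = []
    cr_parts: list[str] = []
    for rec in annotation.records:
        seq = sequence.feature_sequence(rec)
        if rec.category == "PCG":
            pcg_parts.append(seq)
        if rec.category == "control_region":
            cr_parts.append(seq)
        rows.append(row(rec.name, rec.category, rec.strand, seq))
    if pcg_parts:
        rows.append(row("PCGs", "aggregate", "+", "".join(pcg_parts)))
    if cr_parts:
        rows.append(row("CRs", "aggregate", "+", "".join(cr_parts)))
    rows.append(row("genome", "aggregate", "+", sequence.residues))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genetic codes


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map plus the synonymous-family partition it
    induces (codons sharing one letter form one family; stops form the
    '*' family)."""

    name: str
    aa_of_codon: Mapping[str, str]
    starts: frozenset[str] = frozenset({"ATG"})

    def __post_init__(self) -> None:
        missing = set(CODONS) - set(self.aa_of_codon)
        if missing:
            raise ValueError(f"genetic code {self.name!r} missing codons: {sorted(missing)[:3]}...")

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        """Amino-acid letter -> tuple of member codons (canonical order)."""
        fams: dict[str, list[str]] = {}
        for codon in CODONS:
            fams.setdefault(self.aa_of_codon[codon], []).append(codon)
        return {aa: tuple(cods) for aa, cods in fams.items()}

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.aa_of_codon[rna_to_dna(codon)]]


_NCBI_IDS = {
    "standard": 1,
    "invertebrate_mito": 5,
    "echinoderm_mito": 9,
}


@lru_cache(maxsize=None)
def _from_ncbi(table_id: int) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = {c: table.forward_table.get(c, STOP) for c in CODONS}
    name = {v: k for k, v in _NCBI_IDS.items()}.get(table_id, f"ncbi_{table_id}")
    return GeneticCode(name=name, aa_of_codon=mapping, starts=frozenset(table.start_codons))


def get_genetic_code(code: "str | int | GeneticCode") -> GeneticCode:
    """Resolve a code by name ('standard', 'invertebrate_mito',
    'echinoderm_mito'), NCBI translation-table number, or pass through a
    ready GeneticCode (e.g. a user-defined one built from a mapping)."""
    if isinstance(code, GeneticCode):
        return code
    if isinstance(code, int) or (isinstance(code, str) and code.isdigit()):
        return _from_ncbi(int(code))
    key = str(code).strip().lower().replace(" ", "_").replace("-", "_")
    aliases = {
        "invertebrate_mitochondrial": "invertebrate_mito",
        "echinoderm_mitochondrial": "echinoderm_mito",
    }
    key = aliases.get(key, key)
    if key not in _NCBI_IDS:
        raise ValueError(f"unknown genetic code {code!r}")
    return _from_ncbi(_NCBI_IDS[key])


def custom_genetic_code(
    name: str, aa_of_codon: Mapping[str, str], starts: Iterable[str] = ("ATG",)
) -> GeneticCode:
    """Build a user-defined code; codons may be given in RNA or DNA
    alphabet."""
    mapping = {rna_to_dna(c): aa for c, aa in aa_of_codon.items()}
    return GeneticCode(name=name, aa_of_codon=mapping, starts=frozenset(rna_to_dna(s) for s in starts))


# ---------------------------------------------------------------------------
# codon counting, RSCU, amino-acid usage


@dataclass(frozen=True)
class CodonCountTable:
    """Counts for all 64 DNA codons, keyed in canonical TTT..GGG order."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        filled = {c: int(self.counts.get(c, 0)) for c in CODONS}
        if any(v < 0 for v in filled.values()):
            raise ValueError("negative codon count")
        extra = set(self.counts) - set(CODONS)
        if extra:
            raise ValueError(f"non-canonical codon keys: {sorted(extra)[:3]}")
        object.__setattr__(self, "counts", filled)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts[rna_to_dna(codon)]


def count_codons(cds_list: Iterable[str]) -> CodonCountTable:
    """Frame-0 codon tally across a set of in-frame coding sequences.

    Trailing 1-2 bases of a sequence whose length is not a multiple of 3
    are dropped with a warning; codons containing ambiguous characters
    are skipped with a warning.
    """
    counts = {c: 0 for c in CODONS}
    skipped = 0
    for i, cds in enumerate(cds_list):
        seq = rna_to_dna(cds)
        if len(seq) % 3:
            logger.warning("CDS %d length %d not divisible by 3; dropping tail", i, len(seq))
        for j in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[j : j + 3]
            if codon in counts:
                counts[codon] += 1
            else:
                skipped += 1
    if skipped:
        logger.warning("skipped %d codons with ambiguous bases", skipped)
    return CodonCountTable(counts=counts)


def rscu(counts: CodonCountTable, code: "str | int | GeneticCode") -> dict[str, float]:
    """Relative synonymous codon usage under the given *family* code.

    RSCU(c) = count(c) * s / n_F for codon c in a synonymous family F of
    size s with total count n_F; every codon of a family with n_F = 0 gets
    0 by convention.  Keys are DNA codons in canonical order.
    """
    gc = get_genetic_code(code)
    out: dict[str, float] = {}
    for family in gc.families.values():
        n_f = sum(counts[c] for c in family)
        s = len(family)
        for c in family:
            out[c] = counts[c] * s / n_f if n_f else 0.0
    return {c: out[c] for c in CODONS}


def aa_usage(counts: CodonCountTable, code: "str | int | GeneticCode") -> dict[str, float]:
    """Amino-acid usage percentages under the given *label* code.

    Stops are their own row ('*') and remain in the denominator (the total
    codon count), matching how published codon tables report frequencies.
    """
    if counts.total == 0:
        raise ValueError("empty codon count table")
    gc = get_genetic_code(code)
    out: dict[str, float] = {}
    for aa, family in gc.families.items():
        out[aa] = 100.0 * sum(counts[c] for c in family) / counts.total
    return out


def rscu_report(
    counts: CodonCountTable,
    label_code: "str | int | GeneticCode" = "invertebrate_mito",
    family_code: "str | int | GeneticCode" = "standard",
) -> pd.DataFrame:
    """Codon table in display form: RNA-alphabet codons, amino-acid label
    under the label code, count, RSCU (2 decimals, half-up) under the
    family code."""
    lab = get_genetic_code(label_code)
    values = rscu(counts, family_code)
    rows = [
        {
            "codon": dna_to_rna(c),
            "aa": lab.aa_of_codon[c],
            "count": counts[c],
            "rscu": round_half_up(values[c], 2),
        }
        for c in CODONS
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CDS extraction


def extract_cds(sequence: GenomeSequence, annotation: MitogenomeAnnotation) -> dict[str, str]:
    """Coding-strand sequence of every protein-coding gene, in annotation
    order.  Minus-strand genes are reverse-complemented; origin-spanning
    genes are concatenated across the origin."""
    out: dict[str, str] = {}
    for rec in annotation.by_category("PCG"):
        seq = sequence.feature_sequence(rec)
        if len(seq) % 3:
            logger.warning("PCG %s length %d not divisible by 3", rec.name, len(seq))
        out[rec.name] = seq
    return out
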