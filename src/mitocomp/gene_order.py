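"""Signed circular gene orders and their comparison.

A mitochondrial gene order is modelled as a signed circular permutation:
each of the 37 canonical genes carries an orientation (+/-), and the
molecule has no canonical strand or origin, so two orders are compared
under rotation *and* full reflection-with-sign-flip equivalence.

Comparison is by shared signed adjacencies: genes x, y are
adjacent-conserved between orders a and b when the signed pair (x, y) —
or its reading from the other strand, (-y, -x) — is adjacent in both.
Maximal chains of conserved adjacencies are the conserved blocks;
adjacencies of a absent from b are breakpoints.  Rearrangement *events*
(inversion, transposition, reverse transposition, tandem
duplication-random loss) are applied as forward simulations; differences
between two arbitrary orders are reported descriptively as blocks +
singletons, not as a minimal event scenario.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .annotation import MitogenomeAnnotation

logger = logging.getLogger(__name__)


class GeneOrderError(ValueError):
    """Invalid gene-order input (unknown labels, mismatched gene sets...)."""


#: one-letter tRNA symbols, with the serine/leucine isoacceptors split by
#: codon family: S1 (AGN), S2 (UCN), L1 (CUN), L2 (UUR)
TRNA_LABELS = ("A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
               "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y")

#: the canonical 37-gene metazoan mitochondrial alphabet
CANONICAL_GENES = frozenset(
    ("cox1", "cox2", "cox3", "cob", "nad1", "nad2", "nad3", "nad4", "nad4L",
     "nad5", "nad6", "atp6", "atp8", "rrnS", "rrnL") + TRNA_LABELS
)

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "lys": "K", "met": "M",
    "phe": "F", "pro": "P", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

#: synonym table for free-text gene names -> canonical labels
DEFAULT_NAME_MAP: dict[str, str] = {
    "cytb": "cob", "cob": "cob", "cytochrome b": "cob",
    "12s": "rrnS", "rrn12": "rrnS", "rrns": "rrnS", "12s rrna": "rrnS", "srrna": "rrnS",
    "16s": "rrnL", "rrn16": "rrnL", "rrnl": "rrnL", "16s rrna": "rrnL", "lrrna": "rrnL",
    "trna-ser(tga)": "S2", "trna-ser(ucn)": "S2", "trns2": "S2", "s2": "S2",
    "trna-ser(gct)": "S1", "trna-ser(agn)": "S1", "trns1": "S1", "s1": "S1",
    "trna-leu(tag)": "L1", "trna-leu(cun)": "L1", "trnl1": "L1", "l1": "L1",
    "trna-leu(taa)": "L2", "trna-leu(uur)": "L2", "trnl2": "L2", "l2": "L2",
    "nad4l": "nad4L",
}
for _aa3, _aa1 in _AA3_TO_1.items():
    DEFAULT_NAME_MAP[f"trna-{_aa3}"] = _aa1
    DEFAULT_NAME_MAP[f"trn{_aa1.lower()}"] = _aa1
for _g in ("cox1", "cox2", "cox3", "nad1", "nad2", "nad3", "nad4", "nad5",
           "nad6", "atp6", "atp8"):
    DEFAULT_NAME_MAP[_g] = _g
for _t in TRNA_LABELS:
    DEFAULT_NAME_MAP[_t.lower()] = _t


def normalize_label(name: str, name_map: Mapping[str, str] | None = None) -> str:
    """Map a free-text gene name to its canonical label; raises
    GeneOrderError naming the offender when unmapped."""
    table = DEFAULT_NAME_MAP if name_map is None else {**DEFAULT_NAME_MAP, **name_map}
    key = name.strip().lower()
    if key in table:
        return table[key]
    raise GeneOrderError(f"cannot normalize gene name {name!r} to a canonical label")


@dataclass(frozen=True)
class SignedGene:
    label: str
    orientation: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.orientation not in (1, -1):
            raise GeneOrderError(f"orientation must be +1/-1, got {self.orientation}")

    def flipped(self) -> "SignedGene":
        return SignedGene(self.label, -self.orientation)

    def __str__(self) -> str:
        return self.label if self.orientation == 1 else f"-{self.label}"


@dataclass(frozen=True)
class SignedGeneOrder:
    """A circular ordered list of (label, orientation) with unique labels."""

    genome_id: str
    elements: tuple[SignedGene, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.elements]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise GeneOrderError(f"duplicate labels in gene order: {dup}")
        if not self.elements:
            raise GeneOrderError("empty gene order")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(e.label for e in self.elements)

    def index_of(self, label: str) -> int:
        for i, e in enumerate(self.elements):
            if e.label == label:
                return i
        raise KeyError(label)

    def rotated_to(self, label: str) -> "SignedGeneOrder":
        i = self.index_of(label)
        return SignedGeneOrder(self.genome_id, self.elements[i:] + self.elements[:i])

    def reflected(self) -> "SignedGeneOrder":
        """The same molecule read from the other strand."""
        return SignedGeneOrder(
            self.genome_id, tuple(e.flipped() for e in reversed(self.elements))
        )

    def equivalent(self, other: "SignedGeneOrder") -> bool:
        """Equality as circular molecules (under rotation and reflection)."""
        if self.labels != other.labels or len(self) != len(other):
            return False
        for cand in (other, other.reflected()):
            rot = cand.rotated_to(self.elements[0].label)
            if rot.elements == self.elements:
                return True
        return False

    @classmethod
    def from_labels(cls, genome_id: str, items: Iterable[str]) -> "SignedGeneOrder":
        """Build from strings like ``["cox1", "-S2", "nad3"]``."""
        elems = []
        for item in items:
            item = item.strip()
            if item.startswith("-"):
                elems.append(SignedGene(item[1:], -1))
            else:
                elems.append(SignedGene(item, 1))
        return cls(genome_id, tuple(elems))


def order_from_annotation(
    annotation: MitogenomeAnnotation,
    name_map: Mapping[str, str] | None = None,
    require_canonical: bool = True,
) -> SignedGeneOrder:
    """Gene order by start coordinate, orientation by strand; control
    regions are excluded (they are not genes)."""
    elems = []
    for rec in annotation.records:
        if rec.category == "control_region":
            continue
        label = normalize_label(rec.name, name_map)
        if require_canonical and label not in CANONICAL_GENES:
            raise GeneOrderError(f"label {label!r} not in the canonical 37-gene alphabet")
        elems.append(SignedGene(label, -1 if rec.strand == "-" else 1))
    return SignedGeneOrder(annotation.genome_id, tuple(elems))


# ---------------------------------------------------------------------------
# block decomposition and breakpoints


@dataclass(frozen=True)
class Block:
    """A maximal conserved run, listed in a's order with a's signs;
    ``orientation`` is +1 when b carries it forward, -1 when reversed."""

    genes: tuple[SignedGene, ...]
    orientation: int

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.genes)


@dataclass(frozen=True)
class BlockDecomposition:
    blocks: tuple[Block, ...]
    singletons: tuple[str, ...]
    n_breakpoints: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def _restrict(a: SignedGeneOrder, shared: frozenset[str]) -> SignedGeneOrder:
    return SignedGeneOrder(a.genome_id, tuple(e for e in a.elements if e.label in shared))


def _adjacency_set(order: SignedGeneOrder) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    out = set()
    n = len(order)
    for i in range(n):
        x, y = order.elements[i], order.elements[(i + 1) % n]
        out.add(((x.label, x.orientation), (y.label, y.orientation)))
        out.add(((y.label, -y.orientation), (x.label, -x.orientation)))
    return out


def _shared_orders(
    a: SignedGeneOrder, b: SignedGeneOrder, strict: bool
) -> tuple[SignedGeneOrder, SignedGeneOrder]:
    if a.labels != b.labels:
        if strict:
            missing = sorted(a.labels ^ b.labels)
            raise GeneOrderError(f"gene sets differ: {missing}")
        shared = a.labels & b.labels
        if not shared:
            raise GeneOrderError("gene orders share no labels")
        logger.warning("gene sets differ; restricting to %d shared labels", len(shared))
        a, b = _restrict(a, shared), _restrict(b, shared)
    return a, b


def _conserved_flags(a: SignedGeneOrder, b: SignedGeneOrder) -> list[bool]:
    """conserved[i]: is the adjacency a[i] -> a[i+1] present in b?"""
    bset = _adjacency_set(b)
    n = len(a)
    flags = []
    for i in range(n):
        x, y = a.elements[i], a.elements[(i + 1) % n]
        flags.append(((x.label, x.orientation), (y.label, y.orientation)) in bset)
    return flags


def _relative_orientation(genes: Sequence[SignedGene], b: SignedGeneOrder) -> int:
    b_ori = {e.label: e.orientation for e in b.elements}
    g = genes[0]
    return 1 if b_ori[g.label] == g.orientation else -1


def conserved_blocks(
    a: SignedGeneOrder, b: SignedGeneOrder, strict: bool = False
) -> BlockDecomposition:
    """Maximal conserved-block decomposition of two signed circular orders.

    Blocks are maximal chains of shared signed adjacencies on the circle;
    a run reversed-and-flipped in b is still one block, with relative
    orientation -1.  Size-1 runs are reported as singletons.  When the
    label sets differ the comparison restricts to their intersection
    (``strict=True`` raises instead).  Blocks are listed in a's circular
    order starting from the run containing cox1 when present.
    """
    a, b = _shared_orders(a, b, strict)
    n = len(a)
    if n == 1:
        return BlockDecomposition(
            blocks=(Block(genes=a.elements, orientation=_relative_orientation(a.elements, b)),),
            singletons=(), n_breakpoints=0,
        )
    flags = _conserved_flags(a, b)
    n_break = flags.count(False)
    if n_break == 0:
        start = a.index_of("cox1") if "cox1" in a.labels else 0
        genes = a.elements[start:] + a.elements[:start]
        return BlockDecomposition(
            blocks=(Block(genes=genes, orientation=_relative_orientation(genes, b)),),
            singletons=(), n_breakpoints=0,
        )
    # cut the circle after every non-conserved adjacency
    cuts = [i for i, ok in enumerate(flags) if not ok]  # break between i and i+1
    runs: list[tuple[SignedGene, ...]] = []
    for k, cut in enumerate(cuts):
        start = (cut + 1) % n
        end = cuts[(k + 1) % len(cuts)]  # inclusive index of run end
        idx = []
        j = start
        while True:
            idx.append(j)
            if j == end:
                break
            j = (j + 1) % n
        runs.append(tuple(a.elements[j] for j in idx))
    # report starting from the run containing cox1 (or a's first element)
    anchor = "cox1" if "cox1" in a.labels else a.elements[0].label
    for k, run in enumerate(runs):
        if any(g.label == anchor for g in run):
            runs = runs[k:] + runs[:k]
            break
    blocks = tuple(
        Block(genes=run, orientation=_relative_orientation(run, b))
        for run in runs if len(run) >= 2
    )
    singletons = tuple(run[0].label for run in runs if len(run) == 1)
    return BlockDecomposition(blocks=blocks, singletons=singletons, n_breakpoints=n_break)


def breakpoint_distance(a: SignedGeneOrder, b: SignedGeneOrder, strict: bool = False) -> int:
    """Number of signed circular adjacencies of a not conserved in b
    (symmetric for equal gene sets)."""
    a, b = _shared_orders(a, b, strict)
    if len(a) == 1:
        return 0
    return _conserved_flags(a, b).count(False)


# ---------------------------------------------------------------------------
# rearrangement events


EVENT_KINDS = ("inversion", "transposition", "reverse_transposition", "tdrl")


@dataclass
class RearrangementEvent:
    """One rearrangement: ``span`` is a run of labels contiguous in the
    pre-event order; ``params`` holds event-specific positions
    (``insert_after`` for the transpositions, ``keep`` for a TDRL's
    per-gene copy choices)."""

    kind: str
    span: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise GeneOrderError(f"unknown event kind {self.kind!r}")
        if not self.span:
            raise GeneOrderError("event span is empty")


def _locate_span(order: SignedGeneOrder, span: Sequence[str]) -> list[SignedGene]:
    """Return order's elements rotated so the span sits at the front;
    verifies the span is contiguous (circularly) in the given order."""
    n = len(order)
    if len(span) > n:
        raise GeneOrderError("event span longer than the genome")
    start = order.index_of(span[0])
    rotated = list(order.elements[start:] + order.elements[:start])
    for k, label in enumerate(span):
        if rotated[k].label != label:
            raise GeneOrderError(f"span {tuple(span)} not contiguous in {order.genome_id}")
    return rotated


def apply_event(
    order: SignedGeneOrder,
    event: RearrangementEvent,
    rng: np.random.Generator | int | None = None,
) -> SignedGeneOrder:
    """Apply one rearrangement event to a signed circular order.

    * inversion: reverse the span in place and flip orientations;
    * transposition: excise the span and reinsert it after the gene named
      by ``params['insert_after']``;
    * reverse_transposition: transposition plus reversal-and-flip;
    * tdrl: duplicate the span in tandem, then delete one copy of each
      duplicated gene — the surviving copy per gene comes from
      ``params['keep']`` (0 = first copy, 1 = second) or is drawn from
      ``rng`` and recorded back into the event for the log.

    The label set is preserved by every event kind.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    rotated = _locate_span(order, event.span)
    m = len(event.span)
    segment, rest = rotated[:m], rotated[m:]

    if event.kind == "inversion":
        new = [g.flipped() for g in reversed(segment)] + rest
    elif event.kind in ("transposition", "reverse_transposition"):
        target = event.params.get("insert_after")
        if target is None or target in event.span:
            raise GeneOrderError("transposition needs params['insert_after'] outside the span")
        if event.kind == "reverse_transposition":
            segment = [g.flipped() for g in reversed(segment)]
        pos = next(i for i, g in enumerate(rest) if g.label == target)
        new = rest[: pos + 1] + segment + rest[pos + 1 :]
    else:  # tdrl
        keep = event.params.get("keep")
        if keep is None:
            if rng is None:
                raise GeneOrderError("TDRL needs an rng (or pre-drawn params['keep'])")
            keep = tuple(int(k) for k in rng.integers(0, 2, size=m))
            event.params["keep"] = keep
        if len(keep) != m:
            raise GeneOrderError("TDRL keep mask length must equal span length")
        first = [g for g, k in zip(segment, keep) if k == 0]
        second = [g for g, k in zip(segment, keep) if k == 1]
        new = first + second + rest
    # restore the original starting element where possible (cosmetic:
    # circular orders are rotation-equivalent)
    result = SignedGeneOrder(order.genome_id, tuple(new))
    head = order.elements[0].label
    return result.rotated_to(head)


def random_event(
    order: SignedGeneOrder,
    kind: str,
    rng: np.random.Generator,
    max_span: int = 6,
) -> RearrangementEvent:
    """Draw a random event of the given kind with a contiguous random span
    (length 1..max_span, capped so transpositions keep an insertion site)."""
    n = len(order)
    top = min(max_span, n - 1)
    m = int(rng.integers(1, top + 1))
    start = int(rng.integers(0, n))
    span = tuple(order.elements[(start + k) % n].label for k in range(m))
    params: dict = {}
    if kind in ("transposition", "reverse_transposition"):
        outside = [e.label for e in order.elements if e.label not in span]
        params["insert_after"] = str(rng.choice(outside))
    return RearrangementEvent(kind=kind, span=span, params=params)


# ---------------------------------------------------------------------------
# rendering and text I/O


def render_linear(order: SignedGeneOrder, start_label: str = "cox1") -> str:
    """One-line linearisation starting at ``start_label``:
    hyphen-separated labels, minus-orientation genes in brackets."""
    rot = order.rotated_to(start_label)
    return "-".join(g.label if g.orientation == 1 else f"[{g.label}]" for g in rot.elements)


def parse_linear(text: str, genome_id: str = "genome") -> SignedGeneOrder:
    """Inverse of :func:`render_linear`."""
    elems = []
    for token in text.strip().split("-"):
        m = re.fullmatch(r"\[(.+)\]", token)
        if m:
            elems.append(SignedGene(m.group(1), -1))
        else:
            elems.append(SignedGene(token, 1))
    return SignedGeneOrder(genome_id, tuple(elems))


def read_orders(source: "str | Path | IO[str]") -> list[SignedGeneOrder]:
    """Read the gene-order text format: one genome per line,
    ``id: g1 -g2 g3 ...``."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    orders = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise GeneOrderError(f"bad gene-order line (missing 'id:'): {line!r}")
        gid, rest = line.split(":", 1)
        orders.append(SignedGeneOrder.from_labels(gid.strip(), rest.split()))
    if not orders:
        raise GeneOrderError("no gene orders in input")
    return orders


def write_orders(orders: Iterable[SignedGeneOrder], sink: "str | Path | IO[str]") -> None:
    lines = [f"{o.genome_id}: " + " ".join(str(g) for g in o.elements) for o in orders]
    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)
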