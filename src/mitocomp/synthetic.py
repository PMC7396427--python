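"""Synthetic mitogenomes with known ground truth.

The generator emulates the structure of a ~16 kb circular metazoan
mitogenome: 37 named features plus a control region on two strands
(by default the focal annotation geometry shipped with the package),
controllable base composition, an AT-enriched control region, planted
in-frame coding sequences drawn from a controllable codon distribution,
and gene orders perturbed by seeded rearrangement events.  Every
stochastic choice flows from the single integer seed of the spec, in
fixed order, so outputs are reproducible byte for byte.

It does *not* attempt realistic molecular evolution — no substitution
model, no rate heterogeneity, no codon autocorrelation: planted CDS are
i.i.d. codon draws.  Its purpose is ground truth for pipeline testing,
not biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .annotation import AnnotationError, GenomeSequence, MitogenomeAnnotation
from .gene_order import (
    EVENT_KINDS,
    RearrangementEvent,
    SignedGeneOrder,
    apply_event,
    random_event,
)
from .seqstats import CODONS, get_genetic_code

# focal whole-genome base fractions, renormalised (the printed percents
# sum to 99.99)
_PRINTED = {"T": 0.2955, "C": 0.2216, "A": 0.3564, "G": 0.1264}
DEFAULT_COMPOSITION = {b: v / sum(_PRINTED.values()) for b, v in _PRINTED.items()}


@dataclass
class SynthSpec:
    """Parameters of one synthetic genome / order pair.

    Defaults mirror the focal genome: its length, annotation geometry and
    whole-genome base composition.  ``codon_bias`` defaults to the
    per-position product of ``target_composition`` (so planted coding
    sequence does not distort genome-wide composition);
    ``cr_at_boost`` adds that many AT-fraction points inside control
    regions.  The seed is mandatory — there is no wall-clock fallback.
    """

    seed: int
    genome_length: int = 15969
    target_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    annotation_template: "MitogenomeAnnotation | str" = "focal"
    codon_bias: Mapping[str, float] | None = None
    cr_at_boost: float = 0.10
    start_codon: str = "ATG"
    stop_codon: str = "TAA"
    genetic_code: str = "echinoderm_mito"
    n_events: int = 2
    event_mix: Mapping[str, float] = field(
        default_factory=lambda: {k: 0.25 for k in EVENT_KINDS}
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SynthSpec.seed is mandatory")
        if abs(sum(self.target_composition.values()) - 1.0) > 1e-9:
            raise ValueError("target_composition must sum to 1")
        if abs(sum(self.event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("event_mix must sum to 1")
        code = get_genetic_code(self.genetic_code)
        if self.start_codon not in code.starts:
            raise ValueError(
                f"start codon {self.start_codon!r} not permitted under {code.name}"
            )

    def resolve_template(self) -> MitogenomeAnnotation:
        if isinstance(self.annotation_template, MitogenomeAnnotation):
            template = self.annotation_template
        elif self.annotation_template == "focal":
            from .datasets import load_focal_annotation

            template = load_focal_annotation()
        else:
            raise ValueError(f"unknown annotation template {self.annotation_template!r}")
        if template.genome_length > self.genome_length:
            raise AnnotationError("template geometry does not fit genome_length")
        return template


@dataclass
class SyntheticGenome:
    """A generated genome plus its ground truth: the annotation it was
    built from, the final planted CDS per gene (post overlap
    resolution), and the AT fraction targeted inside control regions."""

    sequence: GenomeSequence
    annotation: MitogenomeAnnotation
    cds: dict[str, str]
    cr_at_target: float


def _boosted_at(composition: Mapping[str, float], boost: float) -> dict[str, float]:
    at = composition["A"] + composition["T"]
    gc = composition["G"] + composition["C"]
    at_new = min(at + boost, 0.98)
    out = {}
    for b in "AT":
        out[b] = composition[b] * at_new / at
    for b in "GC":
        out[b] = composition[b] * (1 - at_new) / gc if gc else 0.0
    return out


def _draw_bases(rng: np.random.Generator, n: int, composition: Mapping[str, float]) -> list[str]:
    bases = list("ACGT")
    p = np.array([composition[b] for b in bases], dtype=float)
    p = p / p.sum()
    return list(rng.choice(bases, size=n, p=p))


def _codon_product_bias(composition: Mapping[str, float]) -> dict[str, float]:
    out = {c: composition[c[0]] * composition[c[1]] * composition[c[2]] for c in CODONS}
    total = sum(out.values())
    return {c: v / total for c, v in out.items()}


def synth_genome(spec: SynthSpec) -> SyntheticGenome:
    """Generate a genome matching the template's geometry.

    Background (intergenic, tRNA, rRNA) positions are i.i.d. draws from
    the target composition; control-region positions use the AT-boosted
    composition; protein-coding spans are overwritten, in start order,
    with an in-frame CDS (planted start codon, interior codons from the
    codon distribution, planted stop codon), reverse-complemented onto
    the genome for minus-strand genes.  Where planted features overlap,
    the later write wins; the ground-truth CDS are therefore re-extracted
    from the finished sequence.
    """
    template = spec.resolve_template()
    rng = np.random.default_rng(spec.seed)
    n = template.genome_length
    residues = _draw_bases(rng, n, spec.target_composition)

    cr_comp = _boosted_at(spec.target_composition, spec.cr_at_boost)
    for rec in template.by_category("control_region"):
        positions = list(rec.positions(n))
        filler = _draw_bases(rng, len(positions), cr_comp)
        for pos, base in zip(positions, filler):
            residues[pos - 1] = base

    if spec.codon_bias:
        bias_by_strand = {"+": dict(spec.codon_bias), "-": dict(spec.codon_bias)}
    else:
        # default: composition-product codons; minus-strand genes draw from
        # the complemented composition so the *written* strand still
        # matches the target marginals
        comp_rc = {"A": spec.target_composition["T"], "T": spec.target_composition["A"],
                   "C": spec.target_composition["G"], "G": spec.target_composition["C"]}
        bias_by_strand = {
            "+": _codon_product_bias(spec.target_composition),
            "-": _codon_product_bias(comp_rc),
        }
    for rec in template.by_category("PCG"):
        bias = bias_by_strand[rec.strand]
        codons = sorted(bias)
        p = np.array([bias[c] for c in codons], dtype=float)
        p = p / p.sum()
        length = rec.span_length(n)
        n_codons = length // 3
        if n_codons < 2:
            raise AnnotationError(f"PCG {rec.name!r} too short to plant start+stop")
        interior = list(rng.choice(codons, size=n_codons - 2, p=p))
        start = rec.start_codon if rec.start_codon and len(rec.start_codon) == 3 else spec.start_codon
        stop = rec.stop_codon if rec.stop_codon and len(rec.stop_codon) == 3 else spec.stop_codon
        cds = start + "".join(interior) + stop
        cds += "".join(_draw_bases(rng, length % 3, spec.target_composition))  # frame slack
        if rec.strand == "-":
            written = str(Seq(cds).reverse_complement())
        else:
            written = cds
        for pos, base in zip(rec.positions(n), written):
            residues[pos - 1] = base

    sequence = GenomeSequence(id=template.genome_id, residues="".join(residues),
                              circular=template.circular)
    truth = {rec.name: sequence.feature_sequence(rec) for rec in template.by_category("PCG")}
    at_target = min(spec.target_composition["A"] + spec.target_composition["T"]
                    + spec.cr_at_boost, 0.98)
    return SyntheticGenome(
        sequence=sequence, annotation=template, cds=truth, cr_at_target=at_target
    )


def synth_order_pair(
    spec: SynthSpec, base_order: SignedGeneOrder | None = None
) -> tuple[SignedGeneOrder, SignedGeneOrder, list[RearrangementEvent]]:
    """A gene order and a seeded rearranged copy, with the event log.

    The base order is the focal 37-gene order unless given; kinds are
    drawn from ``event_mix`` and spans at random, sequentially.
    """
    if base_order is None:
        from .datasets import load_focal_gene_order

        base_order = load_focal_gene_order()
    rng = np.random.default_rng(spec.seed)
    kinds = sorted(spec.event_mix)
    probs = np.array([spec.event_mix[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()
    log: list[RearrangementEvent] = []
    current = SignedGeneOrder(base_order.genome_id + "_rearranged", base_order.elements)
    for _ in range(spec.n_events):
        kind = str(rng.choice(kinds, p=probs))
        event = random_event(current, kind, rng)
        current = apply_event(current, event, rng)
        log.append(event)
    return base_order, current, log
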