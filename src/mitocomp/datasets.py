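"""Packaged reference data for the focal sea-cucumber mitogenome.

Two small tables ship with the package, transcribed from the published
annotation of the *Phyllophorus liuwutiensis* mitochondrial genome
(GenBank MN198190, 15 969 bp, 37 genes + 1 control region):

* the full feature table (gene, strand, 1-based inclusive coordinates,
  start/stop codons), and
* the protein-coding codon-count table (5323 codons) with the amino-acid
  labels and RSCU values as printed in the original report.

The printed codon counts are treated as authoritative input — they are
not regenerated from sequence (the deposited sequence is not packaged).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotation import MitogenomeAnnotation, read_annotation_tsv
from .gene_order import SignedGeneOrder, order_from_annotation
from .seqstats import CodonCountTable, rna_to_dna

FOCAL_GENOME_ID = "MN198190"
FOCAL_GENOME_LENGTH = 15969

_ANNOTATION_FILE = "pliuwutiensis_mn198190_annotation.tsv"
_CODON_FILE = "pliuwutiensis_codon_counts.tsv"


def _data_path(name: str):
    return resources.files("mitocomp.data") / name


def load_focal_annotation() -> MitogenomeAnnotation:
    """The packaged 38-record annotation (13 PCG + 22 tRNA + 2 rRNA + CR)."""
    with _data_path(_ANNOTATION_FILE).open("r", encoding="utf-8") as handle:
        return read_annotation_tsv(
            handle, genome_length=FOCAL_GENOME_LENGTH, circular=True, genome_id=FOCAL_GENOME_ID
        )


def load_focal_codon_table() -> pd.DataFrame:
    """The packaged codon table: RNA codon, printed amino-acid label,
    count, and the RSCU value as printed (for cross-checking)."""
    with _data_path(_CODON_FILE).open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle, sep="\t")


def load_focal_codon_counts() -> CodonCountTable:
    """The packaged codon counts as a CodonCountTable (DNA keys)."""
    df = load_focal_codon_table()
    return CodonCountTable(counts={rna_to_dna(c): int(n) for c, n in zip(df["codon"], df["count"])})


def load_focal_gene_order() -> SignedGeneOrder:
    """The focal signed circular gene order (37 genes, CR excluded)."""
    return order_from_annotation(load_focal_annotation())
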