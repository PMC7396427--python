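"""Codon usage and RSCU from the packaged codon-count table.

RSCU (relative synonymous codon usage) is a codon's count divided by its
expected count under uniform use within its synonymous family:
RSCU(c) = count(c) * s / n_F for a family of size s totalling n_F codons.
Values above 1 mark favoured codons.  The label code (amino-acid letters,
invertebrate mitochondrial) and the family code (RSCU denominators,
standard) are deliberately separate parameters.
"""

from mitocomp import aa_usage, rscu_report
from mitocomp.datasets import load_focal_codon_counts
from mitocomp.seqstats import round_half_up

counts = load_focal_codon_counts()
print(f"total codons across the 13 protein-coding genes: {counts.total}")

report = rscu_report(counts, label_code="invertebrate_mito", family_code="standard")
top = report.sort_values("rscu", ascending=False).head(5)
print("\nmost over-represented codons (RSCU):")
for row in top.itertuples():
    print(f"  {row.codon} ({row.aa}): count {row.count}, RSCU {row.rscu}")

usage = aa_usage(counts, "invertebrate_mito")
ranked = sorted((aa for aa in usage if aa != "*"), key=usage.get, reverse=True)[:5]
print("\nmost used amino acids (percent of all codons, stops in denominator):")
for aa in ranked:
    print(f"  {aa}: {round_half_up(usage[aa], 2)}%")
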