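"""Annotation geometry of the packaged sea-cucumber mitogenome.

Loads the packaged annotation (GenBank MN198190, 15 969 bp, 37 genes +
control region), then reports feature census, gene overlaps, the longest
intergenic spacer, and the putative control region.  Overlaps are
negative spacers between features adjacent on the circle; the control
region is the longest noncoding stretch.
"""

from mitocomp import feature_length, identify_control_region, overlaps, spacers
from mitocomp.datasets import load_focal_annotation

ann = load_focal_annotation()
print(f"genome {ann.genome_id}: {ann.genome_length} bp, {len(ann)} features")
print("census:", ann.census())

pcgs = ann.by_category("PCG")
pcg_bp = sum(feature_length(r, ann.genome_length) for r in pcgs)
print(f"{len(pcgs)} protein-coding genes spanning {pcg_bp} bp "
      f"(longest: nad5, {feature_length(ann.get('nad5'), ann.genome_length)} bp)")

ovl = overlaps(ann)
print(f"\n{len(ovl)} overlapping gene pairs (adjacent on the circle):")
for o in ovl:
    print(f"  {o.prev_name} / {o.next_name}: {-o.gap} bp")

longest = max(spacers(ann), key=lambda s: s.gap)
print(f"\nlongest intergenic spacer: {longest.gap} bp "
      f"between {longest.prev_name} and {longest.next_name}")

cr = identify_control_region(ann)
print(f"putative control region: {cr.region.start}-{cr.region.end} "
      f"({cr.region.length} bp), flanked by {cr.region.flanking[0]} / {cr.region.flanking[1]}")
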