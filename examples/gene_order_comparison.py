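"""Signed circular gene-order comparison.

Takes the packaged 37-gene order, applies two known rearrangements (an
inversion and a transposition), and decomposes the pair into conserved
blocks: maximal runs of genes contiguous and co-oriented (or fully
reversed) in both circles.  Breakpoints count the adjacencies of one
order missing from the other.
"""

from mitocomp import (
    RearrangementEvent,
    apply_event,
    breakpoint_distance,
    conserved_blocks,
    render_linear,
)
from mitocomp.datasets import load_focal_gene_order

a = load_focal_gene_order()
print("focal order (from cox1; [x] = minus strand):")
print(" ", render_linear(a, "cox1"))

b = apply_event(a, RearrangementEvent(kind="inversion", span=("M", "Y", "G")))
b = apply_event(b, RearrangementEvent(kind="transposition", span=("C",),
                                      params={"insert_after": "cob"}))
print("\nafter inverting M-Y-G and moving C after cob:")
print(" ", render_linear(b, "cox1"))

decomp = conserved_blocks(a, b)
print(f"\n{decomp.n_blocks} conserved blocks, "
      f"{len(decomp.singletons)} singletons, "
      f"{breakpoint_distance(a, b)} breakpoints:")
for i, blk in enumerate(decomp.blocks, 1):
    ori = "forward" if blk.orientation == 1 else "reversed"
    print(f"  block {i} ({blk.size} genes, {ori}): " + "-".join(blk.labels))
print("  singletons:", ", ".join(decomp.singletons) or "none")
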