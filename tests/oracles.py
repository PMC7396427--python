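"""Independent brute-force oracles used by the test suite.

These deliberately avoid the adjacency-chain algorithm of the package:
conserved runs are found by exhaustively matching every contiguous run of
one circular order against the other order (and its reflection), so the
two code paths share no logic.
"""

from __future__ import annotations

import random

from mitocomp.gene_order import SignedGene, SignedGeneOrder


def _occurs(run, order: SignedGeneOrder) -> bool:
    """Does the signed run occur contiguously in the circular order, read
    forward or from the other strand?"""
    for cand in (order, order.reflected()):
        elems = cand.elements
        n = len(elems)
        for j in range(n):
            if all(elems[(j + k) % n] == run[k] for k in range(len(run))):
                return True
    return False


def brute_force_decomposition(a: SignedGeneOrder, b: SignedGeneOrder):
    """(block label-tuples, singleton labels, breakpoint count) by
    exhaustive contiguous-run search; assumes equal label sets."""
    n = len(a)
    elems = a.elements

    def run_at(i: int, m: int) -> tuple[SignedGene, ...]:
        return tuple(elems[(i + k) % n] for k in range(m))

    if _occurs(run_at(0, n), b):
        return [tuple(g.label for g in elems)], [], 0

    conserved = {}
    for m in range(2, n):
        for i in range(n):
            conserved[(i, m)] = _occurs(run_at(i, m), b)

    blocks = []
    covered = set()
    for m in range(n - 1, 1, -1):
        for i in range(n):
            if not conserved[(i, m)]:
                continue
            left = conserved.get(((i - 1) % n, m + 1), False)
            right = conserved.get((i, m + 1), False)
            if left or right:
                continue  # extendable, not maximal
            labels = tuple(g.label for g in run_at(i, m))
            if set(labels) & covered:
                continue
            blocks.append(labels)
            covered.update(labels)
    singletons = [g.label for g in elems if g.label not in covered]
    breakpoints = sum(1 for i in range(n) if not _occurs(run_at(i, 2), b))
    return blocks, singletons, breakpoints


def random_signed_order(genome_id: str, labels, rng: random.Random) -> SignedGeneOrder:
    perm = list(labels)
    rng.shuffle(perm)
    return SignedGeneOrder(
        genome_id,
        tuple(SignedGene(l, rng.choice((1, -1))) for l in perm),
    )
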