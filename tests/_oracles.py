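"""Independent oracles used to cross-check the implementation.

These deliberately use different algorithms from the package:

* parsimony: exhaustive enumeration of all unrooted binary topologies with
  bit-parallel Fitch counting (the package searches laminar event families);
* Saillard sigma: the pairwise shared-path formula
  sigma^2 = (1/n^2) * sum_{i,j} shared_events(i, j)
  (the package accumulates per-branch l_b * n_b^2);
* functional classification: whole-gene translation before/after the
  substitution (the package translates a single codon).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Seq import Seq


# ---------------------------------------------------------------------------
# parsimony oracle: topologies x Fitch


def _insertions(tree, x):
    yield (tree, x)
    if isinstance(tree, tuple):
        a, b = tree
        for na in _insertions(a, x):
            yield (na, b)
        for nb in _insertions(b, x):
            yield (a, nb)


@lru_cache(maxsize=16)
def rooted_topologies(n_leaves: int):
    """All rooted binary shapes over leaves 1..n_leaves (leaf 0 joins at root)."""
    trees = [1] if n_leaves >= 1 else []
    for leaf in range(2, n_leaves + 1):
        trees = [t for base in trees for t in _insertions(base, leaf)]
    return trees


def min_parsimony_score(tip_sets: list[frozenset], root_set: frozenset) -> int:
    """Exact Steiner/parsimony minimum for binary characters.

    ``tip_sets`` are derived-variant sets; the ancestral haplotype enters as
    one more terminal (leaf 0 = root state). Minimizes Fitch count over every
    unrooted binary topology.
    """
    sites = sorted(set().union(*tip_sets, root_set))
    if not sites:
        return 0
    site_bit = {s: 1 << i for i, s in enumerate(sites)}
    full = (1 << len(sites)) - 1

    terminals = [root_set] + list(tip_sets)
    masks = []
    for t in terminals:
        m1 = 0
        for s in t:
            m1 |= site_bit[s]
        masks.append((full & ~m1, m1))

    n = len(terminals)
    if n == 1:
        return 0
    if n == 2:
        return ((masks[0][1] ^ masks[1][1])).bit_count()

    def fitch(node):
        if not isinstance(node, tuple):
            return masks[node][0], masks[node][1], 0
        a0, a1, ca = fitch(node[0])
        b0, b1, cb = fitch(node[1])
        i0, i1 = a0 & b0, a1 & b1
        empty = full & ~(i0 | i1)
        s0 = i0 | (empty & (a0 | b0))
        s1 = i1 | (empty & (a1 | b1))
        return s0, s1, ca + cb + empty.bit_count()

    best = None
    for shape in rooted_topologies(n - 1):
        s0, s1, c = fitch(shape)
        r0, r1 = masks[0]
        extra = (full & ~((s0 & r0) | (s1 & r1))).bit_count()
        score = c + extra
        if best is None or score < best:
            best = score
    return best


# ---------------------------------------------------------------------------
# Saillard sigma oracle: pairwise shared-path events


def saillard_sigma_pairwise(tree, clade_root, clock, ref=None) -> float:
    """sigma via sum over ordered sample pairs of shared counted events."""
    samples = []  # (node, path of (parent, child) edges from clade_root)

    def collect(node, path):
        for _ in range(tree.multiplicity(node)):
            samples.append((node, tuple(path)))
        for child in tree.children(node):
            collect(child, path + [(node, child)])

    collect(clade_root, [])
    n = len(samples)
    edge_counts = {}
    for u, v in {e for _, p in samples for e in p}:
        edge_counts[(u, v)] = sum(
            1 for e in tree.events(u, v) if clock.counts(e.variant, ref)
        )
    acc = 0.0
    for (_, pi), (_, pj) in itertools.product(samples, samples):
        shared = set(pi) & set(pj)
        acc += sum(edge_counts[e] for e in shared)
    return (acc / (n * n)) ** 0.5


# ---------------------------------------------------------------------------
# functional classification oracle: whole-gene translation


def whole_gene_classify(np_: int, alt: str, gene, ref) -> str:
    """'synonymous' / 'nonsynonymous' / 'coding_terminal' by translating the
    entire gene before and after the substitution."""
    seq = ref.sequence[gene.start - 1 : gene.end]
    offset = np_ - gene.start
    mutated = seq[:offset] + alt + seq[offset + 1 :]
    if gene.strand == "light":
        seq = str(Seq(seq).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
    n_codons = len(seq) // 3
    prot = str(Seq(seq[: 3 * n_codons]).translate(table=2))
    prot_mut = str(Seq(mutated[: 3 * n_codons]).translate(table=2))
    if gene.strand == "heavy":
        in_terminal = offset >= 3 * n_codons
    else:
        in_terminal = (gene.end - np_) >= 3 * n_codons
    if in_terminal:
        return "coding_terminal"
    return "synonymous" if prot == prot_mut else "nonsynonymous"
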