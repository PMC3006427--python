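"""Haplogroup nomenclature tree and motif-based classification.

A haplogroup nomenclature is a rooted tree of named clades; each node carries
the *defining variants* (its motif increment relative to the parent) and,
optionally, *negative markers* that must be absent (e.g. C4e is recognised by
its four transitions together with the lack of the 2232.1A insertion that
marks its sister clade C4a'b'c). The cumulative motif of a node is the union
of defining variants along its root path; a defining entry suffixed ``!``
denotes a back mutation and removes that marker from the cumulative motif.

Assignment returns the most derived clade whose cumulative motif is fully
present in a profile. HVS1-only profiles are matched on control-region
markers alone. Backbone nodes whose motifs are unknown to this fixture carry
empty or synthetic placeholder defining sets (flagged ``backbone`` in the
bundled file) and are never over-committed to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from mtphylo.reference import CONTROL_REGION_SPANS
from mtphylo.variants import SequenceProfile, parse_variant


class NomenclatureError(ValueError):
    """Malformed nomenclature file: orphan parent, duplicate label, cycle."""


def _in_control_region(np_: int) -> bool:
    return any(lo <= np_ <= hi for lo, hi in CONTROL_REGION_SPANS)


@dataclass
class NomenclatureNode:
    label: str
    parent: str | None
    defining_variants: frozenset[str]  # marker names; "name!" = back mutation
    negative_markers: frozenset[str]
    status: str = "paper"  # "paper" | "backbone"
    children: list[str] = field(default_factory=list)

    @property
    def is_placeholder(self) -> bool:
        return self.status == "backbone"


@dataclass(frozen=True)
class MatchReport:
    label: str
    assigned: bool
    ambiguous: bool
    matched: tuple[str, ...]
    missing: tuple[str, ...]
    extra: tuple[str, ...]
    tied_labels: tuple[str, ...] = ()


class NomenclatureTree:
    def __init__(self, nodes: dict[str, NomenclatureNode], root: str):
        self.nodes = nodes
        self.root = root
        self._cum_cache: dict[str, tuple[frozenset[str], frozenset[str]]] = {}

    def __contains__(self, label: str) -> bool:
        return label in self.nodes

    def __iter__(self):
        return iter(self.nodes)

    def depth(self, label: str) -> int:
        d = 0
        node = self.nodes[label]
        while node.parent is not None:
            node = self.nodes[node.parent]
            d += 1
        return d

    def path_to_root(self, label: str) -> list[str]:
        path = [label]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path

    def is_ancestor_or_equal(self, anc: str, label: str) -> bool:
        return anc in self.path_to_root(label)

    def mrca(self, labels: list[str]) -> str:
        paths = [self.path_to_root(l)[::-1] for l in labels]
        out = self.root
        for level in zip(*paths):
            if len(set(level)) == 1:
                out = level[0]
            else:
                break
        return out

    def cumulative(self, label: str) -> tuple[frozenset[str], frozenset[str]]:
        """(cumulative motif, cumulative negative markers) for a node.

        Back-mutated markers (entries suffixed '!') cancel the marker
        inherited from an ancestor.
        """
        if label in self._cum_cache:
            return self._cum_cache[label]
        motif: set[str] = set()
        negatives: set[str] = set()
        for lab in self.path_to_root(label)[::-1]:
            node = self.nodes[lab]
            for m in node.defining_variants:
                if m.endswith("!"):
                    motif.discard(m[:-1])
                else:
                    motif.add(m)
            negatives |= node.negative_markers
        out = (frozenset(motif), frozenset(negatives))
        self._cum_cache[label] = out
        return out

    def cumulative_motif(self, label: str) -> frozenset[str]:
        return self.cumulative(label)[0]


def load_nomenclature(tree_file: str | Path | None = None) -> NomenclatureTree:
    """Load a nomenclature tree from the tab-separated hierarchy format.

    Columns: ``label  parent  defining  negative  status`` where defining and
    negative are comma-separated canonical variant names ('.' for none) and
    parent is '-' for the root. Defaults to the bundled haplogroup C/D
    fixture.
    """
    if tree_file is None:
        from mtphylo.reference import _data_path

        tree_file = _data_path("cd_nomenclature.tsv")
    nodes: dict[str, NomenclatureNode] = {}
    roots: list[str] = []
    for ln, line in enumerate(Path(tree_file).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("label\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise NomenclatureError(f"{tree_file}:{ln}: expected 5 fields, got {len(parts)}")
        label, parent, defining, negative, status = parts
        if label in nodes:
            raise NomenclatureError(f"duplicate label {label!r}")
        if label == parent:
            raise NomenclatureError(f"node {label!r} is its own parent")
        def_set = frozenset(m for m in defining.split(",") if m and m != ".")
        neg_set = frozenset(m for m in negative.split(",") if m and m != ".")
        for m in def_set | neg_set:
            parse_variant(m[:-1] if m.endswith("!") else m)  # validates the name
        nodes[label] = NomenclatureNode(
            label, None if parent == "-" else parent, def_set, neg_set, status
        )
        if parent == "-":
            roots.append(label)
    if len(roots) != 1:
        raise NomenclatureError(f"expected exactly one root, found {roots}")
    for node in nodes.values():
        if node.parent is not None:
            if node.parent not in nodes:
                raise NomenclatureError(f"orphan parent {node.parent!r} of {node.label!r}")
            nodes[node.parent].children.append(node.label)
    tree = NomenclatureTree(nodes, roots[0])
    _check_acyclic(tree)
    return tree


def _check_acyclic(tree: NomenclatureTree) -> None:
    for label in tree.nodes:
        seen = set()
        node = tree.nodes[label]
        while node.parent is not None:
            if node.label in seen:
                raise NomenclatureError(f"cyclic parent links at {node.label!r}")
            seen.add(node.label)
            node = tree.nodes[node.parent]


def _considered(markers: frozenset[str], hvs1_only: bool) -> frozenset[str]:
    if not hvs1_only:
        return markers
    return frozenset(m for m in markers if _in_control_region(parse_variant(m).np))


def assign_haplogroup(
    profile: SequenceProfile,
    tree: NomenclatureTree,
    max_missing: int = 0,
) -> tuple[str, MatchReport]:
    """Assign a profile to the most derived haplogroup whose motif it carries.

    HVS1-only profiles are matched on control-region markers only. Nodes with
    an empty considered motif (unknowable placeholders) are never assigned.
    When several incomparable nodes carry the same maximal matched motif, the
    assignment falls back to their most recent common ancestor and the report
    is flagged ambiguous. ``max_missing`` > 0 tolerates that many missing
    markers per node (off by default; the published assignments are
    motif-exact).
    """
    hvs1_only = profile.coverage == "hvs1"
    names = profile.variant_names

    candidates: list[str] = []
    best_partial: tuple[int, int, str] | None = None  # (-matched, missing, label)
    for label in tree.nodes:
        if label == tree.root:
            continue
        motif, negatives = tree.cumulative(label)
        motif = _considered(motif, hvs1_only)
        if not motif:
            continue
        missing = motif - names
        matched = motif & names
        key = (-len(matched), len(missing), tree.depth(label), label)
        if best_partial is None or key < best_partial:
            best_partial = key
        if len(missing) <= max_missing and not (negatives & names):
            candidates.append(label)

    if not candidates:
        miss: tuple[str, ...] = ()
        if best_partial is not None:
            lab = best_partial[3]
            motif = _considered(tree.cumulative(lab)[0], hvs1_only)
            miss = tuple(sorted(motif - names))
        return tree.root, MatchReport(
            label=tree.root,
            assigned=False,
            ambiguous=False,
            matched=(),
            missing=miss,
            extra=tuple(sorted(names)),
        )

    motifs = {c: _considered(tree.cumulative(c)[0], hvs1_only) for c in candidates}
    if max_missing > 0:
        # tolerant mode: only nodes with the most matched markers compete
        best_matched = max(len(motifs[c] & names) for c in candidates)
        candidates = [c for c in candidates if len(motifs[c] & names) == best_matched]
    # keep only candidates whose considered motif is maximal by inclusion
    maximal = [
        c
        for c in candidates
        if not any(motifs[c] < motifs[o] for o in candidates if o != c)
    ]
    # nodes sharing one motif are indistinguishable: represent by the shallowest
    by_motif: dict[frozenset[str], list[str]] = {}
    for c in maximal:
        by_motif.setdefault(motifs[c], []).append(c)
    reps: list[tuple[str, bool]] = []  # (label, group_was_ambiguous)
    for group in by_motif.values():
        if len(group) == 1:
            reps.append((group[0], False))
        else:
            reps.append((tree.mrca(group), True))
    depth_of = {lab: tree.depth(lab) for lab, _ in reps}
    max_depth = max(depth_of.values())
    deepest = [(lab, amb) for lab, amb in reps if depth_of[lab] == max_depth]
    if len(deepest) == 1:
        label, ambiguous = deepest[0]
        tied: tuple[str, ...] = ()
    else:
        tied = tuple(sorted(lab for lab, _ in deepest))
        label = tree.mrca(list(tied))
        ambiguous = True
    motif = _considered(tree.cumulative(label)[0], hvs1_only)
    return label, MatchReport(
        label=label,
        assigned=True,
        ambiguous=ambiguous,
        matched=tuple(sorted(motif & names)),
        missing=tuple(sorted(motif - names)),
        extra=tuple(sorted(names - motif)),
        tied_labels=tied,
    )
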