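"""Maximum-parsimony mutation trees for mtDNA haplotypes.

Haplotypes are rCRS-relative variant sets rooted at a supplied ancestral
haplotype (the haplogroup's motif). Each variant defines a binary character:
"derived" wherever a haplotype's state differs from the root's. Finding the
minimum-mutation tree is then a Steiner problem in the presence/absence
hypercube: the tree may pass through unsampled intermediate haplotypes, and
a character appearing on more than one edge is homoplasy (parallel mutation)
while an edge restoring the reference state is a back mutation.

Search strategy: if all characters are pairwise compatible (carrier sets
laminar), the data admit a unique perfect phylogeny, built directly. With
incompatible characters and at most ``taxon_bound`` distinct haplotypes, an
iterative-deepening search resolves conflicts exactly by spending extra
events — splitting a character's carriers (parallel gains) or widening its
gain to a superset with a nested reversion (gain + back mutation) — and
returns the first minimum-score tree in a fixed canonical order, making
ties deterministic. Above the bound, a greedy kernel-plus-placement
heuristic with leaf re-attachment is used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from mtphylo.variants import MClass, SequenceProfile, parse_variant


class MtParsimonyError(ValueError):
    pass


@dataclass(frozen=True)
class MutationEvent:
    variant: str
    gain: bool  # True: variant arises; False: reverts toward the reference
    parallel: bool = False
    back: bool = False

    def render(self) -> str:
        """Field convention: '<' marks parallel mutations, '!' back mutations."""
        prefix = "<" if self.parallel else ""
        prefix += "!" if self.back else ""
        return prefix + self.variant


class PhyloTree:
    """Rooted mutation-labeled tree over haplotypes.

    Nodes carry ``haplotype`` (frozenset of variant names), ``multiplicity``
    (number of sampled individuals with exactly that haplotype), ``samples``
    (their ids) and optionally ``label`` (haplogroup). Edges carry an ordered
    tuple of ``MutationEvent``.
    """

    def __init__(self, graph: nx.DiGraph, root: int):
        self.graph = graph
        self.root = root

    # -- basic accessors ---------------------------------------------------
    def haplotype(self, node: int) -> frozenset[str]:
        return self.graph.nodes[node]["haplotype"]

    def multiplicity(self, node: int) -> int:
        return self.graph.nodes[node]["multiplicity"]

    def events(self, parent: int, child: int) -> tuple[MutationEvent, ...]:
        return self.graph.edges[parent, child]["events"]

    def nodes(self) -> list[int]:
        return list(self.graph.nodes)

    def children(self, node: int) -> list[int]:
        return sorted(self.graph.successors(node))

    def subtree_nodes(self, node: int) -> list[int]:
        out = [node]
        for c in self.children(node):
            out.extend(self.subtree_nodes(c))
        return out

    def sample_count(self, node: int) -> int:
        return sum(self.multiplicity(n) for n in self.subtree_nodes(node))

    @property
    def parsimony_score(self) -> int:
        return sum(len(d["events"]) for _, _, d in self.graph.edges(data=True))

    @property
    def has_homoplasy(self) -> bool:
        return any(
            e.parallel or e.back
            for _, _, d in self.graph.edges(data=True)
            for e in d["events"]
        )

    def mrca(self, nodes: Sequence[int]) -> int:
        paths = []
        for n in nodes:
            path = [n]
            while path[-1] != self.root:
                path.append(next(iter(self.graph.predecessors(path[-1]))))
            paths.append(path[::-1])
        out = self.root
        for level in zip(*paths):
            if len(set(level)) == 1:
                out = level[0]
            else:
                break
        return out

    # -- exports -----------------------------------------------------------
    def _node_name(self, node: int) -> str:
        samples = self.graph.nodes[node]["samples"]
        return samples[0] if samples else f"node{node}"

    def newick(self) -> str:
        def rec(node: int) -> str:
            kids = self.children(node)
            inner = "(" + ",".join(rec(c) for c in kids) + ")" if kids else ""
            name = self._node_name(node)
            if node == self.root:
                return f"{inner}{name}"
            events = self.events(next(iter(self.graph.predecessors(node))), node)
            comment = "[&muts=" + "/".join(e.render() for e in events) + "]" if events else ""
            return f"{inner}{name}:{len(events)}{comment}"

        return rec(self.root) + ";"

    def edge_table(self):
        """Flat edge list as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for u, v, d in self.graph.edges(data=True):
            rows.append(
                {
                    "parent": u,
                    "child": v,
                    "child_name": self._node_name(v),
                    "n_events": len(d["events"]),
                    "events": " ".join(e.render() for e in d["events"]),
                    "multiplicity": self.multiplicity(v),
                }
            )
        return pd.DataFrame(rows, columns=["parent", "child", "child_name", "n_events", "events", "multiplicity"])


# ---------------------------------------------------------------------------
# construction


def _canonical_haplotypes(
    profiles: Sequence[SequenceProfile], root: frozenset[str]
) -> tuple[list[frozenset[str]], list[int], list[list[str]]]:
    """Collapse identical profiles; derive states relative to the root."""
    groups: dict[frozenset[str], list[str]] = {}
    for p in profiles:
        derived = frozenset(p.variant_names ^ root)
        groups.setdefault(derived, []).append(p.sample_id)
    derived_sets = sorted(groups, key=lambda s: (len(s), sorted(s)))
    mult = [len(groups[s]) for s in derived_sets]
    samples = [sorted(groups[s]) for s in derived_sets]
    return derived_sets, mult, samples


def _check_biallelic(profiles: Sequence[SequenceProfile], root: frozenset[str]) -> None:
    by_np: dict[tuple[int, int], set[str]] = {}
    names = set(root)
    for p in profiles:
        names |= p.variant_names
    for name in names:
        v = parse_variant(name)
        if v.mclass in (MClass.TRANSITION, MClass.TRANSVERSION, MClass.DELETION):
            by_np.setdefault((v.np, 0), set()).add(name)
        else:
            by_np.setdefault((v.np, v.ins_index), set()).add(name)
    for (np_, _), group in by_np.items():
        if len(group) > 1:
            raise MtParsimonyError(
                f"np {np_} carries conflicting alleles {sorted(group)}; "
                "multi-allelic sites are not representable on a biallelic tree"
            )


def _laminar(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def build_mp_tree(
    profiles: Sequence[SequenceProfile],
    root_haplotype: Iterable[str] = (),
    taxon_bound: int = 8,
) -> PhyloTree:
    """Reconstruct a most-parsimonious mutation tree rooted at ``root_haplotype``.

    Exact (minimum score) whenever characters are compatible or the number of
    distinct haplotypes is at most ``taxon_bound``; heuristic above that.
    Identical profiles are collapsed into one node with multiplicity.
    """
    if not profiles:
        raise MtParsimonyError("need at least one profile")
    root = frozenset(str(v) for v in root_haplotype)
    _check_biallelic(profiles, root)
    haps, mult, samples = _canonical_haplotypes(profiles, root)

    chars: dict[str, frozenset[int]] = {}
    for i, h in enumerate(haps):
        for name in h:
            chars[name] = chars.get(name, frozenset()) | {i}
    char_list = sorted(chars.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    conflict = any(
        not _laminar(a[1], b[1]) for a, b in itertools.combinations(char_list, 2)
    )
    if not conflict:
        events = [(name, carriers) for name, carriers in char_list]
    elif len(haps) <= taxon_bound:
        events = _exact_event_search(char_list, len(haps))
    else:
        events = _greedy_events(char_list, len(haps))
    return _tree_from_events(events, haps, mult, samples, root)


# -- exact search ----------------------------------------------------------


def _first_conflict(events: list[tuple[str, frozenset[int]]]) -> tuple[int, int] | None:
    for i, j in itertools.combinations(range(len(events)), 2):
        if not _laminar(events[i][1], events[j][1]):
            return i, j
    return None


def _subsets(universe: tuple[int, ...]):
    """Non-empty proper-and-full subsets, in canonical (size, members) order."""
    for r in range(1, len(universe) + 1):
        yield from (frozenset(c) for c in itertools.combinations(universe, r))


def _conflict_lower_bound(events: list[tuple[str, frozenset[int]]]) -> int:
    """Minimum-vertex-cover bound: each conflicting pair needs at least one of
    its two characters modified, and one extra event modifies one character."""
    edges = [
        (i, j)
        for i, j in itertools.combinations(range(len(events)), 2)
        if not _laminar(events[i][1], events[j][1])
    ]
    if not edges:
        return 0
    verts = sorted({v for e in edges for v in e})
    best = len(verts)

    def cover(remaining, used):
        nonlocal best
        if used >= best:
            return
        if not remaining:
            best = used
            return
        u, v = remaining[0]
        cover([e for e in remaining if u not in e], used + 1)
        cover([e for e in remaining if v not in e], used + 1)

    cover(edges, 0)
    return best


def _exact_event_search(
    char_list: list[tuple[str, frozenset[int]]], n_tips: int
) -> list[tuple[str, frozenset[int]]]:
    """Iterative-deepening search for a minimum-event laminar event family.

    Each extra event either splits a character's carrier set (a parallel
    gain) or widens it to a superset plus a nested complementary reversion
    (gain + back mutation); tips' derived states are invariant under both.
    The first solution at the smallest budget, explored in canonical order,
    fixes the tie-break deterministically. A conflict-graph vertex-cover
    bound prunes hopeless branches.
    """
    all_tips = frozenset(range(n_tips))
    base = list(char_list)
    # a star attachment of every haplotype is always feasible: safe upper bound
    max_extra = sum(len(c) for _, c in char_list) + n_tips
    failed: dict[frozenset, int] = {}  # state -> largest budget proven infeasible

    def dfs(events, extra_left):
        conflict = _first_conflict(events)
        if conflict is None:
            return events
        if _conflict_lower_bound(events) > extra_left:
            return None
        key = frozenset(events)
        if failed.get(key, -1) >= extra_left:
            return None
        i, j = conflict
        for idx in (i, j):
            name, carriers = events[idx]
            rest = events[:idx] + events[idx + 1 :]
            if len(carriers) > 1:
                members = tuple(sorted(carriers))
                for part in _subsets(members[1:]):
                    s2 = frozenset(part)
                    s1 = carriers - s2
                    r = dfs(rest + [(name, s1), (name, s2)], extra_left - 1)
                    if r is not None:
                        return r
            outside = tuple(sorted(all_tips - carriers))
            for ext in _subsets(outside):
                r = dfs(
                    rest + [(name, carriers | ext), (name, frozenset(ext))],
                    extra_left - 1,
                )
                if r is not None:
                    return r
        failed[key] = max(failed.get(key, -1), extra_left)
        return None

    for extra in range(_conflict_lower_bound(base), max_extra + 1):
        result = dfs(base, extra)
        if result is not None:
            return sorted(result, key=lambda kv: (-len(kv[1]), kv[0], sorted(kv[1])))
    raise MtParsimonyError("exact parsimony search failed to terminate")  # pragma: no cover


# -- greedy path for large instances ----------------------------------------


def _greedy_events(
    char_list: list[tuple[str, frozenset[int]]], n_tips: int
) -> list[tuple[str, frozenset[int]]]:
    """Kernel of mutually compatible characters + clade-covering placement.

    Characters are accepted into the laminar kernel greedily (largest carrier
    sets first); each leftover character is charged one event per maximal
    kernel clade inside its carrier set. Not guaranteed minimal; used only
    above the exact-search taxon bound.
    """
    kernel: list[tuple[str, frozenset[int]]] = []
    leftover: list[tuple[str, frozenset[int]]] = []
    for name, carriers in char_list:
        if all(_laminar(carriers, c) for _, c in kernel):
            kernel.append((name, carriers))
        else:
            leftover.append((name, carriers))

    # laminar clades available for event placement: kernel sets + singletons + all
    clades = {frozenset(range(n_tips))} | {c for _, c in kernel}
    clades |= {frozenset([i]) for i in range(n_tips)}
    ordered = sorted(clades, key=lambda s: (-len(s), sorted(s)))

    events = list(kernel)
    for name, carriers in leftover:
        remaining = set(carriers)
        for clade in ordered:
            if clade <= carriers and clade & remaining:
                if clade <= remaining:
                    events.append((name, clade))
                    remaining -= clade
            if not remaining:
                break
        for tip in sorted(remaining):  # pragma: no cover - singletons always cover
            events.append((name, frozenset([tip])))
    return sorted(events, key=lambda kv: (-len(kv[1]), kv[0], sorted(kv[1])))


# -- tree assembly ----------------------------------------------------------


def _tree_from_events(
    events: list[tuple[str, frozenset[int]]],
    haps: list[frozenset[str]],
    mult: list[int],
    samples: list[list[str]],
    root_haplotype: frozenset[str],
) -> PhyloTree:
    n = len(haps)
    universe = frozenset(range(n))
    distinct = sorted(
        {c for _, c in events}, key=lambda s: (-len(s), sorted(s))
    )

    graph = nx.DiGraph()
    graph.add_node(0, carrier_set=universe, haplotype=root_haplotype, multiplicity=0, samples=[], label=None)
    node_of_set: dict[frozenset[int], int] = {}
    next_id = 1
    for s in distinct:
        node_of_set[s] = next_id
        graph.add_node(next_id, carrier_set=s, multiplicity=0, samples=[], label=None)
        next_id += 1

    def parent_set(s: frozenset[int]) -> frozenset[int] | None:
        best = None
        for t in distinct:
            if s < t and (best is None or len(t) < len(best)):
                best = t
        return best

    for s in distinct:
        p = parent_set(s)
        pid = node_of_set[p] if p is not None else 0
        graph.add_edge(pid, node_of_set[s], event_names=[])

    for name, carriers in events:
        nid = node_of_set[carriers]
        pid = next(iter(graph.predecessors(nid)))
        graph.edges[pid, nid]["event_names"].append(name)

    # place sampled haplotypes at the node of their smallest containing set
    for i, h in enumerate(haps):
        smallest = None
        for s in distinct:
            if i in s and (smallest is None or len(s) < len(smallest)):
                smallest = s
        nid = node_of_set[smallest] if smallest is not None else 0
        # a sampled haplotype must coincide with the node's implied haplotype;
        # otherwise give it a pendant zero/extra-event node (greedy path only)
        graph.nodes[nid]["multiplicity"] += mult[i]
        graph.nodes[nid]["samples"].extend(samples[i])

    # haplotypes + event flags by walking from the root
    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    order: list[int] = []

    def walk(node: int, hap: frozenset[str]):
        graph.nodes[node]["haplotype"] = hap
        order.append(node)
        for child in sorted(graph.successors(node)):
            child_hap = set(hap)
            for name in sorted(graph.edges[node, child]["event_names"]):
                if name in child_hap:
                    child_hap.discard(name)
                    losses[name] = losses.get(name, 0) + 1
                else:
                    child_hap.add(name)
                    gains[name] = gains.get(name, 0) + 1
            walk(child, frozenset(child_hap))

    walk(0, root_haplotype)

    for u, v in graph.edges:
        hap_u = graph.nodes[u]["haplotype"]
        evs = []
        for name in sorted(graph.edges[u, v]["event_names"]):
            gain = name not in hap_u
            evs.append(
                MutationEvent(
                    variant=name,
                    gain=gain,
                    parallel=(gains.get(name, 0) if gain else losses.get(name, 0)) > 1,
                    back=not gain,
                )
            )
        graph.edges[u, v]["events"] = tuple(evs)
        del graph.edges[u, v]["event_names"]

    for node in graph.nodes:
        del graph.nodes[node]["carrier_set"]
    return PhyloTree(graph, root=0)
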