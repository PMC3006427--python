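"""Synthetic mtDNA evolution with known genealogy and mutation process.

Sequences of rCRS length evolve along a star or Kingman-coalescent genealogy
with a Poisson mutation process calibrated in the same units the dating
clocks use (years per mutation), so the whole pipeline — scoring, filtering,
tree building, rho dating — can be validated against a known TMRCA without
any external data.

Mutations are transition-biased (configurable ts/tv ratio), optionally
concentrated at hotspot positions, and by default follow the infinite-sites
idealization (no position is hit twice anywhere in the genealogy), which
cleanly separates estimator tests from homoplasy handling; a finite-sites
mode allows repeat hits — a second hit on the same lineage reverts the
site — to generate deliberate parallel and back mutations for parsimony
tests. Under the synonymous clock, candidate sites are restricted to
positions where a synonymous change exists, making the slower clock
directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from mtphylo.parsimony import MutationEvent, PhyloTree
from mtphylo.reference import PLACEHOLDER_NP, RCRS_LENGTH, ReferenceGenome, synonymous_capable_sites
from mtphylo.rho import COMPLETE_GENOME_CLOCK, ClockSpec
from mtphylo.variants import (
    MClass,
    SequenceProfile,
    Variant,
    parse_variant,
    resolve,
    substitution_class,
)


class MtSimulationError(ValueError):
    pass


_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class TimeTree:
    """A rooted genealogy with branch lengths in years."""

    root: int
    parent: dict[int, int | None]
    children: dict[int, list[int]]
    blen_years: dict[int, float]  # branch above each node; 0 for the root
    leaf_names: dict[int, str]

    @property
    def tmrca_years(self) -> float:
        depths = set()
        for leaf in self.leaf_names:
            d, node = 0.0, leaf
            while self.parent[node] is not None:
                d += self.blen_years[node]
                node = self.parent[node]
            depths.add(round(d, 6))
        return max(depths)

    def total_branch_length(self) -> float:
        return sum(self.blen_years.values())

    def preorder(self) -> list[int]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(sorted(self.children.get(node, []), reverse=True))
        return out


@dataclass
class SimulationConfig:
    n_samples: int
    genealogy: str = "star"  # "star" | "kingman_coalescent" | "fixed_tree"
    tmrca_years: float = 10_000.0  # star tip depth, or coalescent Ne in year units
    clock: ClockSpec = COMPLETE_GENOME_CLOCK
    ts_tv_ratio: float = 20.0
    hotspot_multipliers: dict[int, float] = field(default_factory=dict)
    populations: tuple[tuple[str, str, float], ...] = (("SimPop", "other", 1.0),)
    seed: int = 0
    infinite_sites: bool = True
    root_haplotype: frozenset[str] = frozenset()
    fixed_tree: TimeTree | None = None

    def validate(self) -> None:
        if self.n_samples < 1:
            raise MtSimulationError("n_samples must be >= 1")
        if self.genealogy not in ("star", "kingman_coalescent", "fixed_tree"):
            raise MtSimulationError(f"unknown genealogy {self.genealogy!r}")
        if self.tmrca_years <= 0:
            raise MtSimulationError("tmrca_years must be positive")
        if self.ts_tv_ratio <= 0:
            raise MtSimulationError("ts_tv_ratio must be positive")
        w = sum(w for _, _, w in self.populations)
        if abs(w - 1.0) > 1e-9:
            raise MtSimulationError(f"population weights must sum to 1, got {w}")
        if self.genealogy == "fixed_tree" and self.fixed_tree is None:
            raise MtSimulationError("fixed_tree genealogy needs a fixed_tree")


@dataclass
class SimulatedTruth:
    true_tree: PhyloTree
    true_tmrca_years: float
    variant_sets: dict[str, frozenset[Variant]]
    profiles: list[SequenceProfile]
    labels: dict[str, str]  # sample -> haplogroup label ("" when no scaffold)
    time_tree: TimeTree


def simulate_genealogy(config: SimulationConfig) -> TimeTree:
    """Draw the genealogy: star with all tips at tmrca_years, or a Kingman
    coalescent (via msprime, haploid, population size = tmrca_years in year
    units). Deterministic given ``config.seed``."""
    config.validate()
    n = config.n_samples
    if config.genealogy == "fixed_tree":
        return config.fixed_tree
    if config.genealogy == "star":
        parent = {0: None}
        children = {0: []}
        blen = {0: 0.0}
        leaves = {}
        for i in range(1, n + 1):
            parent[i] = 0
            children[0].append(i)
            children[i] = []
            blen[i] = float(config.tmrca_years)
            leaves[i] = f"S{i:04d}"
        return TimeTree(0, parent, children, blen, leaves)

    import msprime

    rng = np.random.default_rng(config.seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=float(config.tmrca_years),
        random_seed=ms_seed,
    )
    t = ts.first()
    parent: dict[int, int | None] = {}
    children: dict[int, list[int]] = {}
    blen: dict[int, float] = {}
    leaves: dict[int, str] = {}
    for u in t.nodes():
        p = t.parent(u)
        parent[u] = None if p == -1 else p
        children.setdefault(u, [])
        if p != -1:
            children.setdefault(p, []).append(u)
            blen[u] = float(t.time(p) - t.time(u))
        else:
            blen[u] = 0.0
        if t.is_leaf(u):
            leaves[u] = f"S{u + 1:04d}"
    for kids in children.values():
        kids.sort()
    return TimeTree(int(t.root), parent, children, blen, leaves)


def _candidate_sites(
    config: SimulationConfig, ref: ReferenceGenome
) -> tuple[np.ndarray, np.ndarray, dict[int, tuple[str, ...]]]:
    """Mutable positions, their sampling weights, and allowed alts per site."""
    if config.clock.id == "synonymous":
        syn = synonymous_capable_sites(ref)
        sites = np.array(sorted(syn), dtype=np.int64)
        allowed = syn
    else:
        sites = np.array(
            [p for p in range(1, RCRS_LENGTH + 1) if p != PLACEHOLDER_NP], dtype=np.int64
        )
        allowed = {}
    weights = np.ones(len(sites), dtype=float)
    if config.hotspot_multipliers:
        mult = {int(k): float(v) for k, v in config.hotspot_multipliers.items()}
        for i, s in enumerate(sites):
            if int(s) in mult:
                weights[i] = mult[int(s)]
    return sites, weights / weights.sum(), allowed


def _draw_allele(
    np_: int,
    ref: ReferenceGenome,
    allowed: dict[int, tuple[str, ...]],
    ts_tv_ratio: float,
    rng: np.random.Generator,
) -> str:
    refb = ref.base(np_)
    options = allowed.get(np_)
    if options is None:
        options = tuple(b for b in "ACGT" if b != refb)
    ts = [b for b in options if b == _TS_PARTNER.get(refb)]
    tv = [b for b in options if b in _TV_PARTNERS.get(refb, "")]
    if ts and tv:
        pick_ts = rng.random() < ts_tv_ratio / (ts_tv_ratio + 1.0)
        pool = ts if pick_ts else tv
    else:
        pool = ts or tv
    return pool[int(rng.integers(len(pool)))] if len(pool) > 1 else pool[0]


def evolve_sequences(
    tree: TimeTree,
    config: SimulationConfig,
    ref: ReferenceGenome,
    nomenclature=None,
) -> tuple[dict[str, str], SimulatedTruth]:
    """Drop Poisson(branch_length / years_per_mutation) mutations per branch.

    Returns (sample_id -> full-length sequence, truth record). All
    randomness flows from one ``numpy`` Generator seeded with
    ``config.seed``, and branches are visited in a fixed preorder, so output
    is fully reproducible.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.genealogy == "kingman_coalescent":
        rng.integers(1, 2**31 - 1)  # keep streams aligned with simulate_genealogy
    sites, weights, allowed = _candidate_sites(config, ref)
    ypm = config.clock.years_per_mutation

    root_vars = frozenset(resolve(parse_variant(n), ref) for n in config.root_haplotype)
    used = {v.np for v in root_vars}
    available = np.array([i for i, s in enumerate(sites) if int(s) not in used], dtype=np.int64)

    uniform = not config.hotspot_multipliers
    if config.infinite_sites and uniform:
        site_stream = iter(rng.permutation(available))
    branch_events: dict[int, list[Variant]] = {}
    order = tree.preorder()
    for node in order:
        if node == tree.root:
            continue
        k = int(rng.poisson(tree.blen_years[node] / ypm))
        events: list[Variant] = []
        for _ in range(k):
            if config.infinite_sites:
                if uniform:
                    idx = next(site_stream, None)
                    if idx is None:
                        raise MtSimulationError("infinite-sites model exhausted candidate sites")
                    idx = int(idx)
                else:
                    if len(available) == 0:
                        raise MtSimulationError("infinite-sites model exhausted candidate sites")
                    w = weights[available]
                    idx = int(rng.choice(available, p=w / w.sum()))
                    available = available[available != idx]
            else:
                idx = int(rng.choice(len(sites), p=weights))
            np_ = int(sites[idx])
            alt = _draw_allele(np_, ref, allowed, config.ts_tv_ratio, rng)
            events.append(
                Variant(np_, substitution_class(ref.base(np_), alt), alt=alt, ref=ref.base(np_))
            )
        branch_events[node] = events

    # accumulate variant sets down the tree (a repeat hit reverts the site)
    node_vars: dict[int, frozenset[Variant]] = {tree.root: root_vars}
    for node in order:
        if node == tree.root:
            continue
        cur = set(node_vars[tree.parent[node]])
        for ev in branch_events[node]:
            present = next((v for v in cur if v.np == ev.np), None)
            if present is not None:
                cur.discard(present)  # repeat hit on a derived lineage reverts
            else:
                cur.add(ev)
        node_vars[node] = frozenset(cur)

    pops = [(name, region) for name, region, _ in config.populations]
    pop_w = np.array([w for _, _, w in config.populations], dtype=float)

    ref_arr = np.frombuffer(ref.sequence.encode(), dtype="S1").copy()
    sequences: dict[str, str] = {}
    variant_sets: dict[str, frozenset[Variant]] = {}
    profiles: list[SequenceProfile] = []
    for leaf in sorted(tree.leaf_names):
        sid = tree.leaf_names[leaf]
        vs = node_vars[leaf]
        arr = ref_arr.copy()
        for v in vs:
            arr[v.np - 1] = v.alt.encode()
        sequences[sid] = arr.tobytes().decode()
        variant_sets[sid] = vs
        pop_idx = int(rng.choice(len(pops), p=pop_w / pop_w.sum()))
        profiles.append(
            SequenceProfile(
                sample_id=sid,
                population=pops[pop_idx][0],
                region=pops[pop_idx][1],
                coverage="complete",
                variants=vs,
            )
        )

    true_tree = _phylo_from_time_tree(tree, branch_events, node_vars)
    if nomenclature is not None:
        from mtphylo.nomenclature import assign_haplogroup

        labels = {
            p.sample_id: assign_haplogroup(p, nomenclature)[0] for p in profiles
        }
    else:
        labels = {p.sample_id: "" for p in profiles}
    truth = SimulatedTruth(
        true_tree=true_tree,
        true_tmrca_years=tree.tmrca_years,
        variant_sets=variant_sets,
        profiles=profiles,
        labels=labels,
        time_tree=tree,
    )
    return sequences, truth


def _phylo_from_time_tree(
    tree: TimeTree,
    branch_events: dict[int, list[Variant]],
    node_vars: dict[int, frozenset[Variant]],
) -> PhyloTree:
    gains: dict[str, int] = {}
    backs: dict[str, int] = {}
    directions: dict[int, list[tuple[str, bool]]] = {}
    for node in tree.preorder():
        if node == tree.root:
            continue
        evs = []
        for ev in branch_events[node]:
            # an event at a np already derived in the parent reverts it
            parent_at_np = next(
                (v for v in node_vars[tree.parent[node]] if v.np == ev.np), None
            )
            if parent_at_np is not None:
                evs.append((parent_at_np.name, False))
                backs[parent_at_np.name] = backs.get(parent_at_np.name, 0) + 1
            else:
                evs.append((ev.name, True))
                gains[ev.name] = gains.get(ev.name, 0) + 1
        directions[node] = evs

    g = nx.DiGraph()
    for node in tree.preorder():
        g.add_node(
            node,
            haplotype=frozenset(v.name for v in node_vars[node]),
            multiplicity=1 if node in tree.leaf_names else 0,
            samples=[tree.leaf_names[node]] if node in tree.leaf_names else [],
            label=None,
        )
    for node in tree.preorder():
        if node == tree.root:
            continue
        events = tuple(
            MutationEvent(
                variant=name,
                gain=gain,
                parallel=(gains.get(name, 0) if gain else backs.get(name, 0)) > 1,
                back=not gain,
            )
            for name, gain in directions[node]
        )
        g.add_edge(tree.parent[node], node, events=events)
    return PhyloTree(g, root=tree.root)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth(truth: SimulatedTruth, path: str | Path) -> None:
    """Structured-text (JSON) truth record for a simulation."""
    import json

    payload = {
        "true_tmrca_years": truth.true_tmrca_years,
        "newick": truth.true_tree.newick(),
        "samples": {
            sid: sorted(v.name for v in vs) for sid, vs in truth.variant_sets.items()
        },
        "labels": truth.labels,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
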