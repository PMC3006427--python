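"""Rho-statistic coalescence dating with the Saillard standard error.

For a clade of a mutation tree, rho is the average number of counted
mutation events separating each sampled individual from the clade's
ancestral haplotype:

    rho = (1/n) * sum_i d_i

and its standard error follows Saillard et al.'s branch decomposition

    sigma^2 = (1/n^2) * sum_b l_b * n_b^2

where l_b is the number of counted events on branch b and n_b the number of
sampled descendants below it. For a star genealogy this reduces to
sigma^2 = rho / n. Ages are obtained by a strictly linear clock: the
complete-genome clock counts every substitution at one mutation per 3,624
years; the synonymous clock counts only synonymous substitutions at one
mutation per 7,884 years. The reported range is (rho -/+ sigma) converted
linearly, with the lower bound floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable

import pandas as pd

from mtphylo.nomenclature import NomenclatureTree, assign_haplogroup
from mtphylo.parsimony import MutationEvent, PhyloTree
from mtphylo.reference import Category, ReferenceGenome, classify_substitution
from mtphylo.variants import MClass, SequenceProfile, parse_variant


class MtClockError(ValueError):
    pass


@dataclass(frozen=True)
class ClockSpec:
    """A linear molecular clock: which events count, and the years per event."""

    id: str
    years_per_mutation: float
    counted_events: Callable[[str, ReferenceGenome | None], bool]

    def counts(self, variant_name: str, ref: ReferenceGenome | None = None) -> bool:
        return self.counted_events(variant_name, ref)


def _is_substitution(name: str, _ref: ReferenceGenome | None) -> bool:
    return parse_variant(name).mclass in (MClass.TRANSITION, MClass.TRANSVERSION)


def _is_synonymous(name: str, ref: ReferenceGenome | None) -> bool:
    v = parse_variant(name)
    if v.mclass not in (MClass.TRANSITION, MClass.TRANSVERSION):
        return False
    if ref is None:
        raise MtClockError("the synonymous clock needs a reference genome to classify events")
    return _synonymous_cached(name, ref)


@lru_cache(maxsize=65536)
def _synonymous_cached(name: str, ref: ReferenceGenome) -> bool:
    from mtphylo.variants import resolve

    rv = resolve(parse_variant(name), ref)
    return classify_substitution(rv.np, rv.alt, ref).category is Category.SYNONYMOUS


#: One substitution per 3,624 years, counting every (post-filter) substitution.
COMPLETE_GENOME_CLOCK = ClockSpec("complete_genome", 3624.0, _is_substitution)
#: One synonymous substitution per 7,884 years.
SYNONYMOUS_CLOCK = ClockSpec("synonymous", 7884.0, _is_synonymous)

DEFAULT_CLOCKS = (COMPLETE_GENOME_CLOCK, SYNONYMOUS_CLOCK)


@dataclass(frozen=True)
class CladeAgeEstimate:
    clade_label: str
    n: int
    rho: float
    sigma: float
    clock_id: str
    age_years: float
    ci_low_years: float
    ci_high_years: float


def _counted_on_edge(
    events: tuple[MutationEvent, ...], clock: ClockSpec, ref: ReferenceGenome | None
) -> int:
    return sum(1 for e in events if clock.counts(e.variant, ref))


def compute_rho(
    tree: PhyloTree,
    clade_root: int,
    clock: ClockSpec,
    ref: ReferenceGenome | None = None,
) -> tuple[float, float, int]:
    """Return (rho, sigma, n) for the clade rooted at ``clade_root``.

    Every sampled individual counts with its multiplicity; parallel events
    count separately and a back mutation counts as one event.
    """
    n = tree.sample_count(clade_root)
    if n == 0:
        raise MtClockError(f"clade at node {clade_root} contains no sampled individuals")

    total = 0.0
    sigma_acc = 0.0

    def walk(node: int, depth_events: int):
        nonlocal total, sigma_acc
        total += depth_events * tree.multiplicity(node)
        for child in tree.children(node):
            l_b = _counted_on_edge(tree.events(node, child), clock, ref)
            n_b = tree.sample_count(child)
            sigma_acc += l_b * n_b * n_b
            walk(child, depth_events + l_b)

    walk(clade_root, 0)
    rho = total / n
    sigma = (sigma_acc / (n * n)) ** 0.5
    return rho, sigma, n


def rho_to_age(
    rho: float,
    sigma: float,
    clock: ClockSpec,
    clade_label: str = "",
    n: int = 0,
) -> CladeAgeEstimate:
    """Convert rho to a calendar age (years) under a linear clock.

    CI bounds are (rho -/+ sigma) * years_per_mutation, floored at zero.
    """
    if rho < 0 or sigma < 0:
        raise MtClockError("rho and sigma must be non-negative")
    age = rho * clock.years_per_mutation
    lo = max(0.0, (rho - sigma)) * clock.years_per_mutation
    hi = (rho + sigma) * clock.years_per_mutation
    return CladeAgeEstimate(clade_label, n, rho, sigma, clock.id, age, lo, hi)


def label_tree_nodes(
    tree: PhyloTree, nomenclature: NomenclatureTree
) -> dict[int, str]:
    """Classify every sampled node's haplotype; store and return the labels."""
    labels: dict[int, str] = {}
    for node in tree.nodes():
        if tree.multiplicity(node) == 0:
            continue
        profile = SequenceProfile(
            sample_id=f"node{node}",
            variants=frozenset(parse_variant(nm) for nm in tree.haplotype(node)),
        )
        label, _ = assign_haplogroup(profile, nomenclature)
        labels[node] = label
        tree.graph.nodes[node]["label"] = label
    return labels


def date_all_clades(
    tree: PhyloTree,
    nomenclature: NomenclatureTree,
    ref: ReferenceGenome | None = None,
    clocks: Iterable[ClockSpec] = DEFAULT_CLOCKS,
) -> pd.DataFrame:
    """Date every labeled clade of the tree under each clock.

    A clade's members are the sampled nodes assigned to a haplogroup label or
    to any of its descendants in the nomenclature; the clade root is their
    most recent common ancestor in the mutation tree, so rho is computed over
    the tree-defined clade. One row per (clade, clock), ages in ky; by
    convention the complete-genome clock row is listed first for each clade.
    """
    labels = label_tree_nodes(tree, nomenclature)
    rows = []
    for hg in nomenclature:
        members = [
            node
            for node, lab in labels.items()
            if lab in nomenclature and nomenclature.is_ancestor_or_equal(hg, lab)
        ]
        if not members:
            continue
        clade_root = tree.mrca(members)
        for clock in clocks:
            rho, sigma, n = compute_rho(tree, clade_root, clock, ref)
            est = rho_to_age(rho, sigma, clock, clade_label=hg, n=n)
            rows.append(
                {
                    "clade": hg,
                    "n": n,
                    "rho": round(rho, 4),
                    "sigma": round(sigma, 4),
                    "clock": clock.id,
                    "age_ky": round(est.age_years / 1000.0, 3),
                    "ci_low_ky": round(est.ci_low_years / 1000.0, 3),
                    "ci_high_ky": round(est.ci_high_years / 1000.0, 3),
                }
            )
    df = pd.DataFrame(
        rows, columns=["clade", "n", "rho", "sigma", "clock", "age_ky", "ci_low_ky", "ci_high_ky"]
    )
    if not df.empty:
        clock_order = {c.id: i for i, c in enumerate(clocks)}
        df = df.sort_values(
            ["clade", "clock"], key=lambda s: s.map(clock_order) if s.name == "clock" else s
        ).reset_index(drop=True)
    return df
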