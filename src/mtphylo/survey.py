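"""Phylogeographic tabulation: haplogroup frequencies and HVS1 motif surveys.

Population surveys of mtDNA typically sequence only the first hypervariable
segment (HVS1) of the control region, so clades whose motifs include HVS1
positions can be screened across very large published datasets by testing
whether each sample's variant list *contains* the diagnostic motif (extra
private variants are allowed; exact-equality matching is optional).
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from mtphylo.nomenclature import NomenclatureTree
from mtphylo.reference import CONTROL_REGION_SPANS
from mtphylo.variants import SequenceProfile, parse_variant


class MtSurveyError(ValueError):
    pass


def _aggregate_label(label: str, tree: NomenclatureTree, level: int) -> str:
    path = tree.path_to_root(label)[::-1]  # root first
    if level >= len(path):
        return label
    return path[level]


def frequency_table(
    assignments: Iterable[tuple[SequenceProfile, str]],
    tree: NomenclatureTree,
    level: int = 1,
) -> pd.DataFrame:
    """Haplogroup counts and frequencies per population at a nomenclature depth.

    ``level`` is the depth to aggregate at (1 = the root's children, e.g. C
    vs D); labels shallower than the requested depth are kept as they are.
    Returns a tidy table: population, region, haplogroup, n_sampled, count,
    frequency.
    """
    assignments = list(assignments)
    for _, label in assignments:
        if label not in tree:
            raise MtSurveyError(f"unknown haplogroup label {label!r}")
    if not assignments:
        return pd.DataFrame(
            columns=["population", "region", "haplogroup", "n_sampled", "count", "frequency"]
        )
    rows = [
        {
            "population": p.population,
            "region": p.region,
            "haplogroup": _aggregate_label(label, tree, level),
        }
        for p, label in assignments
    ]
    df = pd.DataFrame(rows)
    n_by_pop = df.groupby("population").size().rename("n_sampled")
    counts = (
        df.groupby(["population", "region", "haplogroup"]).size().rename("count").reset_index()
    )
    counts = counts.merge(n_by_pop, on="population")
    counts["frequency"] = counts["count"] / counts["n_sampled"]
    return counts[["population", "region", "haplogroup", "n_sampled", "count", "frequency"]]


def motif_survey(
    hvs1_db: Iterable[SequenceProfile],
    motif: Iterable[str],
    exact: bool = False,
    ignore: Iterable[str] = (),
) -> pd.DataFrame:
    """Survey an HVS1 database for carriers of a diagnostic motif.

    A profile carries the motif when its variant set contains every motif
    variant (containment; set equality with ``exact=True``). Positions in
    ``ignore`` are dropped from both sides before matching (off by default —
    published motifs may legitimately include hypervariable positions).
    Returns one row per population: n_sampled, count, frequency.
    """
    motif = frozenset(str(m) for m in motif)
    ignore = frozenset(str(m) for m in ignore)
    for m in motif:
        v = parse_variant(m)
        if not any(lo <= v.np <= hi for lo, hi in CONTROL_REGION_SPANS):
            raise MtSurveyError(f"not an HVS1 motif: {m} lies in the coding region")
    motif -= ignore

    rows = []
    for p in hvs1_db:
        if p.coverage != "hvs1":
            raise MtSurveyError(f"profile {p.sample_id} is not HVS1 coverage")
        names = p.variant_names - ignore
        carries = names == motif if exact else motif <= names
        rows.append({"population": p.population, "region": p.region, "carrier": carries})
    if not rows:
        return pd.DataFrame(columns=["population", "region", "n_sampled", "count", "frequency"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["population", "region"])
        .agg(n_sampled=("carrier", "size"), count=("carrier", "sum"))
        .reset_index()
    )
    out["count"] = out["count"].astype(int)
    out["frequency"] = out["count"] / out["n_sampled"]
    return out
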