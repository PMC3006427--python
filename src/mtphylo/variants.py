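"""rCRS-relative variant scoring, canonical naming and site-exclusion filters.

Variants are named in the field's standard rCRS-relative convention:

* transitions by bare position — ``16093``
* transversions by position plus derived allele — ``16518T``
* insertions by anchor position, sub-index and inserted base — ``2232.1A``
* deletions by deleted position — ``249del``

Hypervariable stretches around nps 16180-16193 and 303-315 accumulate
length variants and transversion artifacts at rates that defeat mutation
counting, so point indels and transversions in those two windows are
excluded from phylogenetic analysis; transitions there are kept.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import edlib

from mtphylo.reference import (
    HVS1_SPAN,
    PLACEHOLDER_NP,
    RCRS_LENGTH,
    MtReferenceError,
    ReferenceGenome,
)

logger = logging.getLogger(__name__)

_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}
_PURINES = set("AG")

#: Exclusion windows for point indels and transversions (1-based, closed).
EXCLUSION_WINDOWS = ((16180, 16193), (303, 315))

REGIONS = (
    "northeastern_asia",
    "central_southern_siberia",
    "eastern_asia",
    "india",
    "europe",
    "other",
)


class MClass(str, enum.Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True, order=True)
class Variant:
    """One difference from the rCRS.

    ``alt`` is the derived base for substitutions, the inserted base for
    insertions, and empty for deletions. ``ref`` may be empty when the
    variant was parsed from a canonical name without a reference genome.
    """

    np: int
    mclass: MClass
    alt: str = ""
    ref: str = ""
    ins_index: int = 0

    def __post_init__(self):
        if not 1 <= self.np <= RCRS_LENGTH:
            raise ValueError(f"np {self.np} outside 1..{RCRS_LENGTH}")
        if self.mclass is MClass.INSERTION and self.ins_index < 1:
            raise ValueError("insertions need ins_index >= 1")

    @property
    def name(self) -> str:
        if self.mclass is MClass.TRANSITION:
            return str(self.np)
        if self.mclass is MClass.TRANSVERSION:
            return f"{self.np}{self.alt}"
        if self.mclass is MClass.INSERTION:
            return f"{self.np}.{self.ins_index}{self.alt}"
        return f"{self.np}del"

    @property
    def is_substitution(self) -> bool:
        return self.mclass in (MClass.TRANSITION, MClass.TRANSVERSION)

    def __str__(self) -> str:
        return self.name


def substitution_class(ref: str, alt: str) -> MClass:
    if frozenset((ref, alt)) in _TRANSITION_PAIRS:
        return MClass.TRANSITION
    return MClass.TRANSVERSION


def parse_variant(name: str) -> Variant:
    """Parse a canonical variant name; inverse of ``Variant.name``.

    The reference allele is left empty (names do not carry it); transitions
    parsed this way can be resolved against a genome with ``resolve``.
    """
    name = name.strip()
    if name.endswith("del"):
        return Variant(np=int(name[:-3]), mclass=MClass.DELETION)
    if "." in name:
        pos, rest = name.split(".", 1)
        k = "".join(ch for ch in rest if ch.isdigit())
        base = rest[len(k):]
        if not k or len(base) != 1 or base not in "ACGT":
            raise ValueError(f"malformed insertion name {name!r}")
        return Variant(np=int(pos), mclass=MClass.INSERTION, alt=base, ins_index=int(k))
    if name[-1] in "ACGT":
        return Variant(np=int(name[:-1]), mclass=MClass.TRANSVERSION, alt=name[-1])
    return Variant(np=int(name), mclass=MClass.TRANSITION)


def resolve(variant: Variant, ref: ReferenceGenome) -> Variant:
    """Fill in ref/alt bases of a name-parsed variant from the reference."""
    if variant.mclass in (MClass.INSERTION, MClass.DELETION):
        refb = "" if variant.mclass is MClass.INSERTION else ref.base(variant.np)
        return Variant(variant.np, variant.mclass, variant.alt, refb, variant.ins_index)
    refb = ref.base(variant.np)
    alt = variant.alt
    if variant.mclass is MClass.TRANSITION:
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}.get(refb, "")
        if not alt:
            raise MtReferenceError(f"np {variant.np}: reference base {refb} has no transition partner")
    elif alt == refb:
        raise MtReferenceError(f"{variant.name}: alt equals reference base")
    return Variant(variant.np, variant.mclass, alt, refb)


@dataclass(frozen=True)
class SequenceProfile:
    """A sample's rCRS-relative variant list plus population metadata."""

    sample_id: str
    population: str = ""
    region: str = "other"
    coverage: str = "complete"  # "complete" | "hvs1"
    variants: frozenset[Variant] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.coverage not in ("complete", "hvs1"):
            raise ValueError(f"coverage must be 'complete' or 'hvs1', got {self.coverage!r}")
        seen: dict[tuple, str] = {}
        for v in self.variants:
            key = (v.np, v.alt, v.ins_index)
            if key in seen:
                raise ValueError(f"duplicate variant at np {v.np}: {seen[key]} vs {v.name}")
            seen[key] = v.name
            if self.coverage == "hvs1" and not HVS1_SPAN[0] <= v.np <= HVS1_SPAN[1]:
                raise ValueError(
                    f"hvs1 profile {self.sample_id} carries variant {v.name} outside HVS1"
                )

    @property
    def variant_names(self) -> frozenset[str]:
        return frozenset(v.name for v in self.variants)


# ---------------------------------------------------------------------------
# scoring


def score_sequence(query: str, ref: ReferenceGenome) -> frozenset[Variant]:
    """Score a query against the reference, returning its variant set.

    An exact-length query is diffed positionally; a length-divergent but
    near-reference query is aligned first (edit-distance alignment with
    left-aligned, lowest-np indel placement). 'N' positions are skipped with
    a logged warning; any other ambiguity code is an error.
    """
    query = query.upper()
    bad = set(query) - set("ACGTN-")
    if bad:
        raise MtReferenceError(f"ambiguity codes not supported: {sorted(bad)}")
    if len(query) == RCRS_LENGTH:
        return _diff_equal_length(query, ref)
    ref_aln, query_aln = align_to_reference(query, ref)
    return diff_aligned(ref_aln, query_aln, ref)


def _diff_equal_length(query: str, ref: ReferenceGenome) -> frozenset[Variant]:
    import numpy as np

    q_arr = np.frombuffer(query.encode(), dtype="S1")
    r_arr = np.frombuffer(ref.sequence.encode(), dtype="S1")
    out = []
    for i in np.nonzero(q_arr != r_arr)[0]:
        np_ = int(i) + 1
        if np_ == PLACEHOLDER_NP:
            continue
        q = query[i]
        if q == "N":
            logger.warning("np %d: query base N skipped", np_)
            continue
        r = ref.sequence[i]
        out.append(Variant(np_, substitution_class(r, q), alt=q, ref=r))
    return frozenset(out)


def align_to_reference(query: str, ref: ReferenceGenome) -> tuple[str, str]:
    """Globally align a near-reference query; returns (gapped ref, gapped query).

    Thin wrapper over edlib's edit-distance path; intended for sequences a
    handful of indels away from the reference, not for de-novo alignment.
    """
    aln = edlib.align(query, ref.sequence, mode="NW", task="path")
    nice = edlib.getNiceAlignment(aln, query, ref.sequence)
    return nice["target_aligned"], nice["query_aligned"]


def diff_aligned(ref_aln: str, query_aln: str, ref: ReferenceGenome) -> frozenset[Variant]:
    """Convert an aligned (gapped reference, gapped query) pair into variants.

    Insertions are anchored to the preceding reference np and numbered
    ``np.1, np.2, ...``; runs are left-normalized to the lowest equivalent np.
    """
    if len(ref_aln) != len(query_aln):
        raise ValueError("aligned strings differ in length")
    subs: list[Variant] = []
    raw_ins: list[tuple[int, str]] = []  # (anchor np, base)
    raw_del: list[int] = []
    np_ = 0
    for r, q in zip(ref_aln.upper(), query_aln.upper()):
        if r == "-" and q == "-":
            continue
        if r == "-":
            raw_ins.append((np_, q))
            continue
        np_ += 1
        if np_ == PLACEHOLDER_NP:
            continue
        if q == "-":
            raw_del.append(np_)
        elif q == "N":
            logger.warning("np %d: query base N skipped", np_)
        elif q != r:
            subs.append(Variant(np_, substitution_class(r, q), alt=q, ref=r))
    out = list(subs)
    for np_d in raw_del:
        np_d = _left_shift_deletion(np_d, ref)
        out.append(Variant(np_d, MClass.DELETION, ref=ref.base(np_d)))
    counts: dict[int, int] = {}
    for anchor, base in raw_ins:
        anchor = _left_shift_insertion(anchor, base, ref)
        counts[anchor] = counts.get(anchor, 0) + 1
        out.append(Variant(anchor, MClass.INSERTION, alt=base, ins_index=counts[anchor]))
    return frozenset(out)


def _left_shift_insertion(anchor: int, base: str, ref: ReferenceGenome) -> int:
    while anchor > 1 and ref.base(anchor) == base:
        anchor -= 1
    return anchor


def _left_shift_deletion(np_: int, ref: ReferenceGenome) -> int:
    base = ref.base(np_)
    while np_ > 1 and ref.base(np_ - 1) == base:
        np_ -= 1
    return np_


def apply_variants(variants: Iterable[Variant], ref: ReferenceGenome) -> str:
    """Apply a variant set to the reference; inverse of ``score_sequence``."""
    by_np_sub: dict[int, Variant] = {}
    deletions: set[int] = set()
    insertions: dict[int, list[Variant]] = {}
    for v in variants:
        if v.is_substitution:
            if v.np in by_np_sub:
                raise ValueError(f"two substitutions at np {v.np}")
            by_np_sub[v.np] = v
        elif v.mclass is MClass.DELETION:
            deletions.add(v.np)
        else:
            insertions.setdefault(v.np, []).append(v)
    pieces: list[str] = []
    for np_ in range(0, RCRS_LENGTH + 1):
        if np_ >= 1 and np_ not in deletions:
            v = by_np_sub.get(np_)
            pieces.append(v.alt if v else ref.sequence[np_ - 1])
        for v in sorted(insertions.get(np_, []), key=lambda v: v.ins_index):
            pieces.append(v.alt)
    return "".join(pieces)


# ---------------------------------------------------------------------------
# exclusion filters


def apply_exclusion_filters(
    variants: Iterable[Variant],
    windows: tuple[tuple[int, int], ...] = EXCLUSION_WINDOWS,
    indels_only_in_windows: bool = True,
) -> frozenset[Variant]:
    """Drop point indels and transversions in the hypervariable windows.

    Transitions always pass. With ``indels_only_in_windows=False`` indels are
    excluded genome-wide (an alternative reading of the filter's scope),
    while transversions are still excluded only inside the windows.
    Idempotent by construction.
    """

    def in_window(np_: int) -> bool:
        return any(lo <= np_ <= hi for lo, hi in windows)

    kept = []
    for v in variants:
        if v.mclass is MClass.TRANSITION:
            kept.append(v)
        elif v.mclass is MClass.TRANSVERSION:
            if not in_window(v.np):
                kept.append(v)
        else:  # indel
            if indels_only_in_windows and not in_window(v.np):
                kept.append(v)
    return frozenset(kept)


# ---------------------------------------------------------------------------
# variant-list I/O


def read_profiles(path: str | Path) -> list[SequenceProfile]:
    """Read the tab-separated variant-list format.

    Columns: ``sample_id  population  region  coverage  v1,v2,...`` with
    canonical variant names; an empty/'.' variant field means the rCRS type.
    """
    profiles = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (4, 5):
            raise ValueError(f"{path}:{ln}: expected 4-5 tab-separated fields")
        sample, pop, region, coverage = parts[:4]
        names = parts[4] if len(parts) == 5 else ""
        variants = frozenset(
            parse_variant(n) for n in names.split(",") if n.strip() and n.strip() != "."
        )
        profiles.append(SequenceProfile(sample, pop, region, coverage, variants))
    return profiles


def write_profiles(profiles: Iterable[SequenceProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in profiles:
            names = ",".join(v.name for v in sorted(p.variants, key=lambda v: (v.np, v.ins_index, v.alt)))
            fh.write(f"{p.sample_id}\t{p.population}\t{p.region}\t{p.coverage}\t{names or '.'}\n")


def write_vcf(profile: SequenceProfile, ref: ReferenceGenome, path: str | Path) -> None:
    """Minimal single-sample VCF export against the rCRS (1-based)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=rCRS,length={RCRS_LENGTH}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{profile.sample_id}",
    ]
    for v in sorted(profile.variants, key=lambda v: (v.np, v.ins_index)):
        if v.is_substitution:
            pos, refa, alta = v.np, v.ref or ref.base(v.np), v.alt
        elif v.mclass is MClass.DELETION:
            pos = v.np - 1 if v.np > 1 else v.np
            anchor = ref.base(pos)
            refa, alta = anchor + ref.base(v.np), anchor
        else:  # insertion
            pos = v.np
            anchor = ref.base(pos)
            refa, alta = anchor, anchor + v.alt
        lines.append(f"rCRS\t{pos}\t{v.name}\t{refa}\t{alta}\t.\t.\t.\tGT\t1")
    Path(path).write_text("\n".join(lines) + "\n")
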