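"""rCRS reference model: sequence, gene annotation, and functional classification.

The human mitochondrial genome is annotated against the revised Cambridge
Reference Sequence (rCRS), a 16,569-bp circular molecule numbered 1-based.
Position 3107 holds a placeholder character kept for historical numbering
and is never a variant site. Thirteen protein genes are translated with the
vertebrate mitochondrial genetic code; ND6 is the single protein gene encoded
on the light strand and must be read on its reverse complement. Several gene
pairs genuinely overlap (ATP8/ATP6, ND4L/ND4, ATP6/CO3 by one base), and six
protein genes end in incomplete stop codons completed by polyadenylation.

The bundled sequence file ``synthetic_rcrs.fasta`` is a *synthetic* stand-in
for the rCRS: it has the exact rCRS length, the placeholder at np 3107 and a
realistic base composition, but its bases are generated (deterministically)
rather than taken from the real genome. The bundled annotation table uses the
real NC_012920 feature coordinates. Every coordinate-dependent rule in this
package (control region spans, HVS1, codon arithmetic) therefore behaves as
it would on the real reference; only literal base identities differ.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

RCRS_LENGTH = 16569
PLACEHOLDER_NP = 3107

#: Control region spans the origin: nps 16024-16569 joined to 1-576.
CONTROL_REGION_SPANS = ((16024, 16569), (1, 576))
#: Hypervariable segment 1, the span routinely sequenced in population surveys.
HVS1_SPAN = (16024, 16383)

_MITO_TABLE_ID = 2  # vertebrate mitochondrial genetic code

_SYNTH_SEED = 16569
_BASE_PROBS = {"A": 0.309, "C": 0.313, "G": 0.131, "T": 0.247}


class MtReferenceError(ValueError):
    """Raised for malformed reference inputs (wrong length, bad annotation)."""


class Category(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    CODING_TERMINAL = "coding_terminal"  # incomplete stop codon, untranslatable
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL_REGION = "control_region"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class Feature:
    name: str
    start: int  # 1-based, closed
    end: int
    strand: str  # "heavy" | "light"
    ftype: str  # "protein" | "tRNA" | "rRNA" | "control" | "noncoding"

    def __contains__(self, np_: int) -> bool:
        return self.start <= np_ <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FunctionalClass:
    """Primary functional call for one substitution.

    ``per_gene`` keeps the classification against every overlapping protein
    gene; ``category`` is the single primary call after precedence rules.
    Codon fields are populated only for synonymous/nonsynonymous calls.
    """

    category: Category
    gene: str = ""
    codon_index: int | None = None
    codon_position: int | None = None
    per_gene: tuple[tuple[str, Category], ...] = field(default=())

    @property
    def is_synonymous(self) -> bool:
        return self.category is Category.SYNONYMOUS


@dataclass(frozen=True)
class ReferenceGenome:
    sequence: str
    features: tuple[Feature, ...]

    def base(self, np_: int) -> str:
        if not 1 <= np_ <= RCRS_LENGTH:
            raise MtReferenceError(f"np {np_} outside 1..{RCRS_LENGTH}")
        return self.sequence[np_ - 1]

    def features_at(self, np_: int) -> list[Feature]:
        return [f for f in self.features if np_ in f]

    def in_control_region(self, np_: int) -> bool:
        return any(lo <= np_ <= hi for lo, hi in CONTROL_REGION_SPANS)

    def in_hvs1(self, np_: int) -> bool:
        lo, hi = HVS1_SPAN
        return lo <= np_ <= hi


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mtphylo").joinpath("data", name)))


def make_synthetic_reference_sequence(seed: int = _SYNTH_SEED) -> str:
    """Deterministically generate the synthetic rCRS stand-in sequence.

    Length 16,569, 'N' at the np 3107 placeholder, base frequencies matching
    the heavy-strand composition of the real molecule. The bundled FASTA is
    exactly the seed-16569 output of this function.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list(_BASE_PROBS), dtype="U1")
    probs = np.fromiter(_BASE_PROBS.values(), dtype=float)
    probs = probs / probs.sum()
    seq = rng.choice(bases, size=RCRS_LENGTH, p=probs)
    seq[PLACEHOLDER_NP - 1] = "N"
    return "".join(seq)


def load_annotation(path: str | Path | None = None) -> tuple[Feature, ...]:
    """Parse the tab-delimited feature table (name/start/end/strand/type)."""
    path = _data_path("rcrs_annotation.tsv") if path is None else Path(path)
    strand_map = {"H": "heavy", "L": "light", "heavy": "heavy", "light": "light"}
    feats: list[Feature] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, start, end, strand, ftype = line.split("\t")
        if name == "name":
            continue
        feats.append(Feature(name, int(start), int(end), strand_map[strand], ftype))
    return tuple(feats)


def load_reference(
    reference_file: str | Path | None = None,
    annotation_file: str | Path | None = None,
) -> ReferenceGenome:
    """Load the reference genome plus annotation; defaults to the bundled data.

    Raises ``MtReferenceError("not rCRS")`` unless the sequence is exactly
    16,569 bases.
    """
    reference_file = (
        _data_path("synthetic_rcrs.fasta") if reference_file is None else reference_file
    )
    record = next(SeqIO.parse(str(reference_file), "fasta"))
    seq = str(record.seq).upper()
    if len(seq) != RCRS_LENGTH:
        raise MtReferenceError(f"not rCRS: length {len(seq)} != {RCRS_LENGTH}")
    features = load_annotation(annotation_file)
    for f in features:
        if not (1 <= f.start <= f.end <= RCRS_LENGTH):
            raise MtReferenceError(f"feature {f.name} outside reference: {f}")
    return ReferenceGenome(sequence=seq, features=features)


def _codon_of(ref: ReferenceGenome, gene: Feature, np_: int) -> tuple[str, int, int] | None:
    """Return (ref codon on the coding strand, codon_index, codon_position).

    ``None`` when the position falls in the gene's incomplete terminal codon.
    Light-strand genes are read 3'->5' on the heavy strand, i.e. the codon is
    the reverse complement of the genomic triplet.
    """
    if gene.strand == "heavy":
        offset = np_ - gene.start
    else:
        offset = gene.end - np_
    codon_index = offset // 3 + 1
    codon_position = offset % 3 + 1
    if 3 * codon_index > gene.length:
        return None  # incomplete stop codon
    if gene.strand == "heavy":
        lo = gene.start + 3 * (codon_index - 1)
        codon = ref.sequence[lo - 1 : lo + 2]
    else:
        hi = gene.end - 3 * (codon_index - 1)
        codon = str(Seq(ref.sequence[hi - 3 : hi]).reverse_complement())
    return codon, codon_index, codon_position


def _substitute_in_codon(
    gene: Feature, codon: str, codon_position: int, alt: str
) -> str:
    if gene.strand == "light":
        alt = str(Seq(alt).complement())
    return codon[: codon_position - 1] + alt + codon[codon_position:]


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=_MITO_TABLE_ID))


def classify_substitution(np_: int, alt: str, ref: ReferenceGenome) -> FunctionalClass:
    """Classify a single-base substitution at rCRS position ``np_``.

    Precedence: protein calls outrank RNA and control-region calls; among
    overlapping protein genes the most severe call wins (nonsynonymous >
    synonymous > coding-terminal). Substitutions in a gene's incomplete
    terminal stop codon are "coding_terminal" and never count as synonymous.
    """
    alt = alt.upper()
    if alt not in "ACGT":
        raise MtReferenceError(f"invalid alt base {alt!r}")
    if np_ == PLACEHOLDER_NP:
        raise MtReferenceError(f"np {PLACEHOLDER_NP} is the rCRS placeholder, not a variant site")
    if alt == ref.base(np_):
        raise MtReferenceError(f"not a variant: {alt} is the reference base at np {np_}")

    protein_calls: list[tuple[str, Category, int | None, int | None]] = []
    rna: list[Feature] = []
    control = False
    for feat in ref.features_at(np_):
        if feat.ftype == "protein":
            got = _codon_of(ref, feat, np_)
            if got is None:
                protein_calls.append((feat.name, Category.CODING_TERMINAL, None, None))
                continue
            codon, ci, cp = got
            alt_codon = _substitute_in_codon(feat, codon, cp, alt)
            cat = (
                Category.SYNONYMOUS
                if _translate(codon) == _translate(alt_codon)
                else Category.NONSYNONYMOUS
            )
            protein_calls.append((feat.name, cat, ci, cp))
        elif feat.ftype in ("tRNA", "rRNA"):
            rna.append(feat)
        elif feat.ftype == "control":
            control = True

    if protein_calls:
        severity = {
            Category.NONSYNONYMOUS: 0,
            Category.SYNONYMOUS: 1,
            Category.CODING_TERMINAL: 2,
        }
        protein_calls.sort(key=lambda c: (severity[c[1]], c[0]))
        gene, cat, ci, cp = protein_calls[0]
        if cat is Category.CODING_TERMINAL:
            ci = cp = None
        return FunctionalClass(
            category=cat,
            gene=gene,
            codon_index=ci,
            codon_position=cp,
            per_gene=tuple((g, c) for g, c, _, _ in protein_calls),
        )
    if rna:
        rna.sort(key=lambda f: (f.ftype != "tRNA", f.name))
        feat = rna[0]
        cat = Category.TRNA if feat.ftype == "tRNA" else Category.RRNA
        return FunctionalClass(category=cat, gene=feat.name)
    if control or ReferenceGenome.in_control_region(ref, np_):
        return FunctionalClass(category=Category.CONTROL_REGION)
    return FunctionalClass(category=Category.INTERGENIC)


@lru_cache(maxsize=4)
def synonymous_capable_sites(ref: ReferenceGenome) -> dict[int, tuple[str, ...]]:
    """Map np -> alt bases whose primary classification is synonymous.

    These are the candidate sites of the synonymous molecular clock: only
    protein-coding positions where at least one base change leaves every
    overlapping reading frame's amino acid unchanged (severity precedence
    means an overlapping nonsynonymous call disqualifies the alt).
    """
    out: dict[int, tuple[str, ...]] = {}
    protein_spans = [f for f in ref.features if f.ftype == "protein"]
    for feat in protein_spans:
        for np_ in range(feat.start, feat.end + 1):
            if np_ in out or np_ == PLACEHOLDER_NP:
                continue
            refb = ref.base(np_)
            alts = tuple(
                b
                for b in "ACGT"
                if b != refb
                and classify_substitution(np_, b, ref).category is Category.SYNONYMOUS
            )
            if alts:
                out[np_] = alts
    return out
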