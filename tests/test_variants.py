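"""Variant scoring, canonical naming, round trips and exclusion filters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtphylo.reference import PLACEHOLDER_NP, RCRS_LENGTH, MtReferenceError
from mtphylo.variants import (
    EXCLUSION_WINDOWS,
    MClass,
    SequenceProfile,
    Variant,
    apply_exclusion_filters,
    apply_variants,
    parse_variant,
    read_profiles,
    resolve,
    score_sequence,
    substitution_class,
    write_profiles,
    write_vcf,
)


def _mutate(seq: str, np_: int, base: str) -> str:
    return seq[: np_ - 1] + base + seq[np_:]


def _transition_of(base: str) -> str:
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[base]


def _transversion_of(base: str) -> str:
    return {"A": "C", "G": "C", "C": "A", "T": "A"}[base]


# -- scoring ----------------------------------------------------------------


def test_identity_scores_empty(ref):
    assert score_sequence(ref.sequence, ref) == frozenset()


def test_transition_named_by_bare_position(ref):
    q = _mutate(ref.sequence, 16093, _transition_of(ref.base(16093)))
    (v,) = score_sequence(q, ref)
    assert v.name == "16093" and v.mclass is MClass.TRANSITION


def test_transversion_named_with_allele_suffix(ref):
    alt = _transversion_of(ref.base(16518))
    q = _mutate(ref.sequence, 16518, alt)
    (v,) = score_sequence(q, ref)
    assert v.name == f"16518{alt}" and v.mclass is MClass.TRANSVERSION


def test_insertion_named_with_subindex(ref):
    """An extra base after an anchor scores as np.1X (left-aligned anchor)."""
    ins = "C" if ref.base(2232) != "C" else "G"
    q = ref.sequence[:2232] + ins + ref.sequence[2232:]
    variants = score_sequence(q, ref)
    (v,) = variants
    assert v.mclass is MClass.INSERTION and v.alt == ins
    assert v.name.endswith(f".1{ins}")
    # left-aligned: the anchor base never equals the inserted base
    assert ref.base(v.np) != ins


def test_deletion_named_npdel(ref):
    q = ref.sequence[:4999] + ref.sequence[5000:]
    variants = score_sequence(q, ref)
    (v,) = variants
    assert v.mclass is MClass.DELETION and v.name.endswith("del")


def test_n_positions_skipped_other_ambiguity_fatal(ref):
    q = _mutate(ref.sequence, 5000, "N")
    assert score_sequence(q, ref) == frozenset()
    with pytest.raises(MtReferenceError, match="ambiguity"):
        score_sequence(_mutate(ref.sequence, 5000, "R"), ref)


def test_placeholder_site_never_scored(ref):
    q = _mutate(ref.sequence, PLACEHOLDER_NP, "A")
    assert score_sequence(q, ref) == frozenset()


def test_substitution_roundtrip_random_genomes(ref, rng):
    """score(apply(V)) == V for random substitution sets (20 genomes here;
    the acceptance suite runs 200)."""
    for _ in range(20):
        k = int(rng.integers(1, 30))
        positions = rng.choice(np.arange(1, RCRS_LENGTH + 1), size=k, replace=False)
        variants = set()
        for np_ in positions:
            np_ = int(np_)
            if np_ == PLACEHOLDER_NP:
                continue
            refb = ref.base(np_)
            alt = (
                _transition_of(refb)
                if rng.random() < 0.9
                else _transversion_of(refb)
            )
            variants.add(Variant(np_, substitution_class(refb, alt), alt=alt, ref=refb))
        seq = apply_variants(variants, ref)
        assert score_sequence(seq, ref) == frozenset(variants)


@pytest.mark.parametrize("kind", ["insertion", "deletion"])
def test_indel_roundtrip_through_alignment(ref, kind):
    """A length-divergent genome is aligned and its indel recovered, along
    with a substitution; indel spots avoid homopolymer ambiguity."""
    refb = ref.base(8000)
    variants = {
        Variant(8000, substitution_class(refb, _transition_of(refb)), alt=_transition_of(refb), ref=refb),
    }
    if kind == "insertion":
        ins_np = next(
            p for p in range(4000, 5000)
            if ref.base(p) != "A" and ref.base(p + 1) != "A"
        )
        variants.add(Variant(ins_np, MClass.INSERTION, alt="A", ins_index=1))
        expect_len = RCRS_LENGTH + 1
    else:
        del_np = next(
            p for p in range(9000, 10000)
            if ref.base(p - 1) != ref.base(p) and ref.base(p + 1) != ref.base(p)
        )
        variants.add(Variant(del_np, MClass.DELETION, ref=ref.base(del_np)))
        expect_len = RCRS_LENGTH - 1
    seq = apply_variants(variants, ref)
    assert len(seq) == expect_len
    scored = score_sequence(seq, ref)
    # compare by canonical name (ref fields may be unfilled on the input side)
    assert {v.name for v in scored} == {v.name for v in variants}


def test_naming_is_injective_and_parse_inverts(ref, rng):
    seen = {}
    for _ in range(500):
        np_ = int(rng.integers(1, RCRS_LENGTH + 1))
        mclass = [MClass.TRANSITION, MClass.TRANSVERSION, MClass.INSERTION, MClass.DELETION][
            int(rng.integers(4))
        ]
        alt = "ACGT"[int(rng.integers(4))] if mclass in (MClass.TRANSVERSION, MClass.INSERTION) else ""
        v = Variant(np_, mclass, alt=alt, ins_index=1 if mclass is MClass.INSERTION else 0)
        key = (v.np, v.alt, v.mclass, v.ins_index)
        if v.name in seen:
            assert seen[v.name] == key
        seen[v.name] = key
        p = parse_variant(v.name)
        assert (p.np, p.alt, p.mclass, p.ins_index) == key


# -- exclusion filters -------------------------------------------------------


def test_filter_drops_window_transversions_and_indels(ref):
    tv = parse_variant("16182C")
    ins = parse_variant("309.1C")
    assert apply_exclusion_filters({tv}) == frozenset()
    assert apply_exclusion_filters({ins}) == frozenset()


def test_filter_keeps_transitions_everywhere():
    ts_in_window = parse_variant("16189")
    ts_outside = parse_variant("7694")
    kept = apply_exclusion_filters({ts_in_window, ts_outside})
    assert kept == frozenset({ts_in_window, ts_outside})


def test_filter_passes_outside_window_indels_by_default():
    ins = parse_variant("2232.1A")
    assert apply_exclusion_filters({ins}) == frozenset({ins})
    assert apply_exclusion_filters({ins}, indels_only_in_windows=False) == frozenset()


@settings(deadline=None, max_examples=200)
@given(
    st.sets(
        st.builds(
            lambda np_, kind, alt: Variant(
                np_,
                kind,
                alt=alt if kind in (MClass.TRANSVERSION, MClass.INSERTION) else "",
                ins_index=1 if kind is MClass.INSERTION else 0,
            ),
            st.integers(1, RCRS_LENGTH),
            st.sampled_from(list(MClass)),
            st.sampled_from("ACGT"),
        ),
        max_size=30,
    )
)
def test_filter_idempotent_monotone_transition_preserving(variants):
    once = apply_exclusion_filters(variants)
    assert apply_exclusion_filters(once) == once
    assert len(once) <= len(variants)
    for v in variants:
        if v.mclass is MClass.TRANSITION:
            assert v in once
    for lo, hi in EXCLUSION_WINDOWS:
        assert not any(
            lo <= v.np <= hi and v.mclass is not MClass.TRANSITION for v in once
        )


# -- profiles and I/O --------------------------------------------------------


def test_hvs1_profile_rejects_coding_variants():
    with pytest.raises(ValueError, match="outside HVS1"):
        SequenceProfile("s", coverage="hvs1", variants=frozenset({parse_variant("7694")}))


def test_duplicate_variant_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        SequenceProfile(
            "s",
            variants=frozenset({parse_variant("16093"), Variant(16093, MClass.TRANSVERSION, alt="")}),
        )


def test_profile_io_roundtrip(tmp_path, profile_factory):
    profiles = [
        profile_factory("a", "16093,16518T,2232.1A", population="Teleut",
                        region="central_southern_siberia"),
        profile_factory("b", "", population="Pole", region="europe"),
        profile_factory("c", "16223,16362", coverage="hvs1", population="Yukaghir",
                        region="northeastern_asia"),
    ]
    path = tmp_path / "profiles.tsv"
    write_profiles(profiles, path)
    back = read_profiles(path)
    assert [(p.sample_id, p.variant_names, p.coverage) for p in back] == [
        (p.sample_id, p.variant_names, p.coverage) for p in profiles
    ]


def test_vcf_export_minimal(tmp_path, ref, profile_factory):
    p = profile_factory("s1", "16093,2232.1A,5000del")
    out = tmp_path / "s1.vcf"
    write_vcf(p, ref, out)
    text = out.read_text()
    assert text.startswith("##fileformat=VCF")
    body = [l for l in text.splitlines() if not l.startswith("#")]
    assert len(body) == 3
    sub = next(l for l in body if "\t16093\t" in l)
    assert sub.split("\t")[3] == ref.base(16093)


def test_resolve_fills_transition_partner(ref):
    v = resolve(parse_variant("16093"), ref)
    assert v.ref == ref.base(16093)
    assert substitution_class(v.ref, v.alt) is MClass.TRANSITION
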