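"""Rho statistic, Saillard standard error, and clock conversion."""

from __future__ import annotations

import pytest

from mtphylo.parsimony import build_mp_tree
from mtphylo.reference import synonymous_capable_sites
from mtphylo.rho import (
    COMPLETE_GENOME_CLOCK,
    SYNONYMOUS_CLOCK,
    MtClockError,
    compute_rho,
    date_all_clades,
    rho_to_age,
)

from _oracles import saillard_sigma_pairwise
from conftest import make_profile


def _star(k_events_per_tip: int, n_tips: int):
    profiles = []
    site = 5000
    for i in range(n_tips):
        names = []
        for _ in range(k_events_per_tip):
            names.append(str(site))
            site += 1
        profiles.append(make_profile(f"s{i}", names))
    return build_mp_tree(profiles, frozenset())


# -- compute_rho -------------------------------------------------------------


def test_star_clade_closed_form():
    """n=4 tips, 2 events each: rho=2 and sigma=sqrt(rho/n)=0.7071."""
    tree = _star(2, 4)
    rho, sigma, n = compute_rho(tree, tree.root, COMPLETE_GENOME_CLOCK)
    assert (rho, n) == (2.0, 4)
    assert sigma == pytest.approx((2.0 / 4) ** 0.5, abs=1e-9)


def test_single_sample_at_root():
    tree = build_mp_tree([make_profile("only", "")], frozenset())
    rho, sigma, n = compute_rho(tree, tree.root, COMPLETE_GENOME_CLOCK)
    assert (rho, sigma, n) == (0.0, 0.0, 1)


def test_nested_clade_saillard_worked_example():
    """Internal branch (1 event) above two tips (+1 each) plus one direct tip
    (1 event): rho=5/3, sigma^2=7/9."""
    profiles = [
        make_profile("A", "5001,5002"),
        make_profile("B", "5001,5003"),
        make_profile("C", "5004"),
    ]
    tree = build_mp_tree(profiles, frozenset())
    rho, sigma, n = compute_rho(tree, tree.root, COMPLETE_GENOME_CLOCK)
    assert n == 3
    assert rho == pytest.approx(5 / 3, abs=1e-9)
    assert sigma**2 == pytest.approx(7 / 9, abs=1e-9)


def test_sigma_matches_pairwise_oracle_on_random_trees(rng):
    """Branch-sum Saillard sigma equals the shared-path pairwise formula."""
    for _ in range(25):
        n = int(rng.integers(3, 7))
        profiles = []
        site = 6000
        for i in range(n):
            k = int(rng.integers(0, 4))
            names = [str(site + j) for j in range(k)]
            site += k
            profiles.append(make_profile(f"s{i}", names))
        # shared internal structure: give a random prefix to some tips
        tree = build_mp_tree(profiles, frozenset())
        rho, sigma, _ = compute_rho(tree, tree.root, COMPLETE_GENOME_CLOCK)
        assert sigma == pytest.approx(
            saillard_sigma_pairwise(tree, tree.root, COMPLETE_GENOME_CLOCK), abs=1e-9
        )


def test_star_random_fixtures_satisfy_closed_form(rng):
    for _ in range(20):
        n = int(rng.integers(2, 30))
        k = int(rng.integers(0, 5))
        tree = _star(k, n)
        rho, sigma, _ = compute_rho(tree, tree.root, COMPLETE_GENOME_CLOCK)
        assert sigma == pytest.approx((rho / n) ** 0.5, abs=1e-9)


def test_multiplicity_invariance():
    """Collapsing identical tips into multiplicity leaves rho/sigma unchanged."""
    expanded = [make_profile(f"a{i}", "5001") for i in range(3)] + [
        make_profile("b", "5002,5003")
    ]
    tree = build_mp_tree(expanded, frozenset())
    rho, sigma, n = compute_rho(tree, tree.root, COMPLETE_GENOME_CLOCK)
    assert n == 4
    assert rho == pytest.approx((1 * 3 + 2) / 4)
    assert sigma**2 == pytest.approx((1 * 9 + 2 * 1) / 16)


def test_empty_clade_rejected():
    tree = _star(1, 2)
    bare = [n for n in tree.nodes() if tree.sample_count(n) == 0]
    if bare:
        with pytest.raises(MtClockError, match="no sampled"):
            compute_rho(tree, bare[0], COMPLETE_GENOME_CLOCK)


def test_synonymous_clock_counts_only_synonymous_events(ref):
    syn = synonymous_capable_sites(ref)
    syn_np = next(iter(sorted(syn)))
    # a control-region transition never counts under the synonymous clock
    profiles = [make_profile("A", str(syn_np)), make_profile("B", "16129")]
    tree = build_mp_tree(profiles, frozenset())
    rho_all, _, _ = compute_rho(tree, tree.root, COMPLETE_GENOME_CLOCK)
    rho_syn, _, _ = compute_rho(tree, tree.root, SYNONYMOUS_CLOCK, ref)
    assert rho_all == pytest.approx(1.0)
    assert rho_syn == pytest.approx(0.5)


def test_indels_do_not_count_toward_rho():
    profiles = [make_profile("A", "5001,2232.1A"), make_profile("B", "5002")]
    tree = build_mp_tree(profiles, frozenset())
    rho, _, _ = compute_rho(tree, tree.root, COMPLETE_GENOME_CLOCK)
    assert rho == pytest.approx(1.0)


# -- rho_to_age --------------------------------------------------------------


def test_complete_genome_clock_rate():
    assert rho_to_age(1.0, 0.0, COMPLETE_GENOME_CLOCK).age_years == pytest.approx(3624.0)


def test_synonymous_clock_rate():
    assert rho_to_age(1.0, 0.0, SYNONYMOUS_CLOCK).age_years == pytest.approx(7884.0)


def test_zero_rho_zero_age():
    est = rho_to_age(0.0, 0.0, COMPLETE_GENOME_CLOCK)
    assert (est.age_years, est.ci_low_years, est.ci_high_years) == (0.0, 0.0, 0.0)


def test_headline_arithmetic():
    """rho=7.552 under the complete-genome clock dates to ~27.37 ky."""
    est = rho_to_age(7.552, 0.0, COMPLETE_GENOME_CLOCK)
    assert est.age_years == pytest.approx(27368.448, abs=1e-6)
    assert est.age_years / 1000 == pytest.approx(27.37, abs=0.005)


def test_linearity_of_clock():
    a = rho_to_age(1.3, 0.0, COMPLETE_GENOME_CLOCK).age_years
    b = rho_to_age(2.9, 0.0, COMPLETE_GENOME_CLOCK).age_years
    ab = rho_to_age(4.2, 0.0, COMPLETE_GENOME_CLOCK).age_years
    assert ab == pytest.approx(a + b)


def test_ci_floored_at_zero_and_ordered():
    est = rho_to_age(0.5, 2.0, COMPLETE_GENOME_CLOCK)
    assert est.ci_low_years == 0.0
    assert est.ci_low_years <= est.age_years <= est.ci_high_years


def test_negative_inputs_rejected():
    with pytest.raises(MtClockError):
        rho_to_age(-0.1, 0.0, COMPLETE_GENOME_CLOCK)
    with pytest.raises(MtClockError):
        rho_to_age(0.1, -1.0, COMPLETE_GENOME_CLOCK)


# -- date_all_clades ---------------------------------------------------------


def test_date_all_clades_c5c_fixture(ref, nomen):
    """A synthetic C5c-like sample set yields rows for C5c, C5c1, C5c2 under
    both clocks, all satisfying the estimate invariants."""
    c5c = sorted(nomen.cumulative_motif("C5c"))
    profiles = [
        make_profile("p1", c5c + ["16234"]),            # C5c1
        make_profile("p2", c5c + ["16234", "7694"]),    # C5c1a
        make_profile("p3", c5c + ["16291"]),            # C5c2
        make_profile("p4", c5c + ["16291", "5500"]),    # C5c2 + private
    ]
    tree = build_mp_tree(profiles, frozenset(c5c))
    table = date_all_clades(tree, nomen, ref)
    clades = set(table["clade"])
    assert {"C5c", "C5c1", "C5c2"} <= clades
    assert len(table) == 2 * len(clades)
    for _, row in table.iterrows():
        assert row["rho"] >= 0 and row["sigma"] >= 0
        assert row["ci_low_ky"] <= row["age_ky"] <= row["ci_high_ky"]
    c5c_rows = table[table["clade"] == "C5c"]
    assert set(c5c_rows["clock"]) == {"complete_genome", "synonymous"}
    assert list(c5c_rows["clock"])[0] == "complete_genome"  # reporting convention


def test_whole_clade_rho_bounds_child_mixture(ref, nomen):
    """rho of a parent clade >= sample-weighted mean of child rhos minus the
    events on the child root edges (children's internal variation is shared)."""
    c5c = sorted(nomen.cumulative_motif("C5c"))
    profiles = [
        make_profile("p1", c5c + ["16234"]),
        make_profile("p2", c5c + ["16234", "7694"]),
        make_profile("p3", c5c + ["16291"]),
    ]
    tree = build_mp_tree(profiles, frozenset(c5c))
    rho_all, _, n_all = compute_rho(tree, tree.root, COMPLETE_GENOME_CLOCK)
    child_terms = []
    for child in tree.children(tree.root):
        r, _, k = compute_rho(tree, child, COMPLETE_GENOME_CLOCK)
        child_terms.append((r, k))
    mix = sum(r * k for r, k in child_terms) / n_all
    assert rho_all >= mix
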