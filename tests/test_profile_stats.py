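"""Identity distributions, per-position statistics, PFMs and the probability model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimicryscan import (
    build_pfm,
    consensus_match,
    identity_distribution,
    per_position_stats,
    stretch_match_probability,
)
from mimicryscan.mimicry_core import STANDARD_AA
from mimicryscan.profile_stats import (
    MAX_BITS,
    average_6_or_7_share,
    stretch_match_probability_any_window,
)


# ---------------------------------------------------------------------------
# identity_distribution
# ---------------------------------------------------------------------------

def test_identity_distribution_six_or_seven_share(mage_a3, hit_factory):
    """Identity counts {6,7,7,9} give a 75% six-or-seven share."""
    hits = [
        hit_factory(mage_a3, "KIAELVHYY"),  # 6 identical (V2I? no: I,Y,Y -> check below)
        hit_factory(mage_a3, "KIAELVHFY"),  # 7
        hit_factory(mage_a3, "KIAELVHFI"),  # 7
        hit_factory(mage_a3, "KVAELVHFL"),  # 9
    ]
    assert [h.identity_count for h in hits] == [6, 7, 7, 9]
    dist = identity_distribution(hits)
    row = dist.iloc[0]
    assert row.pct_6_or_7 == pytest.approx(75.0)
    assert sum(row[f"pct_{k}"] for k in range(10)) == pytest.approx(100.0)
    assert average_6_or_7_share(dist) == pytest.approx(75.0)


def test_identity_distribution_degenerate_cases(mage_a3, hit_factory):
    all_same = [hit_factory(mage_a3, mage_a3.sequence)] * 3
    row = identity_distribution(all_same).iloc[0]
    assert row.pct_9 == pytest.approx(100.0)
    assert row.pct_6_or_7 == pytest.approx(0.0)

    single5 = [hit_factory(mage_a3, "KIAEYYYFL")]  # 5 identical
    assert single5[0].identity_count == 5
    row = identity_distribution(single5).iloc[0]
    assert row.pct_5 == pytest.approx(100.0)
    assert row.pct_6_or_7 == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# per_position_stats
# ---------------------------------------------------------------------------

def test_per_position_stats_hand_example(mage_a3, hit_factory):
    """One all-identical hit plus one hit conservative at position 2:
    position 2 splits 50/50, every other position is 100% identical."""
    hits = [
        hit_factory(mage_a3, mage_a3.sequence),
        hit_factory(mage_a3, "KIAELVHFL"),
    ]
    stats = per_position_stats(hits)
    t = stats.table
    assert t.loc[2, "pct_identical"] == pytest.approx(50.0)
    assert t.loc[2, "pct_conservative"] == pytest.approx(50.0)
    for pos in (1, 3, 4, 5, 6, 7, 8, 9):
        assert t.loc[pos, "pct_identical"] == pytest.approx(100.0)
    # percentages sum to 100 at every position; counts sum to n_hits
    for pos in range(1, 10):
        assert (
            t.loc[pos, "pct_identical"]
            + t.loc[pos, "pct_conservative"]
            + t.loc[pos, "pct_non_conservative"]
        ) == pytest.approx(100.0, abs=1e-9)
        assert (
            t.loc[pos, "n_identical"]
            + t.loc[pos, "n_conservative"]
            + t.loc[pos, "n_non_conservative"]
        ) == stats.n_hits
    # averages equal the mean of per-position values
    assert stats.averages["identical"] == pytest.approx(t["pct_identical"].mean())


def test_per_position_stats_recovers_planted_rates(mage_a3, hit_factory):
    """Deterministic planting: 1 of 5 hits non-conservative at position 7 -> 20%."""
    hits = [hit_factory(mage_a3, mage_a3.sequence) for _ in range(4)]
    hits.append(hit_factory(mage_a3, "KVAELVDFL"))  # H->D at position 7, cross-class
    stats = per_position_stats(hits)
    assert stats.table.loc[7, "pct_non_conservative"] == pytest.approx(20.0)


# ---------------------------------------------------------------------------
# build_pfm / consensus
# ---------------------------------------------------------------------------

def test_pfm_degenerate_column():
    pfm = build_pfm(["AAAAAAAAA"])
    assert (pfm.frequencies["A"] == 1.0).all()
    assert pfm.information_bits == pytest.approx([MAX_BITS] * 9)
    assert pfm.consensus == "AAAAAAAAA"


def test_pfm_half_split_column():
    pfm = build_pfm(["AAAAAAAAA", "AAAAAAAAC"])
    assert pfm.frequencies.loc[9, "A"] == pytest.approx(0.5)
    assert pfm.frequencies.loc[9, "C"] == pytest.approx(0.5)
    assert pfm.information_bits[8] == pytest.approx(MAX_BITS - 1.0)  # 1 bit entropy
    assert pfm.consensus_ties == (9,)
    assert pfm.consensus[8] == "A"  # alphabetical tie-break
    assert 9 not in [p for p in pfm.consensus_ties if p < 9]


def test_pfm_columns_sum_to_one_and_duplication_invariance():
    rng = np.random.default_rng(11)
    seqs = ["".join(rng.choice(list(STANDARD_AA), 9)) for _ in range(20)]
    pfm = build_pfm(seqs)
    assert np.allclose(pfm.frequencies.sum(axis=1), 1.0, atol=1e-9)
    assert ((pfm.information_bits >= 0) & (pfm.information_bits <= MAX_BITS)).all()
    doubled = build_pfm(seqs + seqs)
    assert np.allclose(pfm.frequencies.values, doubled.frequencies.values)
    assert np.allclose(pfm.information_bits, doubled.information_bits)


def test_pfm_uniform_sample_information_tends_to_zero():
    rng = np.random.default_rng(5)
    seqs = ["".join(rng.choice(list(STANDARD_AA), 9)) for _ in range(5000)]
    pfm = build_pfm(seqs)
    assert pfm.information_bits.max() < 0.05  # entropy limit band


def test_pfm_empty_errors():
    with pytest.raises(ValueError):
        build_pfm([])


def test_consensus_match(mage_a3, hit_factory):
    same = build_pfm([mage_a3.sequence] * 5)
    flags, overall = consensus_match(same, mage_a3)
    assert overall and all(flags)

    biased = build_pfm([mage_a3.sequence] * 3 + ["KIAELVHFL"] * 2)
    flags, overall = consensus_match(biased, mage_a3)
    assert overall  # 60% bias toward the epitope residue keeps the consensus

    shifted = build_pfm(["KIAELVHFL"] * 5)  # consensus I at position 2
    flags, overall = consensus_match(shifted, mage_a3)
    assert not overall
    assert flags.count(False) == 1 and flags[1] is False


# ---------------------------------------------------------------------------
# stretch probability
# ---------------------------------------------------------------------------

def test_stretch_probability_printed_endpoints():
    """k=6 and k=9 reproduce the printed 1.56e-8 and 1.95e-12 endpoints."""
    assert stretch_match_probability(6) == pytest.approx(1.5625e-8)
    assert stretch_match_probability(9) == pytest.approx(1.953125e-12)
    assert float(f"{stretch_match_probability(6):.3g}") == 1.56e-8
    assert float(f"{stretch_match_probability(9):.3g}") == 1.95e-12
    assert stretch_match_probability(1) == pytest.approx(0.05)


@given(k1=st.integers(1, 4), k2=st.integers(1, 4))
@settings(deadline=None)
def test_stretch_probability_multiplicative(k1, k2):
    assert stretch_match_probability(k1 + k2) == pytest.approx(
        stretch_match_probability(k1) * stretch_match_probability(k2)
    )


def test_stretch_probability_decreasing_and_bounds():
    vals = [stretch_match_probability(k) for k in range(1, 10)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    for bad in (0, 10):
        with pytest.raises(ValueError):
            stretch_match_probability(bad)


def test_any_window_variant_is_union_bound():
    assert stretch_match_probability_any_window(6) == pytest.approx(
        4 * stretch_match_probability(6)
    )
    assert stretch_match_probability_any_window(9) == stretch_match_probability(9)
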