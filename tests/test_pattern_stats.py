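"""Balance and neighbourhood statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isvbalance import pattern_stats as ps
from isvbalance.datatypes import VesselSequenceSet
from isvbalance.synthetic_data import SequenceGenParams, generate_sequences

from conftest import brute_force_neighbourhood


def _set_from_bits(bits_per_flank: list[list[int]]) -> VesselSequenceSet:
    flanks = {}
    for i, bits in enumerate(bits_per_flank):
        flanks[(f"e{i}", "L")] = "".join("A" if b else "V" for b in bits)
    return VesselSequenceSet.from_strings(flanks)


class TestGlobalBalance:
    def test_all_arterial(self):
        seqs = VesselSequenceSet.from_strings({("e1", "L"): "AAAA"})
        assert ps.global_balance(seqs).fraction == 1.0

    def test_alternating_is_half(self):
        seqs = VesselSequenceSet.from_strings(
            {(e, f): "AVAVAVAVAV" for e in ("e1", "e2") for f in ("L", "R")}
        )
        b = ps.global_balance(seqs)
        assert b.fraction == 0.5
        assert b.n_total == 40
        assert all(b.per_embryo == 0.5)

    def test_tag_filters(self):
        df = pd.DataFrame({
            "embryo_id": ["e1"] * 4, "flank": ["L"] * 4,
            "position": [1, 2, 3, 4], "label": ["A", "A", "V", "V"],
            "tags": ["NICD_clamped", "", "", "NICD_clamped"],
        })
        seqs = VesselSequenceSet(df)
        assert ps.global_balance(seqs, tag="NICD_clamped").fraction == 0.5
        assert ps.global_balance(seqs, exclude_tag="NICD_clamped").fraction == 0.5
        assert ps.global_balance(seqs).n_total == 4

    def test_empty_selection_raises(self):
        seqs = VesselSequenceSet.from_strings({("e1", "L"): "AV"})
        with pytest.raises(ValueError):
            ps.global_balance(seqs, tag="absent_tag")


class TestNeighbourhood:
    def test_strict_alternation_conditionals(self, alternating_flank):
        t = ps.neighbourhood(alternating_flank, (-1, 1))
        t = t.set_index("condition")
        assert t["n_eligible"].sum() == 8  # L - 2 boundary exclusions
        assert t.loc[0, "p_positive"] == 1.0
        assert t.loc[2, "p_positive"] == 0.0
        assert t.loc[1, "n_eligible"] == 0
        assert np.isnan(t.loc[1, "p_positive"])  # undefined, never 0

    def test_eligibility_arithmetic(self):
        seqs, _ = generate_sequences(SequenceGenParams(n_embryos=74, seed=0))
        t = ps.neighbourhood(seqs, (-1, 1))
        assert t["n_eligible"].sum() == 74 * 2 * (10 - 2) == 1184

    def test_right_neighbour_and_radius_two_variants(self):
        seqs, _ = generate_sequences(SequenceGenParams(n_embryos=10, seed=1))
        right = ps.neighbourhood(seqs, (1,))
        assert right["n_eligible"].sum() == 10 * 2 * 9
        assert set(right["condition"]) == {0, 1}
        radius2 = ps.neighbourhood(seqs, (-2, -1, 1, 2))
        assert radius2["n_eligible"].sum() == 10 * 2 * 6
        assert set(radius2["condition"]) == {0, 1, 2, 3, 4}

    def test_iid_conditionals_equal_marginal(self):
        # independence implies every conditional probability = marginal
        seqs, _ = generate_sequences(
            SequenceGenParams(n_embryos=5000, p_artery=0.5, seed=2)
        )
        t = ps.neighbourhood(seqs, (-1, 1))
        for _, row in t.iterrows():
            if row["n_eligible"] > 0:
                se = 0.5 / np.sqrt(row["n_eligible"])
                assert abs(row["p_positive"] - 0.5) < max(3 * se, 0.02)

    def test_invalid_offsets(self, alternating_flank):
        with pytest.raises(ValueError):
            ps.neighbourhood(alternating_flank, ())
        with pytest.raises(ValueError):
            ps.neighbourhood(alternating_flank, (0, 1))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(0, 1), min_size=1, max_size=12),
            min_size=1, max_size=4,
        ),
        st.sampled_from([(-1, 1), (1,), (-2, -1, 1, 2)]),
    )
    def test_matches_brute_force_enumeration(self, flanks, offsets):
        seqs = _set_from_bits(flanks)
        got = ps.neighbourhood(seqs, offsets)
        want = brute_force_neighbourhood(seqs, offsets)
        pd.testing.assert_frame_equal(got, want, check_dtype=False)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.lists(st.integers(0, 1), min_size=3, max_size=12),
                    min_size=1, max_size=4))
    def test_label_swap_symmetry(self, flanks):
        # relabelling A<->V maps P(A | c positives) to 1 - P(A | |off| - c)
        seqs = _set_from_bits(flanks)
        swapped = _set_from_bits([[1 - b for b in f] for f in flanks])
        t = ps.neighbourhood(seqs, (-1, 1)).set_index("condition")
        ts = ps.neighbourhood(swapped, (-1, 1)).set_index("condition")
        for c in (0, 1, 2):
            n, ns = t.loc[c, "n_eligible"], ts.loc[2 - c, "n_eligible"]
            assert n == ns
            if n > 0:
                assert t.loc[c, "p_positive"] == pytest.approx(
                    1.0 - ts.loc[2 - c, "p_positive"]
                )

    def test_counts_partition_eligible(self):
        seqs, _ = generate_sequences(SequenceGenParams(n_embryos=30, seed=5))
        t = ps.neighbourhood(seqs, (-1, 1))
        assert (t["n_positive"] <= t["n_eligible"]).all()
        defined = t.dropna(subset=["p_positive"])
        assert ((defined["p_positive"] >= 0) & (defined["p_positive"] <= 1)).all()


class TestContralateral:
    def test_identical_flanks(self):
        seqs = VesselSequenceSet.from_strings(
            {("e1", "L"): "AAVV", ("e1", "R"): "AAVV"}
        )
        t = ps.contralateral(seqs).set_index("condition")
        assert t.loc["A", "p_positive"] == 1.0
        assert t.loc["V", "p_positive"] == 0.0

    def test_complementary_flanks(self):
        seqs = VesselSequenceSet.from_strings(
            {("e1", "L"): "AAVV", ("e1", "R"): "VVAA"}
        )
        t = ps.contralateral(seqs).set_index("condition")
        assert t.loc["A", "p_positive"] == 0.0
        assert t.loc["V", "p_positive"] == 1.0

    def test_independent_flanks_conditional_equals_marginal(self):
        seqs, _ = generate_sequences(
            SequenceGenParams(n_embryos=5000, p_artery=0.5, seed=6)
        )
        t = ps.contralateral(seqs)
        for _, row in t.iterrows():
            assert abs(row["p_positive"] - 0.5) < 0.02

    def test_unpaired_flank_raises(self):
        seqs = VesselSequenceSet.from_strings({("e1", "L"): "AV"})
        with pytest.raises(ValueError):
            ps.contralateral(seqs)

    def test_all_vessels_eligible(self):
        seqs, _ = generate_sequences(SequenceGenParams(n_embryos=7, seed=7))
        assert ps.contralateral(seqs)["n_eligible"].sum() == len(seqs)


class TestBootstrap:
    def test_identical_embryos_zero_width(self):
        seqs = VesselSequenceSet.from_strings(
            {(e, "L"): "AVAV" for e in ("e1", "e2", "e3")}
        )
        lo, hi = ps.bootstrap_ci(
            lambda s: ps.global_balance(s).fraction, seqs, n_boot=50, seed=0
        )
        assert lo == hi == 0.5

    def test_single_resample_degenerate(self):
        seqs = VesselSequenceSet.from_strings(
            {("e1", "L"): "AAAA", ("e2", "L"): "VVVV"}
        )
        lo, hi = ps.bootstrap_ci(
            lambda s: ps.global_balance(s).fraction, seqs, n_boot=1, seed=3
        )
        assert lo == hi

    def test_requires_two_embryos(self):
        seqs = VesselSequenceSet.from_strings({("e1", "L"): "AV"})
        with pytest.raises(ValueError):
            ps.bootstrap_ci(lambda s: 0.0, seqs, n_boot=10, seed=0)

    def test_determinism(self):
        seqs, _ = generate_sequences(SequenceGenParams(n_embryos=10, seed=1))
        stat = lambda s: ps.global_balance(s).fraction
        assert ps.bootstrap_ci(stat, seqs, 100, seed=5) == ps.bootstrap_ci(
            stat, seqs, 100, seed=5
        )

    def test_coverage_of_true_fraction(self):
        # 95% interval for fraction_A on iid p=0.6 data should cover 0.6
        # in about 95% of simulation replicates
        hits = 0
        n_rep = 100
        stat = lambda s: ps.global_balance(s).fraction
        for rep in range(n_rep):
            seqs, _ = generate_sequences(
                SequenceGenParams(n_embryos=25, p_artery=0.6, seed=1000 + rep)
            )
            lo, hi = ps.bootstrap_ci(stat, seqs, n_boot=199, seed=rep)
            hits += lo <= 0.6 <= hi
        assert 0.85 <= hits / n_rep <= 1.0
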