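"""Raw differences, p-distances, Nei's D, FST and distance matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kelpcoast import (
    DistanceMatrix,
    as_percent,
    coastal_distance_matrix,
    nei_average_pairwise_D,
    p_distance,
    pairwise_fst,
    pi_within,
    pop_pair_stats,
    population_distance_matrix,
    raw_differences,
)
from kelpcoast.exceptions import (
    AlignmentError,
    EmptyInputError,
    OrderingError,
    UndefinedDistanceError,
)

from conftest import make_haplotype_table, random_seq
from oracles import brute_fst, brute_nei_D, brute_pi_within

seq_strategy = st.text(alphabet="ACGTN-", min_size=1, max_size=30)


class TestRawDifferences:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0),
            ("ACGT", "ACGA", 1),
            ("ACNT", "ACGA", 1),  # N excluded, final site differs
            ("AC-T", "ACGT", 0),  # gap excluded
            ("acgt", "ACGA", 1),  # case-insensitive
            ("AAAA", "TTTT", 4),
        ],
    )
    def test_examples(self, a, b, expected):
        assert raw_differences(a, b) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            raw_differences("ACGT", "ACG")

    @settings(derandomize=True, max_examples=60)
    @given(seq_strategy, seq_strategy)
    def test_symmetric_and_bounded(self, a, b):
        if len(a) != len(b):
            a = (a * (len(b) // len(a) + 1))[: len(b)]
        d = raw_differences(a, b)
        assert d == raw_differences(b, a)
        assert 0 <= d <= len(a)


class TestPDistance:
    def test_identical_is_zero(self):
        assert p_distance("ACGT", "ACGT") == 0.0

    def test_maximum_is_one(self):
        assert p_distance("AAAA", "TTTT") == 1.0

    def test_twelve_over_886_prints_as_1_4_percent(self, rng):
        from kelpcoast import mutate_sequence

        a = random_seq(rng, 886)
        b = mutate_sequence(a, 12, rng)
        assert p_distance(a, b) == pytest.approx(12 / 886)
        assert as_percent(p_distance(a, b)) == 1.4

    def test_no_comparable_sites_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("NNN", "ACG")


class TestNeiD:
    def test_fixed_for_same_haplotype(self):
        assert nei_average_pairwise_D(["ACGT"] * 3, ["ACGT"] * 5) == 0.0

    def test_fixed_for_haplotypes_three_apart(self):
        assert nei_average_pairwise_D(["AAAA"] * 2, ["ATTT"] * 4) == 3.0

    def test_mixed_population_double_sum(self):
        # pop_a = {h1, h1, h2}, pop_b = {h2}, d(h1, h2) = 2
        h1, h2 = "AATT", "AAAA"
        pops = (["AATT", "AATT", "AAAA"], ["AAAA"])
        assert nei_average_pairwise_D(*pops) == pytest.approx(brute_nei_D(*pops))
        assert nei_average_pairwise_D(*pops) == pytest.approx((2 + 2 + 0) / 3)
        assert raw_differences(h1, h2) == 2

    def test_empty_population_rejected(self):
        with pytest.raises(EmptyInputError):
            nei_average_pairwise_D([], ["ACGT"])

    def test_single_sequence_populations_reduce_to_raw_differences(self, rng):
        a, b = random_seq(rng, 50), random_seq(rng, 50)
        assert nei_average_pairwise_D([a], [b]) == raw_differences(a, b)

    def test_duplication_invariance(self, rng):
        """D is frequency weighted: duplicating every member changes nothing."""
        pop_a = [random_seq(rng, 20) for _ in range(3)]
        pop_b = [random_seq(rng, 20) for _ in range(4)]
        d = nei_average_pairwise_D(pop_a, pop_b)
        assert nei_average_pairwise_D(pop_a * 3, pop_b * 2) == pytest.approx(d)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        base = [random_seq(rng, 15) for _ in range(4)]
        pop_a = [base[i] for i in rng.integers(0, 4, size=rng.integers(1, 12))]
        pop_b = [base[i] for i in rng.integers(0, 4, size=rng.integers(1, 12))]
        assert nei_average_pairwise_D(pop_a, pop_b) == pytest.approx(
            brute_nei_D(pop_a, pop_b)
        )
        assert pi_within(pop_a) == pytest.approx(brute_pi_within(pop_a))
        lib, orc = pairwise_fst(pop_a, pop_b), brute_fst(pop_a, pop_b)
        if orc is None:
            assert lib is None
        else:
            assert lib == pytest.approx(orc)


class TestFst:
    def test_fixed_for_different_haplotypes_is_one(self):
        assert pairwise_fst(["AAAA"] * 5, ["AATT"] * 7) == 1.0

    def test_identical_polymorphic_populations_show_no_differentiation(self):
        pop = ["AAAA"] * 10 + ["AATT"] * 10
        assert pairwise_fst(pop, list(pop)) == 0.0

    def test_undefined_when_between_diversity_is_zero(self):
        stats = pop_pair_stats(["ACGT"] * 4, ["ACGT"] * 2)
        assert stats.pi_between == 0.0
        assert stats.fst is None

    def test_enumeration_example(self):
        # pop_a = {h1, h2}, pop_b = {h2, h2}, d(h1, h2) = 4
        pop_a, pop_b = ["AAAA", "TTTT"], ["TTTT", "TTTT"]
        stats = pop_pair_stats(pop_a, pop_b)
        assert stats.pi_between == pytest.approx(brute_nei_D(pop_a, pop_b))
        assert stats.fst == pytest.approx(brute_fst(pop_a, pop_b))


class TestMatrices:
    def test_population_matrix_matches_brute_force(self, rng):
        haps = {f"H{i}": random_seq(rng, 25) for i in range(4)}
        counts = {
            "L1": {"H0": 3, "H1": 1},
            "L2": {"H1": 2, "H2": 2},
            "L3": {"H3": 5},
        }
        ht = make_haplotype_table(haps, counts)
        dm = population_distance_matrix(ht)
        for a in counts:
            for b in counts:
                expected = (
                    0.0
                    if a == b
                    else brute_nei_D(
                        ht.sequences_for_locality(a), ht.sequences_for_locality(b)
                    )
                )
                assert dm.loc(a, b) == pytest.approx(expected)

    def test_fixed_localities_give_planted_distances(self):
        haps = {"H1": "AAAAAA", "H2": "AATAAA", "H3": "TTTAAA"}
        ht = make_haplotype_table(
            haps, {"L1": {"H1": 2}, "L2": {"H2": 2}, "L3": {"H3": 2}}
        )
        dm = population_distance_matrix(ht)
        assert dm.loc("L1", "L2") == 1.0
        assert dm.loc("L1", "L3") == 3.0
        assert dm.loc("L2", "L3") == 2.0

    def test_zero_sample_locality_excluded_with_warning(self):
        haps = {"H1": "AAAA", "H2": "ATAA"}
        ht = make_haplotype_table(
            haps, {"L1": {"H1": 2}, "L2": {}, "L3": {"H2": 1}}
        )
        with pytest.warns(UserWarning):
            dm = population_distance_matrix(ht)
        assert dm.labels == ["L1", "L3"]

    def test_coastal_distances(self):
        table = pd.DataFrame(
            {
                "locality": ["A", "B", "C"],
                "order_index": [1, 2, 3],
                "coastal_position_km": [0.0, 10.0, 25.0],
            }
        )
        dm = coastal_distance_matrix(table)
        assert dm.loc("A", "B") == 10.0
        assert dm.loc("A", "C") == 25.0
        assert dm.loc("B", "C") == 15.0

    def test_coastal_matrix_invariant_to_row_order(self):
        table = pd.DataFrame(
            {
                "locality": ["A", "B", "C"],
                "order_index": [1, 2, 3],
                "coastal_position_km": [0.0, 10.0, 25.0],
            }
        )
        dm1 = coastal_distance_matrix(table)
        dm2 = coastal_distance_matrix(table.iloc[::-1])
        assert dm1.labels == dm2.labels
        assert np.allclose(dm1.values, dm2.values)

    def test_non_monotone_positions_rejected(self):
        table = pd.DataFrame(
            {
                "locality": ["A", "B", "C"],
                "order_index": [1, 2, 3],
                "coastal_position_km": [0.0, 30.0, 25.0],
            }
        )
        with pytest.raises(OrderingError):
            coastal_distance_matrix(table)

    def test_tsv_roundtrip_and_subset(self, tmp_path):
        labels = ["A", "B", "C"]
        values = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        dm = DistanceMatrix(labels, values, "genetic_D")
        dm.to_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.labels == labels
        assert np.allclose(back.values, values)
        sub = dm.subset(["C", "A"])
        assert sub.loc("C", "A") == 2.0

    def test_phylip_export(self, tmp_path):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 1.5], [1.5, 0.0]]), "genetic_D")
        dm.to_phylip(tmp_path / "d.phy")
        lines = (tmp_path / "d.phy").read_text().splitlines()
        assert lines[0] == "2"
        assert lines[1].startswith("A")
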