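"""Adjacent-pair assembly, disjunction classification and the beach regression."""

import numpy as np
import pandas as pd
import pytest

from kelpcoast import (
    DistanceMatrix,
    SimConfig,
    adjacent_pairs,
    chilean_locality_table,
    classify_disjunct,
    collapse_haplotypes,
    disjunction_analysis,
    exclude_pairs,
    generate_dataset,
    population_distance_matrix,
)
from kelpcoast.exceptions import CoverageError, LabelError, ParameterError

from conftest import make_haplotype_table


def simple_locality_table(names, positions):
    return pd.DataFrame(
        {
            "locality": names,
            "order_index": range(1, len(names) + 1),
            "coastal_position_km": positions,
        }
    )


def full_beach_table(names, value=5.0):
    return pd.DataFrame(
        {
            "locality_a": names[:-1],
            "locality_b": names[1:],
            "max_beach_km": [value] * (len(names) - 1),
        }
    )


class TestAdjacentPairs:
    def test_sixteen_localities_give_fifteen_pairs(self):
        table = chilean_locality_table("beach")
        pairs = adjacent_pairs(table)
        assert len(table) == 16
        assert len(pairs) == 15
        assert pairs[0].locality_a == "Pichicuy"
        assert pairs[-1].locality_b == "Cucao"
        assert all(p.coastal_km > 0 for p in pairs)

    def test_two_localities_give_one_pair(self):
        pairs = adjacent_pairs(simple_locality_table(["A", "B"], [0.0, 50.0]))
        assert len(pairs) == 1
        assert pairs[0].coastal_km == 50.0

    def test_region_filter_repairs_across_excluded_locality(self):
        names = ["A", "B", "C", "D"]
        table = simple_locality_table(names, [0.0, 10.0, 30.0, 60.0])
        all_pairs = adjacent_pairs(table)
        filtered = adjacent_pairs(table, region_filter=["A", "C", "D"])
        assert len(filtered) == len(all_pairs) - 1
        assert filtered[0].pair_id == "A--C"
        assert filtered[0].coastal_km == 30.0

    def test_missing_beach_entry_is_a_coverage_error(self):
        names = ["A", "B", "C"]
        table = simple_locality_table(names, [0.0, 10.0, 30.0])
        beach = full_beach_table(names).iloc[:1]
        with pytest.raises(CoverageError):
            adjacent_pairs(table, beach)

    def test_beach_longer_than_coastal_distance_rejected(self):
        names = ["A", "B"]
        table = simple_locality_table(names, [0.0, 10.0])
        beach = full_beach_table(names, value=25.0)
        with pytest.raises(CoverageError):
            adjacent_pairs(table, beach)

    def test_exclusion_reduces_count_by_one(self):
        pairs = adjacent_pairs(chilean_locality_table("beach"))
        kept = exclude_pairs(pairs, ["Lebu--Tirua"])
        assert len(kept) == 14
        with pytest.raises(LabelError):
            exclude_pairs(pairs, ["Nowhere--Else"])


class TestClassification:
    def haplotype_table(self):
        haps = {"H1": "AAAAAA", "H3": "TTTTTT"}
        return make_haplotype_table(
            haps,
            {
                "A": {"H1": 4},
                "B": {"H1": 4},
                "C": {"H3": 4},
            },
        )

    def test_fixed_same_haplotype_not_disjunct(self):
        ht = self.haplotype_table()
        dm = population_distance_matrix(ht)
        table = simple_locality_table(["A", "B", "C"], [0.0, 10.0, 30.0])
        pairs = adjacent_pairs(table, full_beach_table(["A", "B", "C"]))
        result = classify_disjunct(pairs, dm, ht)
        ab = result.pairs[0]
        assert ab.nei_D == 0.0
        assert ab.shares_haplotypes
        assert not ab.disjunct
        assert ab.fst is None  # undefined for zero between-population diversity
        bc = result.pairs[1]
        assert bc.disjunct
        assert not bc.shares_haplotypes
        assert bc.nei_D == pytest.approx(6.0)
        assert bc.fst == 1.0
        assert result.inconsistent_pairs == []

    def test_threshold_is_inclusive_and_strict_below(self):
        ht = self.haplotype_table()
        labels = ["A", "B"]
        values = np.array([[0.0, 0.999], [0.999, 0.0]])
        dm = DistanceMatrix(labels, values, "genetic_D")
        pairs = adjacent_pairs(
            simple_locality_table(labels, [0.0, 10.0]), full_beach_table(labels)
        )
        result = classify_disjunct(pairs, dm, ht, threshold=1.0)
        assert result.pairs[0].disjunct is False  # 0.999 < 1.0
        at = DistanceMatrix(labels, np.array([[0.0, 1.0], [1.0, 0.0]]), "genetic_D")
        result2 = classify_disjunct(pairs, at, ht, threshold=1.0)
        assert result2.pairs[0].disjunct is True  # exactly 1.0 counts

    def test_monotone_in_threshold(self):
        ds = generate_dataset(SimConfig(seed=11))
        ht = collapse_haplotypes(ds.alignment)
        dm = population_distance_matrix(ht)
        north = ds.truth["north_localities"]
        pairs = adjacent_pairs(ds.locality_table, ds.beach_table, region_filter=north)
        counts = []
        for threshold in (0.25, 0.5, 1.0, 2.0, 4.0):
            result = classify_disjunct(pairs, dm, ht, threshold=threshold)
            counts.append(sum(bool(p.disjunct) for p in result.pairs))
        assert counts == sorted(counts, reverse=True)

    def test_unknown_locality_is_a_label_error(self):
        ht = self.haplotype_table()
        dm = population_distance_matrix(ht)
        pairs = adjacent_pairs(
            simple_locality_table(["A", "Z"], [0.0, 10.0]),
            full_beach_table(["A", "Z"]),
        )
        with pytest.raises(LabelError):
            classify_disjunct(pairs, dm, ht)

    def test_disjunct_and_sharing_is_flagged_inconsistent(self):
        ht = self.haplotype_table()
        labels = ["A", "B"]
        dm = DistanceMatrix(labels, np.array([[0.0, 3.0], [3.0, 0.0]]), "genetic_D")
        pairs = adjacent_pairs(
            simple_locality_table(labels, [0.0, 10.0]), full_beach_table(labels)
        )
        result = classify_disjunct(pairs, dm, ht)
        assert result.inconsistent_pairs == ["A--B"]


class TestRegression:
    def classified_pairs(self, seed=5):
        ds = generate_dataset(SimConfig(seed=seed))
        ht = collapse_haplotypes(ds.alignment)
        dm = population_distance_matrix(ht)
        north = ds.truth["north_localities"]
        pairs = adjacent_pairs(ds.locality_table, ds.beach_table, region_filter=north)
        return classify_disjunct(pairs, dm, ht).pairs, ds

    def test_beach_effect_recovered_with_positive_sign(self):
        pairs, _ = self.classified_pairs()
        result = disjunction_analysis(pairs)
        assert result.fit_full.params["max_beach_km"] > 0
        assert result.fit_full.nobs == 15
        assert np.isfinite(result.fit_full.params).all()

    def test_exclusion_refit_drops_exactly_one_pair(self):
        pairs, _ = self.classified_pairs()
        excl = pairs[3].pair_id
        result = disjunction_analysis(pairs, exclude=[excl])
        assert result.fit_full.nobs == 15
        assert result.fit_excluded is not None
        assert result.fit_excluded.nobs == 14

    def test_degenerate_constant_response_is_flagged_but_finite(self):
        pairs, _ = self.classified_pairs()
        for p in pairs:
            p.disjunct = False
        result = disjunction_analysis(pairs)
        assert result.degenerate_response
        assert np.isfinite(result.fit_full.params).all()

    def test_too_few_pairs_rejected(self):
        pairs, _ = self.classified_pairs()
        with pytest.raises(ParameterError):
            disjunction_analysis(pairs[:3])

    def test_null_beach_effect_rejection_rate_is_small(self, rng):
        """With disjunction labels independent of beach length, the penalized
        LR test for the beach term should reject near its nominal 5% level."""
        pairs, _ = self.classified_pairs()
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            for p in pairs:
                p.disjunct = bool(rng.random() < 0.3)
            if len({p.disjunct for p in pairs}) < 2:
                continue
            result = disjunction_analysis(pairs)
            rejections += result.fit_full.pvalues["max_beach_km"] < 0.05
        assert rejections / n_reps < 0.125
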