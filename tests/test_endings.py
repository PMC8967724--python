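"""Ending quantification, fold changes and the exhaustive assignment search."""

import itertools
import time

import numpy as np
import pandas as pd
import pytest

from vagalseq.endings import (
    anatomical_fold_change,
    assignment_variance,
    best_assignment,
    enumerate_assignments,
    identify_enriched_clusters,
    innervation_intensity,
    normalized_innervation,
    projection_fold_change,
)
from vagalseq.organs import ENDING_TYPES, STOMACH_REGIONS
from vagalseq.synthetic import DEFAULT_FIXED_MAP, generate_ending_tables

TRUE_ASSIGNMENT = {"J2": "cIMA", "J4": "cIMA", "I7": "cIMA",
                   "I2": "IGLE", "I4": "IGLE", "I5": "IGLE", "I6": "IGLE"}


def labels_frame(rows):
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "cluster"
    return df


class TestIntensity:
    def test_area_fraction(self):
        rec = pd.DataFrame(
            [{"ending_type": "ME", "region": 4, "measure": 10.0, "sample_total_area": 100.0}]
        )
        assert innervation_intensity(rec)[("ME", 4)] == pytest.approx(0.1)

    def test_count_per_area(self):
        rec = pd.DataFrame(
            [{"ending_type": "IGLE", "region": 6, "measure": 5.0, "sample_total_area": 50.0}]
        )
        assert innervation_intensity(rec)[("IGLE", 6)] == pytest.approx(0.1)

    def test_zero_measure_zero_intensity(self):
        rec = pd.DataFrame(
            [{"ending_type": "ME", "region": 4, "measure": 0.0, "sample_total_area": 10.0}]
        )
        assert innervation_intensity(rec)[("ME", 4)] == 0.0

    def test_zero_area_rejected(self):
        rec = pd.DataFrame(
            [{"ending_type": "ME", "region": 4, "measure": 1.0, "sample_total_area": 0.0}]
        )
        with pytest.raises(ValueError):
            innervation_intensity(rec)

    def test_replicates_averaged(self):
        rec = pd.DataFrame(
            [
                {"ending_type": "ME", "region": 4, "measure": 10.0, "sample_total_area": 100.0},
                {"ending_type": "ME", "region": 4, "measure": 30.0, "sample_total_area": 100.0},
            ]
        )
        assert innervation_intensity(rec)[("ME", 4)] == pytest.approx(0.2)


class TestAnatomicalFoldChange:
    def intensity(self, values):
        idx = pd.MultiIndex.from_tuples(values.keys())
        return pd.Series(list(values.values()), index=idx)

    def test_uniform_innervation_af_one(self):
        s = self.intensity({("ME", r): 0.2 for r in (*STOMACH_REGIONS, "whole")})
        af = anatomical_fold_change(s)
        assert all(af[("ME", r)] == pytest.approx(1.0) for r in STOMACH_REGIONS)

    def test_double_intensity_af_two(self):
        s = self.intensity({("ME", 4): 0.4, ("ME", "whole"): 0.2})
        assert anatomical_fold_change(s)[("ME", 4)] == pytest.approx(2.0)

    def test_absent_type_af_zero(self):
        s = self.intensity({("ME", 4): 0.0, ("ME", "whole"): 0.2})
        assert anatomical_fold_change(s)[("ME", 4)] == 0.0

    def test_zero_whole_intensity_missing(self):
        s = self.intensity({("ME", 4): 0.1, ("ME", "whole"): 0.0})
        assert np.isnan(anatomical_fold_change(s)[("ME", 4)])


class TestProjectionFoldChange:
    def test_forced_ratio(self):
        labels = labels_frame({"A": {"single_pct": 4.0, "dual_pct_4": 8.0,
                                     "dual_pct_6": 0, "dual_pct_7": 0, "dual_pct_8": 0}})
        sf = projection_fold_change({"A": "ME"}, labels)
        assert sf[("ME", 4)] == pytest.approx(2.0)

    def test_dual_equals_single_sf_one(self):
        labels = labels_frame(
            {"A": {"single_pct": 5.0, **{f"dual_pct_{r}": 5.0 for r in STOMACH_REGIONS}}}
        )
        sf = projection_fold_change({"A": "ME"}, labels)
        assert all(v == pytest.approx(1.0) for v in sf.values())

    def test_ratio_of_sums_not_sum_of_ratios(self):
        labels = labels_frame(
            {
                "A": {"single_pct": 1.0, "dual_pct_4": 2.0,
                      "dual_pct_6": 0, "dual_pct_7": 0, "dual_pct_8": 0},
                "B": {"single_pct": 2.0, "dual_pct_4": 4.0,
                      "dual_pct_6": 0, "dual_pct_7": 0, "dual_pct_8": 0},
            }
        )
        sf = projection_fold_change({"A": "ME", "B": "ME"}, labels)
        assert sf[("ME", 4)] == pytest.approx(6.0 / 3.0)

    def test_zero_single_sum_rejected(self):
        labels = labels_frame({"A": {"single_pct": 0.0,
                                     **{f"dual_pct_{r}": 1.0 for r in STOMACH_REGIONS}}})
        with pytest.raises(ValueError):
            projection_fold_change({"A": "ME"}, labels)

    def test_unknown_cluster_rejected(self):
        labels = labels_frame({"A": {"single_pct": 1.0,
                                     **{f"dual_pct_{r}": 1.0 for r in STOMACH_REGIONS}}})
        with pytest.raises(KeyError):
            projection_fold_change({"Z": "ME"}, labels)


class TestAssignmentVariance:
    def setup_tables(self, noise=0.0, seed=0):
        endings_df, labels, _ = generate_ending_tables(TRUE_ASSIGNMENT, seed=seed, noise_sd=noise)
        af = anatomical_fold_change(innervation_intensity(endings_df))
        return af, labels

    def test_sf_equals_af_gives_zero(self):
        af, labels = self.setup_tables()
        full = {**DEFAULT_FIXED_MAP, **TRUE_ASSIGNMENT}
        assert assignment_variance(full, af, labels) == pytest.approx(0.0, abs=1e-20)

    def test_single_discrepancy_squared(self):
        labels = labels_frame({"A": {"single_pct": 2.0, "dual_pct_4": 3.0,
                                     "dual_pct_6": 0, "dual_pct_7": 0, "dual_pct_8": 0}})
        af = {("ME", 4): 1.0, ("ME", 6): 0.0, ("ME", 7): 0.0, ("ME", 8): 0.0}
        # SF(ME,4) = 1.5, AF = 1.0 -> (0.5)^2
        assert assignment_variance({"A": "ME"}, af, labels) == pytest.approx(0.25)

    def test_double_loop_oracle(self):
        af, labels = self.setup_tables(noise=1.0, seed=3)
        full = {**DEFAULT_FIXED_MAP, **TRUE_ASSIGNMENT}
        sf = projection_fold_change(full, labels)
        oracle = 0.0
        for t in ENDING_TYPES:
            for r in STOMACH_REGIONS:
                oracle += (sf[(t, r)] - af[(t, r)]) ** 2
        assert assignment_variance(full, af, labels) == pytest.approx(oracle)

    def test_grid_iteration_order_irrelevant(self):
        af, labels = self.setup_tables(noise=0.5, seed=9)
        full = {**DEFAULT_FIXED_MAP, **TRUE_ASSIGNMENT}
        a = assignment_variance(full, af, labels)
        b = assignment_variance(full, af, labels,
                                regions=tuple(reversed(STOMACH_REGIONS)),
                                types=tuple(reversed(ENDING_TYPES)))
        assert a == pytest.approx(b)


class TestEnumeration:
    @pytest.mark.parametrize("k,m,count", [(7, 4, 16384), (1, 4, 4), (2, 3, 9), (0, 4, 1)])
    def test_counts(self, k, m, count):
        clusters = [f"c{i}" for i in range(k)]
        types = ENDING_TYPES[:m]
        seen = [tuple(a.items()) for a in enumerate_assignments(clusters, types)]
        assert len(seen) == count
        assert len(set(seen)) == count

    def test_full_enumeration_under_one_second(self):
        t0 = time.perf_counter()
        n = sum(1 for _ in enumerate_assignments([f"c{i}" for i in range(7)]))
        assert n == 16384
        assert time.perf_counter() - t0 < 1.0

    def test_lexicographic_order(self):
        first, second = itertools.islice(enumerate_assignments(["a", "b"]), 2)
        assert first == {"a": "ME", "b": "ME"}
        assert second == {"a": "ME", "b": "pIMA"}


class TestBestAssignment:
    def test_zero_noise_recovers_truth_with_exhaustive_check(self):
        endings_df, labels, truth = generate_ending_tables(TRUE_ASSIGNMENT, seed=1)
        af = anatomical_fold_change(innervation_intensity(endings_df))
        free = sorted(TRUE_ASSIGNMENT)
        best, var = best_assignment(af, labels, free, DEFAULT_FIXED_MAP)
        assert {c: best[c] for c in TRUE_ASSIGNMENT} == truth.assignment
        assert var == pytest.approx(0.0, abs=1e-18)

    def test_matches_shuffled_brute_force(self):
        # independent brute force (shuffled order, direct variance calls)
        # on a smaller free set where the full scan is cheap
        subset = {c: TRUE_ASSIGNMENT[c] for c in ("J2", "J4", "I2", "I4")}
        endings_df, labels, _ = generate_ending_tables(subset, seed=6, noise_sd=0.5)
        af = anatomical_fold_change(innervation_intensity(endings_df))
        free = sorted(subset)
        _, var = best_assignment(af, labels, free, DEFAULT_FIXED_MAP)
        rng = np.random.default_rng(0)
        trials = list(enumerate_assignments(free))
        rng.shuffle(trials)
        oracle = min(
            assignment_variance({**DEFAULT_FIXED_MAP, **t}, af, labels) for t in trials
        )
        assert var == pytest.approx(oracle, abs=1e-12)

    def test_exact_tie_breaks_lexicographically(self):
        # two ending types with identical AF profiles: ME and pIMA trials tie
        profiles = {t: {4: 1.0, 6: 1.0, 7: 1.0, 8: 1.0} for t in ENDING_TYPES}
        endings_df, labels, _ = generate_ending_tables(
            {"Z1": "ME"}, seed=2, af_profiles=profiles
        )
        af = anatomical_fold_change(innervation_intensity(endings_df))
        best, var = best_assignment(af, labels, ["Z1"], DEFAULT_FIXED_MAP)
        assert best["Z1"] == "ME"  # first type in canonical order wins the tie

    def test_all_fixed_returns_fixed_map(self):
        endings_df, labels, _ = generate_ending_tables(TRUE_ASSIGNMENT, seed=1)
        af = anatomical_fold_change(innervation_intensity(endings_df))
        fixed = {**DEFAULT_FIXED_MAP, **TRUE_ASSIGNMENT}
        best, var = best_assignment(af, labels, [], fixed)
        assert best == fixed
        assert var == pytest.approx(assignment_variance(fixed, af, labels), abs=1e-18)


class TestEnrichment:
    def test_single_mode_thresholds(self):
        pct = pd.DataFrame({"single_pct": [5.0, 3.9, 4.0]}, index=["a", "b", "c"])
        assert identify_enriched_clusters(pct, "single") == ["a"]

    def test_dual_mode_both_rules(self):
        pct = pd.DataFrame(
            {
                "dual_pct": [10.0, 10.0, 3.0],
                "single_pct_a": [4.0, 6.0, 1.0],
                "single_pct_b": [4.5, 4.0, 1.0],
            },
            index=["a", "b", "c"],
        )
        # b fails the 5-point margin against organ a; c fails the 4% rule
        assert identify_enriched_clusters(pct, "dual") == ["a"]

    def test_region5_mode(self):
        pct = pd.DataFrame(
            {
                "single_pct": [12.0, 12.0],
                "dual_pct_4": [5.0, 8.0],
                "dual_pct_6": [2.0, 2.0],
                "dual_pct_7": [2.0, 2.0],
                "dual_pct_8": [2.0, 2.0],
            },
            index=["a", "b"],
        )
        assert identify_enriched_clusters(pct, "region5") == ["a"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            identify_enriched_clusters(pd.DataFrame({"single_pct": [1.0]}), "nope")


class TestNormalizedInnervation:
    @pytest.mark.parametrize("cre,ref,expected", [(0.2, 0.2, 1.0), (0.1, 0.2, 0.5), (0.0, 0.2, 0.0)])
    def test_ratios(self, cre, ref, expected):
        assert normalized_innervation(cre, ref) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalized_innervation(1.0, 0.0)
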