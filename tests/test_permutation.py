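"""Monte-Carlo permutation testing, binomial bounds, subsampling, triads."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import seedspatial as ss
from seedspatial.cluster import ClusterAssignment
from seedspatial.errors import ParameterError
from seedspatial.permutation import (MACRO_GROUPS, adjust_bonferroni,
                                     binomial_ci_upper,
                                     exact_permutation_test,
                                     permutation_test, subsample_bins,
                                     triad_bias_report)

from conftest import make_binned


def assignment_for(labels, annotation):
    labels = np.asarray(labels)
    bins = pd.DataFrame({"bin_x": np.arange(len(labels)),
                         "bin_y": np.zeros(len(labels), int)})
    return ClusterAssignment(bins=bins, labels=labels, resolution=1.0,
                             seed=0,
                             retained={c: True for c in set(labels)},
                             annotation=annotation)


class TestSubsample:
    def _assignment(self, sizes):
        labels = np.repeat(np.arange(len(sizes)), sizes)
        return assignment_for(labels, {i: f"z{i}" for i in range(len(sizes))})

    def test_five_percent_of_hundred(self):
        sub = subsample_bins(self._assignment([100]), f=0.05, floor_min=1,
                             seed=0)
        assert len(sub.groups["z0"]) == 5

    def test_full_fraction_all_bins(self):
        sub = subsample_bins(self._assignment([30]), f=1.0, floor_min=1,
                             seed=0)
        assert len(sub.groups["z0"]) == 30

    def test_floor_min_applies(self):
        sub = subsample_bins(self._assignment([10]), f=0.05, floor_min=3,
                             seed=0)
        assert len(sub.groups["z0"]) == 3

    def test_capped_at_group_size(self):
        sub = subsample_bins(self._assignment([4]), f=0.05, floor_min=20,
                             seed=0)
        assert len(sub.groups["z0"]) == 4

    def test_deterministic_per_seed(self):
        a = self._assignment([50, 60])
        s1 = subsample_bins(a, f=0.1, floor_min=2, seed=5)
        s2 = subsample_bins(a, f=0.1, floor_min=2, seed=5)
        for g in s1.groups:
            assert np.array_equal(s1.groups[g], s2.groups[g])

    def test_without_replacement(self):
        sub = subsample_bins(self._assignment([40]), f=0.5, floor_min=1,
                             seed=1)
        idx = sub.groups["z0"]
        assert len(np.unique(idx)) == len(idx)


class TestPermutationTest:
    def test_degenerate_identical_values(self):
        r = permutation_test([3, 3, 3], [3, 3, 3], M=100, seed=0)
        assert r.t_obs == 0.0
        assert r.b == r.M
        assert r.p_hat == pytest.approx(1.0, abs=0.01)

    def test_converges_to_exact_third(self):
        # x=(0,0), y=(5,5): 2 of the C(4,2)=6 assignments reach |diff|=5
        r = permutation_test([0, 0], [5, 5], M=60_000, seed=1)
        assert r.p_hat == pytest.approx(1 / 3, abs=0.01)

    def test_within_three_se_of_enumeration(self):
        x, y = [0, 1, 2], [10, 11, 12]
        p_exact = exact_permutation_test(x, y)
        assert p_exact == pytest.approx(2 / 20)
        r = permutation_test(x, y, M=500_000, seed=2)
        se = np.sqrt(p_exact * (1 - p_exact) / r.M)
        assert abs(r.p_hat - p_exact) <= 3 * se

    def test_symmetry_in_arguments(self):
        x = [0, 3, 1, 7]
        y = [9, 12, 10]
        r1 = permutation_test(x, y, M=5000, seed=9)
        r2 = permutation_test(y, x, M=5000, seed=9)
        assert r1.t_obs == r2.t_obs
        assert r1.b == r2.b

    def test_minimum_sizes_enforced(self):
        with pytest.raises(ParameterError):
            permutation_test([1], [2, 3], M=10, seed=0)

    def test_p_hat_never_zero(self):
        r = permutation_test([0, 0, 0], [50, 50, 50], M=1000, seed=0)
        assert r.p_hat > 0
        assert r.ci_upper >= r.b / r.M


class TestExactTest:
    def test_identical_samples_p_one(self):
        assert exact_permutation_test([1, 2], [1, 2]) == 1.0

    def test_enumeration_bound(self):
        with pytest.raises(ParameterError):
            exact_permutation_test(np.zeros(15), np.ones(15))

    def test_small_sample_rejected(self):
        with pytest.raises(ParameterError):
            exact_permutation_test([1], [2])


class TestBinomialBound:
    def test_b_equals_m(self):
        assert binomial_ci_upper(10, 10) == 1.0

    def test_zero_exceedances_closed_form(self):
        # 1 - (alpha/2)**(1/M) at alpha = 0.001, M = 500000
        up = binomial_ci_upper(0, 500_000, level=0.999)
        assert up == pytest.approx(1.5202e-5, rel=1e-3)

    def test_strongest_contrast_survives_bonferroni(self):
        # b=0 at M=500000 stays significant after a 264-fold correction
        up = binomial_ci_upper(0, 500_000, level=0.999)
        assert adjust_bonferroni(up, 264) == pytest.approx(4.01e-3, rel=1e-2)
        assert adjust_bonferroni(up, 264) < 0.01

    @given(st.integers(0, 200), st.integers(1, 200))
    def test_bound_dominates_point_estimate(self, b, m):
        b = min(b, m)
        assert binomial_ci_upper(b, m) >= b / m - 1e-12


class TestBonferroni:
    @pytest.mark.parametrize("p,k,expected", [
        (0.5, 264, 1.0), (1e-5, 264, 2.64e-3), (0.2, 1, 0.2)])
    def test_values(self, p, k, expected):
        assert adjust_bonferroni(p, k) == pytest.approx(expected)

    def test_invalid_k(self):
        with pytest.raises(ParameterError):
            adjust_bonferroni(0.5, 0)


class TestTriadBiasReport:
    def _setup(self, rates, n_bins=60, seed=0):
        """Binned counts for a triad with the given per-bin Poisson rates."""
        rng = np.random.default_rng(seed)
        genes = [f"T_{s}" for s in rates]
        counts = np.column_stack([rng.poisson(r, n_bins)
                                  for r in rates.values()])
        binned = make_binned(counts, genes=genes)
        labels = np.repeat([0, 1], n_bins // 2)
        a = assignment_for(labels, {0: "endosperm", 1: "pericarp"})
        sub = subsample_bins(a, f=1.0, floor_min=2, seed=seed)
        return binned, sub

    def _triad(self, subs=("A", "B", "D")):
        return ss.HomeologTriad(
            "fam", *("T_" + s if s in subs else None for s in ("A", "B", "D")))

    def test_absent_homeolog_runs_remaining_pair(self):
        binned, sub = self._setup({"B": 5.0, "D": 50.0})
        rep = triad_bias_report([self._triad(("B", "D"))], binned, sub,
                                M=2000, seed=1, tissue_contrasts=False)
        assert len(rep.results) == 1
        assert "B vs D" in rep.results[0].comparison

    def test_single_homeolog_skipped(self):
        binned, sub = self._setup({"D": 5.0})
        rep = triad_bias_report([self._triad(("D",))], binned, sub,
                                M=1000, seed=1)
        assert rep.results == []
        assert len(rep.homeolog_totals) == 1

    def test_k_defaults_to_tests_executed(self):
        binned, sub = self._setup({"A": 2.0, "B": 2.0, "D": 2.0})
        rep = triad_bias_report([self._triad()], binned, sub, M=500,
                                seed=2, tissue_contrasts=True)
        # 3 homeologs x 1 group pair + 3 homeolog pairs
        assert len(rep.results) == 6
        assert rep.K == 6
        for r in rep.results:
            assert r.p_adj == pytest.approx(min(1.0, r.ci_upper * 6))

    def test_explicit_k_override(self):
        binned, sub = self._setup({"B": 1.0, "D": 1.0})
        rep = triad_bias_report([self._triad(("B", "D"))], binned, sub,
                                M=500, K=264, seed=3,
                                tissue_contrasts=False)
        assert rep.K == 264

    def test_strong_bias_detected(self):
        binned, sub = self._setup({"A": 4.0, "D": 4.0 * 8.69}, seed=5)
        rep = triad_bias_report([self._triad(("A", "D"))], binned, sub,
                                M=20_000, seed=5, tissue_contrasts=False)
        assert rep.results[0].p_adj < 0.01

    def test_homeolog_totals_reported(self):
        binned, sub = self._setup({"A": 1.0, "B": 2.0, "D": 3.0})
        rep = triad_bias_report([self._triad()], binned, sub, M=500, seed=0,
                                tissue_contrasts=False)
        tot = rep.homeolog_totals.set_index("subgenome")["total_mids"]
        raw = np.asarray(binned.counts.todense())
        assert tot["A"] == raw[:, 0].sum()
        assert tot["D"] == raw[:, 2].sum()


class TestMacroGroups:
    def test_covers_all_eight_zones(self):
        from seedspatial.synthetic import ZONE_NAMES
        assert set(MACRO_GROUPS) == set(ZONE_NAMES)
        assert set(MACRO_GROUPS.values()) == {"pericarp", "endosperm",
                                              "crease", "embryo"}
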