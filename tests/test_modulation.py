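import itertools

import numpy as np
import pytest
from scipy import stats

from serialseq import (
    auroc_value,
    bin_covariate,
    modulation_profile,
    permutation_regression,
    recruitment_fraction,
    z_difference_test,
)
from serialseq.spikes import AlignedRates


def brute_force_auroc(test, base):
    """Exhaustive pairwise win-fraction (ties count one half)."""
    wins = sum((t > b) + 0.5 * (t == b) for t in test for b in base)
    return wins / (len(test) * len(base))


class TestAuroc:
    def test_exchangeable_samples_give_half(self):
        x = [1.0, 2.0, 3.0]
        assert auroc_value(x, x) == 0.5

    def test_full_separation_gives_one(self):
        assert auroc_value([3, 4], [1, 2]) == 1.0

    def test_interleaved_case(self):
        # exhaustive count over 4 pairs: wins {3>2, 3>4? no, 1>2? no, 1>4? no} +
        # no ties -> AUROC 0.25... verified by the brute-force oracle below
        assert auroc_value([1, 3], [2, 4]) == brute_force_auroc([1, 3], [2, 4])

    def test_identical_constant_samples(self):
        assert auroc_value([5, 5, 5], [5, 5]) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9, 2)
        test = rng.integers(0, 6, n1).astype(float)  # many ties
        base = rng.integers(0, 6, n2).astype(float)
        got = auroc_value(test, base)
        assert got == pytest.approx(brute_force_auroc(test, base), abs=1e-12)
        from sklearn.metrics import roc_auc_score

        y = np.r_[np.ones(n1), np.zeros(n2)]
        assert got == pytest.approx(roc_auc_score(y, np.r_[test, base]), abs=1e-12)


def make_aligned(matrix, dt=0.01, pre=4.5):
    n = matrix.shape[1]
    return AlignedRates("u", "P1", (pre, -pre + (n - 1) * dt), -pre + np.arange(n) * dt, matrix)


class TestModulationProfile:
    def test_boxcar_modulation_detected_in_right_bins(self):
        rng = np.random.default_rng(0)
        X = rng.normal(10, 2, (20, 951))
        cols = (np.arange(951) * 0.01 - 4.5 >= 0) & (np.arange(951) * 0.01 - 4.5 < 0.5)
        X[:, cols] += 20.0
        prof = modulation_profile(make_aligned(X), seed=1)
        sig = prof.significant
        inside = (prof.bin_centers > 0.05) & (prof.bin_centers < 0.45)
        outside = (prof.bin_centers > 1.5) | (prof.bin_centers < -1.0)
        assert sig[inside].all()
        assert sig[outside].mean() < 0.2

    def test_too_few_trials_excluded_with_reason(self):
        X = np.random.default_rng(1).normal(10, 2, (4, 951))
        with pytest.raises(ValueError, match="excluded"):
            modulation_profile(make_aligned(X))

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """Small-n permutation p agrees with the full subset enumeration."""
        rng = np.random.default_rng(2)
        n_tr = 5
        X = rng.normal(5, 1, (n_tr, 951))
        prof = modulation_profile(make_aligned(X), n_perm=4000, seed=3)
        # recompute one bin exhaustively: combined = per-trial bin means +
        # pooled baseline bins, all C(n_tot, n_tr) relabelings
        j = 400
        w = 20
        first = int(np.searchsorted(make_aligned(X).bin_times, -4.0 - 1e-9))
        start = first + j
        test = X[:, start : start + w].mean(axis=1)
        bsel = np.arange(0, 40)
        base = X[:, bsel].reshape(n_tr, 2, w).mean(axis=2).ravel()
        combined = np.concatenate([test, base])
        ranks = stats.rankdata(combined)
        def dev(idx):
            u = ranks[list(idx)].sum() - n_tr * (n_tr + 1) / 2
            return abs(u / (n_tr * base.size) - 0.5)
        obs = dev(range(n_tr))
        devs = [dev(idx) for idx in itertools.combinations(range(combined.size), n_tr)]
        p_exact = np.mean([d >= obs - 1e-12 for d in devs])
        assert prof.p_perm[j] == pytest.approx(p_exact, abs=2 / np.sqrt(4000) + 1 / 4001)


class TestRecruitment:
    def test_fraction_arithmetic(self):
        from serialseq.modulation import ModulationProfile

        grid = np.arange(5) * 0.01
        profs = []
        for k in range(34):
            sig = np.zeros(5, bool)
            if k < 7:
                sig[2] = True
            profs.append(ModulationProfile("u", "a", grid, np.full(5, 0.5), np.ones(5), sig))
        _, pct = recruitment_fraction(profs)
        assert pct[2] == pytest.approx(100 * 7 / 34, abs=0.05)
        assert pct[0] == 0.0

    def test_all_significant_gives_100(self):
        from serialseq.modulation import ModulationProfile

        grid = np.arange(3) * 0.01
        profs = [
            ModulationProfile("u", "a", grid, np.full(3, 0.9), np.zeros(3), np.ones(3, bool))
            for _ in range(5)
        ]
        assert recruitment_fraction(profs)[1].tolist() == [100.0] * 3

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            recruitment_fraction([])


class TestBinCovariate:
    def test_press_counts_group_to_even_classes(self):
        labels, keep = bin_covariate(np.array([4, 5, 6]), "n_presses")
        assert labels.tolist() == [4.0, 6.0, 6.0]
        assert keep.all()

    def test_latency_below_first_class_joins_it(self):
        labels, _ = bin_covariate(np.array([0.4, 0.7, 1.6, 2.6]), "latency")
        assert labels.tolist() == [1.0, 1.0, 2.0, 3.0]

    def test_duration_seven_equal_count_descending(self):
        v = np.arange(14, dtype=float)
        labels, _ = bin_covariate(v, "sequence_duration")
        # class 1 = the two longest durations, class 7 = the two shortest
        assert (labels[v >= 12] == 1).all()
        assert (labels[v <= 1] == 7).all()
        assert np.bincount(labels.astype(int))[1:].tolist() == [2] * 7

    def test_undefined_values_dropped(self):
        labels, keep = bin_covariate(np.array([1.0, np.nan, 2.0]), "latency")
        assert keep.tolist() == [True, False, True]
        assert labels.size == 2


class TestPermutationRegression:
    def test_noiseless_recovery(self):
        duration = np.linspace(3, 8, 20)
        rate = 2 + 3 * duration
        res = permutation_regression(rate, duration, n_perm=500, seed=0)
        assert res.beta == pytest.approx(3.0)
        assert res.r == pytest.approx(1.0)
        assert res.accepted

    def test_constant_rates_not_accepted(self):
        res = permutation_regression(np.full(10, 4.0), np.arange(10), seed=0)
        assert res.beta == 0.0 and not res.accepted

    def test_monte_carlo_matches_exhaustive_at_n6(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=6)
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        exact = permutation_regression(y, x, exact=True, seed=0)
        mc = permutation_regression(y, x, n_perm=2000, seed=1)
        assert mc.p_perm == pytest.approx(exact.p_perm, abs=2 / np.sqrt(2000) + 1 / 2001)

    def test_r_squared_criterion_flag(self):
        rng = np.random.default_rng(5)
        x = np.repeat(np.arange(1, 8), 3).astype(float)
        y = 0.8 * x + rng.normal(0, 1.0, x.size)
        r = permutation_regression(y, x, seed=0, use_r_squared=False)
        r2 = permutation_regression(y, x, seed=0, use_r_squared=True)
        assert r.r**2 == pytest.approx(r2.r_squared)


class TestZDifference:
    def test_equal_means_give_zero_and_p_one(self):
        res = z_difference_test(1.3, 1.3, 20, 15)
        assert res.z_diff == 0.0 and res.p == 1.0

    def test_closed_form_value(self):
        res = z_difference_test(1.0, 0.0, 12, 12)
        assert res.z_diff == pytest.approx(1.0 / np.sqrt(2 / 9), abs=1e-9)
        assert res.p == pytest.approx(2 * stats.norm.sf(res.z_diff), abs=1e-12)

    def test_antisymmetry(self):
        a = z_difference_test(1.32, 0.55, 34, 26)
        b = z_difference_test(0.55, 1.32, 26, 34)
        assert a.z_diff == pytest.approx(-b.z_diff)
        assert a.p == pytest.approx(b.p)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            z_difference_test(1.0, 0.0, 3, 12)

    def test_literal_denominator_variant(self):
        res = z_difference_test(1.0, 0.0, 12, 12, denominator="literal")
        assert res.z_diff == pytest.approx(1.0 / np.sqrt(1 / 9 + 1 / 15))
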