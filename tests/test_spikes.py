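import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from serialseq import (
    DegenerateBaselineError,
    ModulationCategory,
    align_rates,
    build_template,
    categorize_unit,
    epoch_mean_z,
    rate_from_spikes,
    rescale_trial,
    trial_anchors,
    zscore_rows,
)
from serialseq.spikes import KERNEL_SIGMA, RateTrace


class TestRateFromSpikes:
    def test_single_spike_unit_mass(self):
        tr = rate_from_spikes(np.array([5.0]), (0.0, 10.0))
        assert np.trapezoid(tr.values, tr.times) == pytest.approx(1.0, abs=1e-6)

    def test_hundred_spikes_mass_linearity(self):
        rng = np.random.default_rng(0)
        tr = rate_from_spikes(np.sort(rng.uniform(1, 9, 100)), (0.0, 10.0))
        assert tr.integral() == pytest.approx(100.0, abs=0.01)

    def test_regular_comb_matches_closed_form(self):
        """10-Hz regular spiking: plateau equals the comb-kernel sum."""
        spikes = np.arange(0.05, 10.0, 0.1)
        tr = rate_from_spikes(spikes, (-1.0, 11.0))
        mid = (tr.times > 3) & (tr.times < 7)
        # independent oracle: truncated-Gaussian comb with discrete unit mass
        # per spike (spikes sit on the grid here, so the per-spike window is
        # the symmetric 21-sample stencil)
        sig = KERNEL_SIGMA
        stencil = np.arange(-10, 11) * 0.01
        norm = np.exp(-0.5 * (stencil / sig) ** 2).sum() * 0.01
        for t, v in zip(tr.times[mid][::37], tr.values[mid][::37]):
            d = t - spikes
            d = d[np.abs(d) <= 4 * sig + 1e-12]
            oracle = np.sum(np.exp(-0.5 * (d / sig) ** 2)) / norm
            assert v == pytest.approx(oracle, rel=1e-9)
        assert tr.values[mid].mean() == pytest.approx(10.0, rel=0.01)

    def test_empty_spike_list_gives_zero_trace(self):
        tr = rate_from_spikes(np.array([]), (0.0, 5.0))
        assert np.all(tr.values == 0)


class TestAlignRates:
    def constant_trace(self, level=5.0):
        return RateTrace(t0=0.0, dt=0.01, values=np.full(2001, level))

    def test_constant_trace_constant_rows(self):
        al = align_rates(self.constant_trace(), [8.0, 10.0, 12.0], (4.0, 5.0))
        assert np.all(al.matrix == 5.0)
        assert al.matrix.shape[0] == 3

    def test_anchor_at_edge_dropped_and_counted(self):
        al = align_rates(self.constant_trace(), [0.5, 10.0], (4.0, 5.0))
        assert al.matrix.shape[0] == 1 and al.n_dropped == 1

    def test_all_anchors_unsupported_raises(self):
        with pytest.raises(ValueError):
            align_rates(self.constant_trace(), [0.1], (4.0, 5.0))

    def test_bump_lands_at_offset_bin(self):
        tr = rate_from_spikes(np.array([10.5]), (0.0, 20.0))
        al = align_rates(tr, [10.0], (4.0, 5.0))
        assert al.bin_times[np.argmax(al.matrix[0])] == pytest.approx(0.5)


class TestZScore:
    def make_aligned(self, matrix):
        n = matrix.shape[1]
        from serialseq.spikes import AlignedRates

        return AlignedRates("u", "P1", (4.5, 5.0), -4.5 + np.arange(n) * 0.01, matrix)

    def test_rows_identical_to_baseline_give_zero(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 2, (6, 951))
        al = self.make_aligned(base.copy())
        z = zscore_rows(al, (-4.5, -4.0))
        bl = z.matrix[:, z.bin_times <= -4.0]
        assert abs(bl.mean()) < 1e-12

    def test_two_sd_above_mean_is_z_two(self):
        rng = np.random.default_rng(2)
        m = rng.normal(10, 2, (5, 951))
        al = self.make_aligned(m)
        z = zscore_rows(al, (-4.5, -4.0))
        sel = al.bin_times <= -4.0
        mu, sd = m[:, sel].mean(), m[:, sel].std(ddof=1)
        j = np.argmin(np.abs(al.bin_times - 2.0))
        expect = (m[0, j] - mu) / sd
        assert z.matrix[0, j] == pytest.approx(expect)
        # synthetic point exactly 2 sd above the mean maps to z = 2
        m2 = m.copy()
        m2[0, -1] = mu + 2 * sd
        z2 = zscore_rows(self.make_aligned(m2), (-4.5, -4.0))
        assert z2.matrix[0, -1] == pytest.approx(2.0, rel=1e-6)

    def test_silent_unit_flagged_excluded(self):
        with pytest.raises(DegenerateBaselineError):
            zscore_rows(self.make_aligned(np.zeros((5, 951))), (-4.5, -4.0))

    def test_inverse_transform_recovers_rates(self):
        rng = np.random.default_rng(3)
        m = rng.normal(8, 3, (5, 951))
        al = self.make_aligned(m)
        z = zscore_rows(al, (-4.5, -4.0))
        back = z.matrix * z.baseline_sd + z.baseline_mean
        assert np.abs(back - m).max() < 1e-9


class TestRescale:
    def bumpy_trace(self, seed=0, span=(0.0, 60.0)):
        rng = np.random.default_rng(seed)
        return rate_from_spikes(np.sort(rng.uniform(span[0] + 1, span[1] - 1, 300)), span)

    def test_identity_when_anchors_match_template(self):
        tr = self.bumpy_trace()
        tmpl = build_template([0.5], [1.0]) + 20.0
        res = rescale_trial(tr, tmpl, tmpl)
        direct = np.interp(res.times, tr.times, tr.values)
        assert np.abs(res.values - direct).max() < 1e-9

    def test_constant_rate_stays_constant(self):
        tr = RateTrace(0.0, 0.01, np.full(6001, 7.0))
        res = rescale_trial(tr, [10, 10.6, 12.0, 12.7, 14.0, 14.5, 15.5, 16.0], build_template([0.5], [1.0]))
        assert np.all(res.values == 7.0)

    def test_linear_ramp_stretched_stays_linear(self):
        """Linear-interpolation oracle: a x2-stretched ramp keeps its endpoints."""
        values = np.interp(np.arange(0, 30, 0.01), [10, 12], [0, 20], left=0, right=20)
        tr = RateTrace(0.0, 0.01, values)
        trial = [10.0, 10.5, 11.5, 12.0, 14.0, 14.5, 15.5, 16.0]
        template = np.array([0.0, 1.0, 3.0, 4.0, 6.0, 7.0, 9.0, 10.0])  # S1 stretched x2
        res = rescale_trial(tr, trial, template)
        a, b = res.anchor_positions[0], res.anchor_positions[3]
        seg = res.values[a : b + 1]
        # endpoints preserved and the segment remains a straight line
        assert seg[0] == pytest.approx(0.0, abs=1e-9)
        assert seg[-1] == pytest.approx(20.0, abs=1e-9)
        fit = np.polyval(np.polyfit(np.arange(seg.size), seg, 1), np.arange(seg.size))
        assert np.abs(seg - fit).max() < 1e-6

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_anchor_values_preserved_exactly(self, seed):
        rng = np.random.default_rng(seed)
        tr = self.bumpy_trace(seed=seed)
        ipis1 = rng.uniform(0.2, 1.0, 3)
        trans = rng.uniform(0.3, 2.0)
        ipis2 = rng.uniform(0.2, 1.0, 3)
        start = rng.uniform(5, 40)
        anchors = start + np.concatenate([[0], np.cumsum(np.concatenate([ipis1, [trans], ipis2]))])
        tmpl = build_template([0.5], [1.0])
        res = rescale_trial(tr, anchors, tmpl)
        expect = np.interp(anchors, tr.times, tr.values)
        got = res.values[res.anchor_positions]
        assert np.array_equal(got, expect)

    def test_duplicate_anchor_collapsed(self):
        tr = RateTrace(0.0, 0.01, np.full(4001, 3.0))
        trial = [10.0, 10.5, 10.5, 11.0, 12.0, 12.5, 13.0, 13.5]  # P2 == PLast-1
        res = rescale_trial(tr, trial, build_template([0.5], [1.0]))
        assert res.anchor_positions[1] == res.anchor_positions[2]
        assert np.all(res.values == 3.0)

    def test_non_monotonic_anchors_raise(self):
        tr = RateTrace(0.0, 0.01, np.zeros(4001))
        with pytest.raises(ValueError):
            rescale_trial(tr, [10, 9, 11, 12, 13, 14, 15, 16], build_template([0.5], [1.0]))


class TestTemplate:
    def test_mean_of_two_ipis(self):
        tmpl = build_template([0.4, 0.6], [1.0])
        assert np.diff(tmpl)[:3] == pytest.approx([0.5, 0.5, 0.5])
        assert tmpl[4] - tmpl[3] == pytest.approx(1.0)

    def test_identical_trials_reproduce_their_anchors(self):
        anchors = trial_anchors([0.0, 0.5, 1.0, 1.5], [2.5, 3.0, 3.5, 4.0])
        tmpl = build_template([0.5], [1.0])
        np.testing.assert_allclose(tmpl, anchors)

    def test_simulator_means_recovered(self):
        from serialseq import Block, Classification, PerformerModel, parse_trials, simulate_session

        m = PerformerModel()
        trials = parse_trials(simulate_session(m, n_rewards_target=120, seed=6))
        ipis = np.concatenate([t.ipis for t in trials if t.classification is Classification.CORRECT])
        trans = np.array(
            [t.transition for t in trials if t.classification is Classification.CORRECT]
        )
        tmpl = build_template(ipis, trans)
        se_i = ipis.std() / np.sqrt(ipis.size)
        se_t = trans.std() / np.sqrt(trans.size)
        assert abs((tmpl[1] - tmpl[0]) - m.ipi_mean) < 3 * se_i + 1e-9
        assert abs((tmpl[4] - tmpl[3]) - m.transition_mean) < 3 * se_t + 1e-9


class TestCategorize:
    @pytest.mark.parametrize(
        "z, expected",
        [
            ((2.5, 2.5, 0, 0), ModulationCategory.INIT_S1_EXECUTION),
            ((0, 0, 0, 0), ModulationCategory.NONE),
            ((0, 2.1, 0, 2.1), ModulationCategory.S1_S2_EXECUTION),
            ((2.2, 0, 2.4, 0), ModulationCategory.INIT_S1_S2),
            ((0, 0, 2.5, 0), ModulationCategory.TRANSITION_INIT_S2),
            ((0, 0, 0, 3.0), ModulationCategory.S2_EXECUTION),
            ((-2.5, 0, 0, -2.1), ModulationCategory.NEGATIVE),
        ],
    )
    def test_taxonomy(self, z, expected):
        assert categorize_unit(z) is expected

    def test_invariant_to_scaling_above_threshold(self):
        z = np.array([2.5, 2.5, 0.4, 0.1])
        assert categorize_unit(z) is categorize_unit(z * 3)

    def test_epoch_means_from_rescaled_profile(self):
        tmpl = build_template([0.5], [1.0])
        tr = RateTrace(-3.0, 0.01, np.zeros(1501))
        res = rescale_trial(tr, tmpl, tmpl)
        vals = np.zeros_like(res.values)
        p = res.anchor_positions
        vals[p[0] : p[3] + 1] = 3.0  # S1 epoch only
        epochs = epoch_mean_z(vals, res.times, p)
        assert epochs["s1"] == pytest.approx(3.0)
        assert epochs["init"] == pytest.approx(0.0)
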