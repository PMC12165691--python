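"""Epoching, re-referencing, ERP removal and artifact exclusion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alphaprf import GroundTruthElectrode, StimulusDesign, simulate_experiment
from alphaprf.preprocess import (
    VoltageEpochs,
    epoch_and_baseline_correct,
    epoch_recording,
    estimate_onset_shift,
    exclude_noisy_epochs,
    flag_high_variance_electrodes,
    regress_out_erp,
    rereference_common_average,
)


def _toy_epochs(data, blank, rate=512.0):
    times = -0.2 + np.arange(data.shape[2]) / rate
    meta = pd.DataFrame({"step": np.arange(len(blank)), "blank": blank, "run": 0})
    return VoltageEpochs(data, times, rate, meta)


class TestRereference:
    def test_zero_mean_per_sample(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((4, 100))
        out = rereference_common_average(v)
        assert np.abs(out.mean(axis=0)).max() < 1e-12

    def test_antisymmetric_pair_unchanged(self):
        v = np.vstack([np.sin(np.arange(50.0)), -np.sin(np.arange(50.0))])
        assert np.allclose(rereference_common_average(v), v)

    def test_common_offset_removed_and_idempotent(self):
        v = np.ones((3, 20)) * 5.0 + np.arange(3)[:, None]
        out = rereference_common_average(v)
        assert np.allclose(out.mean(axis=0), 0.0)
        assert np.allclose(rereference_common_average(out), out)

    def test_singleton_group_warns(self):
        v = np.random.default_rng(1).standard_normal((3, 10))
        with pytest.warns(UserWarning):
            out = rereference_common_average(v, groups=[np.array([0]), np.array([1, 2])])
        assert np.allclose(out[0], v[0])


class TestOnsetShift:
    def test_constructed_delay_recovered(self):
        rate = 512.0
        t = np.arange(int(rate)) / rate
        a = np.exp(-t / 0.1) * np.sin(2 * np.pi * 10 * t)
        shift = int(round(0.072 * rate))  # 72 ms
        b = np.roll(a, shift)
        lag, _ = estimate_onset_shift(a, b, rate)
        assert abs(lag - 72.0) <= 1e3 / rate  # within one sample

    def test_identical_waveforms_zero_lag(self):
        a = np.sin(np.arange(100.0) / 7)
        lag, _ = estimate_onset_shift(a, a, 512.0)
        assert lag == 0.0

    def test_polarity_flip_still_detected(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(300)
        b = -np.roll(a, 10)
        lag, _ = estimate_onset_shift(a, b, 512.0)
        assert lag == pytest.approx(10 / 512.0 * 1e3)

    def test_flat_waveform_rejected(self):
        with pytest.raises(ValueError):
            estimate_onset_shift(np.zeros(50), np.ones(50), 512.0)

    def test_bootstrap_ci_brackets_lag(self):
        rate = 512.0
        t = np.arange(int(rate)) / rate
        base = np.exp(-t / 0.1) * np.sin(2 * np.pi * 10 * t)
        rng = np.random.default_rng(3)
        a = base + 0.05 * rng.standard_normal((6, t.size))
        b = np.roll(base, 37) + 0.05 * rng.standard_normal((6, t.size))
        lag, ci = estimate_onset_shift(a, b, rate, n_boot=50, rng=0)
        assert ci[0] <= lag <= ci[1]


class TestEpoching:
    def test_constant_signal_gives_zero_epochs(self):
        events = pd.DataFrame({"onset": [1.0, 2.0], "step": [0, 1], "blank": [False, True]})
        ep = epoch_and_baseline_correct(np.full((2, 2000), 3.3), events, 512.0)
        assert np.allclose(ep.data, 0.0)

    def test_step_function_baseline_and_height(self):
        rate = 512.0
        v = np.zeros((1, 2048))
        onset = 2.0
        v[0, int(onset * rate):] = 1.0
        events = pd.DataFrame({"onset": [onset], "step": [0], "blank": [False]})
        ep = epoch_and_baseline_correct(v, events, rate)
        pre = ep.data[0, 0, ep.times < 0]
        post = ep.data[0, 0, ep.times >= 0]
        assert np.allclose(pre, 0.0)
        assert np.allclose(post, 1.0)

    def test_full_run_yields_224_epochs_of_one_second(self, design):
        rec = simulate_experiment(design, [GroundTruthElectrode()], seed=1)
        ep = epoch_recording(rec)
        assert ep.n_epochs == 224
        assert ep.data.shape[2] == 512  # [-0.2, 0.8) at 512 Hz, half-open
        assert np.abs(ep.data[:, :, ep.times < 0].mean(axis=2)).max() < 1e-10

    def test_out_of_bounds_event_dropped(self):
        events = pd.DataFrame({"onset": [0.05, 1.0], "step": [0, 1], "blank": [False, False]})
        ep = epoch_and_baseline_correct(np.zeros((1, 1024)), events, 512.0)
        assert ep.n_epochs == 1


class TestERPRegression:
    def test_epoch_equal_to_erp_removed(self):
        t = np.linspace(0, 1, 512)
        erp = np.sin(2 * np.pi * 5 * t)
        data = np.tile(erp, (6, 1, 1))  # 6 epochs, 1 electrode
        ep = _toy_epochs(data, blank=[False] * 3 + [True] * 3)
        out = regress_out_erp(ep)
        assert np.abs(out.data).max() < 1e-12

    def test_orthogonal_epoch_unchanged(self):
        n = 512
        erp = np.sin(2 * np.pi * 4 * np.arange(n) / n)
        orth = np.cos(2 * np.pi * 4 * np.arange(n) / n)
        # stimulus epochs: erp +/- orth (mean = erp); blanks zero-mean pair
        data = np.stack([erp + orth, erp - orth, orth, -orth])[:, None, :]
        ep = _toy_epochs(data, blank=[False, False, True, True])
        out = regress_out_erp(ep)
        assert np.allclose(out.data[0, 0], orth, atol=1e-10)
        assert np.allclose(out.data[1, 0], -orth, atol=1e-10)

    def test_blank_epochs_nearly_unchanged_without_evoked_component(self, design):
        # with no evoked response the blank "ERP" is just a noise average:
        # subtracting it barely changes blanks, and even the amplitude-fitted
        # projection leaves the epochs strongly correlated with the originals
        el = GroundTruthElectrode(erp_gain=0.0, alpha_rms=0.0)
        rec = simulate_experiment(design, [el], n_runs=3, seed=6)
        ep = epoch_recording(rec)
        blank = ep.metadata["blank"].to_numpy()
        orig = ep.data[blank]
        sub = regress_out_erp(ep, mode="subtract").data[blank]
        assert np.linalg.norm(sub - orig) / np.linalg.norm(orig) < 0.1
        proj = regress_out_erp(ep).data[blank]
        assert np.corrcoef(proj.ravel(), orig.ravel())[0, 1] > 0.9

    def test_residual_power_never_exceeds_original(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((40, 2, 256))
        ep = _toy_epochs(data, blank=[False] * 20 + [True] * 20, rate=512.0)
        out = regress_out_erp(ep)
        p_in = (ep.data**2).sum(axis=2)
        p_out = (out.data**2).sum(axis=2)
        assert np.all(p_out <= p_in + 1e-9)

    def test_subtract_mode_is_unit_beta(self):
        t = np.linspace(0, 1, 256)
        erp = np.sin(2 * np.pi * 3 * t)
        data = np.stack([2 * erp, 0 * erp, 0 * t, 0 * t])[:, None, :]
        ep = _toy_epochs(data, blank=[False, False, True, True])
        out = regress_out_erp(ep, mode="subtract")
        assert np.allclose(out.data[0, 0], erp, atol=1e-12)


class TestNoisyEpochExclusion:
    def _noise_epochs(self, n=500, seed=0, rate=512.0):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n, 1, 512))
        blank = [False] * (n - 50) + [True] * 50
        return _toy_epochs(data, blank=blank, rate=rate)

    def test_homogeneous_noise_keeps_everything(self):
        ep = self._noise_epochs()
        keep, params = exclude_noisy_epochs(ep, tail_prob=1e-4)
        assert (~keep).sum() == 0

    def test_planted_outlier_excluded(self):
        # 10x amplitude (100x peak power) among 500 epochs: far beyond the
        # fitted tail even after the evoked average absorbs part of it
        ep = self._noise_epochs(seed=1)
        ep.data[100] *= 10.0
        keep, _ = exclude_noisy_epochs(ep, tail_prob=1e-4)
        assert not keep[100, 0]
        assert (~keep).sum() <= 3

    def test_threshold_matches_analytic_quantile(self):
        # maxima drawn from a known inverse Gaussian: the fitted threshold
        # approaches the analytic (1 - p) quantile of the true distribution
        mu_t, lam_t = 2.0, 5.0
        rng = np.random.default_rng(2)
        n = 20000
        maxima = stats.invgauss.rvs(mu_t / lam_t, scale=lam_t, size=n, random_state=rng)
        data = np.zeros((n, 1, 512))
        data[:, 0, 200] = np.sqrt(maxima)  # peak power = planted value
        ep = _toy_epochs(data, blank=[False] * n)
        # add 2 blank epochs to satisfy the ERP split
        ep.data = np.concatenate([ep.data, np.zeros((2, 1, 512))])
        ep.metadata = pd.concat(
            [ep.metadata, pd.DataFrame({"step": [0, 1], "blank": [True, True], "run": 0})],
            ignore_index=True,
        )
        _, params = exclude_noisy_epochs(ep, tail_prob=1e-4)
        q_true = stats.invgauss.ppf(1 - 1e-4, mu_t / lam_t, scale=lam_t)
        assert params["threshold"].iloc[0] == pytest.approx(q_true, rel=0.1)

    def test_degenerate_maxima_warns_and_keeps(self):
        data = np.ones((30, 1, 512))
        ep = _toy_epochs(data, blank=[False] * 25 + [True] * 5)
        with pytest.warns(UserWarning):
            keep, _ = exclude_noisy_epochs(ep)
        assert keep.all()


class TestHighVarianceFlag:
    def test_identical_variances_unflagged(self):
        assert not flag_high_variance_electrodes(np.ones(10)).any()

    def test_single_outlier_flagged(self):
        v = np.ones(50)
        v[7] = 10.0
        flags = flag_high_variance_electrodes(v)
        assert flags[7] and flags.sum() == 1

    def test_scaling_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(1, 2, 30)
        v[3] = 50.0
        assert np.array_equal(
            flag_high_variance_electrodes(v), flag_high_variance_electrodes(1e6 * v)
        )

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(ValueError):
            flag_high_variance_electrodes(np.ones(3))
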