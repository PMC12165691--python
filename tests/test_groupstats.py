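"""Selection thresholds, pRF-pair geometry, bootstrap comparisons."""

import numpy as np
import pytest

from alphaprf.groupstats import (
    ElectrodeRecord,
    SelectionThresholds,
    bootstrap_area_comparison,
    circular_corrcoef,
    normalize_prf_pair,
    prf_overlap_percent,
    select_electrodes,
    shuffle_null_threshold,
    shuffled_overlap_control,
    size_eccentricity_regression,
    wrap_angle_deg,
)
from alphaprf.prf import PRFFit, PRFParams, dog_response


def _record(i, bb_xy=(2.0, 1.0), al_xy=None, bb_sigma=1.0, al_sigma=2.0,
            r2_bb=0.8, r2_al=0.6, probs=None):
    al_xy = bb_xy if al_xy is None else al_xy
    fits = {
        "broadband": PRFFit(PRFParams(*bb_xy, bb_sigma, 1.0, 0.0), r2_bb,
                            np.zeros(5), np.zeros(5), r2_cv=r2_bb),
        "alpha": PRFFit(PRFParams(*al_xy, al_sigma, 1.0, 0.0, "negative"), r2_al,
                        np.zeros(5), np.zeros(5), r2_cv=r2_al),
    }
    return ElectrodeRecord(i, fits, probs or {})


class TestShuffleNull:
    def test_exchangeable_electrodes_give_threshold_at_real_accuracy(self, stim_matrix):
        series = dog_response(stim_matrix, PRFParams(2.0, 1.0, 1.5, 1.0, 0.001))
        n = 12
        S = np.tile(series, (n, 1))
        thr, null = shuffle_null_threshold(S, S, n_shuffles=20, seed=0)
        assert thr == pytest.approx(1.0)

    def test_heterogeneous_prfs_give_low_null(self, stim_matrix):
        rng = np.random.default_rng(1)
        params = [PRFParams(x, y, 1.2, 1.0, 0.001)
                  for x, y in rng.uniform(-5, 5, (10, 2))]
        series = np.array([dog_response(stim_matrix, p) for p in params])
        thr, null = shuffle_null_threshold(series, series, n_shuffles=50, seed=0)
        real = np.array([1.0] * 10)  # own-prediction accuracy is perfect here
        assert np.median(null) <= 0.5
        assert thr < real.min()

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(2)
        s = rng.standard_normal((6, 75))
        p = rng.standard_normal((6, 75))
        t1, _ = shuffle_null_threshold(s, p, n_shuffles=30, seed=7)
        t2, _ = shuffle_null_threshold(s, p, n_shuffles=30, seed=7)
        assert t1 == t2


class TestSelection:
    def test_good_electrode_kept(self):
        keep, reasons = select_electrodes([_record(0)], SelectionThresholds(0.3, 0.2))
        assert keep[0] and reasons[0] == "kept"

    def test_eccentric_center_excluded(self):
        rec = _record(0, bb_xy=(9.0, 0.5))
        keep, reasons = select_electrodes([rec], SelectionThresholds(0.3, 0.2))
        assert not keep[0] and "eccentricity" in reasons[0]

    def test_threshold_tie_excluded(self):
        rec = _record(0, r2_bb=0.3)
        keep, reasons = select_electrodes([rec], SelectionThresholds(0.3, 0.2))
        assert not keep[0] and "accuracy" in reasons[0]

    def test_missing_fit_reported(self):
        rec = _record(0)
        del rec.fits["alpha"]
        keep, reasons = select_electrodes([rec], SelectionThresholds(0.3, 0.2))
        assert not keep[0] and "missing" in reasons[0]

    def test_selection_is_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        recs = [
            _record(i, bb_xy=tuple(rng.uniform(-6, 6, 2)),
                    r2_bb=rng.uniform(0, 1), r2_al=rng.uniform(0, 1))
            for i in range(30)
        ]
        k_low, _ = select_electrodes(recs, SelectionThresholds(0.2, 0.1))
        k_high, _ = select_electrodes(recs, SelectionThresholds(0.5, 0.4))
        assert not np.any(k_high & ~k_low)


class TestNormalization:
    def test_broadband_lands_at_zero_one(self):
        bb = PRFParams(3.0, 4.0, 1.5, 1.0, 0.0)
        al = PRFParams(2.0, 5.0, 3.0, 1.0, 0.0)
        nb, na = normalize_prf_pair(bb, al)
        assert nb.x == pytest.approx(0.0, abs=1e-12)
        assert nb.y == pytest.approx(1.0)
        assert nb.sigma == pytest.approx(1.5 / 5.0)

    def test_identical_pair_maps_together(self):
        bb = PRFParams(-2.0, 1.0, 1.0, 1.0, 0.0)
        nb, na = normalize_prf_pair(bb, bb)
        assert na.x == pytest.approx(nb.x) and na.y == pytest.approx(nb.y)

    def test_center_distance_ratio_preserved(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            bx, by, ax, ay = rng.uniform(-5, 5, 4)
            if np.hypot(bx, by) < 1e-3:
                continue
            bb = PRFParams(bx, by, 1.0, 1.0, 0.0)
            al = PRFParams(ax, ay, 2.0, 1.0, 0.0)
            nb, na = normalize_prf_pair(bb, al)
            before = np.hypot(bx - ax, by - ay) / np.hypot(bx, by)
            after = np.hypot(nb.x - na.x, nb.y - na.y)
            assert after == pytest.approx(before, rel=1e-9)

    def test_origin_rejected(self):
        with pytest.raises(ValueError):
            normalize_prf_pair(PRFParams(0, 0, 1, 1, 0), PRFParams(1, 1, 1, 1, 0))


class TestOverlap:
    def test_identical_disks_full_overlap(self):
        p = PRFParams(1.0, 1.0, 2.0, 1.0, 0.0)
        assert prf_overlap_percent(p, p) == pytest.approx(100.0)

    def test_disjoint_disks_no_overlap(self):
        a = PRFParams(0.0, 0.0, 1.0, 1.0, 0.0)
        b = PRFParams(5.0, 0.0, 1.0, 1.0, 0.0)
        assert prf_overlap_percent(a, b) == 0.0

    def test_contained_disk_full_overlap(self):
        inner = PRFParams(0.0, 0.0, 1.0, 1.0, 0.0)
        outer = PRFParams(0.0, 0.5, 2.0, 1.0, 0.0)
        assert prf_overlap_percent(inner, outer) == pytest.approx(100.0)

    def test_partial_overlap_matches_monte_carlo(self):
        inner = PRFParams(0.0, 0.0, 1.0, 1.0, 0.0)
        outer = PRFParams(0.0, 1.2, 1.5, 1.0, 0.0)
        exact = prf_overlap_percent(inner, outer)
        rng = np.random.default_rng(5)
        pts = rng.uniform(-1, 1, (1_000_000, 2))
        inside_inner = (pts**2).sum(axis=1) <= 1.0
        inside_outer = (pts[:, 0] ** 2 + (pts[:, 1] - 1.2) ** 2) <= 1.5**2
        mc = 100.0 * (inside_inner & inside_outer).sum() / inside_inner.sum()
        assert exact == pytest.approx(mc, abs=0.1)

    def test_truncation_scales_radii(self):
        a = PRFParams(0.0, 0.0, 1.0, 1.0, 0.0)
        b = PRFParams(3.0, 0.0, 1.0, 1.0, 0.0)
        assert prf_overlap_percent(a, b, truncation=1.0) == 0.0
        assert prf_overlap_percent(a, b, truncation=2.0) > 0.0


class TestShuffledOverlap:
    def test_identical_records_unchanged_by_shuffling(self):
        recs = [_record(i) for i in range(5)]
        matched = np.mean([
            prf_overlap_percent(r.fits["alpha"].params, r.fits["broadband"].params)
            for r in recs
        ])
        shuffled = shuffled_overlap_control(recs, n_shuffles=20, seed=0)
        assert shuffled == pytest.approx(matched)

    def test_scattered_cohort_drops_under_shuffling(self):
        rng = np.random.default_rng(6)
        recs = []
        for i in range(12):
            xy = tuple(rng.uniform(-6, 6, 2))
            recs.append(_record(i, bb_xy=xy, al_xy=xy))
        matched = np.mean([
            prf_overlap_percent(r.fits["alpha"].params, r.fits["broadband"].params)
            for r in recs
        ])
        shuffled = shuffled_overlap_control(recs, n_shuffles=50, seed=0)
        assert shuffled < 0.5 * matched

    def test_two_records_deterministic_swap(self):
        recs = [_record(0, bb_xy=(1, 0)), _record(1, bb_xy=(4, 0))]
        v1 = shuffled_overlap_control(recs, n_shuffles=5, seed=0)
        v2 = shuffled_overlap_control(recs, n_shuffles=50, seed=99)
        assert v1 == pytest.approx(v2)


class TestCircularStats:
    def test_wrap_range(self):
        assert wrap_angle_deg(190.0) == pytest.approx(-170.0)
        assert wrap_angle_deg(-190.0) == pytest.approx(170.0)
        assert wrap_angle_deg(180.0) == pytest.approx(180.0)

    def test_identical_angles_correlate_perfectly(self):
        a = np.array([10.0, 100.0, 250.0, 355.0, 30.0])
        assert circular_corrcoef(a, a) == pytest.approx(1.0)

    def test_wraparound_handled(self):
        a = np.array([350.0, 355.0, 0.0, 5.0, 10.0])
        b = (a + 3.0) % 360.0
        assert circular_corrcoef(a, b) > 0.99


class TestBootstrapAreas:
    def _records(self, n, probs):
        rng = np.random.default_rng(7)
        recs = []
        for i in range(n):
            xy = tuple(rng.uniform(-5, 5, 2))
            recs.append(_record(i, bb_xy=xy, al_xy=xy, probs=dict(probs)))
        return recs

    def test_degenerate_probabilities_use_every_draw(self):
        recs = self._records(10, {"V1-V3": 1.0})
        out = bootstrap_area_comparison(recs, n_boot=50, seed=0)
        assert set(out.samples) == {"V1-V3"}
        assert len(out.samples["V1-V3"]["size"]) == 50 * 10

    def test_even_split_follows_binomial_law(self):
        recs = self._records(40, {"V1-V3": 0.5, "dorsolateral": 0.5})
        out = bootstrap_area_comparison(recs, n_boot=200, seed=1)
        n_v1 = len(out.samples["V1-V3"]["size"]) / 200
        assert n_v1 == pytest.approx(20.0, abs=3 * np.sqrt(40 * 0.25) / np.sqrt(200) * 5)

    def test_matched_cohort_correlates(self):
        recs = self._records(15, {"V1-V3": 1.0})
        out = bootstrap_area_comparison(recs, n_boot=100, seed=2)
        assert out.correlations["V1-V3"]["eccentricity"] > 0.99
        assert out.correlations["V1-V3"]["angle"] > 0.99


class TestSizeEccentricityRegression:
    def test_exact_line_recovered_with_zero_width_band(self):
        ecc = np.linspace(1, 8, 20)
        size = 0.5 * ecc + 0.3
        out = size_eccentricity_regression(ecc, size, n_boot=100, seed=0)
        assert out["slope"] == pytest.approx(0.5, abs=1e-9)
        assert np.allclose(out["band"][0], out["band"][1])

    def test_slope_ratio_recovered_from_noisy_cohorts(self):
        rng = np.random.default_rng(8)
        n = 50
        ecc = rng.uniform(1, 8, n)
        bb = 0.2 * ecc + 0.5
        al = 0.6 * ecc + 0.5
        bb_n = bb * (1 + 0.2 * rng.standard_normal(n))
        al_n = al * (1 + 0.2 * rng.standard_normal(n))
        s_bb = size_eccentricity_regression(ecc, bb_n, n_boot=200, seed=1)["slope"]
        s_al = size_eccentricity_regression(ecc, al_n, n_boot=200, seed=2)["slope"]
        assert 2.0 <= s_al / s_bb <= 4.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            size_eccentricity_regression(np.arange(4), np.arange(4))
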