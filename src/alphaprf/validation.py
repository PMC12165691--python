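"""Ground-truth validation suites: each function runs one slice of the
pipeline against synthetic data with known answers and returns the measured
quantities as a flat dict of floats.

These are the package's own checks of its scientific claims: design
arithmetic of the bar-sweep protocol, invertibility of the spectral
decomposition, the cancellation case that motivates model-based alpha
estimation, end-to-end pRF recovery on a simulated cohort, false-positive
calibration of the shuffle-null selection, and the coherence estimator's
invariants and distance-decay recovery.
"""

from __future__ import annotations

import numpy as np

from . import coherence as coh
from . import decompose, groupstats, preprocess, prf, spectral
from .pipeline import analyze_recording
from .synth import (
    StimulusDesign,
    generate_aperture_sequence,
    make_cohort,
    run_duration,
    simulate_experiment,
    simulate_grid,
)

__all__ = [
    "stimulus_design_arithmetic",
    "decomposition_recovery",
    "cancellation_demonstration",
    "prf_noiseless_recovery",
    "cohort_recovery",
    "null_calibration",
    "coherence_validation",
]

FREQS = np.arange(1, 251, dtype=float)


def stimulus_design_arithmetic() -> dict:
    """Step counts, run duration and series lengths implied by the protocol."""
    design = StimulusDesign()
    seq = generate_aperture_sequence(design)
    n75 = decompose.decimate_series(np.zeros(len(seq)), 3).size
    return {
        "steps_per_run": len(seq),
        "blank_steps": int(seq.blank.sum()),
        "run_duration_s": run_duration(design),
        "summary_points": n75,
        "cv_half_long": prf.CV_SPLIT,
        "cv_half_short": n75 - prf.CV_SPLIT,
    }


def decomposition_recovery(seed: int = 0, n_trials: int = 500,
                           noise_sd: float = 0.05) -> dict:
    """Invert model-generated spectra, noiseless and with log-domain noise."""
    true = np.array([0.3, 0.2, -0.5, np.log10(10.0), 0.05])
    k = np.log10(FREQS)
    pb = FREQS**-1.0
    ps = pb * 10 ** decompose.spectral_model(k, true)
    fit = decompose.fit_electrode_alpha_peak(ps, pb, FREQS)
    exact_err = float(np.abs(
        np.array([fit.broadband_low, fit.slope, fit.alpha_amp, fit.mu, fit.sigma])
        - true
    ).max())

    rng = np.random.default_rng(seed)
    band = (FREQS >= 3) & (FREQS <= 26)
    errs = np.empty(n_trials)
    for i in range(n_trials):
        p = true.copy()
        p[2] = rng.uniform(-0.8, 0.0)  # vary the suppression being recovered
        y = decompose.spectral_model(k, p)
        y[band] = y[band] + noise_sd * rng.standard_normal(band.sum())
        tfit = decompose.decompose_trial(pb * 10**y, pb, FREQS, 10.0)
        errs[i] = abs(tfit.alpha_amp - p[2])
    return {
        "exact_recovery_max_error": exact_err,
        "noisy_beta_alpha_median_abs_error": float(np.median(errs)),
    }


def cancellation_demonstration() -> dict:
    """Broadband elevation exactly masking alpha suppression in raw band power.

    The blank spectrum carries an alpha bump; the stimulus spectrum has the
    bump removed and a broadband shift sized so the raw alpha-band ratio is
    one. Band power sees nothing; the decomposition must report suppression.
    """
    k = np.log10(FREQS)
    a, sig, mu = 0.4, 0.1, 1.0
    G = np.exp(-((k - mu) ** 2) / (2 * sig**2))
    band = (FREQS >= 7.5) & (FREQS <= 12.5)
    c = a * G[band].mean()
    pb = FREQS**-1.0 * 10 ** (a * G)
    ps = FREQS**-1.0 * 10**c
    nocorr = decompose.alpha_band_power_no_correction(ps, pb, FREQS, 10.0)
    fit = decompose.decompose_trial(ps, pb, FREQS, 10.0)
    return {
        "cancellation_nocorr_ratio": float(nocorr),
        "cancellation_beta_alpha": float(fit.alpha_amp),
    }


def prf_noiseless_recovery(seed: int = 0) -> dict:
    """Fit DoG series generated from known parameters; errors in percent."""
    design = StimulusDesign()
    stim = prf.prepare_stimulus(generate_aperture_sequence(design))
    rng = np.random.default_rng(seed)
    center_errs, sigma_errs = [], []
    for _ in range(5):
        x, y = rng.uniform(-5, 5, 2)
        sigma = rng.uniform(0.5, 4.0)
        true = prf.PRFParams(x, y, sigma, 1.0, 0.002)
        fit = prf.fit_prf(prf.dog_response(stim, true), stim)
        center_errs.append(
            100 * max(abs(fit.params.x - x), abs(fit.params.y - y)) / design.field_radius
        )
        sigma_errs.append(100 * abs(fit.params.sigma - sigma) / sigma)
    return {
        "noiseless_center_error_pct": float(np.max(center_errs)),
        "noiseless_sigma_error_pct": float(np.max(sigma_errs)),
    }


def cohort_recovery(seed: int = 0, n_electrodes: int = 40, n_runs: int = 6,
                    n_shuffles: int = 5000) -> dict:
    """Full pipeline on a simulated cohort with alpha sigma = 2 x broadband.

    Simulate, preprocess, decompose and fit pRFs for every electrode; set
    selection thresholds from shuffle nulls; report, over kept electrodes,
    the fraction with suppressive (negative-gain) alpha pRFs, the fraction
    whose alpha/broadband size ratio lies in [1.5, 3], and the fraction
    whose alpha centers fall within 1 degree of the broadband center; and,
    over all electrodes, the fraction where the decomposed alpha pRF
    cross-validates better than the uncorrected alpha-band-power pRF.
    """
    cohort = make_cohort(n_electrodes, seed=seed)
    rec = simulate_experiment(StimulusDesign(), cohort, n_runs=n_runs, seed=seed + 1)
    results, stim = analyze_recording(rec, with_nocorr=True)

    thresholds = {}
    for sig, key in (("broadband", "broadband"), ("alpha", "alpha")):
        series = np.array([
            r.summary.broadband if sig == "broadband" else r.summary.alpha
            for r in results
        ])
        preds = np.array([r.fits[sig].predicted for r in results])
        thresholds[key], _ = groupstats.shuffle_null_threshold(
            series, preds, n_shuffles=n_shuffles, seed=seed + 2
        )

    records = [groupstats.ElectrodeRecord(r.electrode, r.fits) for r in results]
    keep, _ = groupstats.select_electrodes(
        records, groupstats.SelectionThresholds(thresholds["broadband"], thresholds["alpha"])
    )
    kept = [r for r, k in zip(results, keep) if k]

    neg, ratio_ok, center_ok = [], [], []
    for r in kept:
        al, bb = r.fits["alpha"], r.fits["broadband"]
        neg.append(al.params.center_gain < 0)
        ratio_ok.append(1.5 <= al.params.sigma / bb.params.sigma <= 3.0)
        center_ok.append(
            np.hypot(al.params.x - bb.params.x, al.params.y - bb.params.y) <= 1.0
        )
    better = [r.fits["alpha"].r2_cv > r.fits["alpha_nocorr"].r2_cv for r in results]
    n_kept = len(kept)
    return {
        "cohort_n_kept": n_kept,
        "threshold_broadband_r2": float(thresholds["broadband"]),
        "threshold_alpha_r2": float(thresholds["alpha"]),
        "kept_pct_alpha_gain_negative": 100.0 * np.mean(neg) if n_kept else np.nan,
        "kept_pct_sigma_ratio_in_band": 100.0 * np.mean(ratio_ok) if n_kept else np.nan,
        "kept_pct_centers_within_1deg": 100.0 * np.mean(center_ok) if n_kept else np.nan,
        "pct_decomposed_beats_nocorr": 100.0 * np.mean(better),
    }


def null_calibration(seed: int = 0, n_electrodes: int = 40,
                     n_shuffles: int = 1000) -> dict:
    """False-positive rate of selection on electrodes with no spatial tuning.

    Pure-noise summary series are fitted like real data; the shuffle-null
    threshold at the 95th percentile should admit roughly 5% of them.
    """
    design = StimulusDesign()
    stim = prf.prepare_stimulus(generate_aperture_sequence(design))
    rng = np.random.default_rng(seed)
    series = rng.standard_normal((n_electrodes, stim.stim.shape[0]))
    fits = [prf.fit_prf_cv(series[i], stim) for i in range(n_electrodes)]
    preds = np.array([f.predicted for f in fits])
    r2cv = np.array([f.r2_cv for f in fits])
    thr, _ = groupstats.shuffle_null_threshold(
        series, preds, n_shuffles=n_shuffles, seed=seed + 1
    )
    return {
        "null_threshold_r2": float(thr),
        "null_false_positive_pct": 100.0 * float((r2cv > thr).mean()),
    }


def coherence_validation(seed: int = 0) -> dict:
    """MSC invariants and distance-decay behavior on a simulated grid."""
    rng = np.random.default_rng(seed)
    fs = 512.0

    # self-coherence of any signal is one at every defined bin
    x = rng.standard_normal(512)
    f, pxy, px, py = coh.windowed_cpsd(x, x, fs)
    m = coh.msc(pxy, px, py)
    msc_self = float(np.nanmean(m))

    # independent-noise bias floor ~ 1 / number of averaged windows
    vals = []
    for _ in range(100):
        f, pxy, px, py = coh.windowed_cpsd(
            rng.standard_normal(512), rng.standard_normal(512), fs
        )
        vals.append(coh.msc(pxy, px, py))
    n_windows = (512 - 256) // 64 + 1
    floor = float(np.nanmean(vals))

    # spatially mixed alpha: neighboring pairs cohere at alpha, not broadband
    rec = simulate_grid(StimulusDesign(), (3, 3), pitch=3.0,
                        alpha_mixing_length=20.0, seed=seed + 1, n_runs=2)
    epochs = preprocess.epoch_recording(rec)
    clean = preprocess.regress_out_erp(epochs)
    data = clean.data.reshape(2, 224, clean.n_electrodes, -1)
    cs = coh.pairwise_coherence(data, clean.sample_rate, rec.coordinates)
    mean_msc = np.nanmean(cs.msc, axis=1)
    ab = np.array([
        coh.band_coherence(mean_msc[k], cs.freqs, 10.0) for k in range(len(cs.pairs))
    ])
    near = cs.distances <= 3.5
    alpha_3mm = float(ab[near, 0].mean())
    bb_3mm = float(ab[near, 1].mean())

    # exponential-decay parameter recovery on synthetic pair data
    true = (0.3, 5.0, 0.35)
    d = np.repeat(np.arange(3, 27, 3.0), 20)
    v = true[0] * np.exp(-d / true[1]) + true[2] + 0.02 * rng.standard_normal(d.size)
    fit = coh.fit_decay(d, v, n_boot=500, seed=seed + 2)
    decay_err = 100.0 * max(
        abs(fit.amplitude - true[0]) / true[0],
        abs(fit.length_constant - true[1]) / true[1],
        abs(fit.baseline - true[2]) / true[2],
    )
    return {
        "msc_self": msc_self,
        "msc_noise_floor_x_windows": floor * n_windows,
        "alpha_coherence_3mm": alpha_3mm,
        "broadband_coherence_3mm": bb_3mm,
        "decay_recovery_max_error_pct": decay_err,
    }
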