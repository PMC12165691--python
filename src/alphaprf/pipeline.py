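"""End-to-end analysis: recording -> epochs -> spectra -> decomposition -> pRFs.

This is the glue that runs every stage in order on one recording (real or
simulated) and returns per-electrode results in tidy form. Each stage is the
public function from its own module, so any intermediate can be recomputed
or swapped in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import decompose, preprocess, prf, spectral
from .synth import SimulatedRecording

__all__ = ["ElectrodeResult", "analyze_recording", "results_table"]


@dataclass
class ElectrodeResult:
    """All derived quantities for one electrode."""

    electrode: int
    electrode_fit: decompose.DecompositionFit
    summary: decompose.SummaryTimeCourse
    fits: dict[str, prf.PRFFit]  # "broadband", "alpha", optionally "alpha_nocorr"
    nocorr_series: np.ndarray | None = None

    @property
    def alpha_peak_hz(self) -> float:
        return self.electrode_fit.alpha_peak_hz


def analyze_recording(
    recording: SimulatedRecording,
    site: str | tuple = (),
    beta_term: bool = False,
    exclude_epochs: bool = True,
    with_nocorr: bool = False,
    nocorr_halfwidth: float = 2.5,
    decimation: int = 3,
    n_starts: int = 3,
) -> tuple[list[ElectrodeResult], prf.StimulusMatrix]:
    """Run the full pipeline on a recording.

    Stages: epoch and baseline-correct every run; fit the artifact-exclusion
    tail model on the raw epochs; regress out stimulus/blank ERPs; compute
    per-trial Welch spectra, the blank baseline and the run average; fit the
    electrode-level alpha peak, then decompose every trial; summarize alpha
    (model coefficient) and broadband (70-180 Hz ratio, with ``site``
    line-harmonic exclusions) per trial; blank-normalize and decimate; fit
    DoG pRFs with split-half cross-validation — broadband with the positive
    convention, decomposed alpha with the negative convention, and, when
    ``with_nocorr`` is set, the uncorrected alpha band power with a free
    center gain.
    """
    epochs = preprocess.epoch_recording(recording)
    keep = None
    if exclude_epochs:
        keep, _ = preprocess.exclude_noisy_epochs(epochs)
    clean = preprocess.regress_out_erp(epochs)
    spectra = spectral.trial_spectra(clean, keep=keep)
    blank = spectra.metadata["blank"].to_numpy()

    stim = prf.prepare_stimulus(recording.apertures, decimation)
    results = []
    for j in range(epochs.n_electrodes):
        psd_j = spectra.psd[:, j]
        base_j = spectra.baseline[j]
        mean_stim = np.exp(np.log(psd_j[~blank]).mean(axis=0))
        efit = decompose.fit_electrode_alpha_peak(
            mean_stim, base_j, spectra.freqs, beta_term=beta_term
        )

        alpha_vals = np.empty(psd_j.shape[0])
        bb_vals = np.empty(psd_j.shape[0])
        nocorr_vals = np.empty(psd_j.shape[0]) if with_nocorr else None
        for t in range(psd_j.shape[0]):
            tfit = decompose.decompose_trial(
                psd_j[t], base_j, spectra.freqs, efit.alpha_peak_hz,
                beta_term=beta_term, start=efit, sigma_window=0.3,
            )
            alpha_vals[t] = tfit.alpha_amp
            bb_vals[t] = decompose.broadband_power(
                psd_j[t], base_j, spectra.freqs, exclude=site
            )
            if with_nocorr:
                nocorr_vals[t] = decompose.alpha_band_power_no_correction(
                    psd_j[t], base_j, spectra.freqs, efit.alpha_peak_hz,
                    halfwidth=nocorr_halfwidth,
                )

        summary = decompose.build_summary_time_courses(
            alpha_vals, bb_vals, blank, factor=decimation
        )
        fits = {
            "broadband": prf.fit_prf_cv(summary.broadband, stim, sign="positive",
                                        n_starts=n_starts),
            "alpha": prf.fit_prf_cv(summary.alpha, stim, sign="negative",
                                    n_starts=n_starts),
        }
        nocorr_series = None
        if with_nocorr:
            nc = np.log10(nocorr_vals)
            nc = nc - nc[blank].mean()
            nocorr_series = decompose.decimate_series(nc, decimation)
            fits["alpha_nocorr"] = prf.fit_prf_cv(nocorr_series, stim, sign="free",
                                                  n_starts=n_starts)
        results.append(ElectrodeResult(j, efit, summary, fits, nocorr_series))
    return results, stim


def results_table(results: list[ElectrodeResult]) -> pd.DataFrame:
    """Tidy per-electrode, per-signal table of pRF parameters and accuracy."""
    rows = []
    for res in results:
        for sig, fit in res.fits.items():
            pol = fit.params.polar
            rows.append(
                {
                    "electrode": res.electrode,
                    "signal": sig,
                    "x": fit.params.x,
                    "y": fit.params.y,
                    "sigma": fit.params.sigma,
                    "g1": fit.params.g1,
                    "g2": fit.params.g2,
                    "center_gain": fit.params.center_gain,
                    "angle": pol.angle,
                    "eccentricity": pol.eccentricity,
                    "r2_train": fit.r2_train,
                    "r2_cv": fit.r2_cv,
                    "alpha_peak_hz": res.alpha_peak_hz,
                }
            )
    return pd.DataFrame(rows)
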