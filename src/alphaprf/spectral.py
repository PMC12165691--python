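"""Per-trial power spectra on a 1 Hz grid, with blank baselines and run averaging.

Spectra are computed by Welch's method over the stimulus period (0-500 ms of
each epoch) with 200 ms Hann windows at 50% overlap. Each windowed segment is
zero-padded to one sample-rate's worth of samples so the periodogram lands on
an exact 1 Hz grid; neighboring bins are therefore correlated, which is
harmless downstream because every statistic is a ratio or an average over
bands much wider than the window bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import VoltageEpochs

__all__ = ["SpectrumSet", "welch_psd", "baseline_spectrum", "average_across_runs",
           "trial_spectra"]

FREQ_MAX = 250.0  # Hz retained on the analysis grid


@dataclass
class SpectrumSet:
    """Per-trial stimulus PSDs and a per-electrode blank baseline.

    ``psd`` is (trial, electrode, freq) in power density units; ``baseline``
    (electrode, freq) is the geometric mean over blank epochs; ``freqs`` is
    the uniform 1 Hz grid. ``run_averaged`` records whether trials were
    geometric-mean combined across repeated runs.
    """

    psd: np.ndarray
    baseline: np.ndarray
    freqs: np.ndarray
    metadata: pd.DataFrame  # columns: step, blank (and run if not averaged)
    run_averaged: bool = False


def welch_psd(
    segment: np.ndarray, sample_rate: float, window_sec: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of (..., time) segments on a 1 Hz grid (1..250 Hz).

    Hann windows of ``window_sec`` at 50% overlap, zero-padded to
    ``sample_rate`` samples, one-sided density normalization.
    """
    segment = np.asarray(segment, dtype=float)
    nperseg = int(round(window_sec * sample_rate))
    if segment.shape[-1] < nperseg:
        raise ValueError("segment shorter than one Welch window")
    nfft = int(round(sample_rate))
    f, p = signal.welch(
        segment,
        fs=sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=nfft,
        detrend=False,
        axis=-1,
    )
    sel = (f >= 1.0) & (f <= FREQ_MAX)
    return f[sel], p[..., sel]


def baseline_spectrum(blank_psds: np.ndarray) -> np.ndarray:
    """Per-frequency geometric mean across blank-epoch PSDs (first axis)."""
    blank_psds = np.asarray(blank_psds, dtype=float)
    if blank_psds.shape[0] < 1:
        raise ValueError("need at least one blank PSD")
    bad = ~(blank_psds > 0)
    if bad.any():
        bin_idx = np.unique(np.argwhere(bad)[:, -1])
        raise ValueError(f"non-positive PSD values at frequency bins {bin_idx.tolist()}")
    return np.exp(np.log(blank_psds).mean(axis=0))


def average_across_runs(psd: np.ndarray, metadata: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Geometric mean of each trial's PSD across repeated runs.

    ``psd`` is (epoch, electrode, freq) with metadata rows (step, blank, run);
    all runs must share the same step sequence. Returns (step-ordered PSDs,
    metadata without the run column).
    """
    steps = metadata["step"].to_numpy()
    runs = metadata["run"].to_numpy()
    uniq_steps = np.unique(steps)
    counts = {r: set(steps[runs == r]) for r in np.unique(runs)}
    if any(s != set(uniq_steps) for s in counts.values()):
        raise ValueError("runs do not share an identical trial sequence")

    log_p = np.log(psd)
    out = np.empty((uniq_steps.size,) + psd.shape[1:])
    blank_flags = []
    for i, s in enumerate(uniq_steps):
        m = steps == s
        out[i] = np.exp(log_p[m].mean(axis=0))
        blank_flags.append(bool(metadata.loc[m, "blank"].iloc[0]))
    meta = pd.DataFrame({"step": uniq_steps, "blank": blank_flags})
    return out, meta


def trial_spectra(
    epochs: VoltageEpochs,
    keep: np.ndarray | None = None,
    combine_runs: bool = True,
) -> SpectrumSet:
    """Full spectral stage: per-epoch Welch PSDs, blank baseline, run averaging.

    ``keep`` is an optional (epoch, electrode) mask from artifact exclusion;
    excluded epochs still produce a PSD (so the trial grid stays complete)
    but are left out of the baseline. With ``combine_runs`` the per-step
    spectra are geometric-mean averaged across runs.
    """
    freqs, psd = welch_psd(epochs.stimulus_slice(), epochs.sample_rate)
    blank = epochs.metadata["blank"].to_numpy()

    base = np.empty((epochs.n_electrodes, freqs.size))
    for j in range(epochs.n_electrodes):
        m = blank if keep is None else blank & keep[:, j]
        if not m.any():
            m = blank
        base[j] = baseline_spectrum(psd[m, j])

    meta = epochs.metadata.copy()
    if combine_runs and "run" in meta.columns and meta["run"].nunique() > 1:
        psd, meta = average_across_runs(psd, meta)
        averaged = True
    else:
        meta = meta.reset_index(drop=True)
        averaged = meta.get("run", pd.Series([0])).nunique() <= 1
    return SpectrumSet(psd=psd, baseline=base, freqs=freqs, metadata=meta,
                       run_averaged=bool(averaged))
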