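"""Continuous voltage to clean epochs: re-referencing, epoching, ERP removal,
artifact exclusion, and inter-site clock alignment.

Epochs span [-0.2, 0.8) s around each stimulus-step onset (half-open, so
exactly ``sample_rate`` samples at integer rates) and are baseline-corrected
by subtracting the mean over the pre-stimulus interval. The event-related
potential is estimated separately for stimulus and blank epochs and projected
out of each epoch by scalar least squares before any spectral analysis, so
the phase-locked evoked response cannot masquerade as induced power.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

logger = logging.getLogger(__name__)

__all__ = [
    "VoltageEpochs",
    "rereference_common_average",
    "estimate_onset_shift",
    "epoch_and_baseline_correct",
    "epoch_recording",
    "regress_out_erp",
    "exclude_noisy_epochs",
    "flag_high_variance_electrodes",
    "EPOCH_WINDOW",
]

EPOCH_WINDOW = (-0.2, 0.8)  # seconds relative to onset, half-open


@dataclass
class VoltageEpochs:
    """Trial-segmented voltage: (epoch, electrode, time) plus metadata."""

    data: np.ndarray
    times: np.ndarray  # seconds relative to onset
    sample_rate: float
    metadata: pd.DataFrame  # columns: step, blank, run

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    def stimulus_slice(self, start: float = 0.0, stop: float = 0.5) -> np.ndarray:
        """View of the data restricted to [start, stop) s."""
        i0 = int(round((start - EPOCH_WINDOW[0]) * self.sample_rate))
        i1 = int(round((stop - EPOCH_WINDOW[0]) * self.sample_rate))
        return self.data[:, :, i0:i1]


def rereference_common_average(
    voltage: np.ndarray, groups: list[np.ndarray] | None = None
) -> np.ndarray:
    """Subtract the across-electrode mean per sample, within electrode groups.

    ``voltage`` is (n_electrodes, n_samples); ``groups`` a list of index
    arrays (default: all electrodes form one group). Groups with a single
    electrode are left unchanged with a warning.
    """
    out = np.array(voltage, dtype=float, copy=True)
    if groups is None:
        groups = [np.arange(out.shape[0])]
    for g in groups:
        g = np.asarray(g)
        if g.size < 2:
            warnings.warn("singleton re-reference group left unchanged")
            continue
        out[g] -= out[g].mean(axis=0, keepdims=True)
    return out


def estimate_onset_shift(
    erp_a: np.ndarray,
    erp_b: np.ndarray,
    sample_rate: float,
    n_boot: int = 0,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, tuple[float, float] | None]:
    """Lag (ms) of waveform b relative to a, from peak cross-correlation.

    Inputs may be 1-D waveforms or 2-D (electrode, time) sets; in the 2-D
    case the lag is computed on the across-electrode means and, when
    ``n_boot`` > 0, a bootstrap confidence interval (2.5-97.5%) is obtained
    by resampling electrode pairs. The lag maximizes the absolute
    cross-correlation, so a polarity flip does not defeat the estimate; a
    positive lag means b is delayed relative to a.
    """
    a = np.atleast_2d(np.asarray(erp_a, dtype=float))
    b = np.atleast_2d(np.asarray(erp_b, dtype=float))
    if a.shape[-1] != b.shape[-1]:
        raise ValueError("waveforms must have equal length")

    def _lag_ms(wa: np.ndarray, wb: np.ndarray) -> float:
        if np.allclose(wa, 0) or np.allclose(wb, 0):
            raise ValueError("flat waveform: lag undefined")
        xc = signal.correlate(wb, wa, mode="full")
        lags = signal.correlation_lags(wb.size, wa.size, mode="full")
        return lags[np.argmax(np.abs(xc))] / sample_rate * 1e3

    lag = _lag_ms(a.mean(axis=0), b.mean(axis=0))
    ci = None
    if n_boot > 0 and a.shape[0] > 1:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        draws = []
        for _ in range(n_boot):
            ia = rng.integers(0, a.shape[0], a.shape[0])
            ib = rng.integers(0, b.shape[0], b.shape[0])
            try:
                draws.append(_lag_ms(a[ia].mean(axis=0), b[ib].mean(axis=0)))
            except ValueError:
                continue
        ci = tuple(np.percentile(draws, [2.5, 97.5]))
    return lag, ci


def epoch_and_baseline_correct(
    voltage: np.ndarray,
    events: pd.DataFrame,
    sample_rate: float,
    run: int = 0,
) -> VoltageEpochs:
    """Cut [-0.2, 0.8) s epochs around each event onset and zero the baseline.

    Events whose window falls outside the recording are dropped with a log
    entry. The per-epoch, per-electrode mean over the pre-stimulus interval
    [-0.2, 0) s is subtracted.
    """
    voltage = np.atleast_2d(voltage)
    n_samples = voltage.shape[1]
    win = int(round((EPOCH_WINDOW[1] - EPOCH_WINDOW[0]) * sample_rate))
    n_pre = int(round(-EPOCH_WINDOW[0] * sample_rate))

    rows, epochs = [], []
    for _, ev in events.iterrows():
        # anchor the epoch on the onset sample so sample n_pre is t = 0 exactly
        start = int(round(ev["onset"] * sample_rate)) - n_pre
        if start < 0 or start + win > n_samples:
            logger.info("dropping event at %.3f s: outside recording", ev["onset"])
            continue
        epochs.append(voltage[:, start : start + win])
        rows.append({"step": int(ev["step"]), "blank": bool(ev["blank"]), "run": run})

    data = np.stack(epochs).astype(float)  # (epoch, electrode, time)
    data -= data[:, :, :n_pre].mean(axis=2, keepdims=True)
    times = (np.arange(win) - n_pre) / sample_rate
    return VoltageEpochs(data, times, sample_rate, pd.DataFrame(rows))


def epoch_recording(recording, rereference: bool = False) -> VoltageEpochs:
    """Epoch every run of a :class:`~alphaprf.synth.SimulatedRecording`."""
    parts = []
    for r in range(recording.voltage.shape[0]):
        v = recording.voltage[r]
        if rereference:
            v = rereference_common_average(v)
        parts.append(
            epoch_and_baseline_correct(v, recording.events, recording.sample_rate, run=r)
        )
    data = np.concatenate([p.data for p in parts], axis=0)
    meta = pd.concat([p.metadata for p in parts], ignore_index=True)
    return VoltageEpochs(data, parts[0].times, recording.sample_rate, meta)


def _erp_project(data: np.ndarray, erp: np.ndarray, mode: str) -> np.ndarray:
    """Remove ERP from (epoch, time) data for one electrode."""
    power = erp @ erp
    if power == 0:
        return data
    if mode == "subtract":
        return data - erp
    beta = (data @ erp) / power
    return data - beta[:, None] * erp


def regress_out_erp(epochs: VoltageEpochs, mode: str = "project") -> VoltageEpochs:
    """Remove the evoked potential from every epoch.

    ERPs are averaged separately over stimulus and blank epochs (per
    electrode) and each epoch's least-squares projection onto its matching
    ERP is subtracted (``mode="project"``); ``mode="subtract"`` removes the
    ERP with unit amplitude instead.
    """
    blank = epochs.metadata["blank"].to_numpy()
    if (~blank).sum() < 2 or blank.sum() < 2:
        raise ValueError("need at least 2 stimulus and 2 blank epochs")
    out = epochs.data.copy()
    for mask in (~blank, blank):
        erp = epochs.data[mask].mean(axis=0)  # (electrode, time)
        for j in range(epochs.n_electrodes):
            out[np.ix_(mask, [j])] = _erp_project(
                epochs.data[mask, j], erp[j], mode
            )[:, None, :]
    return VoltageEpochs(out, epochs.times, epochs.sample_rate, epochs.metadata.copy())


def exclude_noisy_epochs(
    epochs: VoltageEpochs, tail_prob: float = 1e-4
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag epochs whose peak power is implausible under an inverse Gaussian.

    Per electrode, the maximum of the squared voltage over the stimulus
    period (0-500 ms) of each non-blank epoch is collected and an inverse
    Gaussian distribution is fitted by closed-form maximum likelihood
    (mean mu = sample mean; shape lam from the mean reciprocal difference).
    The evoked potential (mean over non-blank epochs) is then projected out
    of every epoch, and epochs whose residual peak power exceeds the
    distribution's (1 - tail_prob) quantile are marked for exclusion.

    Returns a boolean keep mask of shape (n_epochs, n_electrodes) and a table
    of per-electrode (mu, lam, threshold).
    """
    blank = epochs.metadata["blank"].to_numpy()
    if (~blank).sum() < 20:
        raise ValueError("need at least 20 non-blank epochs to fit the tail model")

    stim = epochs.stimulus_slice()
    maxima = (stim[~blank] ** 2).max(axis=2)  # (stim epoch, electrode)

    keep = np.ones((epochs.n_epochs, epochs.n_electrodes), dtype=bool)
    rows = []
    erp = epochs.data[~blank].mean(axis=0)
    n_pre = int(round(-EPOCH_WINDOW[0] * epochs.sample_rate))
    n_on = int(round(0.5 * epochs.sample_rate))
    for j in range(epochs.n_electrodes):
        x = maxima[:, j]
        mu = x.mean()
        recip = np.mean(1.0 / x - 1.0 / mu)
        if mu <= 0 or recip <= 0 or np.ptp(x) == 0:
            warnings.warn(f"degenerate peak-power distribution on electrode {j}")
            rows.append({"electrode": j, "mu": mu, "lam": np.nan, "threshold": np.inf})
            continue
        lam = 1.0 / recip
        thresh = stats.invgauss.ppf(1 - tail_prob, mu / lam, scale=lam)
        resid = _erp_project(epochs.data[:, j], erp[j], "project")
        resid_max = (resid[:, n_pre : n_pre + n_on] ** 2).max(axis=1)
        keep[:, j] = resid_max <= thresh
        rows.append({"electrode": j, "mu": mu, "lam": lam, "threshold": thresh})
    return keep, pd.DataFrame(rows)


def flag_high_variance_electrodes(trial_variance: np.ndarray) -> np.ndarray:
    """Electrodes whose across-trial variance exceeds mean + 3 SD across electrodes.

    The rule is invariant to common scaling of all variances (it is a
    z-score threshold).
    """
    v = np.asarray(trial_variance, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 electrodes")
    return v > v.mean() + 3 * v.std()
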