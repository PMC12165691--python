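"""Inter-electrode coherence versus distance for alpha and broadband signals.

For every electrode pair the cross power spectral density (CPSD) is computed
over full epochs (-200 to 800 ms, after ERP removal) with 500 ms Hann
windows at 75% overlap on a 1 Hz grid, and the magnitude-squared coherence

    MSC_xy(f) = (1/N) sum_runs |P_xy(f)|^2 / (P_x(f) P_y(f))

is averaged across the N repeated runs. Within each run the Welch average
over the sliding windows is taken *before* forming the ratio; with a single
un-averaged window the ratio is identically 1, so the windowed average is
what gives the estimator its degrees of freedom (independent signals then
converge to a bias floor of roughly one over the number of averaged
windows). Alpha coherence is the MSC at the electrode's alpha peak bin,
broadband coherence the arithmetic mean over 70-180 Hz. Pair values are
binned by inter-electrode distance in multiples of 3 mm and summarized by a
bootstrapped exponential decay fit c(d) = a exp(-d / lambda) + b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

__all__ = [
    "CoherenceSet",
    "DecayFit",
    "windowed_cpsd",
    "msc",
    "band_coherence",
    "bin_by_distance",
    "fit_decay",
    "pairwise_coherence",
]


@dataclass
class CoherenceSet:
    """MSC per electrode pair, trial and frequency, with pair geometry."""

    msc: np.ndarray  # (n_pairs, n_trials, n_freqs) in [0, 1]
    freqs: np.ndarray
    pairs: np.ndarray  # (n_pairs, 2) electrode indices
    distances: np.ndarray  # mm
    n_runs: int


@dataclass
class DecayFit:
    amplitude: float  # a
    length_constant: float  # lambda, mm
    baseline: float  # b, the coherence the curve converges to
    draws: np.ndarray  # (n_kept, 3) per-bootstrap parameters
    n_failed: int = 0
    identifiable: bool = True


def windowed_cpsd(
    x: np.ndarray,
    y: np.ndarray,
    sample_rate: float,
    window_sec: float = 0.5,
    overlap: float = 0.75,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Welch-averaged cross- and auto-spectra of (..., time) epoch pairs.

    Returns (freqs, Pxy, Px, Py) on a 1 Hz grid; auto-spectra are real and
    nonnegative, the cross-spectrum complex.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nperseg = int(round(window_sec * sample_rate))
    if x.shape[-1] < nperseg:
        raise ValueError("epoch shorter than one window")
    kw = dict(
        fs=sample_rate, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), nfft=int(round(sample_rate)),
        detrend=False, axis=-1,
    )
    f, pxy = signal.csd(x, y, **kw)
    _, px = signal.welch(x, **kw)
    _, py = signal.welch(y, **kw)
    return f, pxy, px, py


def msc(pxy: np.ndarray, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Eq.-style MSC: average across runs of |P_xy|^2 / (P_x P_y).

    Inputs are (n_runs, n_freqs); zero auto-spectrum bins are masked (NaN).
    """
    pxy = np.atleast_2d(pxy)
    px = np.atleast_2d(px)
    py = np.atleast_2d(py)
    denom = px * py
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (pxy * np.conj(pxy)).real / denom
    ratio = np.where(denom > 0, ratio, np.nan)
    return np.nanmean(ratio, axis=0)


def band_coherence(
    msc_values: np.ndarray,
    freqs: np.ndarray,
    alpha_peak_hz: float,
    band: tuple[float, float] = (70.0, 180.0),
) -> tuple[float, float]:
    """(alpha, broadband) coherence: peak-bin value and band arithmetic mean."""
    freqs = np.asarray(freqs, dtype=float)
    if not freqs.min() <= alpha_peak_hz <= freqs.max():
        raise ValueError("alpha peak outside the frequency grid")
    alpha = float(msc_values[np.argmin(np.abs(freqs - alpha_peak_hz))])
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return alpha, float(np.nanmean(msc_values[sel]))


def pairwise_coherence(
    epochs: np.ndarray,
    sample_rate: float,
    coordinates: np.ndarray,
    seed_mask: np.ndarray | None = None,
    window_sec: float = 0.5,
    overlap: float = 0.75,
) -> CoherenceSet:
    """MSC for every electrode pair from (run, epoch, electrode, time) data.

    Per trial and per run, the Welch average over the sliding windows inside
    the epoch supplies the cross- and auto-spectra; the MSC ratio is formed
    per run and averaged across runs, yielding one coherence spectrum per
    pair per trial. When ``seed_mask`` is given, only pairs whose first
    (seed) electrode is marked are retained.
    """
    if epochs.ndim == 3:
        epochs = epochs[None]
    n_runs, n_trials, n_el, _ = epochs.shape
    pairs = [(i, j) for i in range(n_el) for j in range(i + 1, n_el)]
    if seed_mask is not None:
        pairs = [(i, j) for i, j in pairs if seed_mask[i]]
    pairs = np.asarray(pairs)

    nperseg = int(round(window_sec * sample_rate))
    if epochs.shape[-1] < nperseg:
        raise ValueError("epoch shorter than one window")
    kw = dict(
        fs=sample_rate, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), nfft=int(round(sample_rate)),
        detrend=False, axis=-1,
    )

    f = None
    acc = None
    for r in range(n_runs):
        f, pauto = signal.welch(epochs[r], **kw)  # (trial, electrode, freq)
        if acc is None:
            acc = np.zeros((len(pairs), n_trials, f.size))
        for k, (i, j) in enumerate(pairs):
            _, pxy = signal.csd(epochs[r, :, i], epochs[r, :, j], **kw)
            denom = pauto[:, i] * pauto[:, j]
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = (pxy * np.conj(pxy)).real / denom
            acc[k] += np.where(denom > 0, ratio, np.nan)

    coords = np.asarray(coordinates, dtype=float)
    dists = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return CoherenceSet(msc=acc / n_runs, freqs=f, pairs=pairs, distances=dists,
                        n_runs=n_runs)


def bin_by_distance(
    values: np.ndarray,
    distances: np.ndarray,
    bin_width: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average pair values in distance bins at multiples of ``bin_width`` mm.

    A pair at distance d is assigned to the bin round(d / width) x width;
    empty bins are omitted. Returns (bin centers, bin means, bin counts);
    counts sum to the number of pairs.
    """
    values = np.asarray(values, dtype=float)
    distances = np.asarray(distances, dtype=float)
    bins = np.round(distances / bin_width) * bin_width
    centers = np.unique(bins)
    means = np.array([values[bins == c].mean() for c in centers])
    counts = np.array([(bins == c).sum() for c in centers])
    return centers, means, counts


def _decay(d, a, lam, b):
    return a * np.exp(-d / lam) + b


def fit_decay(
    distances: np.ndarray,
    values: np.ndarray,
    n_boot: int = 5000,
    seed=0,
    bin_width: float = 3.0,
) -> DecayFit:
    """Bootstrapped least-squares exponential decay over binned distances.

    Per bootstrap, pairs are resampled with replacement, binned, and
    c(d) = a exp(-d / lambda) + b is fitted; non-convergent draws are
    discarded and counted. Reported parameters are the means of the kept
    draws. When the fitted amplitude is indistinguishable from zero the
    length constant is unidentifiable and the fit is flagged.
    """
    distances = np.asarray(distances, dtype=float)
    values = np.asarray(values, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers_all = np.unique(np.round(distances / bin_width) * bin_width)
    if centers_all.size < 4:
        raise ValueError("need at least 4 distance bins")

    draws, failed = [], 0
    p0 = (max(values.max() - values.min(), 1e-3), max(distances.max() / 3, bin_width), values.min())
    bounds = ([0.0, 1e-6, 0.0], [np.inf, np.inf, 1.0])
    for _ in range(n_boot):
        idx = rng.integers(0, distances.size, distances.size)
        c, m, _ = bin_by_distance(values[idx], distances[idx], bin_width)
        if c.size < 4:
            failed += 1
            continue
        try:
            popt, _ = curve_fit(_decay, c, m, p0=p0, bounds=bounds, maxfev=2000)
            draws.append(popt)
        except RuntimeError:
            failed += 1
    draws = np.asarray(draws)
    a, lam, b = np.median(draws, axis=0)
    # lambda is unidentifiable when the amplitude is negligible or the decay
    # is flat over the sampled distance range
    span = distances.max() - distances.min()
    identifiable = bool(a > 0.02 and lam <= 2 * span)
    return DecayFit(float(a), float(lam), float(b), draws, failed, identifiable)
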