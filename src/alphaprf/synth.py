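"""Synthetic bar-sweep ECoG with known ground-truth population receptive fields.

This module generates everything the downstream pipeline consumes: the
binarized bar-aperture sequence of a retinotopic mapping run, and continuous
multi-electrode voltage in which

* a 1/f^chi broadband process has its amplitude raised during stimulus
  presentation according to a positive Difference-of-Gaussians (DoG) pRF,
* a narrowband alpha oscillation (8-13 Hz) has its amplitude suppressed
  according to a second, typically larger, DoG pRF at a similar center,
* an evoked potential is added at stimulus onsets,
* optional line noise and a beta-band bump can be mixed in.

Responses are expressed in log10 power-ratio units: during a step whose
aperture evokes a broadband response r_bb, broadband power is multiplied by
10**r_bb (amplitude by 10**(r_bb/2)); the alpha oscillation's power is
multiplied by 10**(-r_alpha). Blank steps carry baseline broadband and the
full, unsuppressed alpha rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.fft import irfft, rfft, rfftfreq

__all__ = [
    "StimulusDesign",
    "GroundTruthElectrode",
    "ApertureSequence",
    "SimulatedRecording",
    "generate_aperture_sequence",
    "run_duration",
    "simulate_experiment",
    "simulate_grid",
    "grid_coordinates",
    "make_cohort",
    "make_area_probabilities",
    "default_erp_template",
]


@dataclass(frozen=True)
class StimulusDesign:
    """Geometry and timing of one bar-sweep mapping run.

    The defaults reproduce the mapping protocol the pipeline is built around:
    eight sweeps of 28 steps (850 ms each, 500 ms stimulus + 350 ms gap),
    2 degree wide bars inside an 8.3 degree radius field, with the four
    diagonal sweeps stopping at the center and padding the remaining 16
    steps with blanks, plus 3 s of blank at the start and end of the run.
    """

    n_sweeps: int = 8
    steps_per_sweep: int = 28
    step_duration: float = 0.85
    stim_on: float = 0.5
    stim_off: float = 0.35
    pre_post_blank: float = 3.0
    field_radius: float = 8.3
    bar_width: float = 2.0
    grid_resolution: int = 100
    diagonal_truncation: int = 16

    @property
    def n_steps(self) -> int:
        return self.n_sweeps * self.steps_per_sweep

    def pixel_centers(self) -> np.ndarray:
        """1-D pixel-center coordinates in degrees (x rightward, y upward)."""
        r, n = self.field_radius, self.grid_resolution
        return (np.arange(n) + 0.5) * (2 * r / n) - r


@dataclass
class GroundTruthElectrode:
    """One simulated electrode: planar position, pRFs and noise properties.

    pRF tuples are ``(x, y, sigma, g1, g2)`` in degrees / response units;
    the alpha pRF's response is applied with a negative sign to the
    oscillation amplitude (stimulation inside the alpha pRF suppresses the
    rhythm). ``noise_level`` is the broadband RMS in volts; ``alpha_rms``
    defaults to the same value, which puts the alpha peak well above the
    1/f background, as in occipital recordings.
    """

    position: tuple[float, float] = (0.0, 0.0)
    bb_prf: tuple[float, float, float, float, float] = (0.0, 0.0, 1.0, 0.0, 0.0)
    alpha_prf: tuple[float, float, float, float, float] = (0.0, 0.0, 2.0, 0.0, 0.0)
    alpha_peak: float = 10.0
    erp_template: np.ndarray | None = None
    erp_gain: float = 3.0
    noise_level: float = 1.0
    alpha_rms: float | None = None
    line_freq: float | None = None
    beta_bump: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 8.0 <= self.alpha_peak <= 13.0:
            raise ValueError(f"alpha_peak must lie in [8, 13] Hz, got {self.alpha_peak}")
        if self.bb_prf[2] <= 0 or self.alpha_prf[2] <= 0:
            raise ValueError("pRF sigma must be positive")


@dataclass
class ApertureSequence:
    """Ordered binary aperture masks plus per-step metadata."""

    masks: np.ndarray  # (n_steps, res, res) uint8, index [step, y, x]
    metadata: pd.DataFrame  # columns: step, sweep, blank
    design: StimulusDesign

    def __len__(self) -> int:
        return self.masks.shape[0]

    @property
    def blank(self) -> np.ndarray:
        return self.metadata["blank"].to_numpy()


@dataclass
class SimulatedRecording:
    """Continuous voltage for every electrode and run, with its event table."""

    voltage: np.ndarray  # (n_runs, n_electrodes, n_samples)
    events: pd.DataFrame  # onset, duration, step, blank (identical per run)
    sample_rate: float
    design: StimulusDesign
    electrodes: list[GroundTruthElectrode]
    apertures: ApertureSequence
    bb_response: np.ndarray  # (n_electrodes, n_steps) ground-truth log10 ratios
    alpha_response: np.ndarray  # (n_electrodes, n_steps), suppression positive

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([e.position for e in self.electrodes], dtype=float)


# Sweep order: one horizontal and one vertical sweep, the four diagonal
# sweeps, then the reversed vertical and horizontal sweeps. With this order
# each half of the run contains a full horizontal and a full vertical sweep
# (the second half in reversed direction), which is what makes the split-half
# cross-validation of the pRF fits well posed.
_SWEEP_ANGLES_DEG = (0.0, 90.0, 45.0, 135.0, 225.0, 315.0, 270.0, 180.0)
_DIAGONAL = (False, False, True, True, True, True, False, False)


def generate_aperture_sequence(design: StimulusDesign) -> ApertureSequence:
    """Rasterize the full bar-sweep aperture sequence.

    Bars are strips of width ``bar_width`` orthogonal to the sweep direction,
    clipped to the ``field_radius`` disk. Diagonal sweeps stop at the center
    and their trailing ``diagonal_truncation`` steps are all-zero (blank)
    masks.
    """
    if design.grid_resolution < 16:
        raise ValueError("grid_resolution must be at least 16")
    if design.bar_width > 2 * design.field_radius:
        raise ValueError("bar width exceeds the stimulus field diameter")
    if design.step_duration <= 0 or design.stim_on <= 0:
        raise ValueError("durations must be positive")
    if len(_SWEEP_ANGLES_DEG) != design.n_sweeps:
        raise ValueError("design must have 8 sweeps (2 horizontal, 2 vertical, 4 diagonal)")

    px = design.pixel_centers()
    X, Y = np.meshgrid(px, px)  # [y, x] indexing, y upward
    in_field = (X**2 + Y**2) <= design.field_radius**2

    r = design.field_radius
    step = 2 * r / design.steps_per_sweep
    masks = np.zeros(
        (design.n_steps, design.grid_resolution, design.grid_resolution), dtype=np.uint8
    )
    sweep_ids = np.repeat(np.arange(design.n_sweeps), design.steps_per_sweep)

    for s, (angle, diag) in enumerate(zip(_SWEEP_ANGLES_DEG, _DIAGONAL)):
        u = np.array([np.cos(np.radians(angle)), np.sin(np.radians(angle))])
        proj = X * u[0] + Y * u[1]
        n_stim = (
            design.steps_per_sweep - design.diagonal_truncation
            if diag
            else design.steps_per_sweep
        )
        for i in range(n_stim):
            center = -r + (i + 0.5) * step
            bar = np.abs(proj - center) <= design.bar_width / 2
            masks[s * design.steps_per_sweep + i] = (bar & in_field).astype(np.uint8)

    blank = masks.reshape(design.n_steps, -1).sum(axis=1) == 0
    meta = pd.DataFrame(
        {"step": np.arange(design.n_steps), "sweep": sweep_ids, "blank": blank}
    )
    return ApertureSequence(masks=masks, metadata=meta, design=design)


def run_duration(design: StimulusDesign) -> float:
    """Total run length in seconds: all steps plus leading/trailing blanks."""
    return design.n_steps * design.step_duration + 2 * design.pre_post_blank


def default_erp_template(sample_rate: float, duration: float = 0.3,
                         freq: float = 10.0, tau: float = 0.1) -> np.ndarray:
    """Damped sinusoid used as the stock evoked-potential waveform."""
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    return np.exp(-t / tau) * np.sin(2 * np.pi * freq * t)


def dog_step_responses(
    apertures: ApertureSequence, prf: Sequence[float]
) -> np.ndarray:
    """Ground-truth DoG response per step: STIM . (g1 G(x,y,sigma) - g2)."""
    x0, y0, sigma, g1, g2 = prf
    px = apertures.design.pixel_centers()
    X, Y = np.meshgrid(px, px)
    gauss = np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2 * sigma**2))
    flat = apertures.masks.reshape(len(apertures), -1).astype(float)
    return g1 * (flat @ gauss.ravel()) - g2 * flat.sum(axis=1)


def _powerlaw_noise(rng: np.random.Generator, n: int, sample_rate: float,
                    chi: float, highpass: float = 0.16) -> np.ndarray:
    """Gaussian noise with a 1/f^chi power spectrum, unit RMS.

    Frequencies below ``highpass`` (Hz) are removed, mirroring the acquisition
    high-pass of clinical amplifiers; without it the diverging infra-slow
    drift of a pure power law dominates the record.
    """
    w = rfft(rng.standard_normal(n))
    f = rfftfreq(n, d=1.0 / sample_rate)
    shape = np.zeros_like(f)
    keep = f >= highpass
    shape[keep] = f[keep] ** (-chi / 2.0)
    x = irfft(w * shape, n)
    return x / x.std()

def _narrowband_noise(rng: np.random.Generator, n: int, sample_rate: float,
                      f0: float, bw: float) -> np.ndarray:
    """Gaussian noise with a Gaussian spectral profile around f0, unit RMS."""
    w = rfft(rng.standard_normal(n))
    f = rfftfreq(n, d=1.0 / sample_rate)
    shape = np.exp(-((f - f0) ** 2) / (2 * bw**2))
    x = irfft(w * shape, n)
    return x / x.std()


def _event_table(design: StimulusDesign, blank: np.ndarray) -> pd.DataFrame:
    onsets = design.pre_post_blank + np.arange(design.n_steps) * design.step_duration
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": np.full(design.n_steps, design.stim_on),
            "step": np.arange(design.n_steps),
            "blank": blank,
        }
    )


def _step_envelope(
    design: StimulusDesign,
    n_samples: int,
    sample_rate: float,
    log_ratio: np.ndarray,
) -> np.ndarray:
    """Per-sample amplitude multiplier 10**(log_ratio/2) during stimulus-on."""
    env = np.ones(n_samples)
    on = int(round(design.stim_on * sample_rate))
    for i, lr in enumerate(log_ratio):
        if lr == 0.0:
            continue
        start = int(round((design.pre_post_blank + i * design.step_duration) * sample_rate))
        env[start : start + on] = 10.0 ** (lr / 2.0)
    return env


def simulate_experiment(
    design: StimulusDesign,
    electrodes: Sequence[GroundTruthElectrode],
    n_runs: int = 1,
    sample_rate: float = 512.0,
    seed: int | np.random.Generator = 0,
    chi: float = 1.5,
    alpha_bandwidth: float = 2.0,
) -> SimulatedRecording:
    """Simulate continuous voltage for a set of independent electrodes.

    Identical seeds give bit-identical output. ``chi`` is the exponent of the
    broadband 1/f^chi background; ``alpha_bandwidth`` (Hz) the spectral width
    of the alpha rhythm.
    """
    if len(electrodes) == 0:
        raise ValueError("electrode list must not be empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    apertures = generate_aperture_sequence(design)
    n_samples = int(round(run_duration(design) * sample_rate))
    events = _event_table(design, apertures.blank)

    bb_resp = np.array([dog_step_responses(apertures, e.bb_prf) for e in electrodes])
    a_resp = np.array([dog_step_responses(apertures, e.alpha_prf) for e in electrodes])

    voltage = np.empty((n_runs, len(electrodes), n_samples))
    onset_idx = np.round(events["onset"].to_numpy() * sample_rate).astype(int)
    stim_onsets = onset_idx[~apertures.blank]

    for j, e in enumerate(electrodes):
        env_bb = _step_envelope(design, n_samples, sample_rate, bb_resp[j])
        env_a = _step_envelope(design, n_samples, sample_rate, -a_resp[j])
        erp = e.erp_template
        if erp is None:
            erp = default_erp_template(sample_rate) * e.erp_gain * e.noise_level
        a_rms = e.noise_level if e.alpha_rms is None else e.alpha_rms
        for r in range(n_runs):
            v = e.noise_level * _powerlaw_noise(rng, n_samples, sample_rate, chi) * env_bb
            v += a_rms * _narrowband_noise(
                rng, n_samples, sample_rate, e.alpha_peak, alpha_bandwidth
            ) * env_a
            for s in stim_onsets:
                v[s : s + erp.size] += erp[: n_samples - s]
            if e.line_freq is not None:
                t = np.arange(n_samples) / sample_rate
                v += e.noise_level * np.sin(
                    2 * np.pi * e.line_freq * t + rng.uniform(0, 2 * np.pi)
                )
            if e.beta_bump is not None:
                f0, rms = e.beta_bump
                v += rms * _narrowband_noise(rng, n_samples, sample_rate, f0, 2.0)
            voltage[r, j] = v

    return SimulatedRecording(
        voltage=voltage,
        events=events,
        sample_rate=sample_rate,
        design=design,
        electrodes=list(electrodes),
        apertures=apertures,
        bb_response=bb_resp,
        alpha_response=a_resp,
    )


def grid_coordinates(grid_shape: tuple[int, int], pitch: float) -> np.ndarray:
    """Planar electrode coordinates (mm) for a rows x cols grid."""
    rows, cols = grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([cc.ravel() * pitch, rr.ravel() * pitch]).astype(float)


def simulate_grid(
    design: StimulusDesign,
    grid_shape: tuple[int, int],
    pitch: float,
    alpha_mixing_length: float,
    seed: int | np.random.Generator = 0,
    electrodes: Sequence[GroundTruthElectrode] | None = None,
    n_runs: int = 1,
    sample_rate: float = 512.0,
    chi: float = 1.5,
    alpha_bandwidth: float = 2.0,
) -> SimulatedRecording:
    """Simulate a planar grid whose alpha sources are spatially correlated.

    Each electrode receives a weighted mixture of per-electrode narrowband
    alpha sources, with weights exp(-d / alpha_mixing_length) over the
    inter-electrode distance d (mm); mixing length 0 means fully independent
    sources. Broadband noise is always independent per electrode.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if alpha_mixing_length < 0:
        raise ValueError("alpha_mixing_length must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    coords = grid_coordinates(grid_shape, pitch)
    n_el = coords.shape[0]
    if electrodes is None:
        electrodes = [GroundTruthElectrode(position=tuple(c)) for c in coords]
    else:
        electrodes = [replace(e, position=tuple(c)) for e, c in zip(electrodes, coords)]
    if len(electrodes) != n_el:
        raise ValueError("electrode list does not match grid size")

    apertures = generate_aperture_sequence(design)
    n_samples = int(round(run_duration(design) * sample_rate))
    events = _event_table(design, apertures.blank)

    bb_resp = np.array([dog_step_responses(apertures, e.bb_prf) for e in electrodes])
    a_resp = np.array([dog_step_responses(apertures, e.alpha_prf) for e in electrodes])

    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    if alpha_mixing_length == 0:
        W = np.eye(n_el)
    else:
        W = np.exp(-d / alpha_mixing_length)
        W /= np.sqrt((W**2).sum(axis=1, keepdims=True))  # preserve per-electrode RMS

    onset_idx = np.round(events["onset"].to_numpy() * sample_rate).astype(int)
    stim_onsets = onset_idx[~apertures.blank]
    voltage = np.empty((n_runs, n_el, n_samples))
    for r in range(n_runs):
        sources = np.stack(
            [
                _narrowband_noise(rng, n_samples, sample_rate, e.alpha_peak, alpha_bandwidth)
                for e in electrodes
            ]
        )
        mixed_alpha = W @ sources
        for j, e in enumerate(electrodes):
            env_bb = _step_envelope(design, n_samples, sample_rate, bb_resp[j])
            env_a = _step_envelope(design, n_samples, sample_rate, -a_resp[j])
            a_rms = e.noise_level if e.alpha_rms is None else e.alpha_rms
            v = e.noise_level * _powerlaw_noise(rng, n_samples, sample_rate, chi) * env_bb
            v += a_rms * mixed_alpha[j] * env_a
            erp = e.erp_template
            if erp is None:
                erp = default_erp_template(sample_rate) * e.erp_gain * e.noise_level
            for s in stim_onsets:
                v[s : s + erp.size] += erp[: n_samples - s]
            voltage[r, j] = v

    return SimulatedRecording(
        voltage=voltage,
        events=events,
        sample_rate=sample_rate,
        design=design,
        electrodes=list(electrodes),
        apertures=apertures,
        bb_response=bb_resp,
        alpha_response=a_resp,
    )


def make_cohort(
    n_electrodes: int,
    seed: int | np.random.Generator = 0,
    design: StimulusDesign | None = None,
    sigma_ratio: float = 2.0,
    bb_peak_response: float = 0.4,
    alpha_peak_suppression: float = 0.7,
    center_spread: float = 5.0,
    sigma_range: tuple[float, float] = (0.8, 1.8),
    surround_fraction: float = 0.1,
    alpha_rms_factor: float = 0.55,
) -> list[GroundTruthElectrode]:
    """Draw a cohort of ground-truth electrodes with shared-center pRF pairs.

    Each electrode gets a broadband pRF (positive, sigma drawn from
    ``sigma_range``) and an alpha pRF at the same center with
    ``sigma_ratio`` times the size. Gains are scaled per electrode so the
    strongest aperture drives a broadband elevation of
    ``bb_peak_response`` and an alpha suppression of
    ``alpha_peak_suppression`` (both log10 power-ratio units, i.e. a
    x1.6 broadband increase and a x3 alpha power reduction at the center
    of the pRF — magnitudes typical of visual cortex). The surround gain
    g2 removes ``surround_fraction`` of the peak response for a bar at the
    pRF center. ``alpha_rms_factor`` sets the alpha rhythm's RMS relative
    to the broadband RMS; the default puts the blank-spectrum alpha peak
    about five times above the 1/f background, typical of occipital
    recordings, so the broadband elevation and the oscillatory change
    genuinely overlap in the alpha band (the regime the decomposition
    exists for).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if design is None:
        design = StimulusDesign()
    apertures = generate_aperture_sequence(design)

    cohort = []
    for _ in range(n_electrodes):
        ecc = rng.uniform(0.5, center_spread)
        theta = rng.uniform(0, 2 * np.pi)
        x0, y0 = ecc * np.cos(theta), ecc * np.sin(theta)
        sig_bb = rng.uniform(*sigma_range)
        sig_a = sigma_ratio * sig_bb
        peak_hz = rng.uniform(8.5, 12.5)

        prfs = []
        for sig, peak in (
            (sig_bb, bb_peak_response),
            (sig_a, alpha_peak_suppression),
        ):
            raw = dog_step_responses(apertures, (x0, y0, sig, 1.0, 0.0))
            g1 = peak / raw.max()
            # surround sized so a center bar loses surround_fraction of peak
            npix = apertures.masks.reshape(len(apertures), -1).sum(axis=1)
            g2 = surround_fraction * peak / max(npix[np.argmax(raw)], 1)
            prfs.append((x0, y0, sig, g1, g2))

        cohort.append(
            GroundTruthElectrode(
                bb_prf=prfs[0], alpha_prf=prfs[1], alpha_peak=peak_hz,
                alpha_rms=alpha_rms_factor,
            )
        )
    return cohort


def make_area_probabilities(
    n_electrodes: int,
    seed: int | np.random.Generator = 0,
    groups: tuple[str, str] = ("V1-V3", "dorsolateral"),
    overlap: float = 0.3,
    none_mass: float = 0.2,
) -> list[dict[str, float]]:
    """Synthetic visual-area probability vectors for a cohort.

    Each electrode gets probability mass split between two area groups and a
    residual "no area" remainder of about ``none_mass``. With ``overlap`` 0
    every electrode is committed to one group; larger values blur the
    assignment, emulating the uncertainty of matching electrodes to a
    probabilistic atlas.
    """
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(n_electrodes):
        primary = groups[i % 2]
        secondary = groups[(i + 1) % 2]
        assigned = 1.0 - rng.uniform(0.5, 1.5) * none_mass
        assigned = float(np.clip(assigned, 0.1, 1.0))
        mix = overlap * rng.uniform(0.0, 0.5)
        out.append({primary: assigned * (1 - mix), secondary: assigned * mix})
    return out
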