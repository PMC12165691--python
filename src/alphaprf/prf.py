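"""Difference-of-Gaussians population receptive field fitting.

The pRF is a circular 2-D Gaussian center with an infinite (constant)
surround: PRF = g1 G(x, y, sigma) - g2. The predicted response to one
aperture step is the dot product of the (possibly decimated, hence
real-valued) stimulus mask with the pRF image. Model accuracy is the
uncentered coefficient of determination

    R^2 = 1 - sum (RESP_model - RESP_data)^2 / sum RESP_data^2,

computed on training data for the full fit and on concatenated held-out
predictions for the split-half cross-validation (first 38 / last 37 of the
75 decimated time points; with the stock sweep order each half contains a
complete horizontal and a complete vertical sweep).

Sign conventions: broadband responses are fitted with a positive center and
negative surround ("positive"); alpha suppression with a negative center and
positive surround ("negative", implemented by fitting the positive model to
the negated series); "free" leaves the center gain unconstrained, the
control configuration in which uncorrected alpha estimates produce pRFs of
mixed sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares

from .decompose import decimate_series
from .synth import ApertureSequence

__all__ = [
    "PRFParams",
    "PRFFit",
    "StimulusMatrix",
    "prepare_stimulus",
    "dog_response",
    "fit_prf",
    "crossvalidate_prf",
    "fit_prf_cv",
    "to_polar",
    "PolarCoords",
]

XY_BOUND = 16.6  # degrees; twice the maximal stimulus extent
SIGMA_BOUNDS = (0.1, 25.0)
CV_SPLIT = 38  # first-half length of the 75-point series


class PolarCoords(NamedTuple):
    angle: float  # degrees, 0 = right horizontal meridian, counterclockwise
    eccentricity: float
    defined: bool  # False at the origin, where the angle is arbitrary


@dataclass
class PRFParams:
    """DoG pRF parameters in degrees of visual angle.

    ``g1``/``g2`` are nonnegative magnitudes; ``sign`` says how the center
    is applied ("positive", "negative" or "free"; for "free" ``g1`` carries
    its own sign).
    """

    x: float
    y: float
    sigma: float
    g1: float
    g2: float
    sign: str = "positive"

    @property
    def polar(self) -> PolarCoords:
        return to_polar(self.x, self.y)

    @property
    def center_gain(self) -> float:
        return -self.g1 if self.sign == "negative" else self.g1


@dataclass
class PRFFit:
    params: PRFParams
    r2_train: float
    predicted: np.ndarray
    data: np.ndarray
    r2_cv: float | None = None
    degenerate: bool = False


@dataclass
class StimulusMatrix:
    """Flattened aperture sequence ready for fitting: (n_steps, n_pixels)."""

    stim: np.ndarray
    xs: np.ndarray  # pixel x coordinates, degrees
    ys: np.ndarray  # pixel y coordinates, degrees
    npix: np.ndarray = None  # per-step summed mask (surround drive)

    def __post_init__(self) -> None:
        if self.npix is None:
            self.npix = self.stim.sum(axis=1)


def prepare_stimulus(
    apertures: ApertureSequence,
    decimation: int | None = 3,
    spatial_downsample: int = 2,
) -> StimulusMatrix:
    """Flatten (and optionally decimate in time) the aperture masks.

    Temporal decimation uses the same zero-phase Chebyshev filter as the
    summary time courses, so stimulus and response stay aligned sample for
    sample. ``spatial_downsample`` block-sums the masks (each coarse pixel
    carries the covered area of its block), which preserves the aperture-pRF
    dot product up to the Gaussian's variation within a block while cutting
    the fitting cost quadratically; set it to 1 for exact full-resolution
    masks.
    """
    masks = apertures.masks.astype(float)
    res = masks.shape[1]
    f = spatial_downsample
    if f > 1:
        if res % f:
            raise ValueError("grid resolution must be divisible by spatial_downsample")
        masks = masks.reshape(len(masks), res // f, f, res // f, f).sum(axis=(2, 4))
        px = apertures.design.pixel_centers().reshape(-1, f).mean(axis=1)
    else:
        px = apertures.design.pixel_centers()
    flat = masks.reshape(len(masks), -1)
    if decimation:
        flat = decimate_series(flat, decimation, axis=0)
    X, Y = np.meshgrid(px, px)
    return StimulusMatrix(stim=np.ascontiguousarray(flat), xs=X.ravel(), ys=Y.ravel())


def dog_response(stim: StimulusMatrix, params: PRFParams) -> np.ndarray:
    """Predicted response per step: STIM . (g1 G(x,y,sigma) - g2), with sign."""
    g = np.exp(
        -((stim.xs - params.x) ** 2 + (stim.ys - params.y) ** 2)
        / (2 * params.sigma**2)
    )
    resp = params.g1 * (stim.stim @ g) - params.g2 * stim.npix
    return -resp if params.sign == "negative" else resp


def uncentered_r2(predicted: np.ndarray, data: np.ndarray) -> float:
    """R^2 with an uncentered denominator (sum of squared data values)."""
    denom = float(np.sum(np.asarray(data) ** 2))
    if denom == 0:
        return 0.0
    return 1.0 - float(np.sum((np.asarray(predicted) - np.asarray(data)) ** 2)) / denom


def _raw_model(stim: StimulusMatrix, p: np.ndarray) -> np.ndarray:
    g = np.exp(-((stim.xs - p[0]) ** 2 + (stim.ys - p[1]) ** 2) / (2 * p[2] ** 2))
    return p[3] * (stim.stim @ g) - p[4] * stim.npix


def _coarse_starts(stim, target, free_gain, n_keep=3):
    """Grid-search (x, y, sigma) with closed-form gains; return best starts."""
    xs = np.linspace(-0.8 * XY_BOUND / 2, 0.8 * XY_BOUND / 2, 5)
    sigmas = (0.8, 1.6, 3.2, 6.4)
    npix = stim.npix
    cands = []
    for x0 in xs:
        for y0 in xs:
            for s0 in sigmas:
                g = np.exp(
                    -((stim.xs - x0) ** 2 + (stim.ys - y0) ** 2) / (2 * s0**2)
                )
                col = stim.stim @ g
                M = np.column_stack([col, -npix])
                coef, *_ = np.linalg.lstsq(M, target, rcond=None)
                g1, g2 = coef
                if not free_gain:
                    g1 = max(g1, 0.0)
                g2 = max(g2, 0.0)
                sse = float(np.sum((g1 * col - g2 * npix - target) ** 2))
                cands.append((sse, [x0, y0, s0, g1, g2]))
    cands.sort(key=lambda c: c[0])
    return [c[1] for c in cands[:n_keep]]


def fit_prf(
    series: np.ndarray,
    stim: StimulusMatrix,
    sign: str = "positive",
    n_starts: int = 3,
    tol: float = 1e-12,
) -> PRFFit:
    """Bounded nonlinear least-squares DoG fit with a multi-start grid.

    A coarse lattice over (x, y, sigma) — with the two gains solved in
    closed form at each node — seeds local trust-region refinements; the
    best refined solution is kept. Bounds: |x|, |y| <= 16.6 deg,
    sigma in [0.1, 25] deg, gains nonnegative (center gain unconstrained
    in "free" mode).
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] != stim.stim.shape[0]:
        raise ValueError("series and stimulus sequence must have equal length")
    if np.allclose(series, 0):
        params = PRFParams(0.0, 0.0, 1.0, 0.0, 0.0, sign)
        return PRFFit(params, uncentered_r2(np.zeros_like(series), series),
                      np.zeros_like(series), series, degenerate=True)

    target = -series if sign == "negative" else series
    free_gain = sign == "free"
    g1_lo = -np.inf if free_gain else 0.0
    lo = np.array([-XY_BOUND, -XY_BOUND, SIGMA_BOUNDS[0], g1_lo, 0.0])
    hi = np.array([XY_BOUND, XY_BOUND, SIGMA_BOUNDS[1], np.inf, np.inf])

    best, best_cost = None, np.inf
    for x0 in _coarse_starts(stim, target, free_gain, n_keep=n_starts):
        x0 = np.clip(x0, np.where(np.isfinite(lo), lo + 1e-9, -1e6),
                     np.where(np.isfinite(hi), hi - 1e-9, 1e6))
        res = least_squares(
            lambda p: _raw_model(stim, p) - target,
            x0, bounds=(lo, hi), method="trf", xtol=tol, ftol=tol, gtol=tol,
        )
        if res.cost < best_cost:
            best, best_cost = res, res.cost

    p = best.x
    params = PRFParams(p[0], p[1], p[2], p[3], p[4], sign)
    pred = dog_response(stim, params)
    return PRFFit(params, uncentered_r2(pred, series), pred, series)


def crossvalidate_prf(
    series: np.ndarray,
    stim: StimulusMatrix,
    sign: str = "positive",
    split: int = CV_SPLIT,
    **fit_kwargs,
) -> tuple[float, np.ndarray]:
    """Twofold split-half cross-validated accuracy.

    Fit on the first ``split`` points and predict the rest, then the
    converse; the concatenated held-out predictions are scored against the
    full series with the uncentered R^2.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    pred = np.empty(n)
    halves = [(slice(0, split), slice(split, n)), (slice(split, n), slice(0, split))]
    for train, test in halves:
        sub = StimulusMatrix(stim.stim[train], stim.xs, stim.ys)
        fit = fit_prf(series[train], sub, sign=sign, **fit_kwargs)
        test_stim = StimulusMatrix(stim.stim[test], stim.xs, stim.ys)
        pred[test] = dog_response(test_stim, fit.params)
    return uncentered_r2(pred, series), pred


def fit_prf_cv(series, stim, sign: str = "positive", **kw) -> PRFFit:
    """Full fit for parameters plus split-half fit for accuracy."""
    fit = fit_prf(series, stim, sign=sign, **kw)
    if not fit.degenerate:
        fit.r2_cv, _ = crossvalidate_prf(series, stim, sign=sign, **kw)
    else:
        fit.r2_cv = 0.0
    return fit


def to_polar(x: float, y: float) -> PolarCoords:
    """Cartesian pRF center to (polar angle, eccentricity) in degrees.

    Angle is measured counterclockwise from the right horizontal meridian,
    in [0, 360). At the origin the angle is undefined and reported as 0
    with ``defined=False``.
    """
    ecc = float(np.hypot(x, y))
    if ecc == 0.0:
        return PolarCoords(0.0, 0.0, False)
    ang = float(np.degrees(np.arctan2(y, x)) % 360.0)
    return PolarCoords(ang, ecc, True)
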