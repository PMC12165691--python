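"""Cohort-level statistics on fitted pRFs.

Electrode selection uses shuffle nulls: each electrode's summary series is
scored against the pRF predictions fitted to *other* electrodes, and the
resulting null distribution of (uncentered, cross-prediction) R^2 sets the
accuracy threshold. Selected broadband/alpha pRF pairs are compared via a
normalized coordinate frame, exact circle-overlap areas, bootstraps with
probabilistic visual-area assignment, and size-eccentricity regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .prf import PRFFit, PRFParams, to_polar, uncentered_r2

__all__ = [
    "ElectrodeRecord",
    "SelectionThresholds",
    "shuffle_null_threshold",
    "select_electrodes",
    "normalize_prf_pair",
    "prf_overlap_percent",
    "shuffled_overlap_control",
    "bootstrap_area_comparison",
    "size_eccentricity_regression",
    "circular_corrcoef",
    "wrap_angle_deg",
]

STIMULUS_EXTENT = 8.3  # degrees; maximal stimulus eccentricity


@dataclass
class ElectrodeRecord:
    """One electrode's fitted pRFs plus its visual-area probability vector."""

    electrode: int
    fits: dict[str, PRFFit]  # keyed by signal type, e.g. "broadband", "alpha"
    area_probs: dict[str, float] = field(default_factory=dict)  # sums to <= 1
    site: str = "synthetic"

    def __post_init__(self) -> None:
        total = sum(self.area_probs.values())
        if total > 1 + 1e-9 or any(p < 0 for p in self.area_probs.values()):
            raise ValueError("area probabilities must be in [0, 1] and sum to <= 1")


@dataclass
class SelectionThresholds:
    broadband_r2: float
    alpha_r2: float
    max_eccentricity: float = STIMULUS_EXTENT


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation without fixed points (deterministic swap for n=2)."""
    if n < 2:
        raise ValueError("need at least 2 items to shuffle")
    if n == 2:
        return np.array([1, 0])
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def shuffle_null_threshold(
    series: np.ndarray,
    predictions: np.ndarray,
    n_shuffles: int = 5000,
    percentile: float = 95.0,
    seed=0,
) -> tuple[float, np.ndarray]:
    """Accuracy threshold from shuffled series-to-pRF assignment.

    ``series`` and ``predictions`` are (n_electrodes, n_points): each
    electrode's summary time course and the prediction of its own fitted
    pRF. Per shuffle, every electrode's series is scored (uncentered R^2)
    against a different electrode's prediction; the threshold is the given
    percentile of the pooled null scores. Fixed seed gives a fixed
    threshold. Returns (threshold, pooled null scores).
    """
    series = np.asarray(series, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    n = series.shape[0]
    if n < 2:
        raise ValueError("need at least 2 electrodes")
    rng = _rng(seed)
    null = np.empty((n_shuffles, n))
    for s in range(n_shuffles):
        p = _derangement(n, rng)
        for i in range(n):
            null[s, i] = uncentered_r2(predictions[p[i]], series[i])
    pooled = null.ravel()
    return float(np.percentile(pooled, percentile)), pooled


def select_electrodes(
    records: list[ElectrodeRecord],
    thresholds: SelectionThresholds,
    signals: tuple[str, str] = ("broadband", "alpha"),
) -> tuple[np.ndarray, list[str]]:
    """Keep electrodes whose both pRFs beat their thresholds (strictly) and
    whose centers lie within the stimulus extent. Returns a keep mask and a
    per-electrode reason string ("kept" or the first failed rule)."""
    keep = np.zeros(len(records), dtype=bool)
    reasons = []
    th = {signals[0]: thresholds.broadband_r2, signals[1]: thresholds.alpha_r2}
    for i, rec in enumerate(records):
        reason = "kept"
        for sig in signals:
            fit = rec.fits.get(sig)
            if fit is None or fit.r2_cv is None:
                reason = f"missing {sig} fit"
                break
            if not fit.r2_cv > th[sig]:  # strict inequality; ties excluded
                reason = f"{sig} accuracy"
                break
            if fit.params.polar.eccentricity > thresholds.max_eccentricity:
                reason = f"{sig} eccentricity"
                break
        keep[i] = reason == "kept"
        reasons.append(reason)
    return keep, reasons


def normalize_prf_pair(bb: PRFParams, alpha: PRFParams) -> tuple[PRFParams, PRFParams]:
    """Rotate and scale a pRF pair so the broadband center lands at (0, 1).

    Both centers are rotated by the same angle (an isometry, so the
    center-to-center distance over broadband eccentricity is preserved) and
    all lengths (eccentricities and sizes) are divided by the broadband
    eccentricity. Undefined when the broadband center is at the origin.
    """
    ang, ecc, defined = to_polar(bb.x, bb.y)
    if not defined:
        raise ValueError("broadband eccentricity is zero; normalization undefined")
    rot = np.radians(90.0 - ang)
    c, s = np.cos(rot), np.sin(rot)

    def _xform(p: PRFParams) -> PRFParams:
        x = (c * p.x - s * p.y) / ecc
        y = (s * p.x + c * p.y) / ecc
        return PRFParams(x, y, p.sigma / ecc, p.g1, p.g2, p.sign)

    return _xform(bb), _xform(alpha)


def prf_overlap_percent(
    inner: PRFParams, outer: PRFParams, truncation: float = 1.0
) -> float:
    """Percent of the inner pRF disk (radius = truncation x sigma) covered by
    the outer disk, from the exact circle-circle lens area."""
    r1, r2 = truncation * inner.sigma, truncation * outer.sigma
    if r1 <= 0 or r2 <= 0:
        raise ValueError("sigmas must be positive")
    d = float(np.hypot(inner.x - outer.x, inner.y - outer.y))
    if d >= r1 + r2:
        lens = 0.0
    elif d <= abs(r2 - r1):
        lens = np.pi * min(r1, r2) ** 2
    else:
        a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
        a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
        tri = 0.5 * np.sqrt(
            (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
        )
        lens = a1 + a2 - tri
    return 100.0 * lens / (np.pi * r1**2)


def shuffled_overlap_control(
    records: list[ElectrodeRecord],
    n_shuffles: int = 1000,
    seed=0,
    signals: tuple[str, str] = ("broadband", "alpha"),
    truncation: float = 1.0,
) -> float:
    """Mean overlap after randomly re-pairing broadband and alpha pRFs.

    Permutations exclude the identity pairing (with two records this is the
    deterministic swap), so the statistic measures overlap expected from the
    cohort's spatial spread alone.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    rng = _rng(seed)
    bb = [r.fits[signals[0]].params for r in records]
    al = [r.fits[signals[1]].params for r in records]
    vals = []
    for _ in range(n_shuffles):
        p = _derangement(len(records), rng)
        vals.extend(
            prf_overlap_percent(al[p[i]], bb[i], truncation) for i in range(len(records))
        )
    return float(np.mean(vals))


def wrap_angle_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (-180, 180]."""
    return -((180.0 - np.asarray(a)) % 360.0 - 180.0)


def circular_corrcoef(a_deg: np.ndarray, b_deg: np.ndarray) -> float:
    """Fisher-Lee circular correlation of two angle samples (degrees)."""
    a = np.radians(np.asarray(a_deg, dtype=float))
    b = np.radians(np.asarray(b_deg, dtype=float))
    a = a - np.arctan2(np.sin(a).mean(), np.cos(a).mean())
    b = b - np.arctan2(np.sin(b).mean(), np.cos(b).mean())
    num = np.sum(np.sin(a) * np.sin(b))
    den = np.sqrt(np.sum(np.sin(a) ** 2) * np.sum(np.sin(b) ** 2))
    return float(num / den) if den > 0 else 0.0


@dataclass
class AreaComparison:
    """Pooled bootstrap draws of (broadband, alpha) parameter pairs per area."""

    samples: dict[str, dict[str, np.ndarray]]  # area -> param -> (n, 2)
    ellipses: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]  # mean, cov
    correlations: dict[str, dict[str, float]]


def _draw_areas(records, rng) -> list[str | None]:
    out = []
    for rec in records:
        names = list(rec.area_probs)
        probs = np.array([rec.area_probs[k] for k in names])
        probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
        idx = rng.choice(len(names) + 1, p=probs / probs.sum())
        out.append(names[idx] if idx < len(names) else None)
    return out


def bootstrap_area_comparison(
    records: list[ElectrodeRecord],
    n_boot: int = 5000,
    seed=0,
    signals: tuple[str, str] = ("broadband", "alpha"),
) -> AreaComparison:
    """Resample electrodes with replacement and assign areas probabilistically.

    Each bootstrap draws n electrodes with replacement and assigns every
    draw to a visual-area group according to its probability vector (the
    residual probability maps to no area and drops the draw). Pooled
    (broadband, alpha) pairs of polar angle, eccentricity and size are
    accumulated per area; 68% confidence ellipses use the chi-square(2 dof)
    scaling of the sample covariance. Angle pairs use circular correlation
    and are wrapped.
    """
    rng = _rng(seed)
    params = ("angle", "eccentricity", "size")

    def _vals(fit: PRFFit) -> dict[str, float]:
        pol = fit.params.polar
        return {"angle": pol.angle, "eccentricity": pol.eccentricity,
                "size": fit.params.sigma}

    bb_vals = [_vals(r.fits[signals[0]]) for r in records]
    al_vals = [_vals(r.fits[signals[1]]) for r in records]

    pools: dict[str, dict[str, list]] = {}
    n = len(records)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        areas = _draw_areas([records[i] for i in idx], rng)
        for i, area in zip(idx, areas):
            if area is None:
                continue
            pool = pools.setdefault(area, {p: [] for p in params})
            for p in params:
                pool[p].append((bb_vals[i][p], al_vals[i][p]))

    samples, ellipses, correlations = {}, {}, {}
    chi2_68 = stats.chi2(df=2).ppf(0.68)
    for area, pool in pools.items():
        samples[area], ellipses[area], correlations[area] = {}, {}, {}
        for p in params:
            arr = np.asarray(pool[p], dtype=float)
            if p == "angle":
                # wrap alpha angles around the broadband angle before moments
                arr = arr.copy()
                arr[:, 1] = arr[:, 0] + wrap_angle_deg(arr[:, 1] - arr[:, 0])
                corr = circular_corrcoef(arr[:, 0], arr[:, 1])
            else:
                corr = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]) if len(arr) > 1 else np.nan
            samples[area][p] = arr
            ellipses[area][p] = (arr.mean(axis=0), np.cov(arr.T) * chi2_68)
            correlations[area][p] = corr
    return AreaComparison(samples, ellipses, correlations)


def size_eccentricity_regression(
    eccentricity: np.ndarray,
    size: np.ndarray,
    n_boot: int = 5000,
    seed=0,
    grid: np.ndarray | None = None,
) -> dict:
    """Bootstrapped ordinary-least-squares line of pRF size on eccentricity.

    Returns the mean slope/intercept across bootstraps, all per-bootstrap
    draws, and the 16-84% band of the fitted line on an eccentricity grid.
    Degenerate draws (all points at one eccentricity) are discarded.
    """
    ecc = np.asarray(eccentricity, dtype=float)
    sz = np.asarray(size, dtype=float)
    if ecc.size < 5:
        raise ValueError("need at least 5 points")
    if grid is None:
        grid = np.linspace(ecc.min(), ecc.max(), 50)
    rng = _rng(seed)
    slopes, intercepts, lines = [], [], []
    for _ in range(n_boot):
        idx = rng.integers(0, ecc.size, ecc.size)
        e, s = ecc[idx], sz[idx]
        if np.ptp(e) == 0:
            continue
        slope, intercept = np.polyfit(e, s, 1)
        slopes.append(slope)
        intercepts.append(intercept)
        lines.append(slope * grid + intercept)
    lines = np.asarray(lines)
    return {
        "slope": float(np.mean(slopes)),
        "intercept": float(np.mean(intercepts)),
        "slopes": np.asarray(slopes),
        "intercepts": np.asarray(intercepts),
        "grid": grid,
        "band": np.percentile(lines, [16, 84], axis=0),
        "mean_line": lines.mean(axis=0),
    }
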