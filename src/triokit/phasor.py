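"""Phasor-approach FLIM-FRET analysis.

Each pixel's fluorescence decay histogram is mapped to a point in the phasor
plane by its first-harmonic Fourier coefficients

    g = sum_t c_t cos(n w t) / sum_t c_t,   s = sum_t c_t sin(n w t) / sum_t c_t

with ``w = 2 pi / period`` the laser repetition angular frequency and ``t``
the bin midpoint.  Single-exponential decays of lifetime ``tau`` fall on the
universal semicircle at ``g = 1/(1+(w tau)^2)``, ``s = w tau/(1+(w tau)^2)``;
mixtures fall inside it at the intensity-weighted mean of their component
phasors (the linear-combination rule, exact by linearity of the transform).

FRET quenches the donor from ``tau_D`` to ``tau_DA = tau_D (1 - E)``, so the
family of realized phasors for efficiencies E in [0, 1] - each mixed with
fixed background and unquenched-donor pools - traces a curved quenching
trajectory; a measured phasor is assigned the efficiency of its nearest
trajectory point.  Instrument calibration is the rotation + scaling about the
origin that maps a measured single-lifetime reference (e.g. coumarin 6,
tau = 2.55 ns) onto its theoretical phasor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DecayHistogram",
    "PhasorPoint",
    "PhasorCalibration",
    "FretModel",
    "EfficiencyFit",
    "ClusterSummary",
    "phasor_transform",
    "phasor_image",
    "theoretical_phasor",
    "fret_efficiency",
    "calibrate",
    "fret_trajectory",
    "estimate_efficiency",
    "estimate_efficiency_map",
    "cluster_select",
    "median_smooth",
]

DEFAULT_PERIOD_NS = 12.5  # 80 MHz repetition rate


@dataclass(frozen=True)
class PhasorPoint:
    g: float
    s: float

    @property
    def modulus(self) -> float:
        return math.hypot(self.g, self.s)

    def as_complex(self) -> complex:
        return complex(self.g, self.s)

    @classmethod
    def from_complex(cls, z: complex) -> "PhasorPoint":
        return cls(float(z.real), float(z.imag))

    def distance(self, other: "PhasorPoint") -> float:
        return math.hypot(self.g - other.g, self.s - other.s)


@dataclass(frozen=True)
class DecayHistogram:
    """Binned photon arrival times over one laser period."""

    counts: np.ndarray
    bin_width: float  # ns
    period: float = DEFAULT_PERIOD_NS  # ns

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.bin_width <= 0 or self.period <= 0:
            raise ValueError("bin_width and period must be positive")
        if counts.size * self.bin_width > self.period * (1 + 1e-9):
            raise ValueError("histogram span exceeds the laser period")
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


def phasor_transform(decay: DecayHistogram, harmonic: int = 1) -> PhasorPoint:
    """First (or n-th) harmonic phasor of one decay histogram."""
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    total = decay.total_counts
    if total <= 0:
        raise ValueError("phasor undefined for an empty decay")
    omega = 2.0 * math.pi * harmonic / decay.period
    phase = omega * decay.bin_midpoints
    g = float(np.dot(decay.counts, np.cos(phase)) / total)
    s = float(np.dot(decay.counts, np.sin(phase)) / total)
    return PhasorPoint(g, s)


def phasor_image(
    stack: np.ndarray, bin_width: float, period: float = DEFAULT_PERIOD_NS,
    harmonic: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel phasor maps of a (n_bins, height, width) decay stack.

    Pixels with zero photons get NaN coordinates.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must have shape (n_bins, height, width)")
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    omega = 2.0 * math.pi * harmonic / period
    t_mid = (np.arange(stack.shape[0]) + 0.5) * bin_width
    phase = omega * t_mid
    total = stack.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.tensordot(np.cos(phase), stack, axes=(0, 0)) / total
        s = np.tensordot(np.sin(phase), stack, axes=(0, 0)) / total
    g[total == 0] = np.nan
    s[total == 0] = np.nan
    return g, s


def theoretical_phasor(
    tau: float, period: float = DEFAULT_PERIOD_NS, harmonic: int = 1
) -> PhasorPoint:
    """Closed-form phasor of a single-exponential decay of lifetime ``tau``."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if period <= 0 or harmonic < 1:
        raise ValueError("period must be positive and harmonic >= 1")
    wt = 2.0 * math.pi * harmonic / period * tau
    denom = 1.0 + wt * wt
    return PhasorPoint(1.0 / denom, wt / denom)


def fret_efficiency(tau_da: float, tau_d: float) -> float:
    """E = 1 - tau_DA / tau_D."""
    if tau_d <= 0 or tau_da < 0:
        raise ValueError("lifetimes must be positive (tau_d) / non-negative")
    return 1.0 - tau_da / tau_d


@dataclass(frozen=True)
class PhasorCalibration:
    """Rotation + scaling about the origin, as one complex factor."""

    factor: complex

    @property
    def rotation_deg(self) -> float:
        return math.degrees(math.atan2(self.factor.imag, self.factor.real))

    @property
    def scale(self) -> float:
        return abs(self.factor)

    def apply(self, point: PhasorPoint) -> PhasorPoint:
        return PhasorPoint.from_complex(self.factor * point.as_complex())

    def apply_arrays(
        self, g: np.ndarray, s: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        a, b = self.factor.real, self.factor.imag
        return a * g - b * s, b * g + a * s


def calibrate(
    measured_ref: PhasorPoint,
    tau_ref: float,
    period: float = DEFAULT_PERIOD_NS,
    harmonic: int = 1,
) -> PhasorCalibration:
    """Calibration mapping a measured single-lifetime reference onto its
    theoretical phasor (unique rotation + scaling about the origin)."""
    if measured_ref.modulus <= 0:
        raise ValueError("reference phasor has zero modulus; cannot calibrate")
    target = theoretical_phasor(tau_ref, period, harmonic)
    return PhasorCalibration(target.as_complex() / measured_ref.as_complex())


@dataclass(frozen=True)
class FretModel:
    """Donor lifetime plus fixed mixing fractions for trajectory evaluation.

    ``donor_fraction``, ``background_fraction`` and ``unquenched_fraction``
    are intensity weights of the FRET-capable donor pool, the background and
    the donor-without-acceptor pool; they must sum to 1.  The background
    enters as a fixed phasor determined independently.
    """

    tau_d: float  # ns, unquenched donor lifetime
    period: float = DEFAULT_PERIOD_NS
    donor_fraction: float = 1.0
    background_fraction: float = 0.0
    unquenched_fraction: float = 0.0
    background_phasor: PhasorPoint = field(default_factory=lambda: PhasorPoint(0.0, 0.0))
    harmonic: int = 1

    def __post_init__(self):
        weights = (self.donor_fraction, self.background_fraction, self.unquenched_fraction)
        if any(w < 0 for w in weights):
            raise ValueError("fractions must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.tau_d < 0:
            raise ValueError("tau_d must be non-negative")

    def trajectory_point(self, efficiency) -> tuple[np.ndarray, np.ndarray]:
        """Realized (g, s) for efficiency value(s) in [0, 1]; vectorized."""
        e = np.asarray(efficiency, dtype=float)
        if np.any((e < 0) | (e > 1)):
            raise ValueError("efficiency must lie in [0, 1]")
        omega = 2.0 * math.pi * self.harmonic / self.period
        wt = omega * self.tau_d * (1.0 - e)
        denom = 1.0 + wt * wt
        gq, sq = 1.0 / denom, wt / denom
        donor_ref = theoretical_phasor(self.tau_d, self.period, self.harmonic)
        g = (
            self.donor_fraction * gq
            + self.background_fraction * self.background_phasor.g
            + self.unquenched_fraction * donor_ref.g
        )
        s = (
            self.donor_fraction * sq
            + self.background_fraction * self.background_phasor.s
            + self.unquenched_fraction * donor_ref.s
        )
        return g, s


def fret_trajectory(model: FretModel, efficiency_grid) -> list[PhasorPoint]:
    """Realized phasors along the quenching trajectory at the given
    efficiencies."""
    g, s = model.trajectory_point(np.asarray(efficiency_grid, dtype=float))
    return [PhasorPoint(float(gi), float(si)) for gi, si in zip(np.atleast_1d(g), np.atleast_1d(s))]


@dataclass(frozen=True)
class EfficiencyFit:
    efficiency: float
    residual: float
    fitted: PhasorPoint


def estimate_efficiency(measured: PhasorPoint, model: FretModel) -> EfficiencyFit:
    """Nearest-trajectory projection: argmin over E in [0, 1] of the phasor
    distance to the quenching trajectory (dense grid + bounded refinement,
    resolution <= 1e-4 in E)."""
    if model.tau_d <= 0:
        raise ValueError("degenerate trajectory: tau_d must be positive")

    def dist2(e: float) -> float:
        g, s = model.trajectory_point(e)
        return (g - measured.g) ** 2 + (s - measured.s) ** 2

    grid = np.linspace(0.0, 1.0, 2001)
    gg, ss = model.trajectory_point(grid)
    d2 = (gg - measured.g) ** 2 + (ss - measured.s) ** 2
    i = int(np.argmin(d2))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    if hi - lo < 1e-12:
        best = float(grid[i])
    else:
        res = minimize_scalar(dist2, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        best = float(np.clip(res.x, 0.0, 1.0))
        if dist2(best) > d2[i]:
            best = float(grid[i])
    g, s = model.trajectory_point(best)
    fitted = PhasorPoint(float(g), float(s))
    return EfficiencyFit(best, measured.distance(fitted), fitted)


def estimate_efficiency_map(
    g_map: np.ndarray,
    s_map: np.ndarray,
    model: FretModel,
    coarse: int = 512,
    chunk: int = 1024,
) -> np.ndarray:
    """Per-pixel nearest-trajectory efficiency for phasor maps.

    Two-stage vectorized search: a shared coarse grid, then a per-pixel fine
    grid spanning +/- 2 coarse steps (net resolution < 1e-4 in E).  NaN
    phasors (empty pixels) map to NaN.
    """
    if model.tau_d <= 0:
        raise ValueError("degenerate trajectory: tau_d must be positive")
    g_flat = np.asarray(g_map, dtype=float).ravel()
    s_flat = np.asarray(s_map, dtype=float).ravel()
    out = np.full(g_flat.shape, np.nan)
    grid = np.linspace(0.0, 1.0, coarse)
    gg, ss = model.trajectory_point(grid)
    step = grid[1] - grid[0]
    valid = ~(np.isnan(g_flat) | np.isnan(s_flat))
    idx = np.flatnonzero(valid)
    for start in range(0, idx.size, chunk):
        sel = idx[start : start + chunk]
        d2 = (gg[None, :] - g_flat[sel, None]) ** 2 + (
            ss[None, :] - s_flat[sel, None]
        ) ** 2
        best = grid[np.argmin(d2, axis=1)]
        fine_offsets = np.linspace(-2 * step, 2 * step, 81)
        e_fine = np.clip(best[:, None] + fine_offsets[None, :], 0.0, 1.0)
        gf, sf = model.trajectory_point(e_fine)
        d2f = (gf - g_flat[sel, None]) ** 2 + (sf - s_flat[sel, None]) ** 2
        out[sel] = e_fine[np.arange(sel.size), np.argmin(d2f, axis=1)]
    return out.reshape(np.asarray(g_map).shape)


@dataclass(frozen=True)
class ClusterSummary:
    centroid: PhasorPoint
    n_pixels: int


def cluster_select(
    g_map: np.ndarray,
    s_map: np.ndarray,
    center: PhasorPoint,
    radius: float,
) -> tuple[np.ndarray, ClusterSummary]:
    """Boolean mask of pixels whose phasor lies within a disc, plus the
    selected cloud's centroid and size; mask shares the image shape."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    g = np.asarray(g_map, dtype=float)
    s = np.asarray(s_map, dtype=float)
    d2 = (g - center.g) ** 2 + (s - center.s) ** 2
    mask = d2 <= radius * radius
    mask &= ~(np.isnan(g) | np.isnan(s))
    n = int(mask.sum())
    if n:
        centroid = PhasorPoint(float(g[mask].mean()), float(s[mask].mean()))
    else:
        centroid = PhasorPoint(float("nan"), float("nan"))
    return mask, ClusterSummary(centroid, n)


def median_smooth(g_map: np.ndarray, s_map: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optional 3x3 median filter of per-pixel phasors before clustering."""
    from scipy.ndimage import median_filter

    return (
        median_filter(np.asarray(g_map, dtype=float), size=3),
        median_filter(np.asarray(s_map, dtype=float), size=3),
    )
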