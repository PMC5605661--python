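"""Quantal coefficient-of-variation analysis of paired eEPSC recordings.

In the binomial release model an evoked response is the sum over N release
sites, each releasing with probability p a quantum of size q, so the mean is
Npq and, with quantal variability gamma (CV of q), the variance is
N p q^2 (1 - p + gamma^2).  The normalized inverse squared coefficient of
variation, CV^-2 = mean^2 / variance = N p / (1 - p + gamma^2), depends on
quantal content (Np) but not quantal size (q).  Comparing a transfected
neuron against its simultaneously recorded control neighbor: a pure
quantal-size change moves the mean ratio but leaves the CV^-2 ratio at 1
(horizontal line), while a quantal-content change moves both ratios equally
(diagonal); each pair (or the group centroid) is classified by which line it
is closer to in log-log coordinates, with a dead-band for ambiguity.

Exact two-sided Wilcoxon tests (signed-rank for pairs, rank-sum across
conditions) are computed from the full permutation null distribution for
small samples and by normal approximation with continuity correction beyond.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "SweepTrain",
    "PairedRecording",
    "CvSummary",
    "QUANTAL_SIZE",
    "QUANTAL_CONTENT",
    "AMBIGUOUS",
    "extract_amplitude",
    "qc_series_resistance",
    "ppf_ratio",
    "cv_inverse_squared",
    "classify_cv_point",
    "cv_pair_analysis",
    "wilcoxon_signed_rank",
    "rank_sum",
    "simulate_quantal_pairs",
]

QUANTAL_SIZE = "quantal_size"
QUANTAL_CONTENT = "quantal_content"
AMBIGUOUS = "ambiguous"

DEFAULT_DEADBAND = 0.05  # log-distance difference below which a point is ambiguous


@dataclass(frozen=True)
class SweepTrain:
    """Per-sweep eEPSC amplitudes (pA, sign-rectified magnitudes)."""

    amplitudes: np.ndarray
    receptor: str = "AMPAR"
    holding_mv: float = -70.0
    series_resistance_mohm: np.ndarray | None = None

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.ndim != 1 or amps.size < 2:
            raise ValueError("a sweep train needs >= 2 amplitudes")
        if not np.isfinite(amps).all():
            raise ValueError("amplitudes must be finite")
        if self.receptor not in ("AMPAR", "NMDAR"):
            raise ValueError(f"unknown receptor {self.receptor!r}")
        object.__setattr__(self, "amplitudes", amps)
        if self.series_resistance_mohm is not None:
            object.__setattr__(
                self,
                "series_resistance_mohm",
                np.asarray(self.series_resistance_mohm, dtype=float),
            )

    @property
    def n_sweeps(self) -> int:
        return int(self.amplitudes.size)

    @property
    def mean(self) -> float:
        return float(self.amplitudes.mean())

    @property
    def variance(self) -> float:
        return float(self.amplitudes.var(ddof=1))


@dataclass(frozen=True)
class PairedRecording:
    control: SweepTrain
    transfected: SweepTrain
    pair_id: str = ""

    def __post_init__(self):
        if self.control.receptor != self.transfected.receptor:
            raise ValueError("paired trains must share a receptor type")


@dataclass(frozen=True)
class CvSummary:
    pair_id: str
    mean_ratio: float
    cv_inv_sq_ratio: float
    classification: str


def extract_amplitude(
    time_s: np.ndarray,
    current_pa: np.ndarray,
    stim_time_s: float,
    receptor: str = "AMPAR",
    baseline_s: float = 0.005,
    peak_window_s: float = 0.050,
    nmdar_delay_s: float = 0.150,
) -> float:
    """Baseline-subtracted response amplitude (pA magnitude) from one sweep.

    AMPAR: peak magnitude in ``peak_window_s`` after the stimulus.
    NMDAR: value at ``stim_time + nmdar_delay_s`` (temporally isolated after
    the fast component has decayed).
    """
    t = np.asarray(time_s, dtype=float)
    i = np.asarray(current_pa, dtype=float)
    need = stim_time_s + (nmdar_delay_s if receptor == "NMDAR" else peak_window_s)
    if t[0] > stim_time_s - baseline_s or t[-1] < need:
        raise ValueError("trace does not cover the required analysis window")
    base_mask = (t >= stim_time_s - baseline_s) & (t < stim_time_s)
    baseline = float(i[base_mask].mean())
    if receptor == "NMDAR":
        value = float(np.interp(stim_time_s + nmdar_delay_s, t, i))
        return abs(value - baseline)
    win = (t >= stim_time_s) & (t <= stim_time_s + peak_window_s)
    deflection = i[win] - baseline
    return float(np.max(np.abs(deflection)))


def qc_series_resistance(
    train: SweepTrain, max_fractional_change: float = 0.25
) -> bool:
    """Keep/discard rule: discard when series resistance varies by more than
    the allowed fraction over the recording.  Returns True to keep."""
    rs = train.series_resistance_mohm
    if rs is None or rs.size == 0:
        warnings.warn("no series-resistance readings; passing QC by default")
        return True
    lo, hi = float(np.min(rs)), float(np.max(rs))
    if lo <= 0:
        raise ValueError("series resistance must be positive")
    return (hi - lo) / lo <= max_fractional_change


def ppf_ratio(peak1: float, peak2: float) -> float:
    """Paired-pulse ratio: response to stimulus 2 over response to stimulus 1."""
    if peak1 <= 0:
        raise ValueError("peak1 must be positive")
    return peak2 / peak1


def cv_inverse_squared(train: SweepTrain, noise_variance: float = 0.0) -> float:
    """CV^-2 = mean^2 / (unbiased sample variance - noise_variance).

    Optional baseline-noise variance subtraction is off (0) by default.
    """
    if noise_variance < 0:
        raise ValueError("noise_variance must be non-negative")
    corrected = train.variance - noise_variance
    if corrected <= 0:
        raise ValueError("non-positive corrected variance; CV^-2 undefined")
    return train.mean**2 / corrected


def classify_cv_point(
    mean_ratio: float,
    cv_inv_sq_ratio: float,
    deadband: float = DEFAULT_DEADBAND,
) -> str:
    """Classify a (mean ratio, CV^-2 ratio) point in log-log coordinates.

    Distance to the horizontal line (CV^-2 ratio = 1, pure quantal-size
    change) is |log r_cv|; distance to the diagonal (CV^-2 ratio = mean
    ratio, pure quantal-content change) is |log r_cv - log r_mean| / sqrt(2).
    Points whose two distances differ by less than ``deadband`` are
    ambiguous.
    """
    if mean_ratio <= 0 or cv_inv_sq_ratio <= 0:
        raise ValueError("ratios must be positive")
    x = math.log(mean_ratio)
    y = math.log(cv_inv_sq_ratio)
    d_horizontal = abs(y)
    d_diagonal = abs(y - x) / math.sqrt(2.0)
    if abs(d_horizontal - d_diagonal) < deadband:
        return AMBIGUOUS
    return QUANTAL_CONTENT if d_diagonal < d_horizontal else QUANTAL_SIZE


def cv_pair_analysis(
    pairs: list[PairedRecording],
    noise_variance: float = 0.0,
    deadband: float = DEFAULT_DEADBAND,
) -> tuple[list[CvSummary], dict]:
    """Per-pair CV summaries plus the group centroid.

    Degenerate pairs (zero variance) are skipped with a warning.  The
    centroid is the mean +/- SEM of both ratios over valid pairs, classified
    with the same rule - this is the group-level call, mirroring the mean
    marker on a CV scatter plot.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    summaries: list[CvSummary] = []
    for idx, pair in enumerate(pairs):
        try:
            mean_ratio = pair.transfected.mean / pair.control.mean
            ratio_cv = cv_inverse_squared(
                pair.transfected, noise_variance
            ) / cv_inverse_squared(pair.control, noise_variance)
        except (ValueError, ZeroDivisionError) as err:
            warnings.warn(f"skipping degenerate pair {pair.pair_id or idx}: {err}")
            continue
        summaries.append(
            CvSummary(
                pair_id=pair.pair_id or str(idx),
                mean_ratio=mean_ratio,
                cv_inv_sq_ratio=ratio_cv,
                classification=classify_cv_point(mean_ratio, ratio_cv, deadband),
            )
        )
    if not summaries:
        raise ValueError("no valid pairs after QC")
    mr = np.array([s.mean_ratio for s in summaries])
    cr = np.array([s.cv_inv_sq_ratio for s in summaries])
    n = len(summaries)
    centroid = {
        "n_pairs": n,
        "mean_ratio": float(mr.mean()),
        "mean_ratio_sem": float(mr.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
        "cv_inv_sq_ratio": float(cr.mean()),
        "cv_inv_sq_ratio_sem": float(cr.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
        "classification": classify_cv_point(float(mr.mean()), float(cr.mean()), deadband),
    }
    return summaries, centroid


# ---------------------------------------------------------------------------
# Exact two-sided Wilcoxon tests


def _signed_rank_null_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of the 2^n equiprobable W+ values over doubled-rank support,
    via the standard generating-polynomial recursion (identical to full
    sign enumeration)."""
    max_sum = int(doubled_ranks.sum())
    counts = np.zeros(max_sum + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: max_sum + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    x, y=None, exact_limit: int = 25
) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped; |differences| are ranked with average
    ranks for ties.  Exact permutation null for n <= ``exact_limit``
    (default 25), normal approximation with continuity correction beyond.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_null_counts(doubled)
        total = counts.sum()  # == 2**n
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mean = n * (n + 1) / 4.0
    ties = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (ties**3 - ties).sum() / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def _rank_sum_null_counts(doubled_ranks: np.ndarray, m: int) -> np.ndarray:
    """Counts of rank-sum values over all C(n, m) assignments of m items,
    DP over (chosen count, doubled sum) - identical to full enumeration."""
    max_sum = int(doubled_ranks.sum())
    counts = np.zeros((m + 1, max_sum + 1))
    counts[0, 0] = 1.0
    for r in doubled_ranks:
        for j in range(m, 0, -1):
            counts[j, r:] += counts[j - 1, : max_sum + 1 - r]
    return counts[m]


def rank_sum(group_a, group_b, exact_limit: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p-value across independent groups.

    Exact permutation null when the combined sample size is at most
    ``exact_limit`` (default 20), normal approximation with continuity
    correction and tie correction beyond.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    w_a = float(ranks[:n].sum())
    if n + m <= exact_limit:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _rank_sum_null_counts(doubled, n)
        total = counts.sum()  # == C(n+m, n)
        w2 = int(round(2 * w_a))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mean = n * (n + m + 1) / 2.0
    ties = np.unique(ranks, return_counts=True)[1]
    nm = n + m
    var = n * m / 12.0 * (nm + 1 - (ties**3 - ties).sum() / (nm * (nm - 1)))
    z = (w_a - mean - 0.5 * np.sign(w_a - mean)) / math.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Binomial-release simulator

MANIPULATIONS = ("none", "scale_q", "scale_N")


def _release_train(
    rng: np.random.Generator,
    n_sites: int,
    release_p: float,
    quantal_size: float,
    quantal_cv: float,
    n_sweeps: int,
    receptor: str,
) -> SweepTrain:
    released = rng.binomial(n_sites, release_p, size=n_sweeps)
    # Sum of r iid quanta q*(1 + gamma*Z_i) == q*(r + gamma*sqrt(r)*Z) in
    # distribution; drawing the aggregate keeps the generator vectorized.
    noise = rng.standard_normal(n_sweeps)
    amps = quantal_size * (released + quantal_cv * np.sqrt(released) * noise)
    return SweepTrain(np.maximum(amps, 0.0), receptor=receptor)


def simulate_quantal_pairs(
    n_sites: int = 100,
    release_p: float = 0.3,
    quantal_size: float = 10.0,
    quantal_cv: float = 0.3,
    n_sweeps: int = 60,
    manipulation: str = "none",
    factor: float = 1.0,
    seed: int | np.random.Generator = 0,
    receptor: str = "AMPAR",
    pair_id: str = "",
) -> PairedRecording:
    """Simulated control/transfected pair under binomial quantal release.

    Per sweep the amplitude is the sum of ``Bernoulli(p)`` releases over
    ``n_sites`` sites, each contributing ``q * (1 + gamma * Z)`` (floored at
    zero).  The transfected train applies the chosen manipulation:
    ``scale_q`` multiplies the quantal size by ``factor`` (receptor-number
    change at each synapse), ``scale_N`` multiplies the number of functional
    sites (silent-synapse change).  Defaults mirror a typical paired
    recording: ~60 sweeps per cell, N = 100, p = 0.3, quantal CV 0.3.
    """
    if not 0.0 < release_p < 1.0:
        raise ValueError("release_p must lie in (0, 1)")
    if n_sites < 1 or n_sweeps < 2:
        raise ValueError("need n_sites >= 1 and n_sweeps >= 2")
    if manipulation not in MANIPULATIONS:
        raise ValueError(f"manipulation must be one of {MANIPULATIONS}")
    if factor <= 0:
        raise ValueError("factor must be positive")
    if quantal_cv < 0 or quantal_size <= 0:
        raise ValueError("quantal_size must be positive and quantal_cv >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    control = _release_train(
        rng, n_sites, release_p, quantal_size, quantal_cv, n_sweeps, receptor
    )
    q_t = quantal_size * (factor if manipulation == "scale_q" else 1.0)
    n_t = n_sites
    if manipulation == "scale_N":
        n_t = max(1, int(round(n_sites * factor)))
    transfected = _release_train(
        rng, n_t, release_p, q_t, quantal_cv, n_sweeps, receptor
    )
    return PairedRecording(control=control, transfected=transfected, pair_id=pair_id)
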