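"""Seeded synthetic-data generators for every pipeline stage.

Three generators emulate the study conditions each analysis was designed
for: uniform-null placement of protein-level mutations along the gene;
photon-limited FLIM decay stacks (80 MHz repetition, ~100 counts/pixel,
single/mixed exponential decays with optional uniform background); and
binomial quantal release for paired eEPSC recordings (re-exported from
:mod:`triokit.quantal`).  Every generator takes an explicit seed and is
bit-reproducible for a fixed seed and version.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .catalog import GeneModel, MutationRecord
from .phasor import DEFAULT_PERIOD_NS, FretModel, PhasorPoint
from .quantal import simulate_quantal_pairs  # noqa: F401  (generator alias)

__all__ = [
    "generate_null_mutations",
    "FlimSimulation",
    "generate_flim_image",
    "banded_e_map",
    "generate_epsc_trace",
    "generate_paired_ephys",
    "write_decay_stack_tsv",
    "read_decay_stack_tsv",
]

#: CLI-facing alias: paired-recording generator shared with the CV module.
generate_paired_ephys = simulate_quantal_pairs


def generate_null_mutations(
    gene: GeneModel, n_mutations: int, seed: int | np.random.Generator
) -> list[MutationRecord]:
    """Case de novo missense records placed i.i.d. uniformly along the
    protein - the equal-mutation-probability null of the hotspot test."""
    if n_mutations < 0:
        raise ValueError("n_mutations must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = rng.integers(1, gene.protein_length_aa + 1, size=n_mutations)
    return [
        MutationRecord(
            gene=gene.gene_symbol,
            protein_position_aa=int(pos),
            mclass="missense",
            cohort="case_de_novo",
        )
        for pos in positions
    ]


# ---------------------------------------------------------------------------
# FLIM decay-stack generator


@dataclass(frozen=True)
class FlimSimulation:
    """Decay stack (n_bins, height, width), generator truth E map, and the
    acquisition parameters needed to analyse it."""

    stack: np.ndarray
    truth_e_map: np.ndarray
    bin_width: float
    period: float
    model: FretModel


def banded_e_map(
    width: int, height: int, efficiencies: tuple[float, ...]
) -> np.ndarray:
    """Horizontal-band ground-truth efficiency map (one band per value)."""
    bands = np.array_split(np.arange(height), len(efficiencies))
    emap = np.empty((height, width))
    for rows, e in zip(bands, efficiencies):
        emap[rows, :] = e
    return emap


def _truncated_exponential_times(
    rng: np.random.Generator, tau: float, period: float, n: int
) -> np.ndarray:
    """Photon arrival times from an exponential decay truncated to one laser
    period, by inverse CDF (exact; no rejection loop)."""
    if tau <= 0:
        return np.zeros(n)
    u = rng.random(n)
    scale = -np.expm1(-period / tau)  # 1 - exp(-T/tau)
    return -tau * np.log1p(-u * scale)


def generate_flim_image(
    width: int = 64,
    height: int = 64,
    region_e_map: float | np.ndarray = 0.0,
    tau_d: float = 2.5,
    fractions: tuple[float, float, float] = (1.0, 0.0, 0.0),
    counts_per_pixel: float = 100.0,
    n_bins: int = 256,
    period: float = DEFAULT_PERIOD_NS,
    seed: int | np.random.Generator = 0,
) -> FlimSimulation:
    """Synthetic per-pixel decay histograms for a FRET-efficiency image.

    Per pixel, the photon total is Poisson(``counts_per_pixel``) and each
    photon's arrival time is drawn from the mixture implied by
    ``fractions = (donor, background, unquenched)``: the FRET-capable donor
    pool decays with lifetime ``tau_d * (1 - E)`` (E from ``region_e_map``),
    the unquenched pool with ``tau_d``, and the background is uniform over
    the period.  Defaults reproduce the acquisition regime the analysis is
    meant for: ~100 counts/pixel at an 80 MHz repetition rate (12.5 ns
    period); 64 x 64 is the desk-scale default, 256 x 256 mirrors a full
    acquisition.
    """
    if counts_per_pixel <= 0:
        raise ValueError("counts_per_pixel must be positive")
    if n_bins < 2:
        raise ValueError("need at least 2 time bins")
    f_d, f_bg, f_unq = fractions
    if min(fractions) < 0 or abs(f_d + f_bg + f_unq - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    emap = np.broadcast_to(
        np.asarray(region_e_map, dtype=float), (height, width)
    ).copy()
    if np.any((emap < 0) | (emap > 1)):
        raise ValueError("efficiencies must lie in [0, 1]")
    bin_width = period / n_bins
    n_pixels = height * width
    totals = rng.poisson(counts_per_pixel, size=n_pixels)
    pixel_of_photon = np.repeat(np.arange(n_pixels), totals)
    n_photons = int(totals.sum())
    tau_q = tau_d * (1.0 - emap.ravel()[pixel_of_photon])

    # Component choice per photon, then arrival time per component.
    comp = rng.choice(3, size=n_photons, p=[f_d, f_bg, f_unq])
    times = np.empty(n_photons)
    donor_sel = comp == 0
    if donor_sel.any():
        u = rng.random(int(donor_sel.sum()))
        tq = tau_q[donor_sel]
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = -np.expm1(-period / np.where(tq > 0, tq, 1.0))
            t = -tq * np.log1p(-u * scale)
        times[donor_sel] = np.where(tq > 0, t, 0.0)
    bg_sel = comp == 1
    if bg_sel.any():
        times[bg_sel] = rng.random(int(bg_sel.sum())) * period
    unq_sel = comp == 2
    if unq_sel.any():
        times[unq_sel] = _truncated_exponential_times(
            rng, tau_d, period, int(unq_sel.sum())
        )

    bins = np.minimum((times / bin_width).astype(np.int64), n_bins - 1)
    flat = np.zeros((n_pixels, n_bins), dtype=np.int64)
    np.add.at(flat, (pixel_of_photon, bins), 1)
    stack = flat.T.reshape(n_bins, height, width)
    model = FretModel(
        tau_d=tau_d,
        period=period,
        donor_fraction=f_d,
        background_fraction=f_bg,
        unquenched_fraction=f_unq,
        background_phasor=PhasorPoint(0.0, 0.0),
    )
    return FlimSimulation(
        stack=stack, truth_e_map=emap, bin_width=bin_width, period=period, model=model
    )


# ---------------------------------------------------------------------------
# Synthetic eEPSC trace (for amplitude-extraction tests)


def generate_epsc_trace(
    peak_pa: float,
    receptor: str = "AMPAR",
    stim_time_s: float = 0.05,
    duration_s: float = 0.30,
    sample_rate_hz: float = 10_000.0,
    rise_tau_s: float | None = None,
    decay_tau_s: float | None = None,
    noise_sd_pa: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Double-exponential EPSC waveform with a known peak magnitude.

    AMPAR kinetics default to 1 ms rise / 15 ms decay; NMDAR to 5 ms rise /
    150 ms decay (slow enough that the +150 ms isolation point is still on
    the decay).  Returns (time_s, current_pa) with a negative-going response.
    """
    if receptor not in ("AMPAR", "NMDAR"):
        raise ValueError(f"unknown receptor {receptor!r}")
    rise = rise_tau_s if rise_tau_s is not None else (0.001 if receptor == "AMPAR" else 0.005)
    decay = decay_tau_s if decay_tau_s is not None else (0.015 if receptor == "AMPAR" else 0.150)
    if not 0 < rise < decay:
        raise ValueError("need 0 < rise_tau < decay_tau")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    dt = np.maximum(t - stim_time_s, 0.0)
    shape = np.exp(-dt / decay) - np.exp(-dt / rise)
    shape[t < stim_time_s] = 0.0
    # Normalize so the waveform's extremum equals peak_pa exactly.
    t_peak = rise * decay / (decay - rise) * math.log(decay / rise)
    peak_shape = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    current = -peak_pa * shape / peak_shape
    if noise_sd_pa > 0:
        current = current + noise_sd_pa * rng.standard_normal(t.size)
    return t, current


# ---------------------------------------------------------------------------
# Decay-stack TSV dialect


def write_decay_stack_tsv(
    path: str | Path, stack: np.ndarray, bin_width: float, period: float
) -> None:
    """Plain-text decay stack: header comments (n_bins, bin_width_ns,
    period_ns, width, height), then one row per pixel (row-major) of
    per-bin counts."""
    stack = np.asarray(stack)
    n_bins, height, width = stack.shape
    flat = stack.reshape(n_bins, height * width).T
    header = (
        f"# n_bins={n_bins}\n# bin_width_ns={bin_width!r}\n"
        f"# period_ns={period!r}\n# width={width}\n# height={height}"
    )
    np.savetxt(path, flat, fmt="%d", delimiter="\t", header=header, comments="")


def read_decay_stack_tsv(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Inverse of :func:`write_decay_stack_tsv`; returns
    (stack, bin_width, period)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("#").strip().partition("=")
            meta[key.strip()] = value.strip()
    flat = np.loadtxt(path, comments="#", delimiter="\t", ndmin=2)
    n_bins = int(meta["n_bins"])
    width, height = int(meta["width"]), int(meta["height"])
    stack = flat.T.reshape(n_bins, height, width).astype(np.int64)
    return stack, float(meta["bin_width_ns"]), float(meta["period_ns"])
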