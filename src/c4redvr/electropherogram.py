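"""Capillary-electrophoresis trace simulation and peak integration.

A digested, FAM-labelled sample produces up to four peaks on the capillary
trace: C4A wild-type at 794 bp, C4A insertion at 796 bp, C4B wild-type at
864 bp and C4B insertion at 866 bp. The integrated area under each peak is
proportional to the number of gene copies feeding that channel (one shared
primer pair amplifies both paralogs, so amplification efficiency is taken as
equal). Peaks are modelled as Gaussians narrow enough that the 2 bp
wild-type/insertion doublet is clearly separated; per-peak areas carry
multiplicative lognormal noise, on the grounds that fluorescence areas are
positive and scale-proportional.

The PGF spike-in is modelled as post-PCR product mixing: each quartet is
normalised to unit total signal and combined in volume proportion ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .assay_model import PEAK_SIZES, classify_peak_size

__all__ = [
    "NoiseModel",
    "Trace",
    "PeakQuartet",
    "PeakIntegration",
    "PGF_QUARTET",
    "expected_quartet",
    "simulate_trace",
    "integrate_peaks",
    "mix_with_reference",
]

# Trace grid (bp). 0.05 bp steps resolve the 2 bp doublet comfortably.
GRID_START = 780.0
GRID_STOP = 880.0
GRID_STEP = 0.05

_CHANNELS = ("A_wt", "A_ins", "B_wt", "B_ins")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters of the simulated capillary run.

    cv
        Coefficient of variation of the multiplicative lognormal noise on
        each peak area (dimensionless; 0 disables noise).
    baseline
        Additive fluorescence floor (arbitrary units).
    peak_sigma
        Gaussian peak width in bp. The default 0.3 bp keeps the 2 bp
        doublet baseline-resolved.
    """

    cv: float = 0.05
    baseline: float = 0.0
    peak_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be > 0")


@dataclass(frozen=True)
class Trace:
    """A simulated electropherogram: fluorescence intensity on a uniform
    fragment-size grid."""

    size: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if len(self.size) != len(self.intensity) or len(self.size) == 0:
            raise ValueError("size and intensity must be equal-length, non-empty")
        if np.any(np.diff(self.size) <= 0):
            raise ValueError("size grid must be strictly increasing")


@dataclass(frozen=True)
class PeakQuartet:
    """Areas of the four diagnostic peaks (arbitrary fluorescence units)."""

    area_A_wt: float
    area_A_ins: float
    area_B_wt: float
    area_B_ins: float

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.as_array()):
            raise ValueError("peak areas must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.area_A_wt, self.area_A_ins, self.area_B_wt, self.area_B_ins]
        )

    @property
    def total(self) -> float:
        return float(self.as_array().sum())

    def normalized(self) -> "PeakQuartet":
        t = self.total
        if t <= 0:
            raise ValueError("cannot normalize an all-zero quartet")
        return PeakQuartet(*(self.as_array() / t))


#: The PGF reference cell line carries two normal copies each of C4A and C4B.
PGF_QUARTET = PeakQuartet(2.0, 0.0, 2.0, 0.0)


@dataclass(frozen=True)
class PeakIntegration:
    """Result of integrating a trace: the classified quartet, any peaks that
    fell outside the four diagnostic windows, and quality flags."""

    quartet: PeakQuartet
    unclassified: tuple = ()
    flags: frozenset = frozenset()


def expected_quartet(genotype) -> PeakQuartet:
    """Noise-free peak areas implied by a diploid genotype: one area unit per
    gene copy in each channel."""
    return PeakQuartet(
        float(genotype.nA - genotype.iA),
        float(genotype.iA),
        float(genotype.nB - genotype.iB),
        float(genotype.iB),
    )


def _grid() -> np.ndarray:
    n = int(round((GRID_STOP - GRID_START) / GRID_STEP)) + 1
    return GRID_START + GRID_STEP * np.arange(n)


def simulate_trace(genotype, noise: NoiseModel = NoiseModel(), seed: int = 0) -> Trace:
    """Render a genotype as a capillary trace.

    Each channel receives a Gaussian peak whose integrated area equals the
    channel's copy count times a lognormal factor with the configured cv
    (unit mean), plus the additive baseline. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    counts = expected_quartet(genotype).as_array()
    if noise.cv > 0:
        sigma = np.sqrt(np.log1p(noise.cv**2))
        factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=4)
    else:
        factors = np.ones(4)
    grid = _grid()
    y = np.full_like(grid, float(noise.baseline))
    norm = 1.0 / (noise.peak_sigma * np.sqrt(2 * np.pi))
    for count, factor, channel in zip(counts, factors, _CHANNELS):
        if count <= 0:
            continue
        center = PEAK_SIZES[channel]
        y += count * factor * norm * np.exp(
            -0.5 * ((grid - center) / noise.peak_sigma) ** 2
        )
    return Trace(grid, y)


def integrate_peaks(
    trace: Trace,
    tolerance: float = 0.9,
    peak_sigma: float = 0.3,
) -> PeakIntegration:
    """Locate local maxima, classify them by size and integrate their areas.

    The baseline is estimated as the median intensity (peaks occupy a small
    fraction of the grid) and subtracted. Each classified peak is integrated
    over +/-3 peak widths; where both members of a 2 bp doublet are present
    the windows are split at the intensity minimum between them, and a
    doublet whose valley does not drop below 80% of the smaller peak is
    flagged low-quality. A trace with no detectable peak yields an all-zero
    quartet flagged low_quality.
    """
    x, raw = trace.size, trace.intensity
    y = np.clip(raw - np.median(raw), 0.0, None)
    flags: set[str] = set()
    if y.max() <= 1e-9:
        return PeakIntegration(PeakQuartet(0, 0, 0, 0), (), frozenset({"low_quality"}))

    idx, _ = find_peaks(y, height=0.02 * y.max(), prominence=0.02 * y.max())
    by_channel: dict[str, int] = {}
    unclassified = []
    half = 3.0 * peak_sigma

    def window_area(i: int, lo: float, hi: float) -> float:
        sel = (x >= lo) & (x <= hi)
        return float(np.trapezoid(y[sel], x[sel]))

    for i in idx:
        label = classify_peak_size(float(x[i]), tolerance)
        if label is None:
            unclassified.append(
                (float(x[i]), window_area(i, x[i] - half, x[i] + half))
            )
        elif label in by_channel:
            flags.add("low_quality")  # two maxima claim the same channel
            if y[i] > y[by_channel[label]]:
                by_channel[label] = i
        else:
            by_channel[label] = i

    areas = {c: 0.0 for c in _CHANNELS}
    for pair in (("A_wt", "A_ins"), ("B_wt", "B_ins")):
        present = [c for c in pair if c in by_channel]
        if len(present) == 2:
            i0, i1 = by_channel[pair[0]], by_channel[pair[1]]
            valley = i0 + int(np.argmin(y[i0 : i1 + 1]))
            if y[valley] > 0.8 * min(y[i0], y[i1]):
                flags.add("low_quality")  # doublet not resolved
            boundary = float(x[valley])
            areas[pair[0]] = window_area(i0, x[i0] - half, min(x[i0] + half, boundary))
            areas[pair[1]] = window_area(i1, max(x[i1] - half, boundary), x[i1] + half)
        elif len(present) == 1:
            c = present[0]
            i = by_channel[c]
            areas[c] = window_area(i, x[i] - half, x[i] + half)

    return PeakIntegration(
        PeakQuartet(*(areas[c] for c in _CHANNELS)),
        tuple(unclassified),
        frozenset(flags),
    )


def mix_with_reference(
    sample: PeakQuartet, reference: PeakQuartet, alpha: float
) -> PeakQuartet:
    """Post-PCR spike-in mix: ``alpha`` parts sample to ``1 - alpha`` parts
    reference, each first normalised to unit total area (post-PCR products
    contribute signal in proportion to mixing volume, not gene copy number).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    s = sample.normalized().as_array()
    if alpha == 1:
        return PeakQuartet(*s)
    r = reference.normalized().as_array()
    return PeakQuartet(*(alpha * s + (1 - alpha) * r))
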