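"""Core domain containers shared across the pipeline.

Time convention: each record is a sequence of half-open bins labelled by
their start time, tracked in hours since recording start.  Circadian time
(CT) of a bin is ``start_ct + elapsed``; CT 0 is subjective dawn, so
subjective day spans CT 0-12 (mod 24) and subjective night CT 12-24.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

LIGHTING = ("DD", "LL")


@dataclass
class ActivityRecord:
    """One animal's binned swimming-activity time series plus metadata.

    Parameters
    ----------
    animal_id : str
        Unique animal label.
    counts : array-like of int
        Beam interruptions per bin (non-negative integers).
    start_ct : float
        Circadian time (hours) of the first bin's start.
    bin_width_h : float
        Bin width in hours (0.5 for the standard 30-min binning).
    knockdown, collection_id : str
        Group labels used by the cohort statistics layer.
    lighting : str
        Free-running condition, ``"DD"`` or ``"LL"``.
    """

    animal_id: str
    counts: np.ndarray
    start_ct: float = 0.0
    bin_width_h: float = 0.5
    knockdown: str = "control"
    collection_id: str = "c0"
    lighting: str = "DD"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size < 1:
            raise ValueError(f"{self.animal_id}: counts must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(c)):
            raise ValueError(f"{self.animal_id}: counts contain non-finite values")
        if np.any(c < 0) or np.any(c != np.floor(c)):
            raise ValueError(f"{self.animal_id}: counts must be non-negative integers")
        self.counts = c.astype(np.int64)
        if self.bin_width_h <= 0:
            raise ValueError("bin_width_h must be positive")
        if self.start_ct < 0:
            raise ValueError("start_ct must be non-negative")
        if self.lighting not in LIGHTING:
            raise ValueError(f"lighting must be one of {LIGHTING}")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def duration_h(self) -> float:
        return self.n_bins * self.bin_width_h

    @property
    def time_h(self) -> np.ndarray:
        """Bin start times in hours since recording start."""
        return np.arange(self.n_bins) * self.bin_width_h

    @property
    def ct(self) -> np.ndarray:
        """Circadian time of each bin start."""
        return self.start_ct + self.time_h

    def replace_counts(self, counts: Sequence[int], start_ct: Optional[float] = None) -> "ActivityRecord":
        return ActivityRecord(
            animal_id=self.animal_id,
            counts=np.asarray(counts),
            start_ct=self.start_ct if start_ct is None else start_ct,
            bin_width_h=self.bin_width_h,
            knockdown=self.knockdown,
            collection_id=self.collection_id,
            lighting=self.lighting,
        )


@dataclass
class Spectrum:
    """CLEAN spectral density over a period grid.

    ``density`` is the squared amplitude of the restored (clean) spectrum;
    ``cl99`` is the randomization 99% threshold on the same scale, filled
    in by :func:`tidecycle.spectral.randomization_threshold`.
    """

    period_h: np.ndarray
    density: np.ndarray
    cl99: Optional[float] = None
    peaks: list = field(default_factory=list)  # (period_h, density) strict local maxima
    n_shuffles: int = 0
    rng_seed: Optional[int] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.period_h = np.asarray(self.period_h, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.period_h.shape != self.density.shape:
            raise ValueError("period_h and density must have the same shape")
        if np.any(np.diff(self.period_h) <= 0):
            raise ValueError("period_h must be strictly increasing")
        if np.any(self.density < -1e-12):
            raise ValueError("density must be non-negative")

    def density_at(self, period_h: float) -> float:
        """Density at the grid point nearest to ``period_h``."""
        i = int(np.argmin(np.abs(self.period_h - period_h)))
        return float(self.density[i])


@dataclass
class Correlogram:
    """Autocorrelation function with white-noise confidence band."""

    lag_h: np.ndarray
    r: np.ndarray
    ci99: float
    cycle_amplitudes: list = field(default_factory=list)  # peak r − following trough r
    significant: bool = False
    period_acf: Optional[float] = None
    peak_lags_h: list = field(default_factory=list)  # significant positive peak lags

    def __post_init__(self) -> None:
        self.lag_h = np.asarray(self.lag_h, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if abs(self.r[0] - 1.0) > 1e-9:
            raise ValueError("autocorrelation at lag 0 must equal 1")
        if np.any(np.abs(self.r) > 1 + 1e-9):
            raise ValueError("|r| must not exceed 1")
        if self.ci99 <= 0:
            raise ValueError("ci99 must be positive")


@dataclass
class RhythmCall:
    """Per-animal rhythmicity decision.

    ``power`` is peak spectral density divided by the 99% randomization
    threshold; an animal is called rhythmic only when power > 1 *and* a
    significant autocorrelation supports the spectral period.
    """

    animal_id: str
    rhythmic: bool
    period_h: Optional[float]
    power: float
    doublet_used: bool
    band_used: str  # "circatidal" | "circalunidian" | "fallback_12.4"

    def __post_init__(self) -> None:
        if self.rhythmic and self.power <= 1:
            raise ValueError("a rhythmic call requires power > 1")
        if self.band_used not in ("circatidal", "circalunidian", "fallback_12.4"):
            raise ValueError(f"unknown band_used {self.band_used!r}")


@dataclass
class TrimReport:
    animal_id: str
    leading_bins_removed: int
    trailing_bins_removed: int
    final_length_bins: int
    untrimmable: bool = False


@dataclass
class InclusionDecision:
    animal_id: str
    included: bool
    reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.included != (len(self.reasons) == 0):
            raise ValueError("included must be true iff reasons is empty")
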