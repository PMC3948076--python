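"""Time-correlated single photon counting (TCSPC) primitives.

Photon records carry a micro-time: the arrival time of each detected
photon relative to the most recent excitation pulse. Binning those
micro-times over a pixel (or a cell) yields the empirical decay
histogram that lifetime fitting operates on. The repetition window
defaults to 25 ns (a 40 MHz pulsed laser).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DataError, OutOfWindowError

#: Repetition window in ns for a 40 MHz pulsed excitation laser.
DEFAULT_WINDOW_NS = 25.0

#: Default number of micro-time bins per decay histogram.
DEFAULT_N_BINS = 256

#: Default minimum photons per pixel for lifetime fitting.
DEFAULT_PHOTON_THRESHOLD = 500


@dataclass(frozen=True)
class PhotonRecord:
    """One detected photon.

    Parameters
    ----------
    x, y : int
        Pixel column / row (0-based).
    t_ns : float
        Micro-time in ns since the excitation pulse; must lie in
        ``[0, window_ns)``.
    channel : str
        Detector channel label (e.g. ``"donor"``).
    """

    x: int
    y: int
    t_ns: float
    channel: str = "donor"

    def __post_init__(self) -> None:
        if self.t_ns < 0:
            raise DataError(f"negative micro-time {self.t_ns} ns in {self!r}")


@dataclass
class DecayHistogram:
    """A binned fluorescence decay curve.

    ``bin_edges`` has length B+1 and spans ``[0, window_ns]``;
    ``counts`` holds the non-negative photon counts per bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_edges.ndim != 1 or self.counts.ndim != 1:
            raise DataError("bin_edges and counts must be 1-D")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise DataError(
                f"{len(self.bin_edges)} edges incompatible with "
                f"{len(self.counts)} counts"
            )
        if np.any(np.diff(self.bin_edges) <= 0):
            raise DataError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise DataError("negative counts in decay histogram")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total_photons(self) -> int:
        return int(np.sum(self.counts))

    @property
    def window_ns(self) -> float:
        return float(self.bin_edges[-1])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def copy(self) -> "DecayHistogram":
        return DecayHistogram(self.bin_edges.copy(), self.counts.copy())


@dataclass
class IRF:
    """Instrument response function.

    Either parametric (a Gaussian pulse of given center and FWHM, or an
    ideal delta flash) or measured (a :class:`DecayHistogram` that is
    normalized to unit area when used as a convolution kernel).
    """

    kind: str = "gaussian"  # "gaussian" | "delta" | "measured"
    center_ns: float = 0.0
    fwhm_ns: float = 0.3
    histogram: DecayHistogram | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "delta", "measured"):
            raise ConfigError(f"unknown IRF kind {self.kind!r}")
        if self.kind == "gaussian" and self.fwhm_ns <= 0:
            raise ConfigError("Gaussian IRF requires fwhm_ns > 0")
        if self.kind == "measured":
            if self.histogram is None:
                raise ConfigError("measured IRF requires a histogram")
            if self.histogram.total_photons <= 0:
                raise DataError("measured IRF histogram is empty")

    @property
    def sigma_ns(self) -> float:
        """Gaussian standard deviation (FWHM / 2.355)."""
        return self.fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PixelCountMap:
    """Per-pixel total photon counts for one field of view."""

    counts: np.ndarray
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DataError("count map must be 2-D")
        if np.any(self.counts < 0):
            raise DataError("negative photon counts")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")


def bin_photons(
    photons: Iterable[PhotonRecord] | Sequence[float] | np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    window_ns: float = DEFAULT_WINDOW_NS,
) -> DecayHistogram:
    """Bin photon micro-times into an equal-width decay histogram.

    Accepts :class:`PhotonRecord` objects or bare micro-times in ns.
    Bins are half-open ``[left, right)`` with the final bin closed, so
    every in-window photon lands in exactly one bin and the histogram
    conserves the photon count exactly.
    """
    if n_bins < 1:
        raise ConfigError("n_bins must be a positive integer")
    if window_ns <= 0:
        raise ConfigError("window_ns must be positive")

    photons = list(photons) if not isinstance(photons, np.ndarray) else photons
    if len(photons) and isinstance(photons[0], PhotonRecord):
        times = np.array([p.t_ns for p in photons], dtype=float)
        for p in photons:
            if p.t_ns >= window_ns:
                raise OutOfWindowError(
                    f"photon {p!r} has micro-time >= window ({window_ns} ns)"
                )
    else:
        times = np.asarray(photons, dtype=float)
        if times.size and (times.max() >= window_ns or times.min() < 0):
            bad = times[(times >= window_ns) | (times < 0)][0]
            raise OutOfWindowError(
                f"micro-time {bad} ns outside [0, {window_ns}) window"
            )

    edges = np.linspace(0.0, window_ns, n_bins + 1)
    counts, _ = np.histogram(times, bins=edges)
    return DecayHistogram(edges, counts.astype(np.int64))


def threshold_pixels(
    count_map: PixelCountMap | np.ndarray,
    min_photons: int = DEFAULT_PHOTON_THRESHOLD,
) -> np.ndarray:
    """Boolean mask of pixels with at least ``min_photons`` counts.

    The comparison is inclusive: a pixel holding exactly the threshold
    survives. The threshold is configurable; 500 photons per pixel is
    the default working point.
    """
    if min_photons < 1:
        raise ConfigError("min_photons must be a positive integer")
    counts = count_map.counts if isinstance(count_map, PixelCountMap) else np.asarray(count_map)
    return counts >= min_photons


def time_bin_background_subtract(
    hist: DecayHistogram, pre_pulse_bins: int
) -> DecayHistogram:
    """Subtract the mean of the pre-pulse (pre-rise) bins from a decay.

    The first ``pre_pulse_bins`` bins are taken as pure background; their
    mean count is subtracted from every bin and the result is clipped at
    zero. The input histogram is left untouched. ``pre_pulse_bins = 0``
    is the identity.
    """
    if pre_pulse_bins < 0:
        raise ConfigError("pre_pulse_bins must be non-negative")
    if pre_pulse_bins >= hist.n_bins:
        raise ConfigError(
            f"pre_pulse_bins={pre_pulse_bins} must be < n_bins={hist.n_bins}"
        )
    if pre_pulse_bins == 0:
        return hist.copy()
    background = float(np.mean(hist.counts[:pre_pulse_bins]))
    corrected = np.clip(hist.counts.astype(float) - background, 0.0, None)
    return DecayHistogram(hist.bin_edges.copy(), corrected)
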