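"""Phase-lock interval extraction and duration distributions.

A *lock interval* is a maximal run of samples during which the wrapped
phase difference between two channels stays inside ``(-threshold,
+threshold)`` and both channels' phase estimates are valid.  Its duration
(in seconds) is the statistic whose distribution is later tested for
power-law versus exponential tails.

Intervals that abut the start/end of the record or a validity gap are only
lower bounds on the true lock duration; they carry a ``censored`` flag and
are *included* by default, because the longest intervals — exactly the tail
under study — are the most likely to be censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ArgumentError
from .phase_extract import wrap_phase
from .preprocess import BandSpec

__all__ = [
    "LockCriterion",
    "IntervalSet",
    "LogBinnedDistribution",
    "phase_difference",
    "smooth_circular",
    "extract_intervals",
    "pool_intervals",
    "log_binned_distribution",
    "resolve_smoothing_window",
]


@dataclass(frozen=True)
class LockCriterion:
    """Locking rule: |wrapped phase difference| < ``threshold``.

    ``smoothing_window`` is the odd length (in samples) of an optional
    centered circular moving average applied to the phase difference before
    thresholding; 0 turns smoothing off and the string ``"auto"`` defers the
    choice to the pipeline (off for the wavelet backend, one center-period
    for the Hilbert backend).  Runs shorter than ``min_duration`` samples
    are dropped.
    """

    threshold: float = np.pi / 4.0
    smoothing_window: int | str = "auto"
    min_duration: int = 1
    include_censored: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < np.pi):
            raise ArgumentError("threshold must lie in (0, pi)")
        if isinstance(self.smoothing_window, str):
            if self.smoothing_window != "auto":
                raise ArgumentError("smoothing_window must be an int >= 0 or 'auto'")
        elif self.smoothing_window < 0:
            raise ArgumentError("smoothing_window must be >= 0")
        if self.min_duration < 1:
            raise ArgumentError("min_duration must be >= 1")

    def with_window(self, window: int) -> "LockCriterion":
        return LockCriterion(
            threshold=self.threshold,
            smoothing_window=window,
            min_duration=self.min_duration,
            include_censored=self.include_censored,
        )


def resolve_smoothing_window(crit: LockCriterion, method: str, fs: float,
                             band: BandSpec) -> int:
    """Resolve ``"auto"`` smoothing: off for wavelet, ~1 center-period (odd)
    for the Hilbert backend."""
    if crit.smoothing_window != "auto":
        return int(crit.smoothing_window)
    if method == "wavelet":
        return 0
    w = max(1, int(round(fs / band.center)))
    return w if w % 2 == 1 else w + 1


@dataclass
class IntervalSet:
    """Lock-interval durations for one channel pair (or a pooled group)."""

    durations: np.ndarray  # seconds, positive
    censored: np.ndarray  # bool, parallel to durations
    pair: tuple[str, str] | None
    band: BandSpec | None
    n_samples_valid: int
    n_locked_samples: int = 0  # before min-duration / censoring filters
    sources: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.shape != self.censored.shape:
            raise ArgumentError("durations and censored must be parallel")

    def __len__(self) -> int:
        return self.durations.size

    @property
    def total_locked(self) -> float:
        """Total locked time in seconds (surviving intervals)."""
        return float(self.durations.sum())


def phase_difference(phi_a: np.ndarray, phi_b: np.ndarray) -> np.ndarray:
    """Element-wise wrapped difference ``wrap(phi_a - phi_b)`` in (-pi, pi]."""
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_a.shape != phi_b.shape:
        raise ArgumentError("phase sequences must have equal length")
    return wrap_phase(phi_a - phi_b)


def smooth_circular(dphi: np.ndarray, window: int) -> np.ndarray:
    """Centered circular moving average of a phase sequence.

    Each sample is replaced by the argument of the centered moving mean of
    the unit phasors ``exp(i*dphi)``; near the edges the mean runs over the
    available samples only.  ``window`` must be odd and >= 1.
    """
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ArgumentError("smoothing window must be odd and >= 1")
    dphi = np.asarray(dphi, dtype=float)
    if window == 1:
        return wrap_phase(dphi)
    z = np.exp(1j * dphi)
    kernel = np.ones(window)
    num = np.convolve(z, kernel, mode="same")
    count = np.convolve(np.ones(dphi.size), kernel, mode="same")
    return wrap_phase(np.angle(num / count))


def extract_intervals(
    dphi: np.ndarray,
    valid: np.ndarray,
    fs: float,
    crit: LockCriterion,
    pair: tuple[str, str] | None = None,
    band: BandSpec | None = None,
) -> IntervalSet:
    """Extract maximal locked runs from a phase-difference sequence.

    A sample is locked when ``|dphi| < crit.threshold`` and it is valid.
    A run is censored when the sample just before its start (or just after
    its end) is outside the array or invalid — i.e. the run ended for a
    reason other than an observed unlock.
    """
    if crit.smoothing_window == "auto":
        raise ArgumentError(
            "smoothing_window 'auto' must be resolved before extraction "
            "(see resolve_smoothing_window)"
        )
    dphi = np.asarray(dphi, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if dphi.shape != valid.shape or dphi.ndim != 1:
        raise ArgumentError("dphi and valid must be 1-D sequences of equal length")

    if int(crit.smoothing_window) > 1:
        dphi = smooth_circular(dphi, int(crit.smoothing_window))

    locked = (np.abs(dphi) < crit.threshold) & valid
    n = locked.size
    padded = np.concatenate(([False], locked, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]  # ends exclusive
    lengths = ends - starts

    left_open = np.ones(starts.size, dtype=bool)
    m = starts > 0
    left_open[m] = ~valid[starts[m] - 1]
    right_open = np.ones(ends.size, dtype=bool)
    m = ends < n
    right_open[m] = ~valid[ends[m]]
    censored = left_open | right_open

    keep = lengths >= crit.min_duration
    if not crit.include_censored:
        keep &= ~censored

    return IntervalSet(
        durations=lengths[keep] / fs,
        censored=censored[keep],
        pair=pair,
        band=band,
        n_samples_valid=int(valid.sum()),
        n_locked_samples=int(locked.sum()),
    )


def pool_intervals(sets: Sequence[IntervalSet], by: str = "band") -> IntervalSet:
    """Concatenate interval sets sharing a grouping key (``band`` or ``pair``)."""
    sets = list(sets)
    if not sets:
        raise ArgumentError("cannot pool an empty sequence of interval sets")
    if by == "band":
        bands = {None if s.band is None else (s.band.name, s.band.f_lo, s.band.f_hi)
                 for s in sets}
        if len(bands) != 1:
            raise ArgumentError(f"cannot pool across mixed bands: {sorted(map(str, bands))}")
        band, pair = sets[0].band, None
    elif by == "pair":
        pairs = {s.pair for s in sets}
        if len(pairs) != 1:
            raise ArgumentError(f"cannot pool across mixed pairs: {sorted(map(str, pairs))}")
        band, pair = None, sets[0].pair
    else:
        raise ArgumentError(f"unknown grouping key {by!r}")

    return IntervalSet(
        durations=np.concatenate([s.durations for s in sets]),
        censored=np.concatenate([s.censored for s in sets]),
        pair=pair,
        band=band,
        n_samples_valid=sum(s.n_samples_valid for s in sets),
        n_locked_samples=sum(s.n_locked_samples for s in sets),
        sources=[s.pair if by == "band" else s.band for s in sets],
    )


@dataclass
class LogBinnedDistribution:
    """Log-spaced histogram of durations as a probability density.

    ``sum(density * diff(edges)) == 1`` for non-empty inputs.  The
    mean-normalized durations ``t / <t>`` support cross-band scale collapse.
    """

    edges: np.ndarray  # seconds, geometric, len = n_bins + 1
    density: np.ndarray  # 1/seconds, len = n_bins
    counts: np.ndarray
    n: int
    mean_duration: float
    empty: bool = False

    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def normalized_edges(self) -> np.ndarray:
        """Bin edges on the mean-normalized scale t / <t>."""
        return self.edges / self.mean_duration


def log_binned_distribution(
    interval_set: IntervalSet, bins_per_decade: int = 10
) -> LogBinnedDistribution:
    """Histogram durations into geometric bins spanning [min, max]."""
    if bins_per_decade < 1:
        raise ArgumentError("bins_per_decade must be >= 1")
    d = interval_set.durations
    if d.size == 0:
        z = np.array([])
        return LogBinnedDistribution(edges=z, density=z, counts=z, n=0,
                                     mean_duration=float("nan"), empty=True)
    lo, hi = float(d.min()), float(d.max())
    if lo <= 0:
        raise ArgumentError("durations must be positive")
    if np.isclose(lo, hi):
        half = 10.0 ** (0.5 / bins_per_decade)
        edges = np.array([lo / half, hi * half])
    else:
        n_bins = max(1, int(np.ceil(np.log10(hi / lo) * bins_per_decade)))
        edges = np.geomspace(lo, hi, n_bins + 1)
        edges[-1] = np.nextafter(hi, np.inf)  # right-closed top bin
    counts, _ = np.histogram(d, bins=edges)
    widths = np.diff(edges)
    density = counts / (d.size * widths)
    return LogBinnedDistribution(
        edges=edges, density=density, counts=counts,
        n=int(d.size), mean_duration=float(d.mean()),
    )
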