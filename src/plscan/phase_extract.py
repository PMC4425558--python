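"""Instantaneous phase per frequency band via two contrasting backends.

``hilbert_phase``
    Band-pass filter followed by the analytic signal (negative frequencies
    zeroed); phase is its argument, amplitude its modulus.  The "simplified"
    estimator.

``wavelet_phase``
    One analytic Morlet-style complex wavelet coefficient sequence per band,
    centered at the band's geometric-mean frequency with Gaussian frequency
    bandwidth matched to the band width.  The "original" estimator.

Both return a :class:`PhaseStack` with a validity mask: samples within
three center-periods of either record edge are flagged unreliable (filter /
wavelet edge effects), as are samples whose instantaneous amplitude is
numerically degenerate (below 1e-12 x the channel RMS) — the phase of a
near-zero analytic signal is meaningless and must not count as locked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigurationError
from .preprocess import BandSpec, bandpass
from .record import TimeSeriesRecord

__all__ = [
    "BandLadder",
    "PhaseStack",
    "default_ladder",
    "hilbert_phase",
    "wavelet_phase",
    "wrap_phase",
]

#: Band edges of the default dyadic ladder, delta through the >70 Hz control band.
_DEFAULT_EDGES = [
    ("delta", 1.0, 2.0),
    ("theta_lo", 2.0, 4.0),
    ("theta_hi", 4.0, 8.0),
    ("alpha", 8.0, 17.5),
    ("beta", 17.5, 35.0),
    ("gamma", 35.0, 70.0),
    ("high", 70.0, 140.0),
]

DEGENERATE_AMP_FACTOR = 1e-12
EDGE_DISCARD_PERIODS = 3.0


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles into the half-open interval ``(-pi, pi]``."""
    w = np.mod(np.asarray(x, dtype=float), 2.0 * np.pi)
    return np.where(w > np.pi, w - 2.0 * np.pi, w)


@dataclass(frozen=True)
class BandLadder:
    """Ordered, non-degenerate sequence of analysis bands."""

    bands: tuple[BandSpec, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError("ladder must contain at least one band")
        los = [b.f_lo for b in self.bands]
        if los != sorted(los):
            raise ConfigurationError("ladder bands must be ordered by f_lo")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ConfigurationError("ladder band names must be unique")

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def check_nyquist(self, fs: float) -> None:
        for b in self.bands:
            b.check_nyquist(fs)


def default_ladder(fs: float | None = None) -> BandLadder:
    """The default dyadic band ladder, clipped to Nyquist when ``fs`` is given."""
    bands = []
    for name, lo, hi in _DEFAULT_EDGES:
        if fs is not None:
            nyq = fs / 2.0
            if lo >= nyq:
                continue
            hi = min(hi, nyq)
        bands.append(BandSpec(name, lo, hi))
    return BandLadder(tuple(bands))


def parse_ladder(text: str, fs: float | None = None) -> BandLadder:
    """Parse ``"lo-hi,lo-hi,..."`` into a ladder; ``"default"`` gives the default."""
    if text.strip().lower() == "default":
        return default_ladder(fs)
    bands = []
    for part in text.split(","):
        lo_s, hi_s = part.strip().split("-")
        lo, hi = float(lo_s), float(hi_s)
        bands.append(BandSpec(f"{lo:g}-{hi:g}Hz", lo, hi))
    return BandLadder(tuple(bands))


@dataclass
class PhaseStack:
    """Per-band, per-channel instantaneous phase and amplitude.

    ``phases`` and ``amplitudes`` have shape
    ``(n_bands, n_channels, n_samples)``; ``valid`` marks samples reliable
    for interval extraction (edge-discarded and degenerate samples are
    False).  Phases are wrapped to ``(-pi, pi]``.
    """

    phases: np.ndarray
    amplitudes: np.ndarray
    valid: np.ndarray
    ladder: BandLadder
    method: str
    fs: float
    labels: list[str]

    @property
    def n_bands(self) -> int:
        return self.phases.shape[0]

    @property
    def n_channels(self) -> int:
        return self.phases.shape[1]

    @property
    def n_samples(self) -> int:
        return self.phases.shape[2]


def _edge_margin(band: BandSpec, fs: float) -> int:
    return int(round(EDGE_DISCARD_PERIODS * fs / band.center))


def _validity(analytic: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Edge-discard and degenerate-amplitude mask for one band's coefficients."""
    n_ch, n = analytic.shape
    valid = np.ones((n_ch, n), dtype=bool)
    margin = _edge_margin(band, fs)
    if margin > 0:
        valid[:, :margin] = False
        valid[:, n - margin:] = False
    amp = np.abs(analytic)
    rms = np.sqrt(np.mean(amp**2, axis=1, keepdims=True))
    valid &= amp > DEGENERATE_AMP_FACTOR * np.maximum(rms, np.finfo(float).tiny)
    return valid


def _stack_from_analytic(per_band, ladder, method, record) -> PhaseStack:
    phases = np.empty((len(ladder), record.n_channels, record.n_samples))
    amps = np.empty_like(phases)
    valid = np.empty(phases.shape, dtype=bool)
    for i, (band, analytic) in enumerate(zip(ladder, per_band)):
        phases[i] = wrap_phase(np.angle(analytic))
        amps[i] = np.abs(analytic)
        valid[i] = _validity(analytic, band, record.fs)
    return PhaseStack(
        phases=phases, amplitudes=amps, valid=valid,
        ladder=ladder, method=method, fs=record.fs, labels=list(record.labels),
    )


def hilbert_phase(record: TimeSeriesRecord, ladder: BandLadder | None = None) -> PhaseStack:
    """Band-pass + analytic-signal phase for every band of the ladder."""
    ladder = default_ladder(record.fs) if ladder is None else ladder
    ladder.check_nyquist(record.fs)
    per_band = []
    for band in ladder:
        filtered = bandpass(record, band)
        per_band.append(signal.hilbert(filtered.data, axis=1))
    return _stack_from_analytic(per_band, ladder, "hilbert", record)


def wavelet_phase(record: TimeSeriesRecord, ladder: BandLadder | None = None) -> PhaseStack:
    """Analytic-wavelet phase: one complex coefficient sequence per band.

    The wavelet is defined in the frequency domain as a Gaussian window
    ``2 * exp(-(f - fc)^2 / (2 sigma_f^2))`` on positive frequencies only
    (hence exactly analytic), with ``fc`` the band's geometric-mean center
    and ``sigma_f = (f_hi - f_lo) / 4`` so +-2 sigma spans the band.  A unit
    tone at ``fc`` comes out with unit modulus.
    """
    ladder = default_ladder(record.fs) if ladder is None else ladder
    ladder.check_nyquist(record.fs)
    n = record.n_samples
    freqs = np.fft.fftfreq(n, d=1.0 / record.fs)
    spectra = np.fft.fft(record.data, axis=1)
    per_band = []
    for band in ladder:
        fc = band.center
        sigma_f = (band.f_hi - band.f_lo) / 4.0
        # temporal support of the wavelet envelope must fit in the record
        sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
        if 6.0 * sigma_t * record.fs >= n:
            raise ConfigurationError(
                f"band {band.name!r}: wavelet support ({6 * sigma_t:.2f} s) "
                f"exceeds record duration ({record.duration:.2f} s)"
            )
        window = np.where(
            freqs > 0,
            2.0 * np.exp(-0.5 * ((freqs - fc) / sigma_f) ** 2),
            0.0,
        )
        per_band.append(np.fft.ifft(spectra * window[None, :], axis=1))
    return _stack_from_analytic(per_band, ladder, "wavelet", record)


def extract_phase(record: TimeSeriesRecord, method: str,
                  ladder: BandLadder | None = None) -> PhaseStack:
    """Dispatch to the requested backend (``"wavelet"`` or ``"hilbert"``)."""
    if method == "wavelet":
        return wavelet_phase(record, ladder)
    if method == "hilbert":
        return hilbert_phase(record, ladder)
    raise ConfigurationError(f"unknown phase method {method!r}")
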