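"""FFT band decomposition and per-band maximum beating force.

The beating of a trapped spermatozoon shows up as superposed oscillations
in the calibrated force trace.  Human flagellar beating lives below about
30 Hz, so the trace is split into contiguous 3 Hz bands (0-2 Hz, 3-5 Hz,
..., 27-29 Hz by default): the full complex FFT spectrum is masked to one
band at a time (keeping the conjugate-symmetric negative-frequency
partners so the inverse transform is real) and inverse-transformed back to
the time domain.  The per-band statistic is the maximum absolute force
over the recording — the amplitude of the strongest beat the cell drove in
that frequency range, taken as a maximum because the cell's orientation
relative to the cantilever modulates the instantaneous amplitude and only
the perpendicular orientation transmits the full thrust.

Band edges are half-open ``[lo, hi)`` so every spectral bin belongs to
exactly one band; the DC bin is excluded from every band (the static
suction bending is a baseline, not a beating force).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import ForceTrace


@dataclass(frozen=True)
class Band:
    """One half-open frequency interval ``[lo_hz, hi_hz)``."""

    lo_hz: float
    hi_hz: float
    label: str

    @property
    def column_name(self) -> str:
        """CSV-safe column name, e.g. ``band_0_2_nN``."""
        return "band_" + self.label.removesuffix(" Hz").replace("–", "_") + "_nN"


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous, non-overlapping bands covering ``[f_min, f_max)``."""

    f_min_hz: float
    f_max_hz: float
    width_hz: float
    bands: tuple[Band, ...]

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]


def _band_label(lo: float, width: float) -> str:
    hi = lo + width
    if float(lo).is_integer() and float(width).is_integer():
        return f"{int(lo)}–{int(hi) - 1} Hz"
    return f"{lo:g}–{hi:g} Hz"


def make_band_scheme(f_min_hz: float = 0.0, f_max_hz: float = 30.0,
                     width_hz: float = 3.0) -> BandScheme:
    """Build the band scheme: ``[f_min + k*width, f_min + (k+1)*width)``.

    ``width_hz`` must divide ``f_max - f_min`` exactly.  Labels follow the
    instrument-report convention for integer-Hz bands ("0–2 Hz" for
    ``[0, 3)``).
    """
    if not (f_max_hz > f_min_hz >= 0):
        raise ValueError(f"need f_max > f_min >= 0, got ({f_min_hz}, {f_max_hz})")
    if width_hz <= 0:
        raise ValueError("width_hz must be > 0")
    n_bands_f = (f_max_hz - f_min_hz) / width_hz
    n_bands = int(round(n_bands_f))
    if n_bands < 1 or abs(n_bands_f - n_bands) > 1e-9:
        raise ValueError(
            f"width {width_hz} Hz does not divide the range [{f_min_hz}, {f_max_hz}) Hz"
        )
    bands = tuple(
        Band(
            lo_hz=f_min_hz + k * width_hz,
            hi_hz=f_min_hz + (k + 1) * width_hz,
            label=_band_label(f_min_hz + k * width_hz, width_hz),
        )
        for k in range(n_bands)
    )
    return BandScheme(f_min_hz=f_min_hz, f_max_hz=f_max_hz, width_hz=width_hz, bands=bands)


@dataclass(frozen=True)
class BandSignalSet:
    """Per-band time-domain force signals for one cell.

    ``residual_nN`` carries the out-of-scheme frequencies plus DC, so that
    ``sum(signals.values()) + residual == input`` to floating tolerance.
    """

    cell_id: str
    scheme: BandScheme
    time_s: np.ndarray
    signals_nN: dict[str, np.ndarray]
    residual_nN: np.ndarray
    sampling_rate_hz: float


@dataclass(frozen=True)
class BandForceProfile:
    """Per-cell maximum absolute force (nN) and its time, per band."""

    cell_id: str
    band_max_force: dict[str, float]
    band_argmax_time: dict[str, float]


def band_decompose(force: ForceTrace, scheme: BandScheme) -> BandSignalSet:
    """Isolate each band of ``scheme`` from ``force`` by FFT masking + IFFT.

    Both the real and imaginary parts of the in-band coefficients are kept,
    so each band signal is the exact band-limited component of the input
    (no phase distortion).  The DC coefficient is excluded from every band,
    including the first.  Requires a baseline-subtracted trace and a scheme
    within the Nyquist frequency.
    """
    if not force.baseline_removed:
        raise ValueError("band_decompose requires a baseline-subtracted ForceTrace")
    fs = force.meta.sampling_rate_hz
    if scheme.f_max_hz > fs / 2 + 1e-12:
        raise ValueError(
            f"band scheme reaches {scheme.f_max_hz} Hz, above Nyquist {fs / 2} Hz"
        )
    x = force.force_nN
    n = x.size
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    signals: dict[str, np.ndarray] = {}
    in_scheme = np.zeros_like(freqs, dtype=bool)
    for band in scheme.bands:
        mask = (freqs >= band.lo_hz) & (freqs < band.hi_hz) & (freqs > 0)
        in_scheme |= mask
        signals[band.label] = np.fft.irfft(np.where(mask, spectrum, 0.0), n=n)
    # residual from its own complementary mask (not by subtraction) so the
    # reconstruction identity is a genuine check, not a tautology
    residual = np.fft.irfft(np.where(~in_scheme, spectrum, 0.0), n=n)
    return BandSignalSet(
        cell_id=force.meta.cell_id,
        scheme=scheme,
        time_s=force.time_s,
        signals_nN=signals,
        residual_nN=residual,
        sampling_rate_hz=fs,
    )


def band_max_force(signals: BandSignalSet, guard_s: float = 1.0,
                   statistic: str = "absmax") -> BandForceProfile:
    """Extract the per-band maximum force.

    ``guard_s`` seconds are trimmed from each end of the trace before taking
    the maximum: rectangular spectral masking rings at the edges of a
    finite recording, and the guard keeps that ringing out of the statistic.

    ``statistic`` is ``"absmax"`` (maximum of \\|signal\\|, the default) or
    ``"ptp"`` (peak-to-peak range over the guarded window).
    """
    n = signals.time_s.size
    fs = signals.sampling_rate_hz
    duration = n / fs
    if guard_s < 0 or 2 * guard_s >= duration:
        raise ValueError(f"guard_s must satisfy 0 <= 2*guard < duration, got {guard_s}")
    if statistic not in ("absmax", "ptp"):
        raise ValueError(f"unknown statistic {statistic!r}")
    i0 = int(round(guard_s * fs))
    i1 = n - i0
    max_force: dict[str, float] = {}
    argmax_time: dict[str, float] = {}
    for label, y in signals.signals_nN.items():
        window = y[i0:i1]
        if statistic == "absmax":
            idx = int(np.argmax(np.abs(window)))
            max_force[label] = float(abs(window[idx]))
        else:
            max_force[label] = float(np.max(window) - np.min(window))
            idx = int(np.argmax(window))
        argmax_time[label] = float(signals.time_s[i0 + idx])
    return BandForceProfile(
        cell_id=signals.cell_id, band_max_force=max_force, band_argmax_time=argmax_time
    )
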