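"""Exclusion of cells that stop beating during the recording.

A trapped spermatozoon that ceases flagellar movement mid-recording is in
distress, and its trace must not enter the cohort statistics.  With no
simultaneous video available, cessation is detected from the trace itself:
the force signal is band-limited to the beating band (0-30 Hz minus DC by
default), split into contiguous windows, and a window counts as active
when its RMS force reaches a threshold.  A cell fails QC when too little
of the recording is active overall, or when an inactive run reaches the
end of the trace and is longer than a grace period — the cell stopped and
never resumed.

The window length (5 s), RMS threshold (0.05 nN), minimum active fraction
(0.5) and terminal grace (20 s) are detector settings, tuned on synthetic
cohorts and fully configurable; they are not instrument constants.  Cells
of the sparse-burst (circular) phenotype sit near the active-fraction
boundary by construction, so the detector occasionally excludes a healthy
sparse beater — a conservative bias toward dropping doubtful traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import ForceTrace


@dataclass(frozen=True)
class QCReport:
    cell_id: str
    passed: bool
    active_fraction: float
    cessation_time_s: float | None
    window_s: float
    threshold_nN: float


def _band_limit(force: ForceTrace, band: tuple[float, float]) -> np.ndarray:
    """Keep only the beating band (DC excluded) of the force signal."""
    x = force.force_nN
    n = x.size
    fs = force.meta.sampling_rate_hz
    lo, hi = band
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi) & (freqs > 0)
    return np.fft.irfft(np.where(mask, spectrum, 0.0), n=n)


def assess_motility(
    force: ForceTrace,
    band: tuple[float, float] = (0.0, 30.0),
    window_s: float = 5.0,
    threshold_nN: float = 0.05,
    min_active_fraction: float = 0.5,
    cessation_grace_s: float = 20.0,
) -> QCReport:
    """Classify a cell as sustained or ceased from its force trace.

    Windows are contiguous and non-overlapping, so the cessation time is
    resolved to one window length.  ``cessation_time_s`` is the start of
    the final all-inactive run reaching the trace end, or ``None`` when
    the last window is active.
    """
    fs = force.meta.sampling_rate_hz
    duration = force.meta.duration_s
    if not (0 < window_s < duration):
        raise ValueError(f"window_s must be in (0, duration), got {window_s}")
    if band[1] > fs / 2 + 1e-12:
        raise ValueError(f"band {band} exceeds Nyquist ({fs / 2} Hz)")
    if threshold_nN < 0 or not (0 <= min_active_fraction <= 1):
        raise ValueError("threshold_nN >= 0 and min_active_fraction in [0,1] required")

    y = _band_limit(force, band)
    win = int(round(window_s * fs))
    n_win = y.size // win
    windows = y[: n_win * win].reshape(n_win, win)
    rms = np.sqrt(np.mean(windows**2, axis=1))
    active = rms >= threshold_nN
    active_fraction = float(np.mean(active))

    trailing_inactive = 0
    for a in active[::-1]:
        if a:
            break
        trailing_inactive += 1
    if trailing_inactive > 0:
        cessation_time = float((n_win - trailing_inactive) * window_s)
        terminal_run_s = trailing_inactive * window_s
    else:
        cessation_time = None
        terminal_run_s = 0.0

    passed = (active_fraction >= min_active_fraction) and (
        terminal_run_s <= cessation_grace_s
    )
    return QCReport(
        cell_id=force.meta.cell_id,
        passed=passed,
        active_fraction=active_fraction,
        cessation_time_s=cessation_time,
        window_s=window_s,
        threshold_nN=threshold_nN,
    )
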