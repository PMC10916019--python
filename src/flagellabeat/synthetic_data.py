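"""Synthetic deflection traces with the structure the analysis assumes.

No instrument recordings are distributed with the package, so cohorts are
emulated.  A trapped spermatozoon drives the cantilever with band-limited
oscillatory thrust below ~30 Hz; the cell's orientation relative to the
cantilever drifts slowly, modulating how much of the thrust appears in the
measured z-deflection; the residual suction pressure adds a constant
bending; and the detector adds white noise.  A cell's force signal is
modeled as

    F(t) = baseline + sum_i A_i * env_i(t) * sin(2*pi*f_i*t + phi_i) + noise

where each component's envelope ``env_i`` is a slow raised-cosine
modulation (the orientation drift, peaking at a seed-dependent time) gated
by an on/off burst process with duty ``burst_duty`` (circular swimmers
beat in sparse bursts; linear ones near-continuously).  The trace handed
to the pipeline is the voltage V = F / (S*K).

The two phenotype defaults encode the qualitative contrast between motility
classes: the linear profile beats continuously with a 0.6 nN low-band
amplitude (the human low-frequency force scale), the circular profile at
40% of those amplitudes with burst_duty 0.3.  Across a cohort, per-cell
amplitudes are jittered log-normally (CV 0.33, matching a 0.6 +/- 0.2
dispersion) so band-force distributions have realistic spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal

from .calibration import KB_NN_NM_PER_K
from .io_core import (
    CalibrationConstants,
    CellMeta,
    DeflectionTrace,
    Phenotype,
    SampleGroup,
    TrapRegion,
)
from .spectral import BandScheme, make_band_scheme

#: Length of one on/off gating segment, seconds.
BURST_SEGMENT_S = 5.0
#: Raised-cosine ramp applied to gate edges, seconds.
BURST_RAMP_S = 0.5


@dataclass(frozen=True)
class BeatComponent:
    """One spectral component of the beating thrust.

    ``am_rate_hz`` is the slow orientation-modulation rate; it must be much
    smaller than ``frequency_hz`` so the component stays inside its band.
    ``am_rate_hz = 0`` disables the modulation (envelope identically 1 when
    the duty cycle is also 1).
    """

    frequency_hz: float
    amplitude_nN: float
    phase_rad: float = 0.0
    am_rate_hz: float = 0.05

    def __post_init__(self) -> None:
        if self.frequency_hz < 0:
            raise ValueError("frequency_hz must be >= 0")
        if self.amplitude_nN < 0:
            raise ValueError("amplitude_nN must be >= 0")
        if self.am_rate_hz < 0:
            raise ValueError("am_rate_hz must be >= 0")
        if self.frequency_hz > 0 and self.am_rate_hz >= 0.5 * self.frequency_hz:
            raise ValueError("am_rate_hz must be << frequency_hz")


@dataclass(frozen=True)
class PhenotypeProfile:
    """Generative parameters of one motility phenotype."""

    name: Phenotype
    components: tuple[BeatComponent, ...]
    baseline_offset_nN: float = -0.5
    noise_sd_nN: float = 0.05
    burst_duty: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", Phenotype(self.name))
        object.__setattr__(self, "components", tuple(self.components))
        if not (0.0 <= self.burst_duty <= 1.0):
            raise ValueError("burst_duty must be in [0, 1]")
        if self.noise_sd_nN < 0:
            raise ValueError("noise_sd_nN must be >= 0")


#: Default per-component thrust amplitudes of a linear swimmer, nN.  The
#: 1 Hz component anchors the 0-2 Hz band at 0.6 nN; higher bands decay.
_LINEAR_AMPLITUDES = {1.0: 0.60, 4.0: 0.45, 7.0: 0.35, 10.0: 0.30, 13.0: 0.25, 25.0: 0.15}

#: Circular swimmers: same beat frequencies at 40% amplitude, sparse bursts.
_CIRCULAR_AMPLITUDE_RATIO = 0.40
_CIRCULAR_BURST_DUTY = 0.30


def default_linear_profile() -> PhenotypeProfile:
    return PhenotypeProfile(
        name=Phenotype.linear,
        components=tuple(
            BeatComponent(frequency_hz=f, amplitude_nN=a)
            for f, a in _LINEAR_AMPLITUDES.items()
        ),
        baseline_offset_nN=-0.5,
        noise_sd_nN=0.05,
        burst_duty=1.0,
    )


def default_circular_profile() -> PhenotypeProfile:
    return PhenotypeProfile(
        name=Phenotype.circular,
        components=tuple(
            BeatComponent(frequency_hz=f, amplitude_nN=a * _CIRCULAR_AMPLITUDE_RATIO)
            for f, a in _LINEAR_AMPLITUDES.items()
        ),
        baseline_offset_nN=-1.5,
        noise_sd_nN=0.05,
        burst_duty=_CIRCULAR_BURST_DUTY,
    )


def profile_for_group(group_name: str) -> PhenotypeProfile:
    """Default profile for a cohort group, inferred from its name prefix."""
    if group_name.startswith("circular"):
        return default_circular_profile()
    if group_name.startswith("linear"):
        return default_linear_profile()
    raise ValueError(
        f"cannot infer a phenotype profile for group {group_name!r}; "
        "group names must start with 'linear' or 'circular'"
    )


def default_calibration() -> CalibrationConstants:
    """Nominal instrument constants: S = 20 nm/V, K = 0.3 nN/nm, 298 K."""
    return CalibrationConstants(
        sensitivity_nm_per_V=20.0, spring_constant_nN_per_nm=0.3, temperature_K=298.0
    )


def _smooth_gate(n: int, fs: float, duty: float, rng: np.random.Generator) -> np.ndarray:
    """On/off burst gate in [0, 1]: Bernoulli(duty) segments, smoothed edges."""
    if duty >= 1.0:
        return np.ones(n)
    if duty <= 0.0:
        return np.zeros(n)
    seg_len = max(1, int(round(BURST_SEGMENT_S * fs)))
    n_seg = max(1, -(-n // seg_len))
    on = rng.random(n_seg) < duty
    if not on.any():
        on[rng.integers(n_seg)] = True  # a live cell beats at least once
    gate = np.repeat(on.astype(float), seg_len)[:n]
    ramp = int(round(BURST_RAMP_S * fs))
    if ramp >= 2:
        win = scipy.signal.windows.hann(ramp)
        win /= win.sum()
        gate = scipy.signal.fftconvolve(gate, win, mode="same")
        gate = np.clip(gate, 0.0, 1.0)
    return gate


def _component_envelope(
    t: np.ndarray, comp: BeatComponent, duty: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    if comp.am_rate_hz > 0:
        psi = rng.uniform(0.0, 2.0 * np.pi)
        mod = 0.5 * (1.0 - np.cos(2.0 * np.pi * comp.am_rate_hz * t + psi))
    else:
        mod = np.ones_like(t)
    return mod * _smooth_gate(t.size, fs, duty, rng)


def generate_cell_trace(
    profile: PhenotypeProfile,
    meta: CellMeta,
    calib: CalibrationConstants,
    seed: int,
    cease_at_s: float | None = None,
) -> DeflectionTrace:
    """Simulate one cell's deflection trace; deterministic given ``seed``.

    ``cease_at_s`` smoothly switches the beating off at that time — the
    signature of a cell in distress that the QC stage must catch.  Sensor
    noise continues after cessation.
    """
    fs = meta.sampling_rate_hz
    nyquist = fs / 2.0
    for comp in profile.components:
        if comp.frequency_hz >= nyquist:
            raise ValueError(
                f"component at {comp.frequency_hz} Hz is at/above Nyquist ({nyquist} Hz)"
            )
    rng = np.random.default_rng(seed)
    n = meta.n_samples
    t = np.arange(n) / fs

    osc = np.zeros(n)
    for comp in profile.components:
        env = _component_envelope(t, comp, profile.burst_duty, fs, rng)
        osc += comp.amplitude_nN * env * np.sin(
            2.0 * np.pi * comp.frequency_hz * t + comp.phase_rad
        )
    if cease_at_s is not None:
        if not (0 <= cease_at_s <= meta.duration_s):
            raise ValueError("cease_at_s must lie within the recording")
        ramp = max(1, int(round(BURST_RAMP_S * fs)))
        stop = np.ones(n)
        i0 = int(round(cease_at_s * fs))
        i1 = min(n, i0 + ramp)
        stop[i0:i1] = 0.5 * (1.0 + np.cos(np.pi * np.arange(i1 - i0) / ramp))
        stop[i1:] = 0.0
        osc *= stop

    force = profile.baseline_offset_nN + osc
    if profile.noise_sd_nN > 0:
        force = force + rng.normal(0.0, profile.noise_sd_nN, n)
    volts = force / (calib.sensitivity_nm_per_V * calib.spring_constant_nN_per_nm)
    return DeflectionTrace(meta=meta, calib=calib, time_s=t, deflection_V=volts)


def generate_thermal_trace(
    k_nN_per_nm: float,
    temperature_K: float,
    sampling_rate_hz: float,
    duration_s: float,
    seed: int,
) -> np.ndarray:
    """Free-cantilever thermal deflection (nm) for calibration testing.

    Equipartition fixes the positional variance at ``kB*T/k``; the series
    is Gaussian white noise at that variance (a flat-spectrum
    simplification — the equipartition estimator uses only total variance,
    so the spectral shape of the real damped oscillator is irrelevant to
    its contract).
    """
    if min(k_nN_per_nm, temperature_K, sampling_rate_hz, duration_s) <= 0:
        raise ValueError("all thermal-trace parameters must be > 0")
    rng = np.random.default_rng(seed)
    sd_nm = np.sqrt(KB_NN_NM_PER_K * temperature_K / k_nN_per_nm)
    n = int(round(sampling_rate_hz * duration_s))
    return rng.normal(0.0, sd_nm, n)


def _group_meta_defaults(group_name: str, profile: PhenotypeProfile) -> dict:
    if "tail" in group_name:
        region = TrapRegion.tail
    elif "head" in group_name or "mid" in group_name:
        region = TrapRegion.head
    else:
        region = TrapRegion.tail if profile.name is Phenotype.linear else TrapRegion.head
    sample_group = SampleGroup.prog100 if "100" in group_name else SampleGroup.prog80_20
    pressure = -20.0 if profile.name is Phenotype.linear else -200.0
    return {"trap_region": region, "sample_group": sample_group, "trap_pressure_mbar": pressure}


def _jittered(profile: PhenotypeProfile, factors: np.ndarray) -> PhenotypeProfile:
    comps = tuple(
        replace(c, amplitude_nN=c.amplitude_nN * f)
        for c, f in zip(profile.components, factors)
    )
    return replace(profile, components=comps)


def generate_cohort(
    n_per_group: dict[str, int],
    profiles: dict[str, PhenotypeProfile],
    seed: int,
    jitter_cv: float = 0.33,
    sampling_rate_hz: float = 1000.0,
    duration_s: float = 120.0,
    calib: CalibrationConstants | None = None,
    group_meta: dict[str, dict] | None = None,
    return_truth: bool = False,
) -> list[DeflectionTrace] | tuple[list[DeflectionTrace], pd.DataFrame]:
    """Simulate a cohort of cells; deterministic given ``seed``.

    Per-cell component amplitudes are jittered log-normally with
    coefficient of variation ``jitter_cv`` (mean preserved), so cohort
    band-force distributions have nonzero spread.  Group metadata
    (trap region, sample group, holding pressure) is inferred from the
    group name unless overridden via ``group_meta``.

    With ``return_truth=True`` also returns the ground-truth table of
    realized (jittered) component amplitudes — one row per cell and
    component (``cell_id, group, frequency_hz, amplitude_nN``) — for
    recovery studies against the pipeline output.
    """
    for name in n_per_group:
        if name not in profiles:
            raise ValueError(f"group {name!r} has no phenotype profile")
        if n_per_group[name] < 1:
            raise ValueError(f"group {name!r} must have n >= 1")
    if jitter_cv < 0:
        raise ValueError("jitter_cv must be >= 0")
    calib = calib or default_calibration()
    sigma = np.sqrt(np.log1p(jitter_cv**2))
    ss = np.random.SeedSequence(seed)
    traces: list[DeflectionTrace] = []
    truth_rows: list[dict] = []
    for group_name in sorted(n_per_group):
        profile = profiles[group_name]
        meta_kwargs = _group_meta_defaults(group_name, profile)
        if group_meta and group_name in group_meta:
            meta_kwargs.update(group_meta[group_name])
        for i in range(n_per_group[group_name]):
            child = ss.spawn(1)[0]
            jitter_seed, trace_seed = child.generate_state(2) >> 1  # keep < 2**31
            jr = np.random.default_rng(int(jitter_seed))
            if jitter_cv > 0:
                factors = jr.lognormal(-0.5 * sigma**2, sigma, len(profile.components))
            else:
                factors = np.ones(len(profile.components))
            meta = CellMeta(
                cell_id=f"{group_name}_{i:02d}",
                phenotype=profile.name,
                sampling_rate_hz=sampling_rate_hz,
                duration_s=duration_s,
                **meta_kwargs,
            )
            realized = _jittered(profile, factors)
            for comp in realized.components:
                truth_rows.append(
                    {
                        "cell_id": meta.cell_id,
                        "group": group_name,
                        "frequency_hz": comp.frequency_hz,
                        "amplitude_nN": comp.amplitude_nN,
                    }
                )
            traces.append(generate_cell_trace(realized, meta, calib, int(trace_seed)))
    if return_truth:
        return traces, pd.DataFrame(truth_rows)
    return traces


def simulate_band_force_table(
    n_per_group: dict[str, int],
    profiles: dict[str, PhenotypeProfile],
    seed: int,
    jitter_cv: float = 0.33,
    scheme: BandScheme | None = None,
    noise_floor_nN: float = 0.02,
) -> pd.DataFrame:
    """Draw a cohort's band-force table directly at the statistic level.

    Each cell's per-band maximum force is its profile's in-band component
    amplitude (``noise_floor_nN`` for bands with no component) times the
    same log-normal per-cell jitter the trace generator applies.  The
    trace pipeline maps each cell deterministically to (approximately)
    these values, so tables drawn here have the distribution the full
    pipeline produces — at a fraction of the cost.  Used for the
    replicated calibration and power studies of the group tests.
    """
    scheme = scheme or make_band_scheme()
    sigma = np.sqrt(np.log1p(jitter_cv**2)) if jitter_cv > 0 else 0.0
    rng = np.random.default_rng(seed)
    rows = []
    for group_name in sorted(n_per_group):
        if group_name not in profiles:
            raise ValueError(f"group {group_name!r} has no phenotype profile")
        profile = profiles[group_name]
        expected = []
        for band in scheme.bands:
            amp = sum(
                c.amplitude_nN
                for c in profile.components
                if band.lo_hz <= c.frequency_hz < band.hi_hz
            )
            expected.append(amp if amp > 0 else noise_floor_nN)
        expected = np.asarray(expected)
        for i in range(n_per_group[group_name]):
            if sigma > 0:
                factors = rng.lognormal(-0.5 * sigma**2, sigma, expected.size)
            else:
                factors = np.ones(expected.size)
            row = {
                "cell_id": f"{group_name}_{i:02d}",
                "group": group_name,
                "phenotype": profile.name.value,
            }
            row.update(
                {
                    band.column_name: val
                    for band, val in zip(scheme.bands, expected * factors)
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)
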