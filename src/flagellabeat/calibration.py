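"""Cantilever calibration: volts to nanonewtons, and the thermal-noise method.

The optical-beam detector reports cantilever bending as a voltage V.  Two
instrument constants convert it to force:

    F (nN) = V (volts) x S (nm/V) x K (nN/nm)

where S is the deflection sensitivity measured on-instrument and K the
cantilever spring constant.  K is estimated before each measurement by the
thermal-noise method: the free cantilever is a harmonic degree of freedom
in thermal equilibrium, so equipartition fixes its mean-square deflection,
K <z^2> = kB T, and K = kB T / Var(z).  A dimensionless mode-shape factor
``beta`` multiplies the estimate; the ideal point-mass value is 1, the
standard first-mode correction for a rectangular cantilever is ~0.817.

Units: z in nm, K in nN/nm (numerically equal to N/m), kB in nN nm / K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .io_core import DeflectionTrace, ForceTrace

#: Boltzmann constant in nN·nm/K (1.380649e-23 J/K; 1 J = 1e18 nN·nm).
KB_NN_NM_PER_K = 1.380649e-5

#: Minimum series length for a usable thermal-variance estimate.
MIN_THERMAL_SAMPLES = 1000


@dataclass(frozen=True)
class ThermalCalibrationResult:
    spring_constant_nN_per_nm: float
    positional_variance_nm2: float
    n_samples: int
    temperature_K: float


def thermal_noise_spring_constant(
    deflection_nm: np.ndarray,
    temperature_K: float,
    beta: float = 1.0,
) -> ThermalCalibrationResult:
    """Estimate the spring constant from a free-cantilever thermal trace.

    ``k = beta * kB * T / Var(z)`` with Var the unbiased sample variance
    after mean removal.  ``beta`` defaults to 1 (ideal point mass); pass
    ~0.817 for the first flexural mode of a rectangular cantilever.
    """
    z = np.asarray(deflection_nm, dtype=float)
    if z.ndim != 1 or z.size < MIN_THERMAL_SAMPLES:
        raise ValueError(
            f"thermal series too short: need >= {MIN_THERMAL_SAMPLES} samples, got {z.size}"
        )
    if temperature_K <= 0:
        raise ValueError("temperature_K must be > 0")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    var = float(np.var(z - np.mean(z), ddof=1))
    if var == 0.0:
        raise ValueError("degenerate thermal series: zero variance")
    k = beta * KB_NN_NM_PER_K * temperature_K / var
    return ThermalCalibrationResult(
        spring_constant_nN_per_nm=k,
        positional_variance_nm2=var,
        n_samples=z.size,
        temperature_K=temperature_K,
    )


def deflection_to_force(
    trace: DeflectionTrace,
    remove_baseline: bool = True,
    detrend: str = "mean",
) -> ForceTrace:
    """Convert a deflection trace to force: ``F[i] = V[i] * S * K``.

    The residual suction pressure holding the cell bends the cantilever by
    a constant amount; that bending is a baseline, subtracted here
    (``detrend="mean"`` removes the trace mean, ``"linear"`` removes a
    least-squares linear drift as well).  ``remove_baseline=False`` returns
    the raw calibrated force, useful when linearity of the conversion
    itself matters.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    s = trace.calib.sensitivity_nm_per_V
    k = trace.calib.spring_constant_nN_per_nm
    force = trace.deflection_V * s * k
    if remove_baseline:
        if detrend == "mean":
            force = force - np.mean(force)
        elif detrend == "linear":
            force = scipy.signal.detrend(force, type="linear")
        else:
            raise ValueError(f"unknown detrend mode {detrend!r}")
    return ForceTrace(
        meta=trace.meta,
        time_s=trace.time_s,
        force_nN=force,
        baseline_removed=remove_baseline,
    )
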