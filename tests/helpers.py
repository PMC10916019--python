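"""Shared builders for test traces."""

from __future__ import annotations

import numpy as np

import flagellabeat as fb


def make_meta(
    cell_id: str = "c1",
    phenotype: str = "linear",
    trap_region: str = "tail",
    sample_group: str = "prog80_20",
    sampling_rate_hz: float = 1000.0,
    duration_s: float = 10.0,
    trap_pressure_mbar: float = -20.0,
) -> fb.CellMeta:
    return fb.CellMeta(
        cell_id=cell_id,
        phenotype=phenotype,
        trap_region=trap_region,
        sample_group=sample_group,
        trap_pressure_mbar=trap_pressure_mbar,
        sampling_rate_hz=sampling_rate_hz,
        duration_s=duration_s,
    )


def make_force_trace(
    force_nN: np.ndarray,
    sampling_rate_hz: float = 1000.0,
    baseline_removed: bool = True,
    **meta_kwargs,
) -> fb.ForceTrace:
    """Wrap a raw force array (assumed ~zero-mean if baseline_removed)."""
    force_nN = np.asarray(force_nN, dtype=float)
    n = force_nN.size
    meta = make_meta(
        sampling_rate_hz=sampling_rate_hz,
        duration_s=n / sampling_rate_hz,
        **meta_kwargs,
    )
    t = np.arange(n) / sampling_rate_hz
    return fb.ForceTrace(
        meta=meta, time_s=t, force_nN=force_nN, baseline_removed=baseline_removed
    )


def tone_profile(
    freq_hz: float,
    amplitude_nN: float = 1.0,
    noise_sd_nN: float = 0.0,
    burst_duty: float = 1.0,
    am_rate_hz: float = 0.0,
    baseline_offset_nN: float = 0.0,
    phenotype: str = "linear",
) -> fb.PhenotypeProfile:
    return fb.PhenotypeProfile(
        name=phenotype,
        components=(
            fb.BeatComponent(
                frequency_hz=freq_hz, amplitude_nN=amplitude_nN, am_rate_hz=am_rate_hz
            ),
        ),
        baseline_offset_nN=baseline_offset_nN,
        noise_sd_nN=noise_sd_nN,
        burst_duty=burst_duty,
    )
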