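"""Data model, trace file I/O, configuration, and pipeline orchestration.

A FluidFM experiment records the optical-beam deflection of a hollow AFM
cantilever holding a single swimming spermatozoon.  Each recording is a
uniformly sampled voltage trace plus the calibration constants needed to
convert it to force (deflection sensitivity S in nm/V and spring constant K
in nN/nm) and the cell-level annotations the downstream group comparisons
need (motility phenotype, trapping region, semen-sample group).

Traces travel as ``.trace.tsv`` files: a ``#``-prefixed ``key=value``
metadata header followed by a two-column ``time_s<TAB>deflection_V`` block.
The dialect is deliberately plain text so instrument exports can be
inspected and diffed.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("flagellabeat")

#: Maximum tolerated deviation from uniform sample spacing, seconds.
TIME_UNIFORMITY_TOL_S = 1e-9

#: Significant digits used when writing sample values.
WRITE_SIG_DIGITS = 9


class TraceFormatError(ValueError):
    """A trace file does not conform to the ``.trace.tsv`` dialect."""


class PipelineConfigError(ValueError):
    """A pipeline configuration is incomplete or inconsistent."""


class Phenotype(str, enum.Enum):
    linear = "linear"
    circular = "circular"


class TrapRegion(str, enum.Enum):
    tail = "tail"
    midpiece = "midpiece"
    head = "head"


class SampleGroup(str, enum.Enum):
    #: semen sample with 100% progressively motile spermatozoa
    prog100 = "prog100"
    #: semen sample with 80-20% progressive motility
    prog80_20 = "prog80_20"


@dataclass(frozen=True)
class CellMeta:
    """Per-cell annotations attached to every recording.

    ``trap_pressure_mbar`` is the residual holding pressure during the
    measurement (negative = suction); it is metadata only and enters no
    computation.
    """

    cell_id: str
    phenotype: Phenotype
    trap_region: TrapRegion
    sample_group: SampleGroup
    trap_pressure_mbar: float
    sampling_rate_hz: float
    duration_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phenotype", Phenotype(self.phenotype))
        object.__setattr__(self, "trap_region", TrapRegion(self.trap_region))
        object.__setattr__(self, "sample_group", SampleGroup(self.sample_group))
        if self.sampling_rate_hz <= 0:
            raise ValueError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


@dataclass(frozen=True)
class CalibrationConstants:
    """Deflection sensitivity S (nm/V), spring constant K (nN/nm), bath temperature (K).

    The temperature is used only by the thermal-noise spring-constant
    calibration; voltage-to-force conversion needs only S and K.
    """

    sensitivity_nm_per_V: float
    spring_constant_nN_per_nm: float
    temperature_K: float = 298.0

    def __post_init__(self) -> None:
        if self.sensitivity_nm_per_V <= 0:
            raise ValueError("sensitivity_nm_per_V must be > 0")
        if self.spring_constant_nN_per_nm <= 0:
            raise ValueError("spring_constant_nN_per_nm must be > 0")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be > 0")


def _check_uniform_time(time_s: np.ndarray, sampling_rate_hz: float) -> None:
    if time_s.ndim != 1 or time_s.size == 0:
        raise ValueError("time axis must be a nonempty 1-D array")
    if time_s.size > 1:
        dt = np.diff(time_s)
        expected = 1.0 / sampling_rate_hz
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - expected)) > TIME_UNIFORMITY_TOL_S:
            raise ValueError(
                "time axis is not uniform at 1/sampling_rate "
                f"(max deviation {np.max(np.abs(dt - expected)):.3g} s)"
            )


@dataclass(frozen=True)
class DeflectionTrace:
    """Raw photodetector signal (volts) vs. time plus calibration metadata."""

    meta: CellMeta
    calib: CalibrationConstants
    time_s: np.ndarray
    deflection_V: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.deflection_V, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "deflection_V", v)
        _check_uniform_time(t, self.meta.sampling_rate_hz)
        if v.shape != t.shape:
            raise ValueError("deflection and time arrays must have the same shape")
        if t.size != self.meta.n_samples:
            raise ValueError(
                f"trace length {t.size} does not match duration x rate = {self.meta.n_samples}"
            )

    def __len__(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class ForceTrace:
    """Calibrated force (nN) vs. time for one cell.

    ``baseline_removed`` records whether the static suction-induced bending
    has been subtracted; band decomposition requires it.
    """

    meta: CellMeta
    time_s: np.ndarray
    force_nN: np.ndarray
    baseline_removed: bool

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.force_nN, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "force_nN", f)
        _check_uniform_time(t, self.meta.sampling_rate_hz)
        if f.shape != t.shape:
            raise ValueError("force and time arrays must have the same shape")
        if self.baseline_removed:
            scale = max(float(np.max(np.abs(f))), 1.0)
            if abs(float(np.mean(f))) > 1e-6 * scale:
                raise ValueError("baseline_removed is set but mean(force) is not ~0")

    def __len__(self) -> int:
        return self.time_s.size


# --------------------------------------------------------------------------
# Trace file dialect
# --------------------------------------------------------------------------

_META_KEYS = (
    "cell_id",
    "phenotype",
    "trap_region",
    "sample_group",
    "trap_pressure_mbar",
    "sampling_rate_hz",
    "duration_s",
    "sensitivity_nm_per_V",
    "spring_constant_nN_per_nm",
    "temperature_K",
)

_COLUMN_HEADER = "time_s\tdeflection_V"


def write_trace(trace: DeflectionTrace, path: str | Path) -> None:
    """Write ``trace`` in the ``.trace.tsv`` dialect.

    Samples are written with 9 significant digits, enough to round-trip
    float32-class instrument data exactly.
    """
    if len(trace) == 0:
        raise ValueError("refusing to write an empty trace")
    path = Path(path)
    m, c = trace.meta, trace.calib
    header_values: dict[str, object] = {
        "cell_id": m.cell_id,
        "phenotype": m.phenotype.value,
        "trap_region": m.trap_region.value,
        "sample_group": m.sample_group.value,
        "trap_pressure_mbar": f"{m.trap_pressure_mbar:.9g}",
        "sampling_rate_hz": f"{m.sampling_rate_hz:.9g}",
        "duration_s": f"{m.duration_s:.9g}",
        "sensitivity_nm_per_V": f"{c.sensitivity_nm_per_V:.9g}",
        "spring_constant_nN_per_nm": f"{c.spring_constant_nN_per_nm:.9g}",
        "temperature_K": f"{c.temperature_K:.9g}",
    }
    lines = [f"# {k}={header_values[k]}" for k in _META_KEYS]
    lines.append(_COLUMN_HEADER)
    body = "\n".join(
        f"{t:.9f}\t{v:.{WRITE_SIG_DIGITS}g}"
        for t, v in zip(trace.time_s, trace.deflection_V)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n", encoding="utf-8")


def read_trace(path: str | Path) -> DeflectionTrace:
    """Read a ``.trace.tsv`` file.

    Raises :class:`TraceFormatError` naming the offending key when a
    mandatory metadata line is missing, and on a non-uniform time axis or an
    empty sample block.
    """
    import io

    path = Path(path)
    meta_raw: dict[str, str] = {}
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta_raw[key.strip()] = value.strip()
            body_start = i + 1
        elif stripped == "":
            body_start = i + 1
        else:
            break
    try:
        data = pd.read_csv(io.StringIO("\n".join(lines[body_start:])), sep="\t")
    except pd.errors.EmptyDataError:
        raise TraceFormatError(f"{path}: empty sample block") from None

    for key in _META_KEYS:
        if key not in meta_raw:
            raise TraceFormatError(f"{path}: missing mandatory metadata key '# {key}='")
    if list(data.columns) != ["time_s", "deflection_V"]:
        raise TraceFormatError(
            f"{path}: expected columns 'time_s\\tdeflection_V', got {list(data.columns)}"
        )
    if len(data) == 0:
        raise TraceFormatError(f"{path}: empty sample block")

    meta = CellMeta(
        cell_id=meta_raw["cell_id"],
        phenotype=Phenotype(meta_raw["phenotype"]),
        trap_region=TrapRegion(meta_raw["trap_region"]),
        sample_group=SampleGroup(meta_raw["sample_group"]),
        trap_pressure_mbar=float(meta_raw["trap_pressure_mbar"]),
        sampling_rate_hz=float(meta_raw["sampling_rate_hz"]),
        duration_s=float(meta_raw["duration_s"]),
    )
    calib = CalibrationConstants(
        sensitivity_nm_per_V=float(meta_raw["sensitivity_nm_per_V"]),
        spring_constant_nN_per_nm=float(meta_raw["spring_constant_nN_per_nm"]),
        temperature_K=float(meta_raw["temperature_K"]),
    )
    time_s = data["time_s"].to_numpy(dtype=float)
    defl = data["deflection_V"].to_numpy(dtype=float)
    try:
        return DeflectionTrace(meta=meta, calib=calib, time_s=time_s, deflection_V=defl)
    except ValueError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# Pipeline configuration
# --------------------------------------------------------------------------


@dataclass
class SimulationRecipe:
    """Cohort-simulation section of the pipeline config.

    ``n_per_group`` maps a group name to its cell count; ``profile_overrides``
    may adjust the default phenotype profiles (see
    :mod:`flagellabeat.synthetic_data`).  A group name must start with the
    phenotype it simulates (``linear...`` or ``circular...``) unless an
    explicit profile is supplied in code.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"linear_tail": 16, "linear_headmid": 10, "circular": 17}
    )
    jitter_cv: float = 0.33
    sampling_rate_hz: float = 1000.0
    duration_s: float = 120.0


@dataclass
class QCSettings:
    enabled: bool = True
    window_s: float = 5.0
    threshold_nN: float = 0.05
    min_active_fraction: float = 0.5
    cessation_grace_s: float = 20.0


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, mirroring the CLI flags.

    Exactly one of ``simulate`` / ``input_dir`` provides the traces.
    ``comparisons`` lists metadata columns to group by (e.g. ``phenotype``,
    ``sample_group``, ``trap_region``).
    """

    out_dir: Path = Path("flagellabeat_out")
    seed: int = 0
    simulate: SimulationRecipe | None = None
    input_dir: Path | None = None
    band_f_min_hz: float = 0.0
    band_f_max_hz: float = 30.0
    band_width_hz: float = 3.0
    guard_s: float = 1.0
    detrend: str = "mean"
    qc: QCSettings = field(default_factory=QCSettings)
    comparisons: list[str] = field(default_factory=lambda: ["phenotype"])
    write_traces: bool = False

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        cfg = cls()
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw.pop("simulate")
            cfg.simulate = SimulationRecipe(**sim) if isinstance(sim, Mapping) else sim
        if "qc" in raw and raw["qc"] is not None:
            qc = raw.pop("qc")
            cfg.qc = QCSettings(**qc) if isinstance(qc, Mapping) else qc
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise PipelineConfigError(f"unknown config key: {key}")
            setattr(cfg, key, value)
        cfg.out_dir = Path(cfg.out_dir)
        if cfg.input_dir is not None:
            cfg.input_dir = Path(cfg.input_dir)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig):
    """Run calibrate -> QC -> band decomposition -> max-force -> group tests.

    Returns ``(band_force_table, qc_table, comparisons)`` where
    ``band_force_table`` is a :class:`pandas.DataFrame` with one row per
    QC-passing cell and one ``band_*_nN`` column per band, ``qc_table``
    reports every cell (excluded ones retained with ``passed=False``), and
    ``comparisons`` maps each requested grouping to its per-band
    :class:`~flagellabeat.stats.GroupComparisonResult` list.  All three are
    also written as CSV under ``config.out_dir``.
    """
    from . import calibration, qc as qc_mod, spectral, stats, synthetic_data

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if (config.simulate is None) == (config.input_dir is None):
        raise PipelineConfigError("exactly one of 'simulate' or 'input_dir' must be set")

    if config.simulate is not None:
        recipe = config.simulate
        profiles = {
            name: synthetic_data.profile_for_group(name) for name in recipe.n_per_group
        }
        traces = synthetic_data.generate_cohort(
            recipe.n_per_group,
            profiles,
            seed=config.seed,
            jitter_cv=recipe.jitter_cv,
            sampling_rate_hz=recipe.sampling_rate_hz,
            duration_s=recipe.duration_s,
        )
        if config.write_traces:
            trace_dir = out_dir / "traces"
            trace_dir.mkdir(exist_ok=True)
            for tr in traces:
                write_trace(tr, trace_dir / f"{tr.meta.cell_id}.trace.tsv")
    else:
        paths = sorted(Path(config.input_dir).glob("*.trace.tsv"))
        if not paths:
            raise PipelineConfigError(f"no *.trace.tsv files in {config.input_dir}")
        traces = [read_trace(p) for p in paths]

    scheme = spectral.make_band_scheme(
        config.band_f_min_hz, config.band_f_max_hz, config.band_width_hz
    )

    qc_rows = []
    profile_rows = []
    for trace in traces:
        logger.info(
            "cell %s: S=%.6g nm/V, K=%.6g nN/nm",
            trace.meta.cell_id,
            trace.calib.sensitivity_nm_per_V,
            trace.calib.spring_constant_nN_per_nm,
        )
        force = calibration.deflection_to_force(trace, detrend=config.detrend)
        if config.qc.enabled:
            report = qc_mod.assess_motility(
                force,
                band=(config.band_f_min_hz, config.band_f_max_hz),
                window_s=config.qc.window_s,
                threshold_nN=config.qc.threshold_nN,
                min_active_fraction=config.qc.min_active_fraction,
                cessation_grace_s=config.qc.cessation_grace_s,
            )
        else:
            report = qc_mod.QCReport(
                cell_id=trace.meta.cell_id,
                passed=True,
                active_fraction=1.0,
                cessation_time_s=None,
                window_s=config.qc.window_s,
                threshold_nN=config.qc.threshold_nN,
            )
        qc_rows.append(report)
        if not report.passed:
            logger.info(
                "cell %s excluded by QC (active_fraction=%.3f, cessation=%s s)",
                trace.meta.cell_id,
                report.active_fraction,
                report.cessation_time_s,
            )
            continue
        signals = spectral.band_decompose(force, scheme)
        profile = spectral.band_max_force(signals, guard_s=config.guard_s)
        row: dict[str, object] = {
            "cell_id": trace.meta.cell_id,
            "phenotype": trace.meta.phenotype.value,
            "trap_region": trace.meta.trap_region.value,
            "sample_group": trace.meta.sample_group.value,
        }
        for band in scheme.bands:
            row[band.column_name] = profile.band_max_force[band.label]
        profile_rows.append(row)

    n_total = len(traces)
    n_passed = len(profile_rows)
    logger.info("QC: %d of %d cells included, %d excluded", n_passed, n_total, n_total - n_passed)

    band_force_table = pd.DataFrame(
        profile_rows,
        columns=["cell_id", "phenotype", "trap_region", "sample_group"]
        + [b.column_name for b in scheme.bands],
    )
    qc_table = pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "passed": r.passed,
                "active_fraction": r.active_fraction,
                "cessation_time_s": r.cessation_time_s,
            }
            for r in qc_rows
        ]
    )

    comparisons: dict[str, list] = {}
    for group_by in config.comparisons:
        present = set(t.meta.__getattribute__(group_by).value for t in traces)
        surviving = set(band_force_table[group_by]) if n_passed else set()
        empty = sorted(present - surviving)
        if empty:
            raise PipelineConfigError(
                f"no cells survived QC in group(s) {empty} of comparison '{group_by}'"
            )
        if band_force_table[group_by].nunique() < 2:
            logger.info("comparison '%s' skipped: fewer than 2 groups present", group_by)
            continue
        comparisons[group_by] = stats.compare_bands(band_force_table, group_by, scheme=scheme)

    band_force_table.to_csv(out_dir / "band_force.csv", index=False)
    qc_table.to_csv(out_dir / "qc_report.csv", index=False)
    for group_by, results in comparisons.items():
        stats.results_to_frame(results).to_csv(
            out_dir / f"comparison_{group_by}.csv", index=False
        )
    return band_force_table, qc_table, comparisons
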