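"""CSV dialects, run configuration, report tables and the pipeline driver.

File conventions
----------------
* time-course CSV: header ``time_s,<well>,<well>,...``; times in seconds
  (minutes accepted via a config flag, converted once at parse); floats
  written with shortest round-trip repr so writer∘reader is the identity.
* plate CSV: columns ``well,role,compound,fluorescence,od620,replicate``;
  when ``role`` is absent the run config's plate layout supplies it.
* screen report CSV: percents printed to 1 decimal; kinetic report CSV:
  rate constants to 4 significant figures, times as integer seconds
  rounded half up.  Full-precision columns are kept alongside so
  downstream comparisons never consume rounded values.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import metrics as _metrics
from .fitting import FitResult, ThTTimeSeries, fit_condition
from .metrics import PlateRecord, ScreenReport, compare_kinetics, score_plate
from .model import KineticParameters
from .simulate import GeneratorConfig, generate_timecourse

__all__ = [
    "RunConfig",
    "SimulateSettings",
    "ConfigError",
    "TimecourseParseError",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_plate_csv",
    "write_plate_csv",
    "write_screen_report",
    "write_kinetic_report",
    "read_kinetic_report",
    "write_comparison_report",
    "run_pipeline",
    "round_half_up",
    "format_sig4",
]

log = logging.getLogger("amylokin")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class TimecourseParseError(ValueError):
    """Malformed time-course CSV; message carries row/column coordinates."""


# ---------------------------------------------------------------- rounding

def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-symmetric up."""
    return int(math.floor(x + 0.5))


def format_sig4(x: float) -> str:
    """Format to 4 significant figures (report layer only)."""
    return f"{x:.4g}"


# ------------------------------------------------------------- run config

class SimulateSettings(BaseModel):
    """Kinetic-trace generator settings for the ``simulate`` command."""

    k_n: float = Field(gt=0)
    k_e: float = Field(gt=0)
    t_span: float = Field(gt=0)
    t_step: float = 300.0
    noise_cv: float = Field(default=0.05, ge=0)
    n_replicates: int = Field(default=3, ge=1)
    baseline: float = 100.0
    amplitude: float = 1000.0
    condition: str = "condition"


class RunConfig(BaseModel):
    """One pipeline run: inputs, layout, assay settings, output location."""

    seed: int = 0
    outdir: Path = Path("amylokin_out")
    input: Optional[Path] = None
    protein_concentration: float = Field(default=1e-5, gt=0)  # M
    metric: str = "inhibition_in_cellulo"
    strategy: str = "averaged"
    toxicity_threshold: float = Field(default=0.8, gt=0)
    times_in_minutes: bool = False
    #: time-course runs: well id -> condition label (wells sharing a label
    #: are fitted as replicates); plate runs: well id -> "role" or
    #: "role:compound_id" when the plate CSV lacks a role column
    layout: dict[str, str] = Field(default_factory=dict)
    simulate: Optional[SimulateSettings] = None
    control_condition: Optional[str] = None
    verbosity: str = "INFO"

    @field_validator("metric")
    @classmethod
    def _known_metric(cls, v: str) -> str:
        if v not in _metrics.METRIC_ANCHORS:
            raise ValueError(
                f"unknown metric {v!r}; expected one of {sorted(_metrics.METRIC_ANCHORS)}"
            )
        return v

    @field_validator("strategy")
    @classmethod
    def _known_strategy(cls, v: str) -> str:
        if v not in ("averaged", "pooled"):
            raise ValueError("strategy must be 'averaged' or 'pooled'")
        return v

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# -------------------------------------------------------- time-course CSV

def read_timecourse_csv(
    path: Union[str, Path], times_in_minutes: bool = False
) -> list[ThTTimeSeries]:
    """Read a ``time_s,<well>...`` CSV into one series per well column.

    Missing cells are allowed (recorded by dropping the point from that
    well's series); non-numeric cells, duplicate well ids and
    non-monotone times raise :class:`TimecourseParseError` with the
    offending row/column.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
    if not header or header[0] not in ("time_s", "time_min"):
        raise TimecourseParseError(
            f"{path}: first column must be 'time_s' (got {header[:1]!r})"
        )
    wells = header[1:]
    dupes = {w for w in wells if wells.count(w) > 1}
    if dupes:
        raise TimecourseParseError(f"{path}: duplicate well ids {sorted(dupes)}")
    if header[0] == "time_min":
        times_in_minutes = True

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    n_rows = len(df)

    def parse_col(col: str) -> np.ndarray:
        out = np.full(n_rows, np.nan)
        for i, cell in enumerate(df[col].tolist()):
            s = cell.strip()
            if s == "":
                continue
            try:
                out[i] = float(s)
            except ValueError:
                raise TimecourseParseError(
                    f"{path}: non-numeric cell {s!r} at row {i + 2}, column {col!r}"
                ) from None
        return out

    times = parse_col(df.columns[0])
    if np.any(np.isnan(times)):
        row = int(np.nonzero(np.isnan(times))[0][0]) + 2
        raise TimecourseParseError(f"{path}: missing time value at row {row}")
    if np.any(np.diff(times) <= 0):
        row = int(np.nonzero(np.diff(times) <= 0)[0][0]) + 3
        raise TimecourseParseError(f"{path}: non-monotone time column at row {row}")
    if times_in_minutes:
        times = times * 60.0

    series = []
    for well in wells:
        vals = parse_col(well)
        keep = ~np.isnan(vals)
        n_missing = int(n_rows - keep.sum())
        if n_missing:
            log.info("well %s: %d missing cells dropped", well, n_missing)
        series.append(
            ThTTimeSeries(times=times[keep], values=vals[keep], replicate_id=well)
        )
    return series


def write_timecourse_csv(
    traces: Sequence[ThTTimeSeries], path: Union[str, Path]
) -> Path:
    """Write traces sharing one time grid as a ``time_s,<well>...`` CSV."""
    if not traces:
        raise ValueError("no traces to write")
    t0 = traces[0].times
    for tr in traces[1:]:
        if len(tr) != len(traces[0]) or not np.array_equal(tr.times, t0):
            raise ValueError("all traces must share one time grid for CSV export")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s"] + [tr.replicate_id for tr in traces])
        for i, t in enumerate(t0):
            w.writerow([repr(float(t))] + [repr(float(tr.values[i])) for tr in traces])
    return path


# -------------------------------------------------------------- plate CSV

def _parse_layout_entry(entry: str) -> tuple[str, Optional[str]]:
    role, _, cmp_id = entry.partition(":")
    return role.strip(), (cmp_id.strip() or None)


def read_plate_csv(
    path: Union[str, Path], layout: Optional[Mapping[str, str]] = None
) -> list[PlateRecord]:
    """Read endpoint plate records; a config layout may supply roles.

    Layout entries are ``"role"`` or ``"role:compound_id"``.  A well
    with neither an in-file role nor a layout entry is a configuration
    error naming that well.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "well" not in df.columns or "fluorescence" not in df.columns:
        raise TimecourseParseError(f"{path}: need 'well' and 'fluorescence' columns")
    has_role = "role" in df.columns
    records = []
    for _, row in df.iterrows():
        well = str(row["well"])
        role = str(row["role"]) if has_role and not pd.isna(row.get("role")) else None
        cmp_id = None
        if "compound" in df.columns and not pd.isna(row.get("compound")):
            cmp_id = str(row["compound"])
        if role is None:
            if layout is None or well not in layout:
                raise ConfigError(f"no role for well {well!r}: add it to the plate layout")
            role, layout_cmp = _parse_layout_entry(layout[well])
            cmp_id = cmp_id or layout_cmp
        od = None
        if "od620" in df.columns and not pd.isna(row.get("od620")):
            od = float(row["od620"])
        rep = int(row["replicate"]) if "replicate" in df.columns and not pd.isna(row.get("replicate")) else 1
        records.append(
            PlateRecord(
                well=well,
                role=role,
                compound=cmp_id,
                fluorescence=float(row["fluorescence"]),
                od620=od,
                replicate=rep,
            )
        )
    return records


def write_plate_csv(records: Sequence[PlateRecord], path: Union[str, Path]) -> Path:
    if not records:
        raise ValueError("no plate records to write")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["well", "role", "compound", "fluorescence", "od620", "replicate"])
        for r in records:
            w.writerow(
                [
                    r.well,
                    r.role,
                    r.compound or "",
                    repr(float(r.fluorescence)),
                    "" if r.od620 is None else repr(float(r.od620)),
                    r.replicate,
                ]
            )
    return path


# ---------------------------------------------------------------- reports

def write_screen_report(
    reports: Sequence[ScreenReport], path: Union[str, Path]
) -> Path:
    """Screening summary CSV: percents and SEM to 1 decimal place."""
    if not reports:
        raise ValueError("no screen reports to write")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound", "metric", "percent", "sem", "n", "toxicity"])
        for r in reports:
            w.writerow(
                [r.compound, r.metric, f"{r.percent:.1f}", f"{r.sem:.1f}", r.n,
                 "yes" if r.toxicity else "no"]
            )
    return path


_KINETIC_COLUMNS = [
    "condition", "k_n", "k_e", "t0", "t_half", "t1",
    "rho_hat", "k_hat", "a", "residual_rms", "converged", "n_points", "n_replicates",
]


def write_kinetic_report(
    results: Mapping[str, FitResult], path: Union[str, Path]
) -> Path:
    """Kinetic parameter table: k_n/k_e to 4 significant figures, times
    as integer seconds (round half up); full-precision rho/k kept too."""
    if not results:
        raise ValueError("no fit results to write")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_KINETIC_COLUMNS)
        for name, res in results.items():
            w.writerow(
                [
                    name,
                    format_sig4(res.params.k_n),
                    format_sig4(res.params.k_e),
                    round_half_up(res.times.t0),
                    round_half_up(res.times.t_half),
                    round_half_up(res.times.t1),
                    repr(res.rho_hat),
                    repr(res.k_hat),
                    repr(res.params.a),
                    repr(res.residual_rms),
                    res.converged,
                    res.n_points,
                    res.n_replicates,
                ]
            )
    return path


def read_kinetic_report(path: Union[str, Path]) -> dict[str, FitResult]:
    """Rebuild fit results from the full-precision report columns."""
    from .model import characteristic_times

    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, FitResult] = {}
    for _, row in df.iterrows():
        rho, k, a = float(row["rho_hat"]), float(row["k_hat"]), float(row["a"])
        params = KineticParameters.from_rho_k(rho, k, a)
        out[str(row["condition"])] = FitResult(
            params=params,
            times=characteristic_times(params),
            rho_hat=rho,
            k_hat=k,
            residual_rms=float(row["residual_rms"]),
            converged=bool(row["converged"]),
            n_points=int(row["n_points"]),
            n_replicates=int(row["n_replicates"]),
        )
    return out


def write_comparison_report(
    control: str,
    results: Mapping[str, FitResult],
    path: Union[str, Path],
) -> Path:
    """Control-vs-treated fold changes and time increments, one row per condition."""
    if control not in results:
        raise ConfigError(f"control condition {control!r} not among fitted conditions")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["condition", "k_n_fold", "k_e_fold", "delta_t0", "delta_t_half", "delta_t1"])
        for name, res in results.items():
            if name == control:
                continue
            c = compare_kinetics(results[control], res)
            w.writerow(
                [name, f"{c.k_n_fold:.4g}", f"{c.k_e_fold:.4g}",
                 round_half_up(c.delta_t0), round_half_up(c.delta_t_half),
                 round_half_up(c.delta_t1)]
            )
    return path


# --------------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig, command: str) -> int:
    """Execute one subcommand; returns a process exit status.

    ``simulate`` writes a time-course CSV from the generator settings;
    ``fit`` reads a time-course CSV, groups wells into conditions via the
    layout, fits each condition and writes the kinetic report (non-zero
    exit if any fit failed to converge); ``screen``/``disagg`` score an
    endpoint plate; ``report`` derives control-vs-treated comparisons
    from an existing kinetic report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    log.info("amylokin %s | command=%s seed=%d outdir=%s",
             __version__, command, config.seed, outdir)

    if command == "simulate":
        if config.simulate is None:
            raise ConfigError("simulate settings missing from config")
        s = config.simulate
        params = KineticParameters(k_n=s.k_n, k_e=s.k_e, a=config.protein_concentration)
        gen = GeneratorConfig(
            params=params, t_span=s.t_span, t_step=s.t_step, noise_cv=s.noise_cv,
            n_replicates=s.n_replicates, baseline=s.baseline, amplitude=s.amplitude,
            seed=config.seed, condition=s.condition,
        )
        from dataclasses import replace

        traces = [
            replace(tr, replicate_id=f"{s.condition}_{tr.replicate_id}")
            for tr in generate_timecourse(gen)
        ]
        out = write_timecourse_csv(traces, outdir / "timecourse.csv")
        log.info("wrote %s (%d replicates, %d points)", out, len(traces), len(traces[0]))
        return 0

    if command == "fit":
        if config.input is None:
            raise ConfigError("fit requires an input time-course CSV")
        series = read_timecourse_csv(config.input, config.times_in_minutes)
        groups: dict[str, list[ThTTimeSeries]] = {}
        for tr in series:
            condition = config.layout.get(tr.replicate_id, tr.replicate_id)
            groups.setdefault(condition, []).append(tr)
        results: dict[str, FitResult] = {}
        failed = 0
        for name, reps in groups.items():
            try:
                res = fit_condition(reps, config.protein_concentration, config.strategy)
            except ValueError as exc:
                log.error("condition %s: fit failed: %s", name, exc)
                failed += 1
                continue
            results[name] = res
            if not res.converged:
                log.error("condition %s: fit did not converge", name)
                failed += 1
        if results:
            write_kinetic_report(results, outdir / "kinetics.csv")
        return 1 if failed else 0

    if command in ("screen", "disagg"):
        if config.input is None:
            raise ConfigError(f"{command} requires an input plate CSV")
        metric = "disaggregation" if command == "disagg" else config.metric
        records = read_plate_csv(config.input, config.layout or None)
        reports = score_plate(records, metric, config.toxicity_threshold)
        out = write_screen_report(reports, outdir / f"{command}.csv")
        log.info("wrote %s (%d compounds)", out, len(reports))
        return 0

    if command == "report":
        kin_path = Path(config.input) if config.input else outdir / "kinetics.csv"
        results = read_kinetic_report(kin_path)
        control = config.control_condition
        if control is None:
            raise ConfigError("report requires control_condition in config")
        write_comparison_report(control, results, outdir / "comparison.csv")
        return 0

    raise ConfigError(f"unknown command {command!r}")
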