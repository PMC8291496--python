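"""Synthetic plate-reader data with the statistical structure of ThT/ThS assays.

The kinetic generator forward-simulates the autocatalytic sigmoid on a
5-minute sampling grid and applies multiplicative Gaussian noise whose
coefficient of variation defaults to 5% — matching triplicate ThT
measurements whose standard errors stay below 5% of the plateau.  The
endpoint generators invert the screening metrics: plates are built so
that the noiseless metric equals a requested true percent.

One master seed spawns independent per-replicate substreams
(`numpy.random.SeedSequence.spawn`), so a fixed seed reproduces every
trace bit-for-bit regardless of how many replicates are drawn.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .fitting import ThTTimeSeries
from .metrics import METRIC_ANCHORS, PlateRecord
from .model import KineticParameters, aggregated_fraction, characteristic_times

__all__ = [
    "GeneratorConfig",
    "generate_timecourse",
    "generate_endpoint_plate",
    "generate_disaggregation_series",
    "DEFAULT_BASELINE",
    "DEFAULT_AMPLITUDE",
]

# Plate-reader gain is instrument-specific; these arbitrary-unit anchors
# are configurable defaults.
DEFAULT_BASELINE = 100.0
DEFAULT_AMPLITUDE = 1000.0

#: fraction of the multiplicative noise SD used as an additive floor, so
#: early (f ~ 0) points are not artificially noise-free
NOISE_FLOOR_FRACTION = 0.05


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for one simulated kinetic condition.

    ``t_step`` defaults to 300 s (one reading every 5 min); ``noise_cv``
    is the coefficient of variation of the multiplicative Gaussian noise
    (default 5%); triplicates by default.
    """

    params: KineticParameters
    t_span: float
    t_step: float = 300.0
    noise_cv: float = 0.05
    n_replicates: int = 3
    baseline: float = DEFAULT_BASELINE
    amplitude: float = DEFAULT_AMPLITUDE
    seed: int = 0
    condition: str = "condition"

    def __post_init__(self) -> None:
        if self.t_step <= 0 or self.t_span <= 0:
            raise ValueError("t_span and t_step must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def generate_timecourse(config: GeneratorConfig) -> list[ThTTimeSeries]:
    """Simulate replicate ThT traces for one condition.

    Each value is ``baseline + amplitude * f(t) * (1 + eps)`` with
    ``eps ~ N(0, noise_cv)`` independent per point, plus a small additive
    noise floor (``NOISE_FLOOR_FRACTION * noise_cv * amplitude`` SD) so
    pre-lag points carry instrument noise too.  Warns when the time span
    ends before twice the half-aggregation time, where the plateau is
    unconstrained and fits degrade.
    """
    n_steps = int(math.floor(config.t_span / config.t_step + 1e-9))
    times = np.arange(n_steps + 1) * config.t_step
    t_half = characteristic_times(config.params).t_half
    if config.t_span < 2.0 * t_half:
        warnings.warn(
            f"t_span {config.t_span:g} s < 2 * t_half ({2 * t_half:.0f} s): "
            "fit will be poorly constrained",
            stacklevel=2,
        )
    f = aggregated_fraction(config.params, times)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    traces = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        eps = rng.normal(0.0, config.noise_cv, size=times.size) if config.noise_cv else 0.0
        floor_sd = NOISE_FLOOR_FRACTION * config.noise_cv * config.amplitude
        floor = rng.normal(0.0, floor_sd, size=times.size) if floor_sd else 0.0
        values = config.baseline + config.amplitude * f * (1.0 + eps) + floor
        traces.append(
            ThTTimeSeries(
                times=times,
                values=values,
                replicate_id=f"r{i + 1}",
                condition=config.condition,
                protein_concentration=config.params.a,
            )
        )
    return traces


# noiseless anchor fluorescences (a.u.) per metric kind:
# {role: value}; the 0% anchor is high (aggregate-bound dye), the 100%
# anchor low (monomer-level signal)
_ANCHOR_LEVELS = {
    "inhibition_in_vitro": {"positive_control": 1100.0, "monomer_blank": 100.0},
    "disaggregation": {"positive_control": 1100.0, "negative_control": 100.0},
    "inhibition_in_cellulo": {
        "induced_dmso_control": 1100.0,
        "no_inducer_control": 100.0,
    },
}


def generate_endpoint_plate(
    true_percents: Mapping[str, float],
    metric: str,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    anchor_levels: Optional[Mapping[str, float]] = None,
    control_od620: float = 1.0,
) -> list[PlateRecord]:
    """Build an endpoint plate whose noiseless metric equals each requested percent.

    Control and compound wells are laid out in ``n_replicates`` copies;
    noise is multiplicative Gaussian with CV ``noise_cv`` on every
    fluorescence value.  Percents outside [-100, 200] are rejected as
    unphysical for the generator (strong promoters/super-inhibitors are
    representable by the metrics, just not synthesized here).
    """
    if metric not in METRIC_ANCHORS:
        raise ValueError(f"unknown metric {metric!r}")
    for cmp_id, p in true_percents.items():
        if not (-100.0 <= p <= 200.0):
            raise ValueError(f"true percent {p} for {cmp_id} outside [-100, 200]")
    levels = dict(anchor_levels or _ANCHOR_LEVELS[metric])
    zero_role, hundred_role = METRIC_ANCHORS[metric]
    zero_f, hundred_f = levels[zero_role], levels[hundred_role]

    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def noisy(x: float) -> float:
        return x * (1.0 + rng.normal(0.0, noise_cv)) if noise_cv else x

    records = []
    well = 0
    for rep in range(1, n_replicates + 1):
        for role, level in levels.items():
            well += 1
            records.append(
                PlateRecord(
                    well=f"W{well:02d}",
                    role=role,
                    fluorescence=noisy(level),
                    od620=control_od620,
                    replicate=rep,
                )
            )
        for cmp_id in sorted(true_percents):
            well += 1
            p = true_percents[cmp_id]
            value = zero_f - (p / 100.0) * (zero_f - hundred_f)
            records.append(
                PlateRecord(
                    well=f"W{well:02d}",
                    role="compound",
                    compound=cmp_id,
                    fluorescence=noisy(value),
                    od620=control_od620,
                    replicate=rep,
                )
            )
    return records


def generate_disaggregation_series(
    params: KineticParameters,
    compound_effect: float,
    ratios: Sequence[float],
    compound: str = "cmp",
    fibril_f: float = 1100.0,
    monomer_f: float = 100.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[PlateRecord]:
    """Endpoint records for a fibril-disaggregation dose series.

    ``compound_effect`` is the fraction of fibril signal removed at a
    1:1 fibril:compound ratio; at ratio r the effect scales as
    ``1 - (1 - effect)**r``, which is 0 at effect 0, 1 at effect 1, and
    strictly increasing in r — mirroring the stronger disaggregation
    seen at 1:10 than at 1:1.  Fibril (positive) and monomer (negative)
    controls are included.  ``params`` documents which fibril prep the
    series belongs to (concentration metadata); the endpoint arithmetic
    does not depend on it.
    """
    if not ratios:
        raise ValueError("ratios must be non-empty")
    if compound_effect < 0 or compound_effect > 1:
        raise ValueError("compound_effect must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def noisy(x: float) -> float:
        return x * (1.0 + rng.normal(0.0, noise_cv)) if noise_cv else x

    records = [
        PlateRecord(well="CTRL_F", role="positive_control", fluorescence=noisy(fibril_f)),
        PlateRecord(well="CTRL_M", role="negative_control", fluorescence=noisy(monomer_f)),
    ]
    for i, r in enumerate(ratios, start=1):
        if r <= 0:
            raise ValueError("ratios must be positive")
        effect_r = 1.0 - (1.0 - compound_effect) ** r
        after = fibril_f - effect_r * (fibril_f - monomer_f)
        records.append(
            PlateRecord(
                well=f"D{i:02d}",
                role="compound",
                compound=f"{compound}@1:{r:g}",
                fluorescence=noisy(after),
            )
        )
    return records
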