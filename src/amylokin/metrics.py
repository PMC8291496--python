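"""Endpoint screening arithmetic: inhibition, disaggregation, in cellulo.

All three assay families reduce to the same two-point linear
normalization between a 0%-effect control and a 100%-effect anchor:

* in vitro inhibition — aggregated (DMSO) control = 0%, monomer/ThT
  blank = 100%;
* fibril disaggregation — untreated fibril control = 0%, monomer
  control = 100%;
* in cellulo ThS screen — induced DMSO control = 0%, non-induced
  control (minimal protein level) = 100%.

Percentages are never clipped, so aggregation promoters show up as
negative values.  Replicates are summarized as mean +/- SEM (sample SD,
n-1 denominator, over sqrt(n)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fitting import FitResult

__all__ = [
    "ROLES",
    "PlateRecord",
    "ScreenReport",
    "KineticComparison",
    "DegeneratePlateError",
    "inhibition_in_vitro",
    "disaggregation_percent",
    "inhibition_in_cellulo",
    "aggregate_replicates",
    "toxicity_flag",
    "compare_kinetics",
    "score_plate",
]

ROLES = frozenset(
    {
        "positive_control",
        "negative_control",
        "monomer_blank",
        "no_inducer_control",
        "induced_dmso_control",
        "compound",
    }
)

#: anchor roles per metric kind: (zero-percent role, hundred-percent role)
METRIC_ANCHORS = {
    "inhibition_in_vitro": ("positive_control", "monomer_blank"),
    "disaggregation": ("positive_control", "negative_control"),
    "inhibition_in_cellulo": ("induced_dmso_control", "no_inducer_control"),
}

DEFAULT_TOXICITY_RATIO = 0.8


class DegeneratePlateError(ValueError):
    """Control anchors are inverted or coincident; percents undefined."""


@dataclass(frozen=True)
class PlateRecord:
    """One endpoint fluorescence measurement with its plate role."""

    well: str
    role: str
    fluorescence: float
    compound: Optional[str] = None
    od620: Optional[float] = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")
        if self.fluorescence < 0:
            raise ValueError("fluorescence must be non-negative")
        if self.role == "compound" and not self.compound:
            raise ValueError(f"compound record in well {self.well} lacks a compound id")


@dataclass(frozen=True)
class ScreenReport:
    """Per-compound screening summary (mean percent +/- SEM)."""

    compound: str
    metric: str
    percent: float
    sem: float
    n: int
    toxicity: bool = False
    single_replicate: bool = False

    def __post_init__(self) -> None:
        if self.sem < 0 or self.n < 1:
            raise ValueError("sem must be >= 0 and n >= 1")


@dataclass(frozen=True)
class KineticComparison:
    """Control-vs-treated fold changes and time increments."""

    k_n_fold: float  # k_n(control) / k_n(treated)
    k_e_fold: float
    delta_t0: float  # treated - control, s
    delta_t_half: float
    delta_t1: float


def _percent(sample: float, zero_anchor: float, hundred_anchor: float) -> float:
    span = zero_anchor - hundred_anchor
    if span <= 0:
        raise DegeneratePlateError(
            f"0%-anchor ({zero_anchor:g}) must exceed 100%-anchor ({hundred_anchor:g})"
        )
    return 100.0 * (zero_anchor - sample) / span


def inhibition_in_vitro(
    compound_f: float, aggregated_control_f: float, monomer_blank_f: float = 0.0
) -> float:
    """Percent inhibition of fibril formation after 24 h co-incubation.

    100 * (control - compound) / (control - blank); the blank defaults
    to 0 when no monomer/ThT-only blank was run.
    """
    return _percent(compound_f, aggregated_control_f, monomer_blank_f)


def disaggregation_percent(
    after_f: float, fibril_control_f: float, monomer_f: float
) -> float:
    """Percent loss of fibril ThT signal after incubation with compound."""
    return _percent(after_f, fibril_control_f, monomer_f)


def inhibition_in_cellulo(
    sample_f: float, induced_dmso_f: float, no_inducer_f: float
) -> float:
    """Percent inhibition in the bacterial ThS screen.

    The induced DMSO culture defines 0% (maximal aggregate level), the
    non-induced culture 100% (minimal protein level).
    """
    return _percent(sample_f, induced_dmso_f, no_inducer_f)


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Mean and SEM (sample SD / sqrt(n)) of replicate percents.

    For a single replicate the SEM is 0; callers should carry the
    single-replicate flag on the report.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))


def toxicity_flag(
    sample_od620: float,
    control_od620: float,
    threshold_ratio: float = DEFAULT_TOXICITY_RATIO,
) -> bool:
    """Flag suppressed bacterial growth (possible intrinsic toxicity).

    True when sample OD620 / control OD620 < threshold_ratio.
    """
    if control_od620 <= 0:
        raise ValueError("control OD620 must be positive")
    return (sample_od620 / control_od620) < threshold_ratio


def compare_kinetics(control: FitResult, treated: FitResult) -> KineticComparison:
    """Fold decreases in rate constants and characteristic-time shifts."""
    if not (control.converged and treated.converged):
        raise ValueError("both fits must have converged")
    return KineticComparison(
        k_n_fold=control.params.k_n / treated.params.k_n,
        k_e_fold=control.params.k_e / treated.params.k_e,
        delta_t0=treated.times.t0 - control.times.t0,
        delta_t_half=treated.times.t_half - control.times.t_half,
        delta_t1=treated.times.t1 - control.times.t1,
    )


def score_plate(
    records: Sequence[PlateRecord],
    metric: str,
    toxicity_threshold: float = DEFAULT_TOXICITY_RATIO,
) -> list[ScreenReport]:
    """Summarize an endpoint plate into per-compound reports.

    Control anchors are the replicate means of the two roles appropriate
    to ``metric`` (see :data:`METRIC_ANCHORS`); each compound replicate
    is converted to a percent, then replicates are pooled to mean +/-
    SEM.  Growth (OD620) toxicity is flagged against the mean of the
    0%-anchor controls when OD620 values are present.
    """
    if metric not in METRIC_ANCHORS:
        raise ValueError(f"unknown metric {metric!r}")
    zero_role, hundred_role = METRIC_ANCHORS[metric]

    zero_vals = [r.fluorescence for r in records if r.role == zero_role]
    hundred_vals = [r.fluorescence for r in records if r.role == hundred_role]
    if not zero_vals:
        raise DegeneratePlateError(f"plate lacks {zero_role} records")
    if not hundred_vals:
        if metric == "inhibition_in_vitro":
            hundred_vals = [0.0]  # no monomer blank run: blank defaults to 0
        else:
            raise DegeneratePlateError(f"plate lacks {hundred_role} records")
    zero_anchor = float(np.mean(zero_vals))
    hundred_anchor = float(np.mean(hundred_vals))

    ods = [r.od620 for r in records if r.role == zero_role and r.od620 is not None]
    control_od = float(np.mean(ods)) if ods else None

    by_compound: dict[str, list[PlateRecord]] = {}
    for r in records:
        if r.role == "compound":
            by_compound.setdefault(r.compound, []).append(r)

    reports = []
    for cmp_id in sorted(by_compound):
        recs = by_compound[cmp_id]
        percents = [_percent(r.fluorescence, zero_anchor, hundred_anchor) for r in recs]
        mean, sem = aggregate_replicates(percents)
        tox = False
        if control_od is not None:
            sample_ods = [r.od620 for r in recs if r.od620 is not None]
            if sample_ods:
                tox = toxicity_flag(
                    float(np.mean(sample_ods)), control_od, toxicity_threshold
                )
        reports.append(
            ScreenReport(
                compound=cmp_id,
                metric=metric,
                percent=mean,
                sem=sem,
                n=len(percents),
                toxicity=tox,
                single_replicate=len(percents) == 1,
            )
        )
    return reports
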