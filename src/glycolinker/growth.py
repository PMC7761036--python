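"""Substrate-utilization growth screening from sparse OD600 time courses.

Growth on an insoluble carbohydrate source is read manually at a few time
points (default 0, 5, 24 h).  After subtracting the no-inoculum blank, an
isolate is classified against a glucose-grown control culture:

* ``high-efficiency`` — corrected 24 h OD at least ``threshold_fraction``
  (default 0.25) of the control's 24 h OD, and at least ``min_od``
  (default 0.1);
* ``low`` — reaches ``min_od`` but falls short of the fraction;
* ``none`` — below ``min_od``.

The numeric thresholds are explicit parameters echoed into the result; the
qualitative split (moderate growth vs low density vs none) is the screening
outcome of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import ValidationError

DEFAULT_TIMES = (0.0, 5.0, 24.0)


@dataclass
class GrowthCurve:
    """OD600 time course for one isolate x condition, with blank wells."""

    isolate: str
    condition: str  # e.g. "glucose", "MM", "CM NSP"
    times: tuple[float, ...]
    od: tuple[tuple[float, ...], ...]  # one inner tuple per replicate
    blank: tuple[float, ...] | None = None  # per time point
    blank_subtracted: bool = False

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError("time points must be non-decreasing")
        for rep in self.od:
            if len(rep) != len(self.times):
                raise ValidationError("each replicate needs one OD per time point")
        if self.blank is not None and len(self.blank) != len(self.times):
            raise ValidationError("blank needs one reading per time point")

    @property
    def n_replicates(self) -> int:
        return len(self.od)

    def subtract_blank(self) -> "GrowthCurve":
        """Floor-at-zero blank subtraction; idempotent once subtracted."""
        if self.blank_subtracted or self.blank is None:
            return replace(self, blank_subtracted=True)
        corrected = tuple(
            tuple(max(0.0, v - b) for v, b in zip(rep, self.blank)) for rep in self.od
        )
        return replace(self, od=corrected, blank=None, blank_subtracted=True)

    def mean_at(self, time: float) -> float:
        try:
            i = self.times.index(time)
        except ValueError:
            raise ValidationError(
                f"{self.isolate}/{self.condition}: no reading at t = {time} h"
            ) from None
        return sum(rep[i] for rep in self.od) / self.n_replicates


@dataclass(frozen=True)
class GrowthCall:
    """Classification outcome with the thresholds that produced it."""

    isolate: str
    label: str  # "high-efficiency" | "low" | "none"
    od_24h: float
    control_od_24h: float
    fraction_of_control: float
    threshold_fraction: float
    min_od: float


def classify_growth(
    curve: GrowthCurve,
    control: GrowthCurve,
    threshold_fraction: float = 0.25,
    min_od: float = 0.1,
    at_time: float = 24.0,
) -> GrowthCall:
    """Label a growth curve against its glucose control at the endpoint read."""
    curve = curve.subtract_blank()
    control = control.subtract_blank()
    od = curve.mean_at(at_time)
    control_od = control.mean_at(at_time)
    if control_od <= 0:
        raise ValidationError("control final OD must be > 0")
    fraction = od / control_od
    if od >= min_od and fraction >= threshold_fraction:
        label = "high-efficiency"
    elif od >= min_od:
        label = "low"
    else:
        label = "none"
    return GrowthCall(
        isolate=curve.isolate,
        label=label,
        od_24h=od,
        control_od_24h=control_od,
        fraction_of_control=fraction,
        threshold_fraction=threshold_fraction,
        min_od=min_od,
    )


def read_growth_csv(path: str | Path) -> list[GrowthCurve]:
    """Read ``isolate, condition, replicate, time_h, od600, blank_od`` rows."""
    df = pd.read_csv(path)
    required = {"isolate", "condition", "replicate", "time_h", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"growth table missing columns: {sorted(missing)}")
    curves = []
    for (isolate, condition), grp in df.groupby(["isolate", "condition"], sort=False):
        times = tuple(sorted(grp["time_h"].unique()))
        reps = []
        for _, rep_grp in grp.groupby("replicate", sort=True):
            rep_grp = rep_grp.sort_values("time_h")
            if tuple(rep_grp["time_h"]) != times:
                raise ValidationError(
                    f"{isolate}/{condition}: replicates disagree on time points"
                )
            reps.append(tuple(rep_grp["od600"]))
        blank = None
        if "blank_od" in grp.columns and grp["blank_od"].notna().all():
            first = grp.sort_values("time_h").groupby("time_h")["blank_od"].first()
            blank = tuple(first.loc[list(times)])
        curves.append(
            GrowthCurve(isolate=str(isolate), condition=str(condition),
                        times=times, od=tuple(reps), blank=blank)
        )
    return curves
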