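"""Polysaccharide composition estimation from linkage stoichiometry.

Each linkage's molar% is allocated across the polysaccharide classes that
can contain it, in three deterministic passes:

1. *Exclusive*: a linkage mapping to exactly one class (after fraction
   overrides) gives it its full molar%.
2. *Stoichiometric rules*, in fixed order:

   a. 4-GalAp — rhamnogalacturonan I receives min(4-GalAp, 2-Rhap + 2,4-Rhap)
      (alternating Rha/GalA backbone assumption); the remainder is
      homogalacturonan.
   b. 4-Glcp — xyloglucan receives min(remaining, 4,6-Glcp x 1/3)
      (XXXG motif: one unbranched backbone Glc per three branched);
      heteromannan receives min(remaining, 4-Manp x glc_man_ratio)
      (glucomannan Glc:Man default 1:3); the remainder is cellulose — unless
      cellulose is suppressed in this fraction, in which case it goes to
      xyloglucan.
   c. shared terminal residues — split proportionally to each candidate
      class's branch-point demand (the class's already-allocated branch-point
      linkages, weighted); zero total demand sends the full amount to the
      first candidate class in table row order.

3. *Residual*: linkages absent from the table go to UA (unassigned).

Every pass conserves each linkage's input molar% exactly, so the class
totals plus UA sum to the profile total.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .assignments import REPORT_ORDER, AssignmentTable, default_assignment_table
from .errors import ValidationError
from .linkage import FractionLabel, LinkageCode
from .profile import LinkageProfile

_L = LinkageCode.parse  # local shorthand


@dataclass
class AllocationMatrix:
    """Linkage x class allocation with a UA residual column.

    Row sums equal the input molar% of each linkage (conservation).
    """

    frame: pd.DataFrame  # index: canonical linkage strings; columns: classes + "UA"
    fraction: FractionLabel | None = None

    @property
    def input_total(self) -> float:
        return float(self.frame.to_numpy().sum())

    def row_sums(self) -> pd.Series:
        return self.frame.sum(axis=1)

    def class_totals(self) -> pd.Series:
        return self.frame.sum(axis=0)


@dataclass
class PolysaccharideComposition:
    """Estimated molar% per polysaccharide class, including UA."""

    fraction: FractionLabel | None
    values: dict[str, float]
    provenance: AllocationMatrix | None = None

    def __post_init__(self) -> None:
        if any(v < -1e-9 for v in self.values.values()):
            raise ValidationError("composition values must be >= 0")

    @property
    def total(self) -> float:
        return sum(self.values.values())

    def as_series(self) -> pd.Series:
        return pd.Series(
            {c: self.values.get(c, 0.0) for c in REPORT_ORDER}, name=str(self.fraction or "")
        )


def allocate_linkages(
    profile: LinkageProfile, table: AssignmentTable | None = None
) -> AllocationMatrix:
    """Allocate a linkage profile's molar% across polysaccharide classes."""
    table = table or default_assignment_table()
    amounts = profile.means()
    fraction_name = profile.fraction.name if profile.fraction else None
    classes = table.class_order()
    columns = classes + ["UA"]
    index = [str(lk) for lk in sorted(amounts)]
    frame = pd.DataFrame(0.0, index=index, columns=columns)

    deferred: list[LinkageCode] = []
    for lk in sorted(amounts):
        amt = amounts[lk]
        cands = table.candidates(lk, fraction_name)
        if not cands:
            frame.at[str(lk), "UA"] = amt
        elif len(cands) == 1:
            frame.at[str(lk), cands[0]] = amt
        else:
            deferred.append(lk)

    # Rule (a): 4-GalAp between RG-I and HG.
    galA = _L("4-GalAp")
    if galA in deferred:
        cands = table.candidates(galA, fraction_name)
        if "RG-I" in cands and "HG" in cands:
            amt = amounts[galA]
            backbone_rha = amounts.get(_L("2-Rhap"), 0.0) + amounts.get(_L("2,4-Rhap"), 0.0)
            to_rg = min(amt, backbone_rha)
            frame.at[str(galA), "RG-I"] = to_rg
            frame.at[str(galA), "HG"] = amt - to_rg
            deferred.remove(galA)

    # Rule (b): 4-Glcp among XG, HM and CE.
    glc4 = _L("4-Glcp")
    if glc4 in deferred:
        cands = table.candidates(glc4, fraction_name)
        if set(cands) <= {"XG", "HM", "CE"}:
            remaining = amounts[glc4]
            if "XG" in cands:
                take = min(
                    remaining,
                    amounts.get(_L("4,6-Glcp"), 0.0) * table.rules["xg_unbranched_ratio"],
                )
                frame.at[str(glc4), "XG"] = take
                remaining -= take
            if "HM" in cands:
                take = min(
                    remaining, amounts.get(_L("4-Manp"), 0.0) * table.rules["glc_man_ratio"]
                )
                frame.at[str(glc4), "HM"] = take
                remaining -= take
            # Remainder: cellulose, or — where cellulose is suppressed for
            # this fraction — reassigned to xyloglucan, not discarded.
            for sink in ("CE", "XG", "HM"):
                if sink in cands:
                    frame.at[str(glc4), sink] += remaining
                    break
            deferred.remove(glc4)

    # Rule (c): demand-proportional split of remaining shared linkages
    # (with the default table these are the shared terminal residues).
    for lk in sorted(deferred):
        amt = amounts[lk]
        cands = table.candidates(lk, fraction_name)
        demands = []
        for cls in cands:
            demand = sum(
                frame.at[str(dlk), cls] * w
                for dlk, w in table.demand_linkages(cls, lk)
                if str(dlk) in frame.index
            )
            demands.append(demand)
        total_demand = sum(demands)
        if total_demand <= 0:
            frame.at[str(lk), cands[0]] = amt
            continue
        allocated = 0.0
        for cls, demand in zip(cands[:-1], demands[:-1]):
            share = amt * demand / total_demand
            frame.at[str(lk), cls] = share
            allocated += share
        frame.at[str(lk), cands[-1]] = amt - allocated  # exact conservation

    return AllocationMatrix(frame=frame, fraction=profile.fraction)


def estimate_composition(matrix: AllocationMatrix) -> PolysaccharideComposition:
    """Column sums of the allocation matrix: molar% per class plus UA."""
    totals = matrix.class_totals()
    values = {cls: float(v) for cls, v in totals.items()}
    return PolysaccharideComposition(
        fraction=matrix.fraction, values=values, provenance=matrix
    )


def estimate_from_profile(
    profile: LinkageProfile, table: AssignmentTable | None = None
) -> PolysaccharideComposition:
    """Convenience: allocate then sum in one call."""
    return estimate_composition(allocate_linkages(profile, table))


def compare_fractions(compositions: list[PolysaccharideComposition]) -> pd.DataFrame:
    """Long-format table ``fraction, class, molar_percent`` for stacked bars.

    Classes appear in the fixed legend order; every class is reported for
    every fraction (0 when absent).
    """
    if not compositions:
        raise ValidationError("need at least one composition")
    labels = [str(c.fraction or "") for c in compositions]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate fraction labels: {labels}")
    rows = [
        {"fraction": label, "class": cls, "molar_percent": comp.values.get(cls, 0.0)}
        for label, comp in zip(labels, compositions)
        for cls in REPORT_ORDER
    ]
    return pd.DataFrame(rows, columns=["fraction", "class", "molar_percent"])
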