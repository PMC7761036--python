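"""Molar% linkage profiles: normalization, replicate statistics, yields.

A linkage profile is compositional: the molar% of each linkage among all
detected linkages in a sample, summing to 100.  Replicates are aggregated
with the sample standard deviation (n-1 denominator); a linkage absent from
a replicate is a measured zero, not missing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .linkage import FractionLabel, LinkageCode
from .peaks import PeakRecord

#: Tolerance on the sum of molar% means at validation (hand-entered tables round).
SUM_TOLERANCE = 0.5


@dataclass(frozen=True)
class LinkageStat:
    mean: float
    sd: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.mean <= 100 + 1e-9):
            raise ValidationError(f"molar% must be in [0, 100], got {self.mean}")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n < 1:
            raise ValidationError("n must be >= 1")


@dataclass
class LinkageProfile:
    """Per-fraction molar% of linkage types with replicate statistics."""

    fraction: FractionLabel | None
    entries: dict[LinkageCode, LinkageStat]

    def __post_init__(self) -> None:
        total = self.total_check
        if self.entries and abs(total - 100.0) > SUM_TOLERANCE:
            raise ValidationError(
                f"molar% means sum to {total:.3f}, expected 100 +/- {SUM_TOLERANCE}"
            )

    @property
    def total_check(self) -> float:
        return sum(s.mean for s in self.entries.values())

    def means(self) -> dict[LinkageCode, float]:
        return {lk: s.mean for lk, s in self.entries.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: ``fraction, linkage, molar_mean, molar_sd, n``."""
        rows = [
            {
                "fraction": str(self.fraction) if self.fraction else "",
                "linkage": str(lk),
                "molar_mean": s.mean,
                "molar_sd": s.sd,
                "n": s.n,
            }
            for lk, s in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["fraction", "linkage", "molar_mean", "molar_sd", "n"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_means(
        cls, means: dict[LinkageCode | str, float], fraction: FractionLabel | None = None
    ) -> "LinkageProfile":
        """Build an n=1 profile from a {linkage: molar%} mapping."""
        entries = {}
        for lk, value in means.items():
            code = lk if isinstance(lk, LinkageCode) else LinkageCode.parse(lk)
            entries[code] = LinkageStat(mean=float(value))
        return cls(fraction=fraction, entries=entries)


def read_profile_csv(path: str | Path, fraction: FractionLabel | None = None) -> LinkageProfile:
    df = pd.read_csv(path)
    entries = {
        LinkageCode.parse(row.linkage): LinkageStat(
            mean=float(row.molar_mean), sd=float(row.molar_sd), n=int(row.n)
        )
        for row in df.itertuples(index=False)
    }
    return LinkageProfile(fraction=fraction, entries=entries)


def compute_molar_composition(
    peaks: list[PeakRecord],
    response_factors: dict[LinkageCode, float] | None = None,
    fraction: FractionLabel | None = None,
) -> LinkageProfile:
    """Relative molar composition (molar%) from assigned peak areas.

    molar% of linkage L = 100 * (sum of L's areas / factor_L) /
    (total of area/factor over all linkages).  The default response factor
    is 1 for every linkage (raw relative areas); an effective-carbon-response
    table may be supplied.
    """
    unassigned = [p.peak_id for p in peaks if p.assigned_linkage is None]
    if unassigned:
        raise ValidationError(f"unassigned peaks: {', '.join(unassigned)}")
    factors = response_factors or {}
    if any(f <= 0 for f in factors.values()):
        raise ValidationError("response factors must be > 0")
    adjusted: dict[LinkageCode, float] = {}
    for peak in peaks:
        lk = peak.assigned_linkage
        adjusted[lk] = adjusted.get(lk, 0.0) + peak.area / factors.get(lk, 1.0)
    total = sum(adjusted.values())
    if total <= 0:
        raise ValidationError("zero total adjusted area")
    entries = {lk: LinkageStat(mean=100.0 * a / total) for lk, a in adjusted.items()}
    return LinkageProfile(fraction=fraction, entries=entries)


def aggregate_replicates(profiles: list[LinkageProfile]) -> LinkageProfile:
    """Per-linkage mean and sample sd over replicate profiles of one fraction.

    A linkage absent from a replicate contributes 0 in that replicate.
    sd uses the n-1 denominator and is 0 when n = 1.
    """
    if not profiles:
        raise ValidationError("need at least one replicate profile")
    fractions = {p.fraction for p in profiles}
    if len(fractions) != 1:
        raise ValidationError(f"replicates span multiple fractions: {fractions}")
    n = len(profiles)
    linkages = sorted({lk for p in profiles for lk in p.entries})
    entries = {}
    for lk in linkages:
        values = [p.entries[lk].mean if lk in p.entries else 0.0 for p in profiles]
        mean = sum(values) / n
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
        else:
            sd = 0.0
        entries[lk] = LinkageStat(mean=mean, sd=sd, n=n)
    return LinkageProfile(fraction=profiles[0].fraction, entries=entries)


#: Recovered mass above this % of starting mass is flagged as over-recovery.
OVER_RECOVERY_LIMIT = 102.0


@dataclass
class YieldLedger:
    """Fraction-yield bookkeeping: recovered mass as % of starting mass."""

    starting_mass: float  # mg
    fraction_masses: dict[FractionLabel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.starting_mass <= 0:
            raise ValidationError("starting_mass must be > 0")
        if any(m < 0 for m in self.fraction_masses.values()):
            raise ValidationError("fraction masses must be >= 0")

    @property
    def yields(self) -> dict[FractionLabel, float]:
        return {
            f: 100.0 * m / self.starting_mass for f, m in self.fraction_masses.items()
        }

    @property
    def total_yield(self) -> float:
        return sum(self.yields.values())

    @property
    def over_recovery(self) -> bool:
        return self.total_yield > OVER_RECOVERY_LIMIT

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"fraction": str(f), "mass_mg": m, "yield_percent": y}
                for (f, m), y in zip(self.fraction_masses.items(), self.yields.values())
            ]
        )


def compute_yields(
    starting_mass: float, fraction_masses: dict[FractionLabel, float]
) -> YieldLedger:
    """Per-fraction yields (% of starting mass); losses allowed, over-recovery flagged."""
    return YieldLedger(starting_mass=starting_mass, fraction_masses=dict(fraction_masses))
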