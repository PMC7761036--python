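"""Forward simulation of every input the analysis stages consume.

Cell walls with a *known* polysaccharide composition are turned into
linkage profiles through per-class polymer templates; fractionation,
measurement noise, antibody plates, CAZome tables and growth curves are
layered on top.  Because the truth is known, parameter recovery through
the full inverse pipeline (profile -> allocation -> composition) is
measurable.

Templates encode the same stoichiometric assumptions as the estimator's
partition rules (XXXG 1:3 unbranched:branched xyloglucan backbone,
glucomannan Glc:Man = 1:3, alternating rhamnogalacturonan-I backbone), so
the inverse problem is well-posed by construction.  Only non-reducing
termini are emitted (a 1/DP share for finite chains); reducing ends are
ignored, matching the estimator.  All generators are bitwise reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .glycome import AntibodyArray
from .growth import DEFAULT_TIMES, GrowthCurve
from .linkage import FractionLabel, LinkageCode, whole_wall
from .profile import LinkageProfile, LinkageStat, YieldLedger

Template = dict[str, float]  # canonical linkage string -> emitted fraction


def _normalized(template: Template) -> Template:
    total = sum(template.values())
    if total <= 0:
        raise ValidationError("template emits nothing")
    out = {lk: v / total for lk, v in template.items() if v > 0}
    for lk in out:
        LinkageCode.parse(lk)  # validate tokens early
    return out


def template_homogalacturonan(dp: int | None = None) -> Template:
    """Linear 4-linked GalA backbone; finite DP adds a 1/DP terminal share."""
    if dp is None:
        return {"4-GalAp": 1.0}
    return _normalized({"t-GalAp": 1.0 / dp, "4-GalAp": (dp - 1.0) / dp})


def template_rhamnogalacturonan_I(branch_fraction: float = 0.5) -> Template:
    """Alternating GalA/Rha backbone; ``branch_fraction`` of Rha is branched at O-4."""
    b = branch_fraction
    return _normalized({"4-GalAp": 0.5, "2-Rhap": 0.5 * (1 - b), "2,4-Rhap": 0.5 * b})


def template_cellulose(dp: int | None = None) -> Template:
    """4-linked glucan; the practically infinite DP of cellulose is the default."""
    if dp is None:
        return {"4-Glcp": 1.0}
    return _normalized({"t-Glcp": 1.0 / dp, "4-Glcp": (dp - 1.0) / dp})


def template_callose() -> Template:
    return {"3-Glcp": 1.0}


def template_arabinan(
    dp: int | None = None, single_branch: float = 0.3, double_branch: float = 0.0
) -> Template:
    """5-linked Araf backbone with t-Araf side groups at O-2 (and O-2,3)."""
    s, d = single_branch, double_branch
    end = 1.0 / dp if dp else 0.0
    return _normalized(
        {
            "5-Araf": 1.0 - s - d,
            "2,5-Araf": s,
            "2,3,5-Araf": d,
            "t-Araf": s + 2 * d + end,
        }
    )


def template_arabinogalactan_I(
    dp: int | None = None, branch_fraction: float = 0.25
) -> Template:
    """4-linked galactan backbone with t-Araf branches at O-6."""
    b = branch_fraction
    end = 1.0 / dp if dp else 0.0
    return _normalized({"4-Galp": 1.0 - b, "4,6-Galp": b, "t-Araf": b + end})


def template_arabinogalactan_II() -> Template:
    """3,6-branched galactan with arabinose decoration (covers extensin types)."""
    return _normalized(
        {
            "3-Galp": 0.28,
            "6-Galp": 0.15,
            "3,6-Galp": 0.15,
            "t-Galp": 0.15,
            "t-Araf": 0.15,
            "3-Araf": 0.07,
            "t-Arap": 0.03,
            "t-Rhap": 0.02,
        }
    )


def template_heteroxylan(
    arabinose_o2: float = 0.06,
    arabinose_o3: float = 0.06,
    double_branch: float = 0.0,
    glcA: float = 0.05,
) -> Template:
    """Glucuronoarabinoxylan: 4-Xylp backbone, Ara at O-2/O-3, GlcA at O-2."""
    s2, s3, d, u = arabinose_o2, arabinose_o3, double_branch, glcA
    return _normalized(
        {
            "4-Xylp": 1.0 - s2 - s3 - d - u,
            "2,4-Xylp": s2 + u,
            "3,4-Xylp": s3,
            "2,3,4-Xylp": d,
            "t-Araf": s2 + s3 + 2 * d,
            "t-GlcAp": u,
        }
    )


def template_xyloglucan() -> Template:
    """XXLG-type repeat: 1 unbranched + 3 branched backbone Glc, 2 t-Xyl,
    one extended xylose carrying a terminal galactose."""
    return _normalized(
        {
            "4-Glcp": 1.0,
            "4,6-Glcp": 3.0,
            "t-Xylp": 2.0,
            "2-Xylp": 1.0,
            "t-Galp": 1.0,
        }
    )


def template_heteromannan(
    branch_fraction: float = 1.0 / 6.0, glc_man_ratio: float = 1.0 / 3.0
) -> Template:
    """Galactoglucomannan: 4-Man/4-Glc backbone with t-Gal on 4,6-Man.

    ``glc_man_ratio`` is Glc per unbranched 4-Man, mirroring the
    estimator's partition rule for backbone glucose.
    """
    man = 1.0
    branched = man * branch_fraction
    glc = (man - branched) * glc_man_ratio
    return _normalized(
        {
            "4-Manp": man - branched,
            "4,6-Manp": branched,
            "4-Glcp": glc,
            "t-Galp": branched,
        }
    )


def default_templates() -> dict[str, Template]:
    """One template per polysaccharide class, keyed by class code."""
    return {
        "AB": template_arabinan(),
        "AG-I": template_arabinogalactan_I(),
        "AG-II/ET": template_arabinogalactan_II(),
        "HX": template_heteroxylan(),
        "XG": template_xyloglucan(),
        "CE": template_cellulose(),
        "CA": template_callose(),
        "RG-I": template_rhamnogalacturonan_I(),
        "HG": template_homogalacturonan(),
        "HM": template_heteromannan(),
    }


#: A canola-meal-like default composition (weight%): rich in cellulose and
#: pectins (HG, RG-I), with arabinan and xyloglucan next, mannans scarce.
DEFAULT_COMPOSITION: dict[str, float] = {
    "CE": 24.0,
    "HG": 16.0,
    "RG-I": 12.0,
    "AB": 12.0,
    "XG": 12.0,
    "AG-I": 6.0,
    "AG-II/ET": 7.0,
    "HX": 7.0,
    "HM": 2.0,
    "CA": 2.0,
}

#: Default class x fraction extraction proportions (rows sum to 1):
#: pectic classes release into the chelator/carbonate pool, hemicelluloses
#: need strong alkali, cellulose stays in the residue.
DEFAULT_EXTRACTION: dict[str, tuple[float, float, float]] = {
    # (EDTA+Na2CO3, 4M KOH, Residue)
    "HG": (0.80, 0.15, 0.05),
    "RG-I": (0.75, 0.15, 0.10),
    "AB": (0.70, 0.20, 0.10),
    "AG-I": (0.60, 0.30, 0.10),
    "AG-II/ET": (0.60, 0.30, 0.10),
    "HX": (0.15, 0.70, 0.15),
    "XG": (0.10, 0.70, 0.20),
    "HM": (0.20, 0.60, 0.20),
    "CA": (0.30, 0.40, 0.30),
    "CE": (0.02, 0.08, 0.90),
}

LINKAGE_FRACTIONS = ("EDTA+Na2CO3", "4M KOH", "Residue")


def generate_cell_wall(
    composition: dict[str, float] | None = None,
    templates: dict[str, Template] | None = None,
    fraction: FractionLabel | None = None,
) -> tuple[dict[str, float], LinkageProfile]:
    """Noiseless linkage profile of a wall with known composition.

    profile = sum over classes of weight x template distribution,
    renormalized to 100 molar%.
    """
    composition = dict(composition or DEFAULT_COMPOSITION)
    templates = templates or default_templates()
    total = sum(composition.values())
    if abs(total - 100.0) > 1e-6:
        raise ValidationError(f"composition sums to {total}, expected 100")
    mix: dict[str, float] = {}
    for cls, weight in composition.items():
        if cls not in templates:
            raise ValidationError(f"no template for class {cls!r}")
        for lk, frac in templates[cls].items():
            mix[lk] = mix.get(lk, 0.0) + weight * frac
    grand = sum(mix.values())
    entries = {
        LinkageCode.parse(lk): LinkageStat(mean=100.0 * v / grand)
        for lk, v in mix.items()
        if v > 0
    }
    profile = LinkageProfile(fraction=fraction or whole_wall(), entries=entries)
    return composition, profile


def add_noise(
    profile: LinkageProfile,
    cv: float,
    n_replicates: int,
    seed: int | np.random.Generator = 0,
) -> list[LinkageProfile]:
    """Replicate profiles with truncated-Gaussian noise, renormalized to 100.

    Each linkage is perturbed by N(0, (cv x mean)^2), floored at 0, then the
    replicate is renormalized.  cv = 0 returns exact copies.
    """
    if cv < 0:
        raise ValidationError("cv must be >= 0")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    linkages = sorted(profile.entries)
    means = np.array([profile.entries[lk].mean for lk in linkages])
    out = []
    for _ in range(n_replicates):
        if cv == 0:
            values = means.copy()  # exact copies, no renormalization drift
        else:
            values = np.clip(rng.normal(means, cv * means), 0.0, None)
            values = 100.0 * values / values.sum()
        out.append(
            LinkageProfile(
                fraction=profile.fraction,
                entries={
                    lk: LinkageStat(mean=float(v)) for lk, v in zip(linkages, values)
                },
            )
        )
    return out


def generate_fractionation(
    composition: dict[str, float] | None = None,
    extraction: dict[str, tuple[float, ...]] | None = None,
    templates: dict[str, Template] | None = None,
    fraction_names: tuple[str, ...] = LINKAGE_FRACTIONS,
    scheme: str = "linkage-series",
) -> tuple[dict[str, LinkageProfile], YieldLedger, dict[str, dict[str, float]]]:
    """Split a wall across fractions and profile each one.

    Returns (per-fraction profiles, yield ledger, per-fraction true class
    masses).  Mass is conserved exactly: the last fraction of each class is
    computed as the class weight minus the earlier fractions.
    """
    composition = dict(composition or DEFAULT_COMPOSITION)
    extraction = extraction or DEFAULT_EXTRACTION
    templates = templates or default_templates()
    for cls in composition:
        row = extraction.get(cls)
        if row is None:
            raise ValidationError(f"no extraction row for class {cls!r}")
        if len(row) != len(fraction_names):
            raise ValidationError(f"extraction row for {cls!r} has wrong length")
        if abs(sum(row) - 1.0) > 1e-9:
            raise ValidationError(f"extraction row for {cls!r} does not sum to 1")

    # class -> fraction masses, exact by construction
    masses: dict[str, dict[str, float]] = {name: {} for name in fraction_names}
    for cls, weight in composition.items():
        row = extraction[cls]
        allocated = 0.0
        for name, p in zip(fraction_names[:-1], row[:-1]):
            m = weight * p
            masses[name][cls] = m
            allocated += m
        masses[fraction_names[-1]][cls] = weight - allocated

    profiles: dict[str, LinkageProfile] = {}
    fraction_masses: dict[FractionLabel, float] = {}
    for name in fraction_names:
        label = FractionLabel(scheme, name)
        class_masses = masses[name]
        fraction_masses[label] = sum(class_masses.values())
        mix: dict[str, float] = {}
        for cls, m in class_masses.items():
            for lk, frac in templates[cls].items():
                mix[lk] = mix.get(lk, 0.0) + m * frac
        grand = sum(mix.values())
        entries = {
            LinkageCode.parse(lk): LinkageStat(mean=100.0 * v / grand)
            for lk, v in mix.items()
            if v > 0
        }
        profiles[name] = LinkageProfile(fraction=label, entries=entries)
    ledger = YieldLedger(
        starting_mass=sum(composition.values()), fraction_masses=fraction_masses
    )
    return profiles, ledger, masses


def generate_antibody_plate(
    compositions: dict[str, dict[str, float]],
    affinities: pd.DataFrame,
    epitope_groups: dict[str, str],
    background: float = 0.05,
    noise_sd: float = 0.01,
    n_replicates: int = 3,
    dilution_factors: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125),
    seed: int | np.random.Generator = 0,
) -> AntibodyArray:
    """Simulate a probe x extract OD plate.

    reading = dilution x sum(affinity x class abundance) + background +
    Gaussian noise, floored at 0.  ``affinities`` is probe x class;
    ``compositions`` maps extract -> class abundances.
    """
    if (affinities.to_numpy() < 0).any():
        raise ValidationError("affinities must be >= 0")
    if not (1 <= len(dilution_factors) <= 4):
        raise ValidationError("need 1..4 dilutions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for mab_id in affinities.index:
        group = epitope_groups.get(mab_id)
        if group is None:
            raise ValidationError(f"no epitope group for probe {mab_id!r}")
        for extract, abundances in compositions.items():
            signal = sum(
                affinities.at[mab_id, cls] * abundances.get(cls, 0.0)
                for cls in affinities.columns
            )
            for dilution, factor in enumerate(dilution_factors, start=1):
                for replicate in range(1, n_replicates + 1):
                    od = factor * signal + background + float(rng.normal(0, noise_sd))
                    rows.append(
                        {
                            "mab_id": mab_id,
                            "epitope_group": group,
                            "extract": extract,
                            "replicate": replicate,
                            "dilution": dilution,
                            "od": max(0.0, od),
                        }
                    )
    return AntibodyArray(data=pd.DataFrame(rows), background=background)


#: Logistic growth presets shaped like a substrate-utilization screen:
#: glucose control grows high, a good NSP utilizer reaches moderate density,
#: a poor one stays low, and the no-carbohydrate medium is flat.
GROWTH_PRESETS: dict[str, dict[str, float]] = {
    "glucose": {"max_od": 1.0, "rate": 0.4},
    "nsp-moderate": {"max_od": 0.4, "rate": 0.3},
    "nsp-low": {"max_od": 0.12, "rate": 0.2},
    "mm": {"max_od": 0.0, "rate": 0.0},
}


def logistic_od(t: float, max_od: float, rate: float, od0: float = 0.01) -> float:
    """Logistic OD(t) from inoculum ``od0``; zero rate or capacity stays flat."""
    if max_od <= 0 or rate <= 0:
        return od0
    growth = np.exp(rate * t)
    return float(max_od * od0 * growth / (max_od + od0 * (growth - 1.0)))


def generate_growth_curves(
    conditions: dict[str, dict[str, float]] | None = None,
    isolate: str = "SIM1",
    times: tuple[float, ...] = DEFAULT_TIMES,
    od0: float = 0.01,
    blank_od: float = 0.05,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
) -> dict[str, GrowthCurve]:
    """Simulated OD600 curves (blank included in readings) per condition.

    With ``noise_sd`` = 0 the curves are exact logistic samples, so the
    moderate preset classifies high-efficiency and the low preset low
    against the glucose control.
    """
    conditions = conditions or GROWTH_PRESETS
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    curves = {}
    for condition, params in conditions.items():
        reps = []
        for _ in range(n_replicates):
            readings = []
            for t in times:
                od = logistic_od(t, params["max_od"], params["rate"], od0)
                noise = float(rng.normal(0, noise_sd)) if noise_sd > 0 else 0.0
                readings.append(max(0.0, od + blank_od + noise))
            reps.append(tuple(readings))
        blank = tuple(blank_od for _ in times)
        curves[condition] = GrowthCurve(
            isolate=isolate, condition=condition, times=tuple(times),
            od=tuple(reps), blank=blank,
        )
    return curves


@dataclass
class SimulationConfig:
    """Bundle of generator settings, loadable from YAML."""

    composition: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    noise_cv: float = 0.05
    n_replicates: int = 3
    extraction: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EXTRACTION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 100.0) > 1e-6:
            raise ValidationError(f"composition sums to {total}, expected 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("composition", "noise_cv", "n_replicates", "seed"):
            if key in data:
                kwargs[key] = data[key]
        if "extraction" in data:
            kwargs["extraction"] = {
                cls: tuple(row) for cls, row in data["extraction"].items()
            }
        return cls(**kwargs)
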