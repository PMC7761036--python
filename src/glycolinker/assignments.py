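"""Linkage -> polysaccharide assignment table.

Houses the default assignment of glycosidic linkage types to plant
cell-wall polysaccharide classes, including:

* t-Fucp assigned to both AG-II/ET and XG;
* extensin merged with type II arabinogalactan into the single AG-II/ET class
  (AG-II already contains every extensin linkage type);
* 3-Glcp assigned to callose (dicots lack mixed-linkage beta-glucans);
* cellulose x 4-Glcp suppressed in the EDTA+Na2CO3 and 4M KOH fractions
  (cellulose is not extracted by chelator or alkali; its 4-Glcp signal there
  belongs to xyloglucan).

The table is configurable from YAML/JSON: classes may gain/lose linkages,
fraction overrides may be added or removed, and the stoichiometric rule
constants of the allocator live under ``rules``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import SchemaError
from .linkage import LinkageCode

#: Closed set of polysaccharide class codes, in assignment-table row order.
CLASS_ORDER: tuple[str, ...] = (
    "AB", "AG-I", "AG-II/ET", "HX", "XG", "CE", "CA", "RG-I", "HG", "HM",
)

#: Reporting (stacked-bar legend) order, with the unassigned residual last.
REPORT_ORDER: tuple[str, ...] = (
    "AB", "AG-I", "AG-II/ET", "HX", "XG", "CA", "CE", "RG-I", "HG", "HM", "UA",
)

CLASS_NAMES: dict[str, str] = {
    "AB": "arabinan",
    "AG-I": "type I arabinogalactan",
    "AG-II/ET": "type II arabinogalactan / extensin",
    "HX": "heteroxylan",
    "XG": "xyloglucan",
    "CE": "cellulose",
    "CA": "callose",
    "RG-I": "rhamnogalacturonan I",
    "HG": "homogalacturonan",
    "HM": "heteromannan",
    "UA": "unassigned linkages",
}

#: Default class -> linkage assignments (AG-II and ET merged; the extensin
#: linkages t-Araf, 2-Araf, 3-Araf, t-Galp are all already in AG-II).
DEFAULT_CLASSES: dict[str, tuple[str, ...]] = {
    "AB": ("t-Araf", "5-Araf", "2,5-Araf", "2,3,5-Araf"),
    "AG-I": ("t-Araf", "4-Galp", "4,6-Galp"),
    "AG-II/ET": (
        "t-Arap", "t-Araf", "2-Araf", "3-Araf", "t-Rhap", "t-Fucp",
        "t-Galp", "3-Galp", "6-Galp", "3,6-Galp", "3,4,6-Galp",
    ),
    "HX": ("t-Araf", "4-Xylp", "2,4-Xylp", "3,4-Xylp", "2,3,4-Xylp", "t-GlcAp"),
    "XG": ("t-Xylp", "2-Xylp", "t-Fucp", "t-Galp", "2-Galp", "4-Glcp", "4,6-Glcp"),
    "CE": ("4-Glcp",),
    "CA": ("3-Glcp",),
    "RG-I": ("2-Rhap", "2,4-Rhap", "4-GalAp", "3,4-GalAp"),
    "HG": ("t-GalAp", "4-GalAp"),
    "HM": ("4-Manp", "4,6-Manp", "t-Galp", "4-Glcp"),
}

#: Fraction-specific suppression of class x linkage pairs.
DEFAULT_OVERRIDES: tuple[dict[str, str], ...] = (
    {"fraction": "EDTA+Na2CO3", "class": "CE", "linkage": "4-Glcp"},
    {"fraction": "4M KOH", "class": "CE", "linkage": "4-Glcp"},
)

#: Stoichiometric rule constants used by the allocator.
#: - xg_unbranched_ratio: unbranched backbone Glc per branched (XXXG -> 1/3)
#: - glc_man_ratio: glucomannan Glc:Man ratio (default 1:3)
#: - demand_sets: per-class branch-point linkages (with weights) that create
#:   demand for shared terminal residues; "default" applies to any terminal,
#:   per-linkage keys override it (XG demands 2-Xylp for t-Galp/t-Fucp but
#:   4,6-Glcp otherwise).
DEFAULT_RULES: dict = {
    "xg_unbranched_ratio": 1.0 / 3.0,
    "glc_man_ratio": 1.0 / 3.0,
    "demand_sets": {
        "AB": {"default": [["2,5-Araf", 1.0], ["2,3,5-Araf", 1.0]]},
        "AG-I": {"default": [["4,6-Galp", 1.0]]},
        "AG-II/ET": {"default": [["3,6-Galp", 1.0], ["3,4,6-Galp", 1.0]]},
        "HX": {"default": [["2,4-Xylp", 1.0], ["3,4-Xylp", 1.0], ["2,3,4-Xylp", 2.0]]},
        "XG": {
            "default": [["4,6-Glcp", 1.0]],
            "t-Galp": [["2-Xylp", 1.0]],
            "t-Fucp": [["2-Xylp", 1.0]],
        },
        "HM": {"default": [["4,6-Manp", 1.0]]},
    },
}


@dataclass
class AssignmentTable:
    """Class -> linkage map with fraction overrides and partition-rule constants."""

    classes: dict[str, tuple[LinkageCode, ...]]
    overrides: tuple[dict[str, str], ...] = ()
    rules: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_RULES)))

    def __post_init__(self) -> None:
        for code in self.classes:
            if code not in CLASS_ORDER:
                raise SchemaError(f"unknown polysaccharide class code {code!r}")
        pair_set = {
            (cls, str(lk)) for cls, lks in self.classes.items() for lk in lks
        }
        for ov in self.overrides:
            missing = {"fraction", "class", "linkage"} - set(ov)
            if missing:
                raise SchemaError(f"override {ov} missing keys {sorted(missing)}")
            if (ov["class"], ov["linkage"]) not in pair_set:
                raise SchemaError(
                    f"override references unknown pair {ov['class']} x {ov['linkage']}"
                )

    def class_order(self) -> list[str]:
        """Classes present, in canonical table row order."""
        return [c for c in CLASS_ORDER if c in self.classes]

    def candidates(self, linkage: LinkageCode, fraction_name: str | None) -> list[str]:
        """Classes a linkage may be allocated to in a given fraction, row order."""
        out = []
        suppressed = {
            (ov["class"], ov["linkage"])
            for ov in self.overrides
            if fraction_name is not None and ov["fraction"] == fraction_name
        }
        for cls in self.class_order():
            if linkage in self.classes[cls] and (cls, str(linkage)) not in suppressed:
                out.append(cls)
        return out

    def demand_linkages(self, cls: str, terminal: LinkageCode) -> list[tuple[LinkageCode, float]]:
        """Branch-point linkages (with weights) whose allocation to ``cls``
        creates demand for the shared terminal ``terminal``."""
        spec = self.rules.get("demand_sets", {}).get(cls)
        if not spec:
            return []
        entry = spec.get(str(terminal), spec.get("default", []))
        return [(LinkageCode.parse(lk), float(w)) for lk, w in entry]


def default_assignment_table() -> AssignmentTable:
    classes = {
        cls: tuple(LinkageCode.parse(s) for s in lks)
        for cls, lks in DEFAULT_CLASSES.items()
    }
    return AssignmentTable(classes=classes, overrides=DEFAULT_OVERRIDES)


def load_assignment_table(config: str | Path | None = None) -> AssignmentTable:
    """Built-in default table, or one customised from a YAML/JSON config.

    Config schema::

        classes:            # replaces the linkage set of each listed class;
          CODE: [linkage, ...]   # a class set to [] (or omitted under
                                 # replace_classes: true) is removed
        replace_classes: false   # true -> config classes replace the default
        overrides:          # replaces the default override list when present
          - {fraction: ..., class: ..., linkage: ...}
        rules:              # deep-merged over the default rule constants
          glc_man_ratio: ...
          xg_unbranched_ratio: ...
          demand_sets: {...}
    """
    table = default_assignment_table()
    if config is None:
        return table
    path = Path(config)
    raw = path.read_text()
    data = json.loads(raw) if path.suffix.lower() == ".json" else yaml.safe_load(raw)
    if not isinstance(data, dict):
        raise SchemaError("assignment config must be a mapping")
    unknown = set(data) - {"classes", "replace_classes", "overrides", "rules"}
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")

    classes = {} if data.get("replace_classes") else {
        cls: list(map(str, lks)) for cls, lks in DEFAULT_CLASSES.items()
    }
    for cls, lks in (data.get("classes") or {}).items():
        if cls not in CLASS_ORDER:
            raise SchemaError(f"unknown polysaccharide class code {cls!r}")
        if not lks:
            classes.pop(cls, None)
        else:
            classes[cls] = [str(lk) for lk in lks]
    parsed = {
        cls: tuple(LinkageCode.parse(s) for s in lks) for cls, lks in classes.items()
    }

    overrides = tuple(data["overrides"]) if "overrides" in data else DEFAULT_OVERRIDES
    # Drop overrides whose pair vanished with a removed class.
    pair_set = {(c, str(lk)) for c, lks in parsed.items() for lk in lks}
    overrides = tuple(ov for ov in overrides if (ov.get("class"), ov.get("linkage")) in pair_set)

    rules = json.loads(json.dumps(DEFAULT_RULES))
    for key, value in (data.get("rules") or {}).items():
        if key not in DEFAULT_RULES:
            raise SchemaError(f"unknown rule {key!r}")
        if key == "demand_sets":
            rules["demand_sets"].update(value)
        else:
            rules[key] = float(value)
    return AssignmentTable(classes=parsed, overrides=overrides, rules=rules)
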