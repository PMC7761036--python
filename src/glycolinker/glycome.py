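"""Antibody-based glycome screens: ELISA panels and MAPP arrays.

A screen is a probe x extract grid of OD readings with replicate and
dilution structure and a no-antigen (ELISA) or no-primary (MAPP)
background.  Processing is a short, logged pipeline: subtract background
(flooring at zero), average replicates, collapse dilutions, then pivot into
an epitope-grouped heatmap matrix.  No hidden normalization is applied: the
heatmap cells are exactly the corrected means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError

_COLUMNS = ("mab_id", "epitope_group", "extract", "replicate", "dilution", "od")


@dataclass(frozen=True)
class AntibodyProbe:
    """One monoclonal antibody and the epitope group it belongs to."""

    mab_id: str
    epitope_group: str


@dataclass
class AntibodyArray:
    """Long-format OD readings plus background, with a processing log.

    ``data`` columns: mab_id, epitope_group, extract, replicate, dilution, od
    (plus optionally ``background`` in per-cell mode).  ``background`` may
    instead be a scalar, a per-probe dict, or a per-extract dict.
    """

    data: pd.DataFrame
    background: float | dict | None = None
    log: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"antibody readings missing columns: {missing}")
        if (self.data["od"] < 0).any():
            raise ValidationError("OD readings must be >= 0")
        n_dilutions = self.data["dilution"].nunique()
        if not (1 <= n_dilutions <= 4):
            raise ValidationError(f"dilution count must be 1..4, got {n_dilutions}")

    @property
    def probes(self) -> list[AntibodyProbe]:
        seen = self.data[["mab_id", "epitope_group"]].drop_duplicates()
        return [AntibodyProbe(r.mab_id, r.epitope_group) for r in seen.itertuples(index=False)]

    @property
    def extracts(self) -> list[str]:
        return list(dict.fromkeys(self.data["extract"]))

    def _with(self, data: pd.DataFrame, note: str) -> "AntibodyArray":
        return replace(self, data=data.reset_index(drop=True), log=self.log + (note,))


def read_antibody_csv(path: str | Path, background: float | dict | None = None) -> AntibodyArray:
    """Read readings from CSV; a ``background`` column enables per-cell mode."""
    df = pd.read_csv(path)
    return AntibodyArray(data=df, background=background)


def subtract_background(array: AntibodyArray) -> AntibodyArray:
    """corrected = max(0, reading - matched background); mode is logged.

    Background resolution order: per-cell ``background`` column, per-probe or
    per-extract dict, scalar.  Missing background for a cell in per-cell
    mode is an error naming the cell.
    """
    df = array.data.copy()
    if "background" in df.columns:
        mode = "per-cell"
        if df["background"].isna().any():
            bad = df.loc[df["background"].isna()].iloc[0]
            raise ValidationError(
                f"missing background for cell ({bad['mab_id']}, {bad['extract']})"
            )
        bg = df["background"]
        df = df.drop(columns=["background"])
    elif isinstance(array.background, dict):
        keys = set(array.background)
        if keys & set(df["mab_id"]):
            mode = "per-probe"
            bg = df["mab_id"].map(array.background)
        elif keys & set(df["extract"]):
            mode = "per-extract"
            bg = df["extract"].map(array.background)
        else:
            raise ValidationError("background dict keys match neither probes nor extracts")
        if bg.isna().any():
            bad = df.loc[bg.isna()].iloc[0]
            raise ValidationError(
                f"missing background for cell ({bad['mab_id']}, {bad['extract']})"
            )
    elif array.background is not None:
        mode = "scalar"
        bg = float(array.background)
    else:
        raise ValidationError("no background available to subtract")
    df["od"] = (df["od"] - bg).clip(lower=0.0)
    out = replace(array, data=df.reset_index(drop=True), background=0.0)
    return replace(out, log=array.log + (f"subtract_background[{mode}]",))


def average_replicates(array: AntibodyArray) -> AntibodyArray:
    """Per-cell mean over replicates; replicate count kept as ``n_replicates``."""
    df = array.data
    grouped = (
        df.groupby(["mab_id", "epitope_group", "extract", "dilution"], sort=False)["od"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "od", "size": "n_replicates"})
    )
    grouped["replicate"] = 1
    grouped = grouped[list(_COLUMNS) + ["n_replicates"]]
    return array._with(grouped, "average_replicates")


def collapse_dilutions(array: AntibodyArray, mode: str | int | float = "max") -> AntibodyArray:
    """One value per probe x extract (x replicate): max, mean, or a named dilution."""
    df = array.data
    keys = [c for c in ("mab_id", "epitope_group", "extract", "replicate", "n_replicates")
            if c in df.columns]
    if mode == "max":
        out = df.groupby(keys, sort=False)["od"].max().reset_index()
    elif mode == "mean":
        out = df.groupby(keys, sort=False)["od"].mean().reset_index()
    else:
        if mode not in set(df["dilution"]):
            raise ValidationError(f"dilution {mode!r} not present in the array")
        out = df.loc[df["dilution"] == mode, keys + ["od"]].copy()
    out["dilution"] = 1
    out = out[[c for c in list(_COLUMNS) + ["n_replicates"] if c in out.columns]]
    return array._with(out, f"collapse_dilutions[{mode}]")


#: Default ELISA extract column order.
DEFAULT_EXTRACT_ORDER = ("AO", "SC", "1M KOH", "4M KOH", "CH", "4M KOHPC")


@dataclass
class HeatmapMatrix:
    """Probe rows (grouped by epitope group) x extract columns of corrected signal."""

    values: pd.DataFrame  # index: mab_id; columns: extracts
    row_groups: pd.Series = field(default=None)  # epitope group per row

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "epitope_group", self.row_groups)
        out.to_csv(path)


def build_heatmap(
    array: AntibodyArray,
    group_order: list[str],
    extract_order: list[str] | None = None,
) -> HeatmapMatrix:
    """Pivot a processed (subtracted + collapsed) array into a heatmap matrix.

    Rows are sorted by (epitope-group rank, mab_id); columns follow
    ``extract_order``.  The output is independent of input row order.
    """
    df = array.data
    unknown = sorted(set(df["epitope_group"]) - set(group_order))
    if unknown:
        raise ValidationError(f"probes with unknown epitope groups: {unknown}")
    extract_order = list(extract_order or DEFAULT_EXTRACT_ORDER)
    missing = sorted(set(df["extract"]) - set(extract_order))
    if missing:
        raise ValidationError(f"extracts missing from extract_order: {missing}")
    rank = {g: i for i, g in enumerate(group_order)}
    pivot = df.pivot_table(index=["epitope_group", "mab_id"], columns="extract",
                           values="od", aggfunc="mean")
    pivot = pivot.reindex(columns=[e for e in extract_order if e in pivot.columns])
    order = sorted(pivot.index, key=lambda ix: (rank[ix[0]], ix[1]))
    pivot = pivot.loc[order].fillna(0.0)
    groups = pd.Series([g for g, _ in pivot.index], index=[m for _, m in pivot.index],
                       name="epitope_group")
    values = pivot.copy()
    values.index = [m for _, m in pivot.index]
    values.index.name = "mab_id"
    values.columns.name = None
    return HeatmapMatrix(values=values, row_groups=groups)
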