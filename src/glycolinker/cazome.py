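"""CAZome comparison: family counts per genome, category totals, enrichment.

Carbohydrate-active enzyme (CAZyme) family counts (GH/PL/CE families, as
tabulated from dbCAN output) are grouped into functional categories and
compared between gut isolates and environmental "wild-type" reference
strains.  Two bundled tables ship with the package: the major glycoside
hydrolase families and the carbohydrate esterase / polysaccharide lyase
families of six canola-meal-degrading *Bacteroides* isolates and two
reference strains.  A family may legitimately appear in two categories
(GH27 does, under both debranching and oligosaccharide-degrading); the
duplication is kept — it contributes to both category totals — and flagged.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError

#: Default isolate -> wild-type reference pairing for the bundled tables.
#: The *B. fragilis* isolates have no reference strain in the tables.
DEFAULT_REFERENCE_PAIRS: dict[str, str] = {
    "CMU13": "VPI-5482",
    "CMU108": "VPI-5482",
    "CMU19": "ATCC8483",
    "CMU33": "ATCC8483",
}

_META_COLUMNS = ("category", "family", "activity")


@dataclass
class CazomeTable:
    """Family x genome CAZyme counts with category labels.

    ``counts`` rows are (category, family, activity, <genome columns>);
    ``emphasis`` mirrors the genome columns with booleans marking cells
    emphasised in the source table (bold/underline).
    """

    counts: pd.DataFrame
    emphasis: pd.DataFrame

    def __post_init__(self) -> None:
        for col in _META_COLUMNS:
            if col not in self.counts.columns:
                raise ValidationError(f"cazome table missing column {col!r}")
        values = self.counts[list(self.genomes)]
        as_int = values.astype(float)
        if ((as_int % 1) != 0).any().any() or (as_int < 0).any().any():
            raise ValidationError("cazome counts must be non-negative integers")
        dup = self.counts["family"][self.counts["family"].duplicated()]
        if not dup.empty:
            warnings.warn(
                f"family listed in more than one category: {sorted(set(dup))} "
                "(kept as printed; contributes to both category totals)",
                stacklevel=2,
            )

    @property
    def genomes(self) -> list[str]:
        return [c for c in self.counts.columns if c not in _META_COLUMNS]

    @property
    def categories(self) -> list[str]:
        return list(dict.fromkeys(self.counts["category"]))

    @property
    def duplicated_families(self) -> list[str]:
        return sorted(set(self.counts["family"][self.counts["family"].duplicated()]))


def _parse_cell(text: str) -> tuple[int, bool]:
    text = str(text).strip()
    emphasised = text.startswith("**") and text.endswith("**")
    return int(text.strip("*")), emphasised


def read_cazome_tsv(path: str | Path) -> CazomeTable:
    """Read a wide family x genome TSV; ``**n**`` cells mark emphasis."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    genome_cols = [c for c in df.columns if c not in _META_COLUMNS]
    counts = df.copy()
    emphasis = df.copy()
    for col in genome_cols:
        parsed = df[col].map(_parse_cell)
        counts[col] = parsed.map(lambda t: t[0])
        emphasis[col] = parsed.map(lambda t: t[1])
    return CazomeTable(counts=counts, emphasis=emphasis)


def read_cazome_long(path: str | Path) -> CazomeTable:
    """Read long-format TSV ``family, activity, category, genome, count``."""
    df = pd.read_csv(path, sep="\t")
    wide = (
        df.pivot_table(index=["category", "family", "activity"], columns="genome",
                       values="count", aggfunc="sum", fill_value=0)
        .reset_index()
    )
    wide.columns.name = None
    emphasis = wide.copy()
    for col in [c for c in wide.columns if c not in _META_COLUMNS]:
        emphasis[col] = False
    return CazomeTable(counts=wide, emphasis=emphasis)


def load_bundled_table(which: str = "gh") -> CazomeTable:
    """Bundled isolate tables: ``"gh"`` (glycoside hydrolases) or ``"ce_pl"``
    (carbohydrate esterases + polysaccharide lyases)."""
    if which not in ("gh", "ce_pl"):
        raise ValidationError("which must be 'gh' or 'ce_pl'")
    resource = importlib.resources.files("glycolinker.data") / f"cazome_{which}.tsv"
    with importlib.resources.as_file(resource) as path:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # GH27 duplication is expected here
            return read_cazome_tsv(path)


def combine_tables(*tables: CazomeTable) -> CazomeTable:
    """Stack tables (e.g. GH + CE/PL) over the same genome columns."""
    genomes = tables[0].genomes
    for t in tables[1:]:
        if t.genomes != genomes:
            raise ValidationError("tables have different genome columns")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CazomeTable(
            counts=pd.concat([t.counts for t in tables], ignore_index=True),
            emphasis=pd.concat([t.emphasis for t in tables], ignore_index=True),
        )


def aggregate_cazome(table: CazomeTable) -> pd.DataFrame:
    """Per-category, per-genome column sums, plus a grand-total row.

    A family printed in two categories contributes to both totals.
    """
    sums = table.counts.groupby("category", sort=False)[table.genomes].sum()
    sums.loc["Total"] = sums.sum(axis=0)
    return sums


def flag_enrichment(
    table: CazomeTable, pairs: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-family flags: isolate count strictly greater than its reference.

    Returns a DataFrame aligned with the table rows, one boolean column per
    isolate in ``pairs`` (default: the bundled isolate -> wild-type map).
    """
    pairs = pairs if pairs is not None else DEFAULT_REFERENCE_PAIRS
    genomes = set(table.genomes)
    for isolate, reference in pairs.items():
        if isolate not in genomes:
            raise ValidationError(f"unknown genome id {isolate!r}")
        if reference not in genomes:
            raise ValidationError(f"unknown genome id {reference!r}")
    flags = table.counts[list(_META_COLUMNS)].copy()
    for isolate, reference in pairs.items():
        flags[isolate] = table.counts[isolate] > table.counts[reference]
    return flags


def enrichment_report(table: CazomeTable, pairs: dict[str, str] | None = None) -> pd.DataFrame:
    """Long listing of flagged families: isolate, family, counts."""
    pairs = pairs if pairs is not None else DEFAULT_REFERENCE_PAIRS
    flags = flag_enrichment(table, pairs)
    rows = []
    for isolate, reference in pairs.items():
        for i in flags.index[flags[isolate]]:
            rows.append(
                {
                    "isolate": isolate,
                    "reference": reference,
                    "category": table.counts.at[i, "category"],
                    "family": table.counts.at[i, "family"],
                    "isolate_count": int(table.counts.at[i, isolate]),
                    "reference_count": int(table.counts.at[i, reference]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["isolate", "reference", "category", "family",
                 "isolate_count", "reference_count"],
    )


def cazome_ratio(table: CazomeTable, genome_a: str, genome_b: str) -> float:
    """Grand-total CAZyme count ratio a/b over the families in this table only."""
    for g in (genome_a, genome_b):
        if g not in table.genomes:
            raise ValidationError(f"unknown genome id {g!r}")
    total_a = int(table.counts[genome_a].sum())
    total_b = int(table.counts[genome_b].sum())
    if total_b == 0:
        raise ValidationError(f"genome {genome_b!r} has zero total count")
    return total_a / total_b
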