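from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glycolinker import (
    AntibodyArray,
    FractionLabel,
    default_assignment_table,
)
from glycolinker.assignments import DEFAULT_CLASSES

#: Full linkage vocabulary of the default assignment table.
VOCABULARY = sorted({lk for lks in DEFAULT_CLASSES.values() for lk in lks})


@pytest.fixture(scope="session")
def table():
    return default_assignment_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def random_profile_means(rng: np.random.Generator, max_linkages: int = 6,
                         must_include: str | None = None) -> dict[str, float]:
    """Random molar% dict over the default vocabulary, summing to 100."""
    k = int(rng.integers(1, max_linkages + 1))
    chosen = list(rng.choice(VOCABULARY, size=k, replace=False))
    if must_include and must_include not in chosen:
        chosen[0] = must_include
    weights = rng.random(len(chosen)) + 0.05
    weights = 100.0 * weights / weights.sum()
    return dict(zip(chosen, weights))


@pytest.fixture()
def elisa_array() -> AntibodyArray:
    """Small balanced ELISA-style plate: 2 groups x 2 probes, 2 extracts,
    triplicates, 2 dilutions, constant background 0.1."""
    rows = []
    signal = {
        ("mAb-XG1", "AO"): 0.6, ("mAb-XG1", "4M KOH"): 1.2,
        ("mAb-XG2", "AO"): 0.3, ("mAb-XG2", "4M KOH"): 0.9,
        ("mAb-HG1", "AO"): 1.5, ("mAb-HG1", "4M KOH"): 0.2,
        ("mAb-HG2", "AO"): 1.1, ("mAb-HG2", "4M KOH"): 0.1,
    }
    groups = {"mAb-XG1": "xyloglucan", "mAb-XG2": "xyloglucan",
              "mAb-HG1": "HG backbone", "mAb-HG2": "HG backbone"}
    for (mab, extract), s in signal.items():
        for dilution, factor in ((1, 1.0), (2, 0.5)):
            for replicate in (1, 2, 3):
                rows.append(
                    {"mab_id": mab, "epitope_group": groups[mab], "extract": extract,
                     "replicate": replicate, "dilution": dilution,
                     "od": s * factor + 0.1}
                )
    return AntibodyArray(data=pd.DataFrame(rows), background=0.1)


EDTA = FractionLabel("linkage-series", "EDTA+Na2CO3")
KOH4 = FractionLabel("linkage-series", "4M KOH")
RESIDUE = FractionLabel("linkage-series", "Residue")
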