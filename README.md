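# glycolinker

Combinatorial glycomics of plant cell walls and the bacteria that degrade
them, as a tested Python library. `glycolinker` takes the measurements a
cell-wall characterization campaign produces — PMAA GC-MS linkage peak
tables, antibody-array OD plates, per-genome CAZyme family counts, OD600
growth reads — and turns them into the quantities people argue about:
molar% linkage profiles, estimated polysaccharide composition per fraction,
epitope-grouped glycome heatmaps, CAZome enrichment calls, and
growth-proficiency labels. A forward simulator generates every one of those
inputs from known ground truth, so the whole pipeline is testable and its
recovery error measurable.

It is written for carbohydrate chemists and microbiologists who work on
feedstock deconstruction (the bundled data concern canola meal non-starch
polysaccharides and chicken-cecum *Bacteroides* isolates), but every stage
is generic: bring your own peak tables, assignment rules, antibody panels
and count tables.

## The core computation

Partially methylated alditol acetate (PMAA) analysis reports, for each
sample, the relative molar abundance of glycosidic linkage types
(`t-Araf`, `5-Araf`, `4-GalAp`, `4-Glcp`, ...). Each linkage *L* gets

```
molar%(L) = 100 · (Σ areas of L / f_L) / Σ_M (Σ areas of M / f_M)
```

with response factors `f` defaulting to 1. Linkages are then allocated to
polysaccharide classes (arabinan AB, arabinogalactans AG-I and AG-II/ET,
heteroxylan HX, xyloglucan XG, cellulose CE, callose CA,
rhamnogalacturonan-I RG-I, homogalacturonan HG, heteromannan HM, plus an
unassigned residual UA) by a deterministic three-pass scheme:

1. **exclusive** — a linkage with a single candidate class gives it its
   full molar%;
2. **stoichiometric** — shared backbone linkages are split by structural
   ratios: RG-I receives `min(4-GalAp, 2-Rhap + 2,4-Rhap)` (alternating
   Rha/GalA backbone) with the excess going to HG; XG receives
   `min(4-Glcp, 4,6-Glcp / 3)` (XXXG motif), HM receives
   `min(remainder, 4-Manp / 3)` (glucomannan Glc:Man = 1:3), and the rest
   is cellulose — except in chelator/alkali fractions, which cannot contain
   cellulose, where it is reassigned to XG; shared terminal residues are
   split in proportion to each candidate class's already-allocated
   branch-point linkages;
3. **residual** — anything outside the table is UA.

Every pass conserves each linkage's molar% exactly, so class totals + UA
always sum to the profile total.

## Worked example

```python
from glycolinker import LinkageProfile, estimate_from_profile

profile = LinkageProfile.from_means(
    {"2-Rhap": 10, "2,4-Rhap": 5, "4-GalAp": 40, "t-GalAp": 2, "5-Araf": 43}
)
comp = estimate_from_profile(profile)
print(comp.values["RG-I"], comp.values["HG"], comp.values["AB"])
```

prints `30.0 27.0 43.0`: the 15 molar% of rhamnose backbone pulls an equal
share of 4-GalAp into RG-I (10 + 5 + 15 = 30), the surplus 25 plus the
2 molar% terminal GalA is homogalacturonan (27), and 5-Araf is arabinan.

The simulator closes the loop (`examples/03_fractionation_recovery.py`):

```
zero-noise recovery: max per-class error 0.249 molar%
cv=5%, n=3 recovery:  max per-class error 0.374 molar%
```

a 10-class wall pushed through profile generation, 5% measurement noise,
triplicate aggregation and re-estimation comes back well inside 2 molar%
per class. The other examples cover peak assignment and yields (`01`),
the allocation rules (`02`), antibody heatmaps (`04`), CAZome comparison
(`05`, e.g. the CE6 acetyl xylan esterase expansion: 17 members in isolate
CMU19 vs 3 in the wild-type strain) and growth screening (`06`).

A thin CLI mirrors the library for shell use: `glycolinker linkages
compute`, `glycolinker poly estimate`, `glycolinker elisa process`,
`glycolinker cazome aggregate|flag|ratio`, `glycolinker growth classify`,
`glycolinker simulate wall|fractions|growth`.

## Layout

- `src/glycolinker/` — the library (`linkage`, `peaks`, `profile`,
  `assignments`, `estimator`, `glycome`, `cazome`, `growth`, `synthetic`,
  `cli`), with the bundled count tables under `data/`.
- `examples/` — one short narrative script per capability.
- `tests/` — unit and property tests plus `test_acceptance.py` for the
  end-to-end guarantees.
- `docs/methods.md` — the model, its assumptions, parameter defaults and
  known limitations.
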