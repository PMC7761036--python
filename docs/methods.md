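# Methods

This note documents the models behind `glycolinker`: what is assumed, which
parameters matter, what the synthetic generators do and do not emulate, and
where the design was genuinely open.

## Linkage profiles from peak tables

A PMAA GC-MS run yields peaks with retention time, area and (optionally) a
centroided EI spectrum. Identification compares the query spectrum to a
library of standards with a cosine over greedily paired peaks: candidate
pairs within `mz_tolerance` (default 0.5 Da) are ranked by m/z distance and
consumed greedily, each peak used once; the dot product of paired
intensities is divided by the norms over *all* peaks, so unmatched signal
penalizes the score. The top hit is assigned only if similarity ≥ 0.7
(configurable) and the peak's retention time falls inside the standard's
retention window when one is given. Ties in ranking are broken by the
canonical linkage string, for determinism. Tests cross-check the score
against an independent spectral-similarity implementation (matchms
`CosineGreedy`) on spectra whose peak separations make the pairing
unambiguous.

Molar% is relative area, optionally corrected by user-supplied response
factors (default 1 — peak areas are taken as proportional to molar
amounts, the conventional reading of relative PMAA quantification; an
effective-carbon-response table can be supplied where rigor demands it).
Multiple peaks of one linkage are summed before normalization, so the
output sums to 100 exactly.

Replicate aggregation uses the sample standard deviation (n−1); a linkage
absent from a replicate is a measured zero, not missing data — molar% is
compositional, and absence below detection is best represented as 0.
Profiles validate to a 100 ± 0.5 sum on input, tolerating hand-entered,
rounded tables. Deuterium labelling of carboxyl-reduced uronic acids is
carried as a boolean property of the linkage code only; no spectral
mass-shift arithmetic is attempted.

Yield bookkeeping is plain percent-of-starting-mass, with losses allowed
and recovery above 102% flagged rather than rejected.

## Polysaccharide composition estimation

The allocator (three passes: exclusive, stoichiometric, residual — see the
README for the rule statement) is deterministic and conservative by
construction: shares for all but the last candidate are computed
proportionally and the last receives the exact remainder, so row sums equal
input molar% to machine precision.

Rule constants, all exposed in the assignment-table config:

| constant | default | meaning |
|---|---|---|
| `xg_unbranched_ratio` | 1/3 | unbranched per branched backbone Glc in xyloglucan (XXXG motif) |
| `glc_man_ratio` | 1/3 | backbone Glc per unbranched 4-Man in glucomannan |
| `demand_sets` | per class | branch-point linkages (with weights) that create demand for shared terminals |

Default terminal demand: AB ← 2,5-Araf + 2,3,5-Araf; AG-I ← 4,6-Galp;
AG-II/ET ← 3,6-Galp + 3,4,6-Galp; HX ← 2,4-Xylp + 3,4-Xylp + 2·2,3,4-Xylp;
XG ← 2-Xylp for t-Galp/t-Fucp and 4,6-Glcp otherwise; HM ← 4,6-Manp.
When total demand is zero the full amount goes to the first candidate class
in table row order — deterministic rather than silently dropped. The
demand-proportional split is applied to *any* remaining multi-candidate
linkage; with the default table only the shared terminals ever reach it.

Open choices made here, exposed as configuration rather than buried:

- How shared terminals (t-Fucp between AG-II/ET and XG; t-Galp among
  AG-II/ET, XG and HM) are divided is not fixed by the underlying
  protocol; demand-proportional splitting is this package's documented
  stand-in.
- Where the cellulose × 4-Glcp pair is suppressed for a fraction
  (chelator/carbonate and 4 M KOH extracts cannot contain cellulose), the
  leftover backbone glucose is reassigned to xyloglucan, not discarded:
  the override re-attributes signal, and XG is the remaining 4-Glcp
  consumer in those fractions.
- AG-II and extensin are a single reporting class: extensin's linkage
  types are a subset of AG-II's, so the two are not separable from linkage
  data alone.
- 3-Glcp goes to callose unconditionally; dicot walls lack mixed-linkage
  β-glucan.
- Reducing-end derivatives are not modelled; profiles are assumed to
  contain glycosidic-linkage peaks only.

An independent brute-force implementation of the same rule text (plain
dicts, no shared code with the allocator) lives in the test suite and is
required to agree to 1e-9 on a thousand random profiles.

## Antibody screens

Processing is deliberately minimal and logged: `max(0, OD − background)`
(per-cell, per-probe, per-extract or scalar background, mode recorded),
replicate means with the count retained, one value per probe × extract by
max / mean / a named dilution (default **max**, the in-range-spot
convention of printed-array practice; the published combination rule for
multi-dilution arrays is not stated, so the mode is configurable and
recorded), then a pivot with rows ordered by (epitope-group rank, antibody
id). Negative corrected signals are floored at zero — heatmaps bottom out
at "no binding". No per-extract carbohydrate-amount normalization is
applied; cells are corrected means, nothing else.

## CAZome comparison and growth screening

Category totals are column sums over each category's family rows; a family
printed under two categories (GH27 in the bundled glycoside hydrolase
table) is kept as printed, contributes to both totals, and is flagged in a
warning — fidelity to the printed totals beats tidiness. Enrichment is a
strict inequality against the paired reference strain ("more members", not
"at least as many"); the *B. fragilis* isolates have no reference in the
bundled tables and are not flagged. The total-CAZyme ratio is explicitly
table-scoped: it covers the families present in the table fed to it, and
is not comparable to ratios computed over other family universes.

Growth classification needs two numeric thresholds the qualitative
vocabulary ("moderate growth", "low density") does not supply; the
defaults — 25% of the glucose control's 24 h OD, with an absolute floor of
0.1 OD — are explicit parameters echoed into every result. Labels are
monotone in the endpoint OD by construction. Blank (no-inoculum)
subtraction floors at zero and is idempotent.

## Synthetic data

The generators emulate: linkage profiles of walls with known composition
(per-class polymer templates), sequential fractionation (a class × fraction
extraction matrix with rows summing to 1; pectins pool in the
chelator/carbonate fraction, hemicelluloses in strong alkali, cellulose in
the residue), compositional measurement noise (truncated Gaussian with a
coefficient of variation on molar%, then renormalization — the simplest
noise model consistent with mean ± sd error bars), antibody plates
(signal = affinity × abundance, linear, plus background and Gaussian
noise), and logistic growth curves sampled at 0/5/24 h with blank wells.

Default study conditions: triplicate profiles at cv = 5% (four replicates
are typical for whole walls, three for fractions; the simulator default is
3), a 10-class canola-meal-like composition (CE 24, HG 16, RG-I 12, AB 12,
XG 12, AG-I 6, AG-II/ET 7, HX 7, HM 2, CA 2 weight%), growth presets with
glucose reaching OD 1.0, a good NSP utilizer 0.4, a poor one 0.12, and a
flat no-carbohydrate medium.

Templates mirror the estimator's stoichiometric constants, so the inverse
problem is well-posed by construction; only non-reducing termini are
emitted (a 1/DP share for finite chains). One deliberate exception: the
default heteroxylan template is a glucuronoarabinoxylan whose GlcA branch
occupies 2,4-Xylp positions that the terminal-demand heuristic counts but
whose terminal is t-GlcAp, not t-Araf. This leaves a small systematic
recovery offset (≈0.25 molar% on the default mixture) that the tests
measure rather than hide. Template sets emitting only unambiguous linkages
are recovered to 1e-9 at zero noise; the full default mixture is recovered
within 2 molar% per class at cv = 5% with triplicates (measured over 100
seeded trials as the per-class trial mean, with ≥95% of individual trial
errors also inside the band — the per-trial worst case over 1,000
trial × class draws is not a stable statistic at this noise level).

What the generators do *not* emulate — and hence what passing tests do not
show about real data: chromatographic peak overlap and detector response
differences between PMAAs, incomplete methylation/degradation artifacts,
cross-linked polymers shared between classes (arabinan chains on RG-I are
generated as separate AB mass), antibody cross-reactivity and epitope
masking, and lag-phase variability in growth.

## Problem sizes and numerical choices

The test and acceptance workloads use profiles of up to ~30 linkage types,
1,000-case randomized property sweeps for the allocator (oracle agreement
and the cellulose-override guarantee), 100-trial recovery studies, and the
bundled 75-family × 8-genome count tables — sizes chosen so the full suite
runs in well under a minute on one core while the randomized sweeps still
cover the rule interactions densely. Conservation assertions use 1e-9
absolute tolerance; exact-by-construction quantities (fractionation mass,
last-share remainders) are asserted exactly. All randomized tests and
generators are seeded; generator outputs are bitwise reproducible for a
fixed seed.
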