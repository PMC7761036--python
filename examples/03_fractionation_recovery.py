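"""Simulate a wall of known composition, fractionate, add noise, recover.

The forward model emits a linkage profile from per-class polymer templates;
the estimator inverts it.  At zero noise the default mixture comes back
within a quarter molar% per class; with 5% measurement noise and triplicate
profiles the error stays well inside 2 molar%.
"""

import numpy as np

from glycolinker import (
    add_noise,
    aggregate_replicates,
    compare_fractions,
    estimate_from_profile,
    generate_cell_wall,
    generate_fractionation,
)

truth, profile = generate_cell_wall()  # canola-meal-like 10-class wall
print("true composition (weight%):", {k: v for k, v in sorted(truth.items())})

recovered = estimate_from_profile(profile)
worst = max(abs(recovered.values[c] - truth[c]) for c in truth)
print(f"zero-noise recovery: max per-class error {worst:.3f} molar%")

replicates = add_noise(profile, cv=0.05, n_replicates=3, seed=20260920)
noisy = estimate_from_profile(aggregate_replicates(replicates))
worst = max(abs(noisy.values[c] - truth[c]) for c in truth)
print(f"cv=5%, n=3 recovery:  max per-class error {worst:.3f} molar%")

# Fractionation: pectins pool in EDTA+Na2CO3, hemicelluloses in 4M KOH,
# cellulose in the residue — and the profiles show it.
profiles, ledger, _ = generate_fractionation()
print("\nfraction yields:", {str(k): round(v, 1) for k, v in ledger.yields.items()})
compositions = [estimate_from_profile(p) for p in profiles.values()]
report = compare_fractions(compositions)
wide = report.pivot(index="class", columns="fraction", values="molar_percent")
print("\nestimated composition per fraction (molar%):")
print(wide.round(1).to_string())
# RG-I + HG dominate the chelator/carbonate pool; CE dominates the residue.
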