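"""Growth-proficiency screening on a non-starch polysaccharide source.

Simulates logistic OD600 curves (read at 0, 5 and 24 h, as for insoluble
substrates that rule out plate readers) for a glucose control, a good NSP
utilizer, a poor one, and a no-carbohydrate medium, then classifies each
against the control after blank subtraction.
"""

from glycolinker import classify_growth, generate_growth_curves

curves = generate_growth_curves(noise_sd=0.005, seed=42)
control = curves["glucose"]

print("condition        label            OD(24h)  fraction of control")
for condition in ("nsp-moderate", "nsp-low", "mm"):
    call = classify_growth(curves[condition], control)
    print(f"{condition:<16} {call.label:<16} {call.od_24h:7.3f}  "
          f"{call.fraction_of_control:.3f}")
print(f"\nthresholds: >= {0.25:.2f} x control and >= 0.1 OD for high-efficiency;"
      " >= 0.1 OD for low")
# A moderate grower reaching ~40% of the glucose endpoint is called a
# high-efficiency utilizer; flat no-carbohydrate wells classify as none.
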