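"""Triage the packaged Data Deficient species table.

Applies the published cutoffs (0.21 all-species model, 0.18 morphology
model) and the two-model verdict rule to the 44 packaged DD species and
prints the verdict distribution.
"""

from bryorisk import triage_dd_fixture

report = triage_dd_fixture()
counts = report.counts()
pct = report.percentages()

print(f"{report.n_species} Data Deficient species triaged:\n")
for verdict, n in counts.items():
    print(f"  {verdict:<20s} {n:3d}  ({pct[verdict]:.0f}%)")

frame = report.to_frame()
print("\nFirst rows (risk under each model and combined verdict):")
print(frame.head(6).to_string())
print("\n'Threatened' species should be prioritised for full IUCN assessment;")
print("'Possibly Threatened' (the models disagree) warrant a precautionary look.")
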