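"""Generate a synthetic cohort and rerun the whole analysis on it.

Simulates a 723-species cohort with the published effect sizes, masks a
random ~6% of species as Data Deficient, then screens traits, selects the
two minimum adequate models by forward AIC, picks sensitivity-aware
cutoffs and triages the held-out species — printing what each stage found.
"""

import tempfile
import json
from pathlib import Path

from bryorisk.pipeline import RunConfig, run_pipeline

out = Path(tempfile.mkdtemp(prefix="bryorisk_run_"))
run_pipeline(RunConfig(out_dir=str(out), seed=17))

mam1 = json.loads((out / "mam1.json").read_text())
mam2 = json.loads((out / "mam2.json").read_text())
cut1 = json.loads((out / "cutoff_mam1.json").read_text())
cut2 = json.loads((out / "cutoff_mam2.json").read_text())
triage = json.loads((out / "triage.json").read_text())

print(f"run directory: {out}\n")
print(f"model 1 (n={mam1['n']}, {mam1['n_threatened']} threatened) selected:"
      f" {mam1['selected_predictors']}")
print(f"model 2 (n={mam2['n']}, {mam2['n_threatened']} threatened) selected:"
      f" {mam2['selected_predictors']}")
print(f"model 1 AUC {cut1['auc']:.2f}, cutoff {cut1['chosen_cutoff']:.2f}"
      f" ({cut1['rule_applied']})")
print(f"model 2 AUC {cut2['auc']:.2f}, cutoff {cut2['chosen_cutoff']:.2f}"
      f" ({cut2['rule_applied']})")
print(f"\nDD holdout verdicts: {triage['counts']}")
print("\nThe selected predictors should recover the generating effects"
      " (plant sex, sporophyte presence, substrate breadth, seta length);")
print("the smaller n of model 2 reflects the sporophyte-morphology block"
      " missing for ~22% of species.")
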