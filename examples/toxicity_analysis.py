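"""Toxicodynamic exceedance probabilities on day 2 of therapy.

For each regimen/renal pairing, reports the percentage of 2000 simulated
patients whose unbound trough concentration over [24, 48) h exceeds the
literature-reported neurotoxicity (157.2 and 361.4 mg/L) and nephrotoxicity
(452.65 mg/L) thresholds.
"""

from pippk import (
    NORMAL_RENAL,
    SEVERE_RENAL,
    reference_parametric_sample,
    standard_dosages,
    toxicity_probability,
)

sample = reference_parametric_sample(2000, seed=0)
regimens = standard_dosages()
layout = [("D1", NORMAL_RENAL), ("D2", NORMAL_RENAL), ("D3", NORMAL_RENAL),
          ("D4", SEVERE_RENAL), ("D5", SEVERE_RENAL), ("D6", SEVERE_RENAL)]

print("unbound day-2 Cmin exceedance, % of 2000 virtual patients\n")
print(f"{'regimen':8} {'renal':15} {'neuro 157.2':>12} "
      f"{'neuro 361.4':>12} {'nephro 452.65':>14}")
for i, (name, scen) in enumerate(layout):
    tox = toxicity_probability(sample, scen, regimens[name], seed=100 + i)
    vals = tox.set_index("threshold_name")["exceedance_pct"]
    print(f"{name:8} {scen.label:15} {vals['neurotoxicity_low']:12.2f} "
          f"{vals['neurotoxicity_high']:12.2f} {vals['nephrotoxicity']:14.2f}")

print(
    "\nWith normal renal function no threshold is reached. In severe"
    "\nimpairment the q12h dose adjustment keeps nephrotoxicity at zero;"
    "\nextended infusions carry a ~0.1-1% probability of crossing the lower"
    "\n(most conservative) neurotoxicity threshold — highest with the"
    "\nloading regimen — driven by the small-clearance tail of the"
    "\nsimulated population."
)
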