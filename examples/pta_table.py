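"""Monte Carlo probability-of-target-attainment table for six regimens.

Draws 2000 virtual patients from the published population estimates
(moment-matched log-normals), pairs q8h regimens with normal renal function
and q12h regimens with severe impairment / kidney failure, and prints the
PTA (free drug above MIC for >= 50% of the first 24 h) across the
doubling-dilution MIC grid, banded as optimal (>= 90%), intermediate
(50-90%) or poor (< 50%).
"""

from pippk import (
    NORMAL_RENAL,
    SEVERE_RENAL,
    pta_curve,
    reference_parametric_sample,
    standard_dosages,
)

N = 2000
sample = reference_parametric_sample(N, seed=0)
regimens = standard_dosages()
layout = [("D1", NORMAL_RENAL), ("D2", NORMAL_RENAL), ("D3", NORMAL_RENAL),
          ("D4", SEVERE_RENAL), ("D5", SEVERE_RENAL), ("D6", SEVERE_RENAL)]

curves = {
    name: pta_curve(sample, scen, regimens[name], seed=i + 1)
    for i, (name, scen) in enumerate(layout)
}

mics = curves["D1"]["mic"]
header = "MIC mg/L " + "".join(f"{name:>8}" for name, _ in layout)
print(f"{N}-patient simulation; D1-D3 normal renal function, "
      "D4-D6 severe impairment/failure\n")
print(header)
for k, mic in enumerate(mics):
    row = "".join(f"{curves[name]['pta_pct'].iloc[k]:8.1f}" for name, _ in layout)
    print(f"{mic:8.4g} {row}")

print(
    "\nEach entry: % of virtual patients with unbound piperacillin above"
    "\nthe MIC for at least half of the first day. Extended (4 h) infusions"
    "\nand loading doses hold the target through the susceptible range"
    "\n(MIC <= 8 mg/L); short infusions lose it earlier."
)
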