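"""Plasma pharmacokinetics of a multi-dose regimen and the Hill kill law.

Prints the resolved dosing calendar for a docetaxel/cyclophosphamide
regimen, the plasma concentration at a few times, and the specific kill
rate as a function of local tissue concentration.
"""

import numpy as np

import tumorsim as ts
from tumorsim.pkpd import Administration, Regimen

lib = ts.load_drug_library()
doc = lib["docetaxel"]

reg = Regimen([Administration("docetaxel", 120.0, 21.0 * c) for c in range(4)],
              surgery_day=84.0)
print("dosing calendar (drug, hour, mg):")
for row in reg.calendar():
    print("  ", row)

for t_h in (0.0, 12.0, 48.0, 21 * 24.0):
    c = ts.plasma_drug_concentration(doc, reg, t_h)
    print(f"plasma concentration at t={t_h:6.0f} h: {float(c):.4f} mg/L")

print("\nHill kill law (kill_max=%.3f /h, IC50=%.2f mg/L, hill=%.1f):"
      % (doc.kill_max, doc.IC50, doc.hill))
for c in (0.0, doc.IC50 / 10, doc.IC50, 10 * doc.IC50):
    print(f"  C={c:6.3f} mg/L -> kill rate {float(ts.kill_rate(doc, c)):.5f} /h")
# At C = IC50 the kill rate is exactly half of kill_max.
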