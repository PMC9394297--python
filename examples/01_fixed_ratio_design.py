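"""Build a fixed-ratio combination dose table from two single-drug ED30s.

The two drugs are kept in the constant ratio of their ED30s and serially
diluted; each combination's total dose is expressed on the fused axis
(mg/kg + µg/1000), which is what the combination dose-response curve is
fit against.
"""

import isobolab as ib

ED_A = 39.54  # systemic drug ED30, mg/kg
ED_B = 2.74   # local drug ED30, µg/paw

design = ib.build_fixed_ratio_design(ED_A, ED_B, factors=(1, 4, 16, 32))

print(f"{'factor':>8} {'A mg/kg':>10} {'B ug/paw':>10} {'fused total':>12}")
for row in design.rows:
    print(f"{row.factor:>8g} {row.dose_a:>10.2f} {row.dose_b:>10.2f} {row.fused_total:>12.5f}")

# Each row is one combination arm: e.g. the 1/4 dilution administers
# 9.89 mg/kg of drug A plus 0.69 µg/paw of drug B, a fused total of 9.89069.
# Component doses are rounded half-up to 2 decimals before fusing, so the
# printed components always reconstruct the printed total exactly.
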