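"""Simulate the full 16-arm formalin study and run the whole analysis chain.

The generator is calibrated so its expected group effects match the
reported means (56.6% at the top systemic dose, 63.56% for the best
combination, ...) with a true interaction index of 0.14 built into the
combination arms. The pipeline then has to recover that truth from noisy
per-animal flinch counts at n = 6.
"""

import warnings

import isobolab as ib

cfg = ib.default_paper_config(gamma_true=0.14, n_per_arm=6, seed=7)
sim = ib.simulate_study(cfg, ib.default_paper_design())

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # ED30 sits just below drug B's observed range
    report = ib.run_analysis(sim.study, ib.AnalysisConfig(seed=7))

print("group means (% antinociception):")
for row in report.group_effects.itertuples():
    print(f"  {row.arm:>18}: {row.mean:6.2f} ± {row.sem:.2f} (n={row.n})")

iso = report.to_dict()["isobologram"]
print(f"\nED30 drug A = {report.ed_a.dose:.2f} mg/kg (true {cfg.model_ed30('A'):.2f})")
print(f"ED30 drug B = {report.ed_b.dose:.2f} ug/paw (true {cfg.model_ed30('B'):.2f})")
print(f"T = {iso['z_additive']:.3f}  E = {iso['z_experimental']:.3f}")
print(f"gamma = {iso['gamma_raw']:.3f} (true {cfg.gamma_true}), p = {iso['p']:.2e}")
print(f"classification: {iso['classification']}")

print("\nantagonist reversal of the combination effect:")
for row in report.participation.itertuples():
    print(f"  {row.antagonist:>14}: {row.percent_reversal:6.1f}% {row.flag}")

# With a single simulated experiment at n = 6 the estimated gamma scatters
# around the generating 0.14 but the supra-additive call is robust: E sits
# an order of magnitude below T.
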