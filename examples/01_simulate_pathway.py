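"""Simulate the flavonoid network under constant vs transcript-driven enzymes.

Builds the default 12-species network, assigns a plausible set of lumped rate
constants, and integrates the ODEs over days 5-9 twice: once with constant
(unit) enzyme levels and once with decaying transcript-derived profiles.
"""

import numpy as np

import flavopath as fp

topo = fp.build_default_topology()
print(f"network: {len(topo.species)} species, {len(topo.reactions)} reactions "
      f"({len(topo.reduction_ids)} reductions), {len(topo.enzymes)} enzymes")

rng = np.random.default_rng(0)
cfg = fp.GeneratorConfig(noise_cv=0.0, seed=0)
rates = fp.sample_true_rates(cfg, topo, rng)
_, profiles = fp.generate_transcript_profiles(cfg, rng, enzymes=topo.enzymes)
constant = fp.constant_profiles(topo, ["cotyledons"])

x0 = {sp: 10.0 for sp in topo.end_products}  # intermediates start below detection
for label, prof in (("constant enzymes", constant), ("transcript-driven", profiles)):
    traj = fp.simulate(topo, rates, prof, x0, 5.0, 9.0, tissue="cotyledons")
    finals = {sp: traj.series(sp)[-1] for sp in topo.end_products}
    peak_inter = max(traj.series(sp).max() for sp in topo.intermediates)
    print(f"\n{label}:")
    for sp, v in finals.items():
        print(f"  {sp:5s} day-9 concentration: {v:7.2f} µmol/kg")
    print(f"  peak intermediate: {peak_inter:.2f} µmol/kg (detection threshold 2)")

print("\nDecaying transcripts slow every enzymatic step over the window, so less "
      "material is drawn into (and through) the pathway than with constant enzymes.")
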