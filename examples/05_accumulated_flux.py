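"""Accumulated flux: how transcript contrasts redirect material between branches.

Integrates every edge's reaction rate over days 5-9 (trapezoid rule on a fine
grid) under identical rate constants but tissue-specific transcript profiles,
then compares the flavonol vs anthocyanin branches between tissues.
"""

import numpy as np

import flavopath as fp

topo = fp.build_default_topology()
cfg = fp.GeneratorConfig(noise_cv=0.0, seed=41)
rng = np.random.default_rng(cfg.seed)
_, profiles = fp.generate_transcript_profiles(cfg, rng, enzymes=topo.enzymes)
rates = fp.sample_true_rates(cfg, topo, rng)
grid = fp.SolverSettings(grid_step=0.01)  # flux-reporting resolution

maps = {}
for tissue in ("cotyledons", "hypocotyls"):
    traj = fp.simulate(topo, rates, profiles, np.zeros(12), 5.0, 9.0, grid, tissue=tissue)
    fmap = fp.accumulated_flux(traj, rates, profiles, topo, tissue=tissue)
    bal = fp.node_balance(fmap, traj, topo)
    maps[tissue] = fmap
    print(f"{tissue}: influx {fmap['F3H:->DHK']:.1f} µmol/kg over the window, "
          f"max node-balance residual {bal.max_relative:.2e}")

print(f"\n{'edge':20s} {'cotyledons':>11s} {'hypocotyls':>11s}   (µmol/kg, days 5-9)")
for r in topo.reactions:
    c, h = maps["cotyledons"][r.id], maps["hypocotyls"][r.id]
    if max(c, h) > 0.5:
        print(f"{r.id:20s} {c:11.2f} {h:11.2f}")

to_dhm = lambda m: m["F3'5'H:DHK->DHM"] + m["F3'5'H:DHQ->DHM"]
print(f"\nflux into dihydromyricetin: cotyledons {to_dhm(maps['cotyledons']):.2f}, "
      f"hypocotyls {to_dhm(maps['hypocotyls']):.2f}")
print("Higher F3H/F3'5'H and lower FLS expression in hypocotyls pull flux toward "
      "dihydromyricetin, myricetin and the anthocyanins — the branch-point mechanism "
      "behind the different pigment accumulation of the two tissues.")
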