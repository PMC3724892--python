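"""Fit the transcript-driven model: cotyledon fit, then hypocotyl transfer.

Model 2 workflow on a noiseless synthetic study: the 22 lumped rate constants
are estimated from the cotyledon end-product curves (transcript profiles
modulating every enzymatic step), then transferred to the hypocotyl where only
the 4 reduction rates are re-estimated.  Runs a reduced optimizer budget to
finish in about a minute.
"""

import numpy as np

import flavopath as fp

topo = fp.build_default_topology()
cfg = fp.GeneratorConfig(noise_cv=0.0, seed=11)
metabolites, transcripts, truth = fp.generate_study(cfg)
profiles = fp.normalize_transcript_profiles(transcripts)

fit = fp.fit_two_stage(
    metabolites, profiles, topo,
    fp.ObjectiveConfig(),
    fp.GASettings(population=40, generations=200),
    fp.LocalSettings(),
    seed=3,
)

print(f"stage 1 (cotyledons):  {fit.cotyledon.n_free} free parameters, "
      f"objective {fit.cotyledon.objective_value:.4f}, "
      f"reported relative SSE {fit.cotyledon.reported_value:.4f}")
print(f"stage 2 (hypocotyls):  {fit.hypocotyl.n_free} free parameters "
      f"(18 frozen at cotyledon values), objective {fit.hypocotyl.objective_value:.4f}, "
      f"reported relative SSE {fit.hypocotyl.reported_value:.4f}")

days = np.array(cfg.metabolite_days)
for tissue, fr in (("cotyledons", fit.cotyledon), ("hypocotyls", fit.hypocotyl)):
    tr_true = truth.trajectories[tissue]
    x0 = np.maximum(tr_true.states[0], 0.0)
    tr_fit = fp.simulate(topo, fr.params, profiles, x0, 5.0, 9.0, tissue=tissue)
    errs = [
        (np.interp(days, tr_fit.t, tr_fit.series(sp))
         - np.interp(days, tr_true.t, tr_true.series(sp)))
        / np.maximum(np.interp(days, tr_true.t, tr_true.series(sp)), 0.2)
        for sp in topo.end_products
    ]
    rms = 100 * float(np.sqrt(np.mean(np.square(errs))))
    print(f"{tissue}: end-product RMS error vs truth at sampling days = {rms:.2f}%")

print("\nThe hypocotyl fit uses only the measured transcript contrast (plus its "
      "own reduction rates) — a low RMS there shows the between-tissue "
      "differences are explained by expression, not by different enzymes.")
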