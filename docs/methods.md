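# Methods

## Model

The pathway is modeled from the synthesis of dihydrokaempferol by F3H down to
the four accumulating end-product classes; the upstream flavanone pool is not a
state — its (assumed constant) level is lumped into the influx rate constant.
The 12 states are the dihydroflavonols (DHK, DHQ, DHM), the flavonol and
anthocyanidin aglycones (KMP, QUE, MYR, DPH), leucodelphinidin (LCD), and the
modified end products (KMPg, QUEg, MYRg, ANT). The default network has 22
reactions: one influx, 17 enzyme-labeled conversions, and a first-order
reduction (degradation/export/further conversion) on each of the four end
products. The F3'5'H edge KMP→MYR is included alongside the double
hydroxylation DHK→DHM; this is the enumeration consistent with 18
influx+conversion edges and the enzyme's involvement in nearly all reactions it
can catalyze. The topology is configurable through a YAML/JSON descriptor
(`flavopath/data/default_topology.yaml` ships the default), and descriptors
are validated: conversion edges must be acyclic, every intermediate must lie on
an influx→end-product path, and reductions must act on exactly the end
products.

Every reaction rate is the low-substrate (initial-slope) limit of
Michaelis–Menten kinetics, `v = c·E(t)·S`, justified because the observable
intermediates never rise above the ~2 µmol kg⁻¹ detection threshold, far below
typical K_M values. `c` deliberately lumps k_cat/K_M with the absolute enzyme
scale — the data cannot separate them — so `E(t)` only needs to be a *relative*
activity proxy. Units: concentrations in µmol kg⁻¹ dry weight, time in days
after sowing (window [5, 9]), conversion/reduction constants in day⁻¹, influx
in µmol kg⁻¹ day⁻¹.

## Enzyme profiles

Transcript measurements (days 5, 6, 7, 9; both tissues) are replicate-averaged,
optionally linearized from a log2 scale (`log2_input`; microarray summaries
such as RMA are log2 — the default assumes linear input, and both readings are
supported because the upstream convention varies), divided by the enzyme's
global maximum over *both* tissues, and interpolated with shape-preserving
PCHIP curves. Sharing one normalization constant per enzyme across tissues is
essential: the absolute scale is unidentifiable (absorbed into `c`), but the
cross-tissue expression ratio is exactly the mechanism the transcript-driven
model uses to explain between-tissue differences. Day 8 (unmeasured for
transcripts) comes from the interpolant, not imputation. Model 1 replaces the
curves with constant unit profiles, letting the fitted constants absorb the
enzyme level.

## Objective and optimization

End-product targets are PCHIP curves through the replicate means. The data
term is the time integral (trapezoid rule, 0.05-day grid) of the squared
relative residual `((x_e − c_e)/max(c_e, δ))²` summed over the four end
products; δ = 0.2 µmol kg⁻¹ (0.1× the detection threshold) keeps the relative
error bounded where targets approach zero (anthocyanins in cotyledons
decline). A `points` mode restricts the comparison to the measured days. The
penalty term is `w · ∫ max(0, x_i − θ) dt` summed over intermediates, with
θ = 2 µmol kg⁻¹ and w = 100 by default: an integral form is grid-stable and
smooth enough for local refinement. Initial conditions: end products start at
their day-5 target value, intermediates at 0 (below detection).

Optimization is differential evolution (population 100, 300 generations by
default, log-uniform initialization because plausible rates span orders of
magnitude) followed by L-BFGS-B refinement kept only when it improves;
parameter bounds are [0, 10³]. All randomness flows from one integer seed and
results are bitwise reproducible. Besides the optimization objective, each fit
reports a "total sum of squares" metric — the unweighted sum of squared
relative residuals at the measured days over the four end products — which is
the quantity summarized over ensembles (mean/best/worst).

Integration inside the optimization loop uses an exponential-midpoint (Magnus)
propagator on the evaluation grid: the system is linear and time-varying, so
freezing coefficients at each interval midpoint and advancing with one matrix
exponential is unconditionally stable, exactly nonnegativity-preserving (the
system matrix is Metzler), and exact for constant coefficients. In the
generator's regime its end-product error is below 1e-4 relative at the 0.05-day
step — and it is several-fold faster than an adaptive stiff solver. Reported
objective values and all published trajectories are recomputed with LSODA at
rtol 1e-8 / atol 1e-10.

## Ensembles and edge usage

`run_ensemble` repeats the full two-stage workflow from consecutive seeds.
An edge counts as "used" when its rate constant exceeds ε = 1e-6 day⁻¹ (a
report-time parameter, never part of fitting); usage percentages are taken
over successful runs, edges are classified solid when used in strictly more
than 2/3 of runs, and failed runs are tallied and excluded. Edge-usage
accounting uses the stage-1 parameter set (conversions are shared between
tissues there). The `parameter_spread` diagnostic quantifies sloppiness: the
maximum relative L∞ distance between parameter vectors whose objectives lie
within a factor (default 1.5) of the ensemble best.

## Accumulated flux

Per-edge accumulated flux is the trapezoid-rule time integral of
`c·E(t)·x_src(t)` along the trajectory grid, in µmol kg⁻¹ over the window —
continuous integration rather than a sum over sampling days, so the number is
grid-convergent and unit-consistent. Flux analyses run on a 0.01-day grid (the
flux-reporting resolution): intermediates start below detection and equilibrate
within ~1/k days of the window start, and the default 0.05-day simulation grid
under-resolves that transient for quadrature purposes. At 0.01 day, per-node
balance residuals (Σ in − Σ out vs net concentration change, scaled by node
turnover) stay below 1e-3 relative across the tested regimes, and halving the
grid moves fluxes by well under 0.5%.

## Synthetic data generator

The generator emulates the study design, not any particular dataset: two
tissues, end products sampled on days 5–9 with 3 replicates, transcripts for 7
enzymes on days 5, 6, 7, 9, and censoring of intermediates below θ (emitted as
`BD` flags). Transcript base curves are exponential decays with a floor
(`v(t) = floor + (1−floor)e^{−r(t−5)}`, r ∈ [0.3, 1.0], floor ∈ [0.15, 0.35]),
matching the observed "almost all genes decrease" trend; the hypocotyl curve is
the cotyledon curve times a per-enzyme ratio, by default DFR/ANS ×4, FLS ×0.5
(the measured contrasts) and F3H/F3'5'H ×2 (elevated, the driver of the larger
hypocotyl influx and of the flux toward dihydromyricetin/myricetin; the factor
2 is a declared choice). Replicate noise is multiplicative lognormal with mean
1 and CV 0.15 — concentrations stay positive and spread scales with level;
the real replicate variance structure is unknown, so the CV is a declared
choice. True rate constants are log-uniform per kind (influx 5–20
µmol kg⁻¹ day⁻¹, conversions 3–30 day⁻¹, reductions 0.05–0.5 day⁻¹), chosen so
end products accumulate at measured-scale magnitudes (tens of µmol kg⁻¹) while
intermediates stay below the detection threshold, as observed; the default
sparsity mask forces FLS:DHM→MYR to zero, the most frequent fitted solution
family. End products start at log-uniform values in [5, 30] µmol kg⁻¹.

What passing recovery tests on this generator shows: the pipeline can estimate
a transcript-driven model whose end-product predictions transfer across
tissues when the truth is itself transcript-driven, with the study's sampling
design and noise level. What it does not show: robustness to model
misspecification (real enzyme kinetics may saturate, enzymes form complexes,
transcript→protein lags exist), to unmodeled measurement error structure, or
to upstream pathway dynamics — all outside this model class.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down configurations chosen as
sensible desk-scale analyses: recovery fits use population 40 / 200
generations (per-stage objective calls ≈ 10⁴), ensembles use 4–5 independent
runs instead of hundreds, and conservation checks use 100 random instances.
Solver defaults: LSODA, rtol 1e-8, atol 1e-10, 0.05-day output grid; the
optimization loop relaxes to the expm propagator as described above. Ties and
degenerate cases: zero-width parameter bounds return the bound directly; an
integration failure inside the objective returns a large finite sentinel
(1e12) so the optimizer can retreat; optimizer results are clipped at 0 so
"unused edge" means an exactly-zero or sub-ε rate.

## Known limitations

* Linear (non-saturating) kinetics only; no enzyme–enzyme complexes; the
  upstream PAL→CHS→CHI segment is out of scope.
* Transcript abundance stands in for enzyme activity with no translation or
  turnover delay.
* The reported-metric definition (relative SSE at measured days) is one
  reasonable reading of a "total sum of squares" fit summary; it is
  configurable and recorded with every result.
* Parameter values themselves are not identifiable (the model is sloppy by
  design of the data); only end-product trajectories and coarse edge-usage
  statements are supported conclusions.
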