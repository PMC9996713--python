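# Methods

## Mechanistic network construction

The switch couples four site-specific recombination events: inversions
`i1: S1 → tS1` and `i2: S1 → tS2`, and excisions `e1: tS1 → S2 + SX` and
`e2: tS2 → S2 + SX`. Events acting on the same FRT attachment-site pair share
binding constants (`i1`/`e2` pair A, `i2`/`e1` pair B). Each event is
expanded into elementary, at-most-bimolecular reactions:

- **Cooperative binding cascade.** Up to two FlpO monomers bind each of the
  two FRT sites: free → F1 → {F1,1 | F2,0} → F3 → F4, where F1,1 has one
  monomer per site and F2,0 two on one site. Positive cooperativity is
  encoded by multipliers 0 < m1, m2 < 1: a monomer binds a *free* site at
  m1·k_on and leaves at k_off, but binds an *occupied* site at k_on and
  leaves at m2·k_off, guaranteeing the affinity ordering k1/k−1 < k2/k−2.
  No combinatorial multiplicity factors (×2 for two equivalent sites) are
  applied — fitted constants absorb them.
- **Holliday-junction ladder.** F4 enters a ladder of five sequential
  junction complexes (entry/exit k3/k−3; internal strand exchanges k4–k7 with
  reverses).
- **Exit.** Inversions leave the ladder through a mirrored product-side
  cascade (HJ5 ⇌ product·F4 at k−3/k3, then stepwise dissociation). Excisions
  resolve HJ5 into two disparate products — the shortened S2 strand and the
  ligated SX loop, each carrying two bound monomers on its composite site —
  at k8, with bimolecular re-association at k−8, followed by independent
  dissociation of both products.
- **Protein/drug module.** Constitutive expression α_a (cytosolic FlpO Fa)
  and α_b (leak-pathway FlpO Fb); 4-OHT source α_d (the dose input);
  degradation β_p (free recombinase pools only — DNA-bound monomers are
  protected) and β_d; activation flux K_a·V̄·[4OHT]·[Fa] and leak flux
  K_b·V̄·[Fb], where V̄ = 0.3 is the nucleus-to-cytoplasm volume correction
  applied to the *production* of nuclear F while the cytosolic pools deplete
  without it. In the reaction network this asymmetry is realised as a
  consumption reaction (rate K) plus a catalytic production reaction (rate
  K·V̄), keeping the right-hand side pure mass action. The dilution sink δ
  acts only on the free excised loop.

This yields 63 DNA-containing species (5 free genetic states, 15 per
inversion, 14 per excision), 4 protein/drug species, 148 reactions and
exactly 27 fitted rate constants. Two structural invariants are enforced by
construction and tested numerically: every reaction conserves the
promoter-strand count, and the blank-sequence count changes only through the
δ sink (d/dt Σ blank = −δ·[SX]).

**Aggregation.** For reporting, species are grouped into a State-1 pool (free
S1, both inversion substrate cascades, and the inversion Holliday ladders —
the group boundary is the HJ5 ⇌ product·F4 transition, fixed by the sign
structure of the boundary fluxes) and a CAR-expressing pool (everything
else). Each S2-strand and each SX-containing species carries weight ½ in the
aggregate so that one excised parental DNA contributes one unit — the
factor-of-half bookkeeping that preserves total concentration. Weights apply
only to aggregate reporting; raw species concentrations are the source of
truth. Excision junction complexes are grouped with the expressing pool,
which is the one grouping choice the flux structure does not fully determine.

## Reduced model

Removing the junction ladders and cooperative-binding detail leaves nine
ODEs: F, 4OHT, Fa, Fb and five DNA states (D_S1, the CAR-expressing
transients D_tS1/D_tS2, the excised loop D_SX, and D_S2), with each
recombination collapsed to one reversible reaction and a single shared
reverse rate k_r, for 12 fitted constants. The implementation reproduces the
published rate equations term for term, including two properties a modeller
might not guess: the forward *and* reverse inversion fluxes consume free F,
and the reverse excision flux k_r·D_SX·D_S2 (no F) feeds *both* transient
states while removing 2·k_r·D_SX·D_S2 from each of D_SX and D_S2. The
genomic total D_S1 + D_tS1 + D_tS2 + D_S2 cancels algebraically and is
conserved along trajectories; tests assert this to 1e-6 relative over ten
days for 100 random parameter draws.

## Observables, dosing and solvers

Percent CAR is the DNA fraction in expressing states ×100 (ON construct:
transients + State 2; the mirrored OFF construct expresses only from
State 1). Both constructs share one dynamical system; only the readout
differs. The response time is the earliest time, by linear interpolation on
the simulation grid, at which the ON series reaches 90% of its maximum over
the horizon (default 10 days), or the OFF series achieves 90% of its total
decrease. Series that never move (e.g. uninduced runs with the leak disabled)
are reported censored at the horizon rather than clipped; a constant positive
series has response time 0 (it already sits at 90% of its own maximum).

The micromolar dose maps linearly onto the model inputs: α_d =
`alpha_d_at_1uM`·dose (default 1 a.u./day at 1 µM, representing continuous
replenishment of inducer-containing media) and optionally an initial inducer
amount OHT(0) = `oht0_at_1uM`·dose (default 0). Both channels are
configurable because the data constrain only their combination.

Integration uses LSODA (via `scipy`), rtol 1e-8/atol 1e-10 for trajectories
and 1e-7/1e-9 inside the inference loops; halving tolerances moves percent-CAR
outputs by far less than 0.1 percentage points. Integration failures raise a
typed error carrying the solver message; the GA converts them into penalty
scores, ABC counts them as assessed rejections.

## Synthetic data

The generator emulates the shape of the experimental readout: four series
(ON/OFF × 0/1 µM) of ten values at days 1…10, normalised to the global
maximum across all series (the device used to restrict attention to cells
carrying both the recombinase and the switch), with additive Gaussian noise
(default sd 3 percentage points) clipped to [0, 100]. It does **not** emulate
flow-cytometry gating, transduction-efficiency subpopulations, cell
proliferation or measurement-day jitter, so passing recovery tests show the
inference machinery works on data of this statistical form, not that it is
robust to those real-data effects. The observation days are a convention —
the real sampling days are not published.

The shipped ground truth is a synthetic parameter set (it is **not** the
study's fitted optimum, which is unavailable); changing it is a breaking
change gated by tests. It was chosen once so that: the induced ON switch
rises to a high (~92%) plateau within the window with a mid-range response
time, the plateau sits below 100% (set by the inversion/reverse balance
k1+k2 vs k_r) and the uninduced series drift visibly (leak α_b, K_b), keeping
most observations in the interior of [0, 100] where the additive-noise model
is faithful; and the qualitative predictions (inverse dose–response,
faster-but-leakier switching under FlpO over-expression) hold. With FlpO
production capped at V̄·(α_a+α_b) ≤ 0.33 a.u./day and every recombination
event consuming one F, the ON response time at 1 µM cannot fall much below
~7 days at this truth — the switch is supply-limited.

The fitted-error expectation under sd-3 noise follows from the distance
definition: d at the truth ≈ 4·E|N(0,3)| = 12·√(2/π) ≈ 9.6, slightly reduced
by boundary clipping and by fit flexibility; the acceptance checks band the
desk-scale GA result at ±30% of that analytic floor.

## Genetic algorithm

The search box is [0,1] per fitted constant. One candidate evaluation solves
the ODEs once per dose and scores both orientations. Operators (the algorithm
family is standard; the specific set is this package's choice and is fixed by
`GAConfig` defaults): tournament selection (size 3), blend/BLX crossover
(α = 0.1), per-gene Gaussian mutation whose scale decays geometrically from
0.35 to 3e-4 across generations, and an exploitation block (30% of each
generation) cloned from the incumbent best and perturbed by isotropic steps,
differential steps (scaled differences of better-half individuals), and
samples from the covariance of the top quartile — the correlated moves follow
the curved, sloppy valleys of this model's error surface. The first half of
the run evolves four independent islands that are then merged, which keeps
several basins of attraction alive; the error surface has genuine local
optima (verified with adaptive single-point search from stalled solutions).
Elitism makes the best-so-far error non-increasing, and runs are
bit-reproducible given the seed. Desk scale (population 200, 150
generations, ~1 minute) recovers noiseless synthetic data to d < 0.5;
full-scale settings (≥1000 × 1000) are a config choice away.

## ABC-SMC

Population 1 is rejection sampling from the uniform prior at ε₁; later
populations resample the previous by importance weights, perturb with a
component-wise Gaussian kernel (scale √2 × weighted sd per parameter — the
classic "twice the empirical variance" proposal — floored at 1e-3; a uniform
kernel is available), reject proposals outside the prior box before
simulating, and accept at the current ε with the same distance d as the GA.
Weights follow the standard SMC update (uniform prior density over the
kernel mixture of the previous population). A population that cannot be
filled within `max_draws` (default 200,000) ends the run with the last
completed population and a stall report — the expected behaviour when a final
threshold is set at a previously attained optimisation error to test whether
better solutions exist. Narrower kernels concentrate faster but under-cover;
the √2 kernel keeps the generating parameters inside the weighted 5–95%
marginal intervals for ≥ 9 of 12 parameters on desk-scale schedules.

## Post-fit scans

All scans are deterministic, one-at-a-time, and censored at the horizon
rather than extrapolated. Sensitivity multiplies each fitted constant by up
to two orders of magnitude either side (default 9 log-spaced factors per
side) and ranks parameters by the largest |log10| change in either switch's
response time. Fold scans scale α_a and α_b jointly (one promoter-strength
knob). The trade-off grid reuses the dose–response code path per row, so its
fold-1 row equals the dose–response curve exactly.

A known limitation of the ranking at the shipped truth: because the response
time is defined relative to each trajectory's own maximum, a parameter change
that merely freezes the switch saturates near the horizon, capping its
measurable sensitivity; in the supply-limited regime of the shipped truth the
expression/leak rates and the forward inversion constants top the ranking,
while the degradation rates β_p, β_d sit mid-table. Rankings measured at
other optima — in particular degradation-limited ones — can differ, and
single-parameter rankings should not be read as statements about the real
circuit's fitted optimum.

## Degenerate inputs and tie-breaks

All-zero datasets cannot be normalised (error). Percent CAR is undefined at
zero genomic total (error). Response-time crossings interpolate linearly and
clip to the bracketing segment; an exactly flat crossing segment resolves to
its right endpoint. ABC weights guard against zero kernel mixture with a
1e-300 floor. Parameter containers reject negative rates and cooperativity
multipliers outside (0,1) at construction.

## Limitations

- Deterministic mass action only; no stochastic simulation, no spatial model
  of loop re-insertion (transitions back from State 2 are correspondingly
  rare here).
- The mechanistic and reduced models are related by structure, not by a
  parameter map: the reduced constants are re-fitted, never derived.
- Practical identifiability of individual constants is limited (the ABC
  marginals are wide and correlated); the fitting error, not the parameter
  point estimate, is the reliable quantity.
- No modelling of proliferation, antigen response or cytotoxicity downstream
  of CAR expression.
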