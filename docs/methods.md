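# Methods

## The model

`glncycle` implements a neuronal–astroglial two-compartment model of ¹³C
label flow through the glutamate–glutamine cycle, as measured by in vivo
¹³C MRS during infusion of a labeled substrate. The observables are labeled
concentrations (μmol/g) of specific carbon positions — principally neuronal
glutamate C4 and astroglial glutamine C4 under [1-¹³C]/[1,6-¹³C₂] glucose —
sampled on a time grid during the infusion.

Labeling kinetics follow standard chemical-kinetic bookkeeping: the rate of
change of each labeled pool is the sum of incoming labeled fluxes minus the
sum of outgoing fluxes, each flux carrying the fractional enrichment (FE,
labeled/total) of its source pool. The fluxes are:

| symbol | meaning | default (μmol/g/min) |
|---|---|---|
| `vcyc` | glutamate–glutamine neurotransmitter cycling | 0.32 |
| `n_vtca` | neuronal TCA cycle flux | 0.60 |
| `a_vtca` | astroglial TCA cycle flux | 0.10 |
| `vana` | astroglial anaplerosis (pyruvate carboxylase) | 0.04 |
| `vgln` | total glutamine synthesis, = vcyc + vana | derived |
| `vefflux` | glutamine loss to blood, = vana at steady state | derived |
| `vdil_gln` | lumped glutamine-level isotopic dilution | 0.14 |
| `vdil_lac` | lumped lactate/pyruvate-level dilution | 0.05 |

Two mass balances are enforced as invariants (`vgln = vcyc + vana`,
`vefflux = vana`) and one inequality (`a_vtca >= vana`: the astroglial TCA
cycle must at least carry the anaplerotic inflow).

Two small pools — astroglial glutamate and neuronal glutamine — are treated
with the standard small-pool approximation: they are assumed to be
instantaneously at isotopic steady state with their through-fluxes, making
them algebraic functions of the dynamic states. The dynamic state is
therefore two-dimensional per labeling strategy (astroglial glutamine and
neuronal glutamate at the labeled position). The full glucose-infusion
variant keeps the astroglial TCA feed, anaplerosis and glutamine efflux; the
simplified variant reduces the astroglial glutamine balance to cycling in,
cycling plus dilution out, which is the form that makes the role of
`vdil_gln` transparent.

Three labeling strategies are supported:

* **GLC_C1** (full or simplified): glucose labeled at C1 (or C1+C6);
  label flows pyruvate → neuronal glutamate C4 → astroglial glutamine C4.
* **GLC_C2_VIA_PC** (simplified only): glucose labeled at C2 (or C2+C5);
  label enters glutamine C3 through the glia-specific anaplerotic pathway
  and is passed to neuronal glutamate C3 by the cycle. A factor 0.5 on the
  neuronal clearance term encodes symmetric label scrambling at fumarate.
* **ACETATE_C2** (simplified only): the glia-preferring substrate acetate
  labels astroglial glutamine C4 first; neuronal glutamate C4 is labeled
  through the cycle.

Because the C2-glucose and acetate routes read the cycling flux off a
*neuronal* balance, the astroglial glutamine dilution flux cancels out of
their steady-state ratios — the package asserts this invariance numerically.

### Steady-state relations

At isotopic steady state the balances give closed forms
(`glncycle.steady_state`):

* glucose C4: FE(Gln C4) = FE(Glu C4) · vcyc/(vcyc + vdil_gln). With the
  defaults this puts glutamine C4 ≈ 30% below glutamate C4; the simulated
  160-min endpoint shows ≈ 26% dilution because the curves have not fully
  plateaued.
* glucose C2→C3: vcyc/n_vtca = 0.5·FE(Glu C3)/(FE(Gln C3) − FE(Glu C3)).
  A small correction term of order FE(Glu C4) is ignored, a known
  approximation of this reduced form.
* acetate C4: vcyc/n_vtca = FE(Glu C4)/(FE(Gln C4) − FE(Glu C4)).
* the C3 dilution balance additionally yields vdil_gln/vcyc given an
  externally supplied vana/vcyc.

Enrichment configurations that would imply negative flux ratios (e.g.
glutamine below glutamate on the acetate route) raise
`InfeasibleEnrichmentError` rather than returning unphysical values.

### Precursor input and lactate dilution

The arterial input is configurable (`step`, `exp_rise`, or a
piecewise-linear table of knots); glucose transport kinetics are out of
scope. The lactate-level dilution flux enters multiplicatively:
FE_lac(t) = FE_input(t) · k/(k + vdil_lac) with the label-feeding rate k
defaulting to `n_vtca`. This reproduces the required steady-state dilution
without an explicit lactate state equation. The acetate route feeds
astroglial acetyl-CoA directly and bypasses this factor.

The acetate strategy supports two drive modes: mode A (default for the
right-hand-side API) forces the astroglial glutamine C4 enrichment with a
user-supplied curve; mode B gives glutamine its own balance with
`a_vtca`·FE(acetyl) as labeled source and a_vtca + vcyc + vdil_gln total
outflow, which keeps enrichments in [0, 1].

## Numerics

For constant (step) inputs the labeling system is linear time-invariant in
the two dynamic states, and the simulator uses an exact eigendecomposition
propagator — machine-precision accurate and cheap enough for the ~10⁴ cost
evaluations a fit needs. For time-varying inputs it integrates with LSODA at
rtol 1e-8 / atol 1e-10 (the two paths agree to < 1e-6 μmol/g on the
benchmark protocol, which is tested). Initial labeled concentrations default
to zero, i.e. the 1.1% natural-abundance background is assumed subtracted.

## Synthetic data

`synthetic_data` emulates the benchmark protocol: 160-min infusion, 32
samples per curve on two curves (Glu C4, Gln C4), additive i.i.d. Gaussian
noise with σ = 0.1 μmol/g applied to the concentration curves (matching σ's
units), step input with plateau FE 0.35. One master seed spawns
per-realization child seeds through `numpy.random.SeedSequence.spawn`;
child i drives both the noise draw and the fit seed of realization i, so
ensembles are bit-reproducible and order-independent.

What the generator does *not* emulate: the time-varying arterial input of a
real infusion, glucose transport, physiological drift, spectral-fitting
error correlations, or natural-abundance baselines. Passing tests therefore
demonstrate correctness of the estimation machinery under the stated noise
model, not robustness to every feature of real MRS data.

## Fitting

`flux_fitting.fit_fluxes` minimizes SS = Σ(obs − model)² over the free
fluxes, default (vcyc, n_vtca, a_vtca, vana), with χ² = SS/σ². σ is always
supplied (by the generator or the user), never estimated jointly. The
search is scipy's `dual_annealing` (generalized simulated annealing) over
box bounds, followed by a bounded trust-region least-squares polish from
the annealing optimum. Defaults: maxiter 120, one restart — enough that a
stronger schedule changes the minimized χ² by < 1e-4 on benchmark
realizations, while one fit costs ~0.2 s on a single core.

Constraints:

* box bounds per flux; the benchmark set fixes vdil_gln = 0.14,
  vdil_lac = 0.05 and bounds a_vtca ≤ 0.1;
* `a_vtca >= vana` via a smooth quadratic penalty during the search, with a
  final projection (the model equations themselves are insensitive to the
  violation, so this only shapes the search);
* the optional named equality `vefflux = 0.2·vgln` is enforced by
  substitution (it pins vana = 0.25·vcyc and removes vana from the free
  set), never by penalty. It is off by default.

σ_min = √(SS/N) estimates the per-point noise after fitting; at the global
minimum its expectation is σ·√((N−n)/N), slightly below the injected σ.

## Monte Carlo diagnostics

`monte_carlo.run_monte_carlo` repeats simulate → add noise → fit over
independent realizations and summarizes χ², σ_min and per-flux spread, plus
a 20-bin histogram of fitted vcyc. For a well-specified model fitted to
global minima the minimized χ² has mean N − n and sd √(2(N − n)) — here
(60, 11.0) for 64 points and 4 free fluxes — so ensemble deviations from
these values flag local-minimum trapping. With the defaults the ensemble
mean lands near 60–61: slightly above N − n because the truth sits exactly
on the a_vtca ≤ 0.1 constraint and the weakly identified astroglial
parameters sometimes pin at bounds, reducing the effective number of fitted
parameters. σ_min averages ≈ 0.098 μmol/g with ≈ 9% relative spread.

The dilution-misspecification experiment refits the same noisy datasets
with `vdil_gln` fixed to zero and the total glutamine pool rescaled by the
steady-state ratio vcyc/(vcyc + vdil_gln) (3.7 → 2.57 μmol/g), so the
misspecified model still matches the labeled-glutamine level. This
reproduces, in direction, the large loss of vcyc precision that motivates
including the glutamine dilution flux: on matched 40-realization ensembles
the vcyc relative sd grows by an order of magnitude (≈ 20% → ≈ 230% at
σ = 0.1). The magnitude depends on the flux/pool configuration, so only the
direction is asserted.

Problem sizes used by the shipped analyses: 100 realizations for the χ²
and σ_min diagnostics, 40 + 40 matched realizations for the
misspecification contrast — chosen so the sampling error of each ensemble
statistic is small against the asserted effect.

## Known limitations and open choices

* The reference pool set (aGlu 0.8, aGln 3.7 μmol/g) sits marginally above
  the 0.2 aGlu/aGln caution threshold of the small-pool validator, so
  constructing it emits a `SmallPoolWarning`; the approximation error is
  accepted as part of the reference configuration.
* The glutamine efflux exchange term dropped from the simplified astroglial
  balance assumes FE(aGlu) ≈ FE(aGln); in regimes where they diverge the
  full variant should be used.
* Ammonia fixation and glucose utilization rates appear in the wider
  physiology but in none of the implemented balances; they are deliberately
  not represented.
* ¹⁵N kinetics, the GABA shunt, ketone-body/lactate substrate strategies,
  and isotopomer (multiplet) bookkeeping are out of scope.
* Eq-level identifiability: with only the two C4 curves, a_vtca and vana
  are weakly identified; their ensemble spreads are wide by nature and the
  package reports them as such rather than regularizing them away.
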