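# glncycle

Two-compartment modeling of the glutamate–glutamine neurotransmitter cycle
from in vivo ¹³C MRS turnover curves.

Glutamate released by neurons is taken up by astroglia, converted to
glutamine, and shuttled back — the glutamate–glutamine cycle, whose flux
V_cyc couples neurotransmission to brain energy metabolism. V_cyc can be
measured by infusing a ¹³C-labeled substrate ([1-¹³C]/[1,6-¹³C₂] glucose,
[2-¹³C]/[2,5-¹³C₂] glucose, or [2-¹³C] acetate) and fitting the time courses
of labeled glutamate and glutamine to a neuronal–astroglial two-compartment
kinetic model. A subtle but decisive ingredient is the glutamine
isotopic-dilution flux V_dil(Gln) — exchange of astroglial glutamine with
unlabeled carbon (blood glutamine, fatty-acid and amino-acid oxidation) —
which holds the glutamine C4 enrichment below glutamate C4:

    FE(Gln C4) / FE(Glu C4) = V_cyc / (V_cyc + V_dil(Gln))   (steady state)

Omitting V_dil(Gln) makes the glutamine curve insensitive to V_cyc at
steady state and destroys the precision of the estimate; the package lets
you demonstrate and quantify this.

`glncycle` is aimed at MRS spectroscopists and metabolic modelers. It
provides:

* **`isotope_model`** — the model equations (full and simplified variants,
  three labeling strategies) over labeled concentrations, with the
  small-pool approximation for astroglial glutamate and neuronal glutamine;
* **`steady_state`** — closed-form flux-ratio calculators (e.g.
  V_cyc/ⁿV_TCA from steady-state C3 or acetate-C4 enrichments);
* **`synthetic_data`** — a turnover-curve generator for the standard
  160-min / 32-point / σ = 0.1 μmol/g benchmark protocol;
* **`flux_fitting`** — global least-squares flux estimation by simulated
  annealing with box/equality constraints, χ² and σ_min diagnostics;
* **`monte_carlo`** — repeat-fit ensembles: χ² goodness-of-fit versus the
  theoretical N−n statistics, V_cyc probability density, and
  misspecification experiments;
* **`cli_io`** — a `glncycle` command line (`simulate | fit | mc | ratios`)
  with YAML/JSON configs and full provenance sidecars.

## Worked example

```python
from glncycle import (
    FitConfig, LabelingStrategy, add_noise, default_fluxes, default_pools,
    default_protocol, fit_fluxes, run_monte_carlo, simulate_turnover,
)

strategy = LabelingStrategy()            # [1-13C] glucose, full model
fluxes, pools, protocol = default_fluxes(), default_pools(), default_protocol()

curves = simulate_turnover(strategy, fluxes, pools, protocol)
noisy = add_noise(curves, sigma=0.1, seed=1)
result = fit_fluxes(noisy, FitConfig(seed=1), strategy, pools, protocol)
print(f"chi2 = {result.chi2:.1f}  sigma_min = {result.sigma_min:.4f}")
print(f"vcyc = {result.fitted.vcyc:.3f}  n_vtca = {result.fitted.n_vtca:.3f}")

mc = run_monte_carlo(strategy, fluxes, pools, protocol, FitConfig(), 100, 42)
print(f"chi2 mean = {mc.chi2_mean:.1f} sd = {mc.chi2_sd:.1f}; "
      f"sigma_min mean = {mc.sigma_min_mean:.4f} sd = {mc.sigma_min_sd:.4f}")
```

prints

```
chi2 = 45.9  sigma_min = 0.0847
vcyc = 0.327  n_vtca = 0.616
chi2 mean = 63.1 sd = 11.2; sigma_min mean = 0.0989 sd = 0.0088
```

The single noisy fit recovers the generating cycling flux (0.32 μmol/g/min)
with χ² well inside the χ²₆₀ range; over 100 noise realizations the
minimized χ² tracks the theoretical mean N − n = 64 − 4 = 60 and sd
√(2·60) ≈ 11.0, the signature that the annealing search is finding global
minima, and the post-fit noise estimate σ_min sits just below the injected
σ = 0.1 μmol/g. On the noiseless simulation the 160-min endpoint glutamine
C4 enrichment sits 25.7% below glutamate C4 — the experimentally observed
glutamine dilution that V_dil(Gln) = 0.14 μmol/g/min encodes.

The same pipeline runs from the shell:

```bash
glncycle simulate --config config.yaml --out curves.csv
glncycle fit --curves curves.csv --config config.yaml --out fit.json
glncycle mc --config config.yaml --out mc.json
glncycle ratios --acetate --fe-nglu4 0.05 --fe-agln4 0.15
```

Each command writes a `.provenance.json` sidecar with the fully resolved
configuration and seeds, sufficient to reproduce the output bit-exactly.

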