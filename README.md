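# exokin

Pre-steady-state kinetics of processive 3′→5′ exonucleolytic degradation of
structured RNA, modelled after the single-nucleotide-resolution analysis of
human Dis3L2 acting on uridylated hairpin substrates.

A 34-nt hairpin with a single-stranded 3′ tail is shortened one nucleotide
at a time down to a 5-nt end product. Each intermediate length *n* appears
as one band on a denaturing sequencing gel, and the per-lane normalized
band fractions over an enzyme titration (single-turnover regime: enzyme at
5–1,000 nM in far excess over 1 nM labelled RNA) and pulse–chase
experiments (cold scavenger RNA added mid-reaction so released RNA can
never rebind) carry enough information to resolve, for every step of the
ladder:

* **k_on, k_off** — productive association/dissociation rate constants
  (nM⁻¹ s⁻¹, s⁻¹),
* **k_f** — the committed forward step (the slower of catalysis and
  translocation, s⁻¹),
* **processivity** P(n) = k_f / (k_f + k_off), the probability of cleaving
  the next nucleotide rather than dissociating,
* **K½** = k_off / k_on, the functional half-saturation constant,
* a **nonproductive binding mode** (bound but unable to cleave) with its
  own K½.

The package provides, as separately usable layers:

| module | contents |
| --- | --- |
| `exokin.kinetic_scheme` | ladder + rate-set containers, P and K½ from rates, the pseudo-first-order generator matrix |
| `exokin.forward_sim` | deterministic (matrix-exponential) and stochastic (event-driven) simulation of titration and pulse–chase protocols, gel-lane observables |
| `exokin.estimators` | exponential k_obs, sequential-cascade (Bateman) rate fits, the binding isotherm k_obs = k_obs_max·E/(K½+E), and the pulse–chase release-distribution processivity method |
| `exokin.global_fit` | constraint-linked global fitting of all experiments at once, χ²/R² accounting, profile-likelihood bounds, error propagation for P and K½ |
| `exokin.synthetic_data` | noise-model'd synthetic gel data under the published designs; documented anchor rate profiles |
| `exokin.cli_io` / `exokin.cli` | band-table CSV and scheme YAML formats, config-driven pipeline, `exokin` command-line tool |

## Worked example

Generate a synthetic wild-type-like titration suite (eight enzyme
concentrations, nine time points from 7 s to 15 min, five replicates, 2%
band noise), take a first pass with the classical estimators, then fit the
full productive + nonproductive model globally from a neutral start:

```python
from exokin import (wt_like_scheme, default_titration_protocol, NoiseModel,
                    ReplicateDesign, generate_titration, Dataset,
                    ProfileParameterization, global_fit, LadderRateProfile)
from exokin.estimators import kobs_curve_from_titration, fit_isotherm

scheme = wt_like_scheme()                      # anchors: P1=0.23, K1/2=508.3 nM, K1/2(np)=4.2 nM
protocol = default_titration_protocol()
table = generate_titration(scheme, protocol, NoiseModel(band_cv=0.02),
                           ReplicateDesign(5), seed=42)

curve = kobs_curve_from_titration(table, species_length=34)
iso = fit_isotherm(curve)
print(f"isotherm: kobs_max = {iso.kobs_max:.2e} 1/s, K1/2_eff = {iso.khalf:.1f} nM")

start = LadderRateProfile(first_kf=0.05, first_p=0.4, first_khalf=150.0,
                          np_khalf=15.0, np_koff=2e-3, peak_kf=0.5, second_koff=0.08)
fit = global_fit([Dataset(table, protocol)], scheme,
                 parameterization=ProfileParameterization(start), seed=7)
print(f"chi2 = {fit.chi2:.4f}, R2 = {fit.r2:.4f}, converged = {fit.converged}")
for name in ("first_p", "first_khalf", "np_khalf", "first_kf"):
    print(f"  {name:12s} = {fit.params[name]:.4g} +/- {fit.stderr[name]:.2g}")
```

prints

```
isotherm: kobs_max = 1.01e-01 1/s, K1/2_eff = 419.6 nM
chi2 = 0.0136, R2 = 0.9999, converged = True
  first_p      = 0.2288 +/- 0.00079
  first_khalf  = 505.3 +/- 1.1
  np_khalf     = 4.155 +/- 0.0089
  first_kf     = 0.09943 +/- 0.0002
```

The isotherm pass sees only the fast (pre-sequestration) decay phase, so
its K½ is an effective first guess; the global fit then resolves the
first-step processivity (0.229 vs the generating 0.23), the productive K½
(505 vs 508.3 nM) and the nonproductive K½ (4.16 vs 4.2 nM) from the same
data, with standard errors from the Jacobian at the optimum.

The same run is available from the shell:

```bash
exokin synth --profile wt --kind titration --band-cv 0.02 --seed 42 --out titration.csv
exokin fit-isotherm --table titration.csv --species-length 34
exokin pipeline --config demo.yaml --out demo_out/
```

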