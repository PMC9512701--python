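# lagoon

Modelling and analysis toolkit for single-molecule experiments that control
NTP-driven reactions by **local generation of NTPs**: a caged (photolabile)
NTP analog is photolysed by near-UV light inside the observed field of view
while a scavenger enzyme (hexokinase, for ATP) consumes the free nucleotide.
Free NTP is then present only where and when the uncaging laser is on, which
(i) lets one irreversible reaction be observed field-of-view after
field-of-view on the same slide — orders of magnitude more molecules per
experiment — and (ii) allows NTP to be delivered in pulses shorter than a
single hydrolysis cycle, isolating elementary mechanical steps
(*single-turnover* observations).

The package is written for single-molecule biophysicists who design or
analyze such experiments (smFRET or acoustic force spectroscopy). It covers:

| module | contents |
|---|---|
| `lagoon.uncaging` | reaction–diffusion model of photolysis + scavenging; free-NTP fields in 0-D/1-D/2-D |
| `lagoon.kinetics` | stochastic enzyme turnover driven by the NTP supply: helicase unwinding, pulsed remodeler stepping |
| `lagoon.traces` | synthetic three-channel smFRET traces and AFS bead traces with full ground-truth annotations |
| `lagoon.analysis` | channel corrections & FRET, acceptor-ratio classification, change-point step detection with counter-fit acceptance, two-Gaussian step-size mixtures, unwinding rates & titrations, AFS elongation rates |
| `lagoon.design` | power-density, throughput and photobleaching calculators |
| `lagoon.pipeline` / `lagoon` CLI | reproducible end-to-end runs |

## The models in brief

**Uncaging.** Photolysis is first order in the caged compound with rate
constant

    k_unc = ln(10)·ε·Φ·I·λ / (N_A·h·c)

(ε molar absorptivity, Φ quantum yield, I power density, λ wavelength) —
linear in laser intensity, which is what makes the effective NTP
concentration tunable by laser power. The free nucleotide obeys

    ∂c/∂t = D∇²c + k_unc(x,t)·[caged] − Vmax·c/(Km + c)

with hexokinase consumption (1 U ml⁻¹ ≙ 16.7 µM s⁻¹ at saturation,
Km ≈ 120 µM) or its linearization k_scav·c. Outside a wide illuminated spot
the steady-state profile decays exponentially with length
L = sqrt(D·Km/(activity·Vmax_per_unit)); with D = 300 µm² s⁻¹ and
10 U ml⁻¹ scavenger, L ≈ 14.7 µm, i.e. a two-fold decay ≈ 10 µm from the
spot edge — free NTP stays confined to the chosen field of view. Because ε
and Φ of the cage are not known precisely for the actual optical geometry,
`calibrate_photolysis` anchors k_unc to a measured effective concentration
(default: 40 µM at 5 W cm⁻², 2 mM caged ATP, 10 U ml⁻¹ hexokinase).

**Turnover.** Enzymes see the simulated free-NTP series. A helicase unwinds
with Michaelis–Menten speed v = v_max·c/(K_m+c); FRET decays from E_high to
E_low over the unwinding interval and the donor strand is lost at
completion. A nucleosome-remodeling motor binds NTP as an inhomogeneous
Poisson process with rate k_on·c(t), completes each engaged nucleotide after
a 0.2–0.6-s hydrolysis time, and advances its FRET state by one elementary
step per completed turnover; under 8-s pulse trains this reproduces the
single-turnover staircases, and at long (180 ms) pulses the double
engagements that appear as compound (double-size) steps.

**Analysis.** Corrected FRET is
E = (I_DA − β·I_DD − α·I_AA)/((I_DA − β·I_DD − α·I_AA) + γ·I_DD). Steps are
found by iterative greedy χ² change-point placement; each k-step fit is
scored against a *counter-fit* with the same number of change points placed
at plateau midpoints, and the fit with the best score above an acceptance
threshold is kept (flat traces yield zero steps). First-step sizes are
decomposed by a maximum-likelihood two-Gaussian mixture in which the
compound component's centre and width can be frozen to a reference
condition's fit.

## Worked example

Simulate the pulsed single-turnover experiment at three pulse durations and
decompose the first-step FRET changes:

```python
from lagoon.pipeline import (SingleTurnoverCondition, run_single_turnover,
                             compound_fractions)

cond = SingleTurnoverCondition()          # 10 mM caged ATP, 100 W/cm², 8-s period
res = run_single_turnover(cond, n_traces=200, seed=1)
print(compound_fractions(res, seed=1).round(4).to_string(index=False))
```

```
 duration_s   n  compound_fraction  elementary_mean  compound_mean  compound_sigma  component2_fixed
       0.18 169             0.5753           0.0993         0.1916           0.057             False
       0.09 152             0.1165           0.0983         0.1916           0.057              True
       0.03 154             0.0476           0.1024         0.1916           0.057              True
```

Each row is one pulse duration: `n` first steps were detected,
`compound_fraction` is the weight of the larger-mean Gaussian — the fraction
of first steps that contain two (or more) unresolved turnovers. At 180-ms
pulses more than half of the first steps are compound (the pulse outlasts
the enzyme's engagement dead time, so a second nucleotide is often loaded);
at 90 ms and 30 ms the elementary ~0.1-FRET step dominates and the compound
weight stays near the 5–12% floor — the single-turnover regime. The compound
component (mean 0.19, σ 0.06) is fitted freely on the 180-ms histogram and
frozen for the shorter pulses.

Design calculators for the same experiment:

```bash
$ lagoon design power-density --power-mw 1
9.259 W/cm^2
$ lagoon design throughput --n-fov 1000 --time-per-fov 60
1000 FOVs x 60 s (+0 s overhead) = 16.67 h, 1000000 molecules
$ lagoon design bleach --exposure 60
Cy3: 0.7937
Cy5: 0.6300
```

An end-to-end reproducible run (`lagoon run --config cfg.yaml --seed 1
--out run/`) writes the free-ATP field, ground-truth event tables, synthetic
traces, first-step samples, mixture fits and a provenance-stamped
`report.json`; identical config + seed give byte-identical outputs.

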