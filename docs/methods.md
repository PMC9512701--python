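# Methods

This note documents the models behind `lagoon`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## 1. Photolysis and the free-NTP field

Photolysis of the caged nucleotide is first order with rate constant
k_unc = ln(10)·ε·Φ·I·λ/(N_A·h·c): the decadic absorption cross-section
ln(10)·ε·1000/N_A (cm² molecule⁻¹) times the photon flux I·λ/(h·c) times the
quantum yield. Units are µm, s, µM and W cm⁻² throughout.

The free nucleotide obeys, on a 0-D (well-mixed), 1-D or 2-D domain,

    ∂c/∂t = D ∇²c + k_unc(x,t)·[caged] − v_scav(c),

with v_scav either full Michaelis–Menten
(activity·vmax_per_unit·c/(km + c)) or its linearization k_scav·c,
k_scav = activity·vmax_per_unit/km. Key defaults, all configurable:

| parameter | default | why |
|---|---|---|
| ε (M⁻¹cm⁻¹) | 4000 | placeholder magnitude for an ortho-nitrobenzyl cage near 360 nm; a calibration parameter, see below |
| Φ | 0.07 | same |
| vmax_per_unit | 16.7 µM s⁻¹ per U ml⁻¹ | manufacturer unit convention, 1 U = 1 µmol min⁻¹ at saturation; glucose assumed saturating |
| km (hexokinase·ATP) | 120 µM | typical yeast hexokinase Km for ATP |
| D (ATP) | 300 µm² s⁻¹ | free-nucleotide diffusivity in buffer |
| caged reservoir | constant | mM caged stock vs µM-scale release; a closed (depleting) 0-D mode exists for conservation checks |

**ε and Φ are calibration parameters.** The model's absolute free-NTP scale
additionally depends on optical geometry (evanescent illumination, inner
filtering, local depletion) that the model deliberately omits, so
`calibrate_photolysis` rescales the quantum yield so that the linearized
0-D steady state k_unc·[caged]/k_scav matches a *measured* effective
concentration. The packaged anchor is 40 µM at 5 W cm⁻² with 2 mM caged ATP
and 10 U ml⁻¹ hexokinase. After calibration the model's useful outputs are
ratios and shapes (linearity in power, pulse responses, spatial profiles),
not ab-initio concentrations.

**Numerics.** Method of lines; second-order central differences; the
illumination protocol is integrated piecewise per on/off segment (LSODA in
0-D, BDF with the analytic sparse Jacobian in 1-D/2-D) so pulse edges are
never smeared by the step controller. The outer boundary is an absorbing
far-field sink by default (reflecting available); the grid validator
requires spacing ≤ L/10 and ≥ 5·L of domain beyond the spot edge, where
L = sqrt(D/k_scav) is the analytic decay length of the linearized
steady-state tail. In closed 0-D mode caged + free + consumed is checked to
1e-6 relative; violation raises a numerical error suggesting a smaller step.
Negative undershoot beyond solver tolerance is an error, not clipped.

## 2. Enzyme turnover

**Helicase.** Each molecule waits an exponential time with hazard
onset_rate·c/(km+c), then unwinds with fractional speed
s_i·vmax·c/(km+c), where s_i is a unit-mean gamma multiplier with CV
`speed_cv` (default 0.3) expressing molecule-to-molecule heterogeneity.
FRET decays linearly from E_high (0.9) to E_low (0.1) over the unwinding
interval; completion dissociates the donor-labelled strand. The linear decay
is a declared stand-in: the true FRET trajectory during unwinding is not
resolved at these frame rates, and no conclusion in the package depends on
its shape. Defaults vmax = 2.5 s⁻¹, km = 100 µM give ≈ 0.26 s⁻¹ at an
effective 12.5 µM ATP, the magnitude typical of the hexameric-helicase
assay this emulates.

**Remodeler (pulsed single-turnover regime).** Productive NTP binding is an
inhomogeneous Poisson process with rate k_on·c(t). Each engaged nucleotide
completes after a hydrolysis time drawn uniform on 0.2–0.6 s (the reported
range of average hydrolysis times for Chd1; exponential and fixed
alternatives are selectable) and advances the FRET state by one elementary
step (default ΔE = 0.1 from E₀ = 0.3, capped at `max_steps` = 6 — the
reporter saturates). Two further mechanistic choices are genuinely open and
were decided as follows:

* **Engagement gating** (`gating`). A nucleotide arriving during an ongoing
  cycle either queues (its hydrolysis starts at the previous completion;
  default) or is rejected. Strict rejection cannot produce the compound
  (double-size) first steps that long pulses are known to generate: under
  rejection a second cycle can only start from the decaying residual NTP, so
  consecutive completions are separated by a waiting time plus a fresh
  0.2–0.6-s hydrolysis time and are almost always resolved as two steps.
  Queueing lets a second nucleotide engage *during* a long pulse, producing
  completions one hydrolysis time apart that the step detector merges. Both
  modes are implemented; analyses report which routes contributed (the event
  table carries per-event binding and completion times).

* **Engagement dead time** (`dead_time`, default 0.1 s). After a productive
  binding the catalytic pocket is committed and a further nucleotide cannot
  be accepted for one commitment interval. This is what makes the compound
  fraction strongly super-linear in pulse duration: a 90-ms pulse is over
  before the pocket reopens (residual NTP is already mostly cleared — see
  clearance below), whereas a 180-ms pulse is still on, at full
  concentration, when it reopens. Without a dead time the per-pulse turnover
  count is Poisson and doubling the pulse can at most double the
  multi-turnover odds — demonstrably too weak to reproduce the observed
  contrast between 90-ms and 180-ms conditions.

Per-molecule elementary step size carries a CV of 0.15 (normal multiplier,
truncated at 0.2): labeling geometry and nucleosome register vary between
molecules, and measured first-step histograms show correspondingly broad
elementary peaks. Completions falling in the same camera frame are merged
into one compound step in the emitted ground-truth path; most compound
steps, however, arise at the analysis stage when the step detector cannot
resolve two completions separated by less than its minimum plateau.

**The packaged single-turnover condition** (`SingleTurnoverCondition`):
10 mM caged ATP, 100 W cm⁻² pulses of 30/90/180 ms every 8 s, one dark 8-s
baseline period before the first pulse (acquisition starts before
uncaging — also necessary for the first step to have a measurable
pre-plateau), 12 pulses, 10-Hz camera. Post-pulse free-ATP decay uses the
linearized scavenging model with an **effective clearance of 40 s⁻¹**
(25-ms lifetime). This is deliberately not the bulk 1 U ml⁻¹ hexokinase rate
(0.14 s⁻¹): the single-turnover regime is only possible at all if free ATP
is gone well before a 0.2–0.6-s hydrolysis cycle completes — otherwise
residual nucleotide would drive multiple turnovers per period regardless of
pulse length — so the effective in-spot clearance (enzymatic consumption
plus diffusive escape from the thin illuminated surface region) must be an
order of magnitude faster than the hydrolysis floor. 40 s⁻¹ encodes that
regime; it is an effective constant of the packaged condition, not a
measured rate.

**Calibration of k_on.** k_on is not identifiable from first principles
(it multiplies the calibrated concentration scale), so
`calibrate_binding_rate` sets it on the reference 90-ms condition: in queue
mode the expected number of engaged nucleotides per pulse cycle equals
k_on × (free-NTP exposure per cycle), which is solved directly from the
simulated pulse response. The packaged condition targets 2.0 engaged
nucleotides per cycle; with the engagement dead time this realizes roughly
one completed step per pulse — a processive staircase, predominantly single
steps — which is the defining description of the 90-ms working point.

## 3. Synthetic traces

Per frame, before noise: I_DD = γ_D(1−E)·I_tot, I_DA = E·I_tot + β·I_DD +
α·I_AA, I_AA = direct-excitation acceptor signal (recorded every
`aa_interleave`-th frame, default 1:10). Defaults β = 0.10, α = 0.05,
γ_D = 1, σ = 0.02–0.03·I_tot per channel. Bleach times are exponential with
half-lives 180 s (donor) and 90 s (acceptor); donor bleach or donor-strand
loss zeroes I_DD/I_DA while I_AA persists; acceptor bleach zeroes transfer
and I_AA. Every trace carries its complete ground truth (step times/sizes,
bleach and loss times), so detector recall/precision can be scored exactly.

What the generator does **not** emulate: camera offset/gain and EM-register
statistics (noise is plain Gaussian), triplet blinking (suppressed by Trolox
in the emulated assays), z-drift, spot-detection artefacts, baseline drift,
and any correlation between channels beyond the forward model. Passing
tests therefore demonstrate correctness of the *analysis logic* under
realistic signal levels, not robustness to every camera pathology.

AFS traces: position = −bp(t)·rise_per_bp + drift·t + Gaussian noise
(default rise 0.3 nm/bp, σ 5 nm), with elongation nonzero only inside
uncaging windows.

## 4. Analysis pipeline

**Corrections.** acceptor' = I_DA − β·I_DD − α·I_AA (per-trace median I_AA,
acceptor assumed constant between bleaching events), donor' = γ·I_DD with
γ = 1/γ_D, E = acceptor'/(acceptor'+donor') clamped to [−0.1, 1.1] with
out-of-range frames flagged. Frames whose total corrected intensity falls
below 10% of the trace's bright level (98th percentile) are masked — they
carry no FRET information (donor bleached or strand lost) — rather than
errored.

**Step detection.** Greedy χ²-optimal change-point insertion (minimum
plateau 5 frames, earliest index on ties), recording the S-curve
S(k) = χ²_counter(k)/χ²_fit(k), where the counter-fit has the same number of
change points placed at the plateau midpoints of the k-step fit. The fit
maximizing S is accepted if S exceeds the acceptance threshold (default
2.0, set so that fewer than 5% of step-free noisy traces yield a spurious
step; measured false-positive rate ≈ 0 at that setting, recall/precision
≥ 0.9 at step/σ = 3 with ≥ 20-frame dwells). Two numerical details: the
argmax of the raw S-curve systematically overshoots by a step or two
(noise-chasing splits shave χ²_fit without helping the counter-fit), so the
smallest k within 2% of the maximum is used; and expansion stops when the
residual is numerically exhausted, making the detector exact and idempotent
on noiseless staircases.

**First steps and the mixture.** Traces are analyzed to the first masked
frame; steps after the first FRET decrease are discarded (the assay cannot
distinguish reporter reversal from non-processive events) and the first
positive step per trace enters the sample. The two-Gaussian decomposition is
maximum-likelihood EM on the raw sizes (10 restarts; a histogram is never
binned), with the option to freeze the compound component's centre and width
to a reference condition's free fit — the longest-pulse condition, where the
compound population is large enough to define them. A component may collapse
to zero weight (no compound steps present); that is a valid fit, not a
failure. The compound fraction is the weight of the larger-mean component.

**Rates.** The per-molecule unwinding rate is
(1 − δ/(E_high−E_low))/transit, where transit runs from sustained departure
below E_high − δ (δ = 0.1, 3 consecutive frames) to donor-strand loss; the
prefactor corrects for the fraction of the interval consumed before the
threshold crossing, so the estimator is an unbiased reciprocal of the full
unwinding interval. Aggregation is the unweighted mean ± s.e.m. over
molecules. Titration curves are fitted to v = Vmax·c/(Km+c) by nonlinear
least squares, and the power→effective-[ATP] map inverts the regular-ATP
titration by monotone PCHIP interpolation, refusing extrapolation beyond
the measured rate range.

**Acceptor-ratio classification.** Per molecule, mean(I_DA)/mean(I_AA) over
the first/last 20 frames (window length an open choice; results are
insensitive for plateaus ≥ window). Intact high-FRET molecules keep a large
ratio; donor-strand loss drops it to the direct-excitation floor α.
Classification threshold: Otsu on the pooled log-ratios; molecules without
detectable direct acceptor signal are excluded.

**AFS.** Exactly the published filter cascade: 10-s median filter then
Savitzky–Golay (3-s window, order 3); elongation rates are slopes of the
smoothed position over consecutive 6.25-s windows within ±30 s of each
uncaging transition, reported as separate on/off samples.

## 5. Problem sizes and reproducibility

The packaged analyses run 500 molecules per pulse-duration condition
(12 pulses, 10-Hz frames), 1-D reaction–diffusion grids of ~400 nodes, and
titrations of 8 concentrations × 200 molecules; these sizes put Monte-Carlo
uncertainty on the reported fractions near one percentage point, and all of
them complete in seconds on one CPU. Every stochastic stage derives its
generator from one `numpy.random.SeedSequence`, so identical configuration
and seed reproduce identical outputs byte for byte; the end-to-end runner
stamps a SHA-256 hash of the configuration into every report.

## 6. Known limitations

* The uncaging model is a lateral reaction–diffusion picture with an
  effective clearance; it does not model the evanescent-field geometry, the
  z-extent of the flow cell, flow, or photon-level stochastic photolysis.
  Absolute concentrations are meaningful only after calibration.
* The engagement dead time and the queue/reject dichotomy are effective
  kinetic devices, not structural statements about any particular motor;
  they are exposed as parameters precisely because the underlying mechanism
  of compound steps is not settled.
* The step detector is greedy; pathological staircases (steps of strongly
  alternating sign at dwell times near the minimum plateau) can be
  mis-segmented even when an exhaustive search would succeed.
* The mixture analysis assumes exactly two Gaussian components; triple
  turnovers are absorbed into the compound component's width.
* The AFS model has no bead-tether compliance or acoustic-force noise
  spectrum; rates are defined purely by the position profile.
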