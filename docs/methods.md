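# Methods

## The model

`nvugrey` models the cerebrovascular response to anodal transcranial
direct-current stimulation (tDCS) as a lumped neurovascular unit (NVU) of
four compartments — synaptic space, astrocyte, perivascular space, and
arteriolar smooth muscle cell (SMC) — with 17 state variables and the mean
vessel circumference `x` as output. The equation set follows the
bidirectional astrocyte–vessel lineage of compartmental NVU models:
IP3/calcium dynamics of the Li–Rinzel type in the astrocyte, EET
production above a calcium threshold, BK-channel potassium release into
the perivascular space, TRPV4 mechanosensing on the endfoot (strain
activates, perivascular calcium inhibits, and the influx scales with the
electrochemical driving force so the astrocyte membrane potential couples
into the calcium chain), a Morris–Lecar-type SMC with KIR feedback from
perivascular potassium, calcium-driven cross-bridge attachment, and
Kelvin–Voigt vessel-wall mechanics.

The scalp current `I_tdcs(t)` is a trapezoid (2 mA, 30 s ramps, 600 s
total in the emulated protocol). Each hypothesis ("pathway") injects the
first-order-filtered current `v_i = K_i/(s·tau + 1)·I_tdcs`
(`tau` = 20 ms passive membrane time constant; `K_i` an arbitrary
lead-field gain) additively at one site:

| pathway | perturbed quantity | injection state |
|---|---|---|
| 1 | synaptic K+ release flux | `K_s` |
| 2 | astrocyte transmembrane current | `Vk` (scaled 1/C_astr) |
| 3 | perivascular K+ concentration rate | `K_p` |
| 4 | SMC voltage-gated K current | `V_smc` (scaled 1/C_SMC) |

The pathways are nested: they share every equation and differ only in the
injection site.

### Parameter provenance and the pathway timescale ladder

All constants live in `src/nvugrey/data/parameters.yaml`, each tagged
`lineage` (form and magnitude follow the published source-model family) or
`package` (a coupling or scale constant set here). Two `package` choices
deserve explanation because they shape the scientific behavior:

* **BK recruitment rate `phi_bk` = 0.07/s.** The gating variable `n_bk`
  lumps fast channel gating with the slower calcium/EET-dependent
  recruitment of endfoot BK activity. Treated as fast (its channel-gating
  value), the astrocyte pathway becomes dynamically indistinguishable from
  direct perivascular injection — the two hypotheses then differ by a
  40 ms lag that no physiological recording could resolve, and
  hypothesis testing between them is vacuous. The slow value gives the
  astrocyte pathway its own ~14 s signature, consistent with the
  seconds-scale astrocytic contribution seen in neurovascular-coupling
  experiments.
* **Timescale ladder.** Each nested pathway adds one upstream lag:
  synaptic K+ clearance ~7 s plus IP3/calcium (~4 s, heavy endfoot
  buffering `beta_buff` = 0.004) for pathway 1, BK recruitment ~14 s for
  pathway 2, perivascular clearance 1/`R_decay` = 10 s for pathway 3;
  pathway 4 acts directly on the SMC membrane. Vessel mechanics are fast
  (`tau_x` = 2 s, `tau_y` = 1 s) so the evoked transient carries its
  energy inside the 0.01–0.05 Hz analysis band that the pipeline
  prescribes; with slower wall mechanics, more than 95% of the response
  energy falls below the band edge and the band-passed data retain almost
  no evoked signal.

The baseline operating point (`find_equilibrium`) is a stable fixed point
in this parameterization (vessel circumference ≈ 132 µm, SMC potential
≈ −50 mV, cross-bridge fraction ≈ 0.21); an oscillatory baseline, had one
arisen, would be reported as the cycle's temporal mean with an explicit
flag. Newton root-finding is tried first, with a 300 s unforced settling
fallback.

### Numerical choices

* Stiff-capable adaptive integration (LSODA by default; `rtol` 1e-8,
  `atol` 1e-9, recorded in every trajectory). Probability states are never
  clamped; excursions beyond 1e-6 outside [0, 1] raise.
* The EET production threshold uses a softplus with width 0.02 µM instead
  of `max(·, 0)` so the right-hand side is smooth at the operating point
  (central-difference Jacobians would otherwise straddle a kink).
* Linearization uses the whole-system central-difference Jacobian with
  per-state scaled steps (relative step 1e-6); the compartmental block
  structure is kept only as state-label metadata. This is equivalent to a
  block-by-block linearization at a shared operating point.
* Linear simulations discretize exactly under a first-order-hold input
  (the trapezoid is piecewise linear) via one augmented matrix
  exponential, then run one first-order IIR recursion per eigenmode; a
  dense recursion is the fallback for defective eigenbases.
* Transfer functions are kept in factored zero/pole/gain form. The
  composed reference pathway TFs have pole magnitudes spanning seven
  decades (0.24 to 9.6e6 rad/s); expanding them into polynomial
  coefficients destroys precision, so impulse responses are evaluated by
  exact partial fractions on the factored form (distinct poles), with a
  residue fallback for repeated poles. The very fast factors contribute
  negligibly after peak normalization.
* Near pole-zero cancellations are removed at a relative tolerance of
  1e-7 when converting state-space models to transfer functions.

## Grey-box fitting

`pem_fit` fits the cascade of the 20 ms input filter with a pathway model
to a normalized tHb series by bounded trust-region nonlinear least
squares. The default identifiable parameters are an overall signed gain
(absorbing the lead-field gain and the circumference-to-tHb scale), a
global rate scale `kappa` (A → κA), and an additive decay adjustment on
the injection state's diagonal entry. The rate scale and decay stay
within a physiological band around the linearized initialization
(κ ∈ [0.74, 1.35], decay ± 0.5/s): the refinement is meant to adapt a
physiologically derived model to a subject, not to re-identify an
arbitrary system — with unbounded rates a wrong pathway model can morph
into the right one and the hypothesis test loses its meaning. Unstable
candidates are penalized during the search and never returned; on
non-convergence up to five randomized restarts (±20% around the
initialization) are tried.

Fit quality is the mean squared error on the normalized series, and the
model-selection score is the normalized Akaike information criterion
`AIC = ln(MSE) + 2k/N` (k = 3 free parameters, N samples). The log-MSE
form keeps the score O(1) for max-normalized data. Selection is the
lowest median AIC across subjects, with median MSE as tie-break.

When the recorded output has been zero-phase band-passed, the model input
is prefiltered with the identical filter and the model is simulated over
the full record with the loss restricted to the 0–150 s analysis window.
Zero-phase filtering is an LTI operation, so it commutes with the model
and preserves the input-output relationship — but it spreads input
history backward in time, which is why a window-only simulation from zero
initial state would be systematically wrong at the window start.

Residual diagnostics report the residual autocorrelation (unbiased, no
mean removal, so constant residuals score exactly 1) and the
input-residual cross-correlation over lags ±25, with 99% whiteness bands
at ±2.58/√N.

## Reduced-order analysis

Balanced truncation uses the square-root algorithm on the controllability
and observability Gramians (Lyapunov solves), reporting the Hankel
singular values and the worst-case frequency-response bound
2·Σ(discarded HSV); marginal or unstable modes are split off by an
ordered Schur decomposition, carried unreduced, and re-attached.

The reference minimal-realization transfer functions of the four
pathways are composed from their factored forms, nested from the SMC
pathway outward (6/1, 8/2, 10/3, 11/3 poles/zeros; the
numerator/denominator assignment of the factors is the unique one
consistent with those counts). Their normalized impulse responses peak at
0.40 s (SMC), 1.96 s (perivascular), 2.67 s (astrocyte) and 5.14 s
(synaptic) at 1 ms resolution — the nested ordering from fastest direct
SMC action to the classical ~5 s hemodynamic-response timing. The peak
times are computed for the TFs alone; cascading the 20 ms input filter
shifts them by less than the 0.1 s reporting precision.

Fixed-order output-error estimation (`tf_estimate`) parameterizes poles
as −exp(θ) — real and stable by construction — with free real zeros and
gain. The chi-square goodness-of-fit is the normalized residual sum
Σ(y−ŷ)²/Σ(y−ȳ)², an interpretation chosen because it is dimensionless and
small for good fits; the nested difference test refers
N·(χ²_small − χ²_large) to a chi-square distribution with df equal to the
parameter-count difference (α = 0.05 default) and prefers the
lowest-order model not significantly worse than the next larger.

## The synthetic study

The generator emulates the study protocol the analysis assumes: 11 subjects, two
regions (targeted under the 4×1 montage, contralateral nontargeted), a
120 s pre-stimulation baseline followed by 600 s of 2 mA stimulation, and
10 Hz oxy/deoxy recordings — 4 channels per region plus 8 "outer" montage
channels carrying systemic physiology and only a residual (0.1×) evoked
response.

Each subject's vessel drive comes from the nonlinear simulator under the
region's true pathway (3 targeted, 4 nontargeted at 0.35× amplitude,
matching the minimal contralateral responses such montages produce) and a
log-normal lead-field gain (σ = 0.2) around reference gains calibrated
once for a ~0.25 µm small-signal circumference change at 2 mA — small
enough that the linearized models are faithful, large enough to dominate
the noise floor. The pathway-4 reference gain is negative: a net increase
in SMC voltage-gated K conductance hyperpolarizes and dilates, and the
sign is absorbed into the arbitrary lead-field gain. Ground-truth tHb is
4 µM per µm of circumference change (≈1 µM response peaks).

Per channel: heterogeneous response sensitivity (±30%) and a
subject-shared Mayer mode (0.1 Hz) with a channel-varying spatial weight
(±50%) — the spatial structure the PCA stage is meant to find and the
reason the evoked pattern is not collinear with it; jittered respiration
(~0.25 Hz) and cardiac (~1 Hz) sinusoids; slow drift; white noise
(0.02 µM). Oxy/deoxy split: oxy = (1−λ)·tHb + s, deoxy = λ·tHb − s with
λ = −0.3 (deoxy moves opposite, the classical activation pattern) and a
shared band-limited anti-phase process s — the sum is the ground-truth
tHb exactly. Three of eleven subjects are generated under a common-drive
regime (λ = +0.35, a shared co-moving component instead of s) paired with
an initial-dip drive (an early negative gain transient, depth 2,
τ = 20 s): these fail the anti-correlation QC by construction, mirroring
a realistic 3-of-11 rejection.

What the generator does **not** emulate: real optical-density conversion
and motion artifacts, spatially correlated extra-cerebral layers,
non-stationary systemic physiology, baseline vasomotion limit cycles, and
neuroplastic after-effects beyond the analysis window. Passing tests
therefore show that the pipeline recovers the truth under the stated
statistical structure, not that it would on any particular real
recording.

## Preprocessing

Fixed order: tHb = oxy + deoxy per channel → PCA systemic removal →
zero-phase Butterworth band-pass (order 3, forward–backward,
0.01–0.05 Hz analysis band) → baseline subtraction and max-normalization
(dividing by the maximum absolute post-onset value, so initial-dip
subjects normalize to −1 with a flag) → anti-correlation QC (Pearson r
between regional oxy and deoxy over 600 s; pass iff r < −0.5) → ensemble
averaging of QC-passing subjects.

The PCA spatial filter is estimated on the pre-stimulus baseline across
the subject's entire montage and then projected out of the whole record.
Estimating it on the full record would regress out the evoked response
itself whenever few channels respond (with 4 all-responding channels the
response *is* the leading spatial component); the baseline contains only
systemic physiology, so the filter captures what it is meant to remove.
One component is removed by default.

## Problem sizes used by the test suite

Pathway-recovery experiments use the study's native sizes: N = 1500
samples (150 s at 10 Hz), 50 noise seeds for single-model recovery and
4-way selection at SNR 10, and 20 full 11-subject cohort replicates for
the end-to-end selection experiment. The balanced-truncation bound is
checked on 100 random stable 10-state systems. The nested fixed-order
comparison experiment runs 10 noise replicates in the module tests.

## Known limitations

* The 17-equation system is a reconstruction from the published source
  lineage; parameter values tagged `package` are this package's own
  calibration of the baseline operating point and timescale ladder, not
  measured constants.
* Subject-level MSE/AIC values on real recordings depend on the data and
  are not reproduced by the synthetic study; only structural and
  recovery properties are claimed.
* `tf_estimate` fits real poles only; resonant data would need the
  complex-pair extension.
* The AIC and chi-square conventions are documented interpretations
  (normalized forms); other conventions shift absolute values but not
  rankings.
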