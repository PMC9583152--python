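# Methods

## Model and procedure

### Dose–inhibition and conductance block

A drug's action on one ionic current is the static pore-block Hill model.
With dose D (nM), half-maximal inhibitory concentration IC50 (nM) and Hill
coefficient h (dimensionless), the *inhibition factor*

    IF(D) = 1 / (1 + (D / IC50)^h)

is the fraction of maximal conductance remaining (IF(0) = 1,
IF(IC50) = 1/2), and the drugged current is

    I'_ion = IF(D) · G_ion · m_ion · (Vm − E_ion).

The name is the field's convention even though the quantity is the remaining
(not the inhibited) fraction; we keep the convention and document it.
Measured inhibition is 1 − IF. Numerically both are evaluated through the
logistic `expit(±h·(ln D − ln IC50))`, which is exact at D = 0 and immune to
power-law overflow. Fitting is least squares on (log IC50, log h), so
positivity is structural; the fit requires at least three distinct positive
doses and a non-flat response.

Assumptions: static (equilibrium) binding only — no state-dependent or
kinetic hERG binding, no preprocessing of raw patch-clamp sweeps; one Hill
curve per drug–channel.

### In vitro uncertainty

Measurement uncertainty is propagated as 2,000 resampled (IC50, h) pairs per
drug–channel, generated by residual bootstrap: fit the Hill curve, resample
the residuals with replacement, add them to the fitted curve (clipped to
[0, 1]), refit. Parameters are drawn jointly (one refit per replicate), so
the IC50–h correlation of the fit survives. A replicate whose refit diverges
is redrawn (up to 20 attempts); if more than half of the replicates fail on
the first try the set is reported as "unstable uncertainty". A lognormal
parametric fallback with a user-supplied coefficient of variation covers
blocks that ship without raw points. The bootstrap has the same output
contract as the Bayesian/MCMC samplers used in regulatory CiPA work (2,000
curves whose 2.5–97.5 percentile band covers the point-estimate curve) while
needing no external sampler.

### Pacing protocol

All simulation constants are package defaults (`RunConfig`), not hard-coded:
cycle length 2,000 ms (30 bpm — the bradycardic condition under
which the QT interval is longest and TdP risk is highest), 10,000 drug-free
pre-beats to reach steady state (cached to a flat text file keyed by model
identity), 1,000 drugged beats from that saved state, fixed 0.1 ms output
grid, last 250 beats retained. Doses are integer multiples 1–4× Cmax.
Drugged runs start from the *drug-free* steady state and are not
re-equilibrated — the drug is "switched on" at the first recorded beat.

### Feature extraction

Twelve features are read from the worst retained beat — the beat whose
repolarisation is steepest (most negative post-peak dVm/dt), the beat
nearest to early-afterdepolarisation behaviour; ties go to the latest beat.

- Slopes are centred first differences on the output grid (`np.gradient`).
  The 0.1 ms grid is a recorded configuration item because the upstroke
  velocity dVm/dt_max is resolution-sensitive.
- Activation time (and calcium-transient onset) is the midpoint of the
  contiguous run of maximal slope. For smooth signals the maximum is unique
  and this is simply its time; on piecewise-linear test fixtures it lands
  mid-upstroke, which makes the closed-form oracle values exact.
- APDx is the linearly interpolated time from activation until Vm first
  falls below `vm_peak − (x/100)·amplitude`, with amplitude referenced to Vm
  at the stimulus onset of the same beat (no separate resting-Vm feature is
  needed). CaDx is analogous with the diastolic Cai at beat start as
  baseline. APD_tri = APD90 − APD50 and CaD_tri = CaD90 − CaD50 exactly.
- qNet integrates I_NaL + I_CaL + I_Kr + I_Ks + I_K1 + I_to over the beat
  (trapezoidal rule, A/F × s ≡ µC/µF). qInward is
  `0.5·(q_CaL/q_CaL,ctl + q_NaL/q_NaL,ctl)` with absolute charges, so the
  sign convention of inward currents cannot flip the ratio; the control is
  the drug-free beat under the same protocol.
- Missing-value policy: a beat whose Vm never recrosses the APDx level
  (repolarisation failure) yields NaN for that duration; the NaN propagates
  through the four-dose average and the affected rows are dropped (and
  counted) when that feature's ordinal model is fitted. Ca peak is reported
  in mM (diastolic ≈ 1e-4, transient ≈ 4e-4 mM).

Per drug: 2,000 uncertainty samples × 4 doses = 8,000 simulated biomarkers,
averaged over doses to 2,000 feature rows.

### Ordinal risk model

Each feature gets its own single-feature proportional-odds model for the
ordered classes low < intermediate < high:

    P(Y ≤ j | x) = σ(ζ_j − βx),  j ∈ {low, intermediate},  ζ₁ < ζ₂.

Fitting is maximum likelihood with an analytic gradient. The cutpoint order
is structural (ζ₂ = ζ₁ + e^δ); the feature is standardised internally, which
makes the fit invariant to affine rescaling; optimisation is L-BFGS from an
empirical-cumulative-logit start plus three perturbed restarts (best
likelihood wins), polished by Newton steps on the 3-parameter problem with a
finite-difference Hessian. The fit is flagged converged when the mean-NLL
gradient norm is below 1e-8 and the standardised slope is bounded (|β_z| <
30; beyond that the data are treated as completely separated). Thresholds
TH1 = ζ₁/β and TH2 = ζ₂/β are the feature values where the cumulative
probability of the lower class group is exactly one half; when the feature
*decreases* with risk (β < 0), TH1 > TH2 and the comparison flips —
classification always goes through the cumulative-probability rule
(P(Y ≤ low) ≥ ½ → low; P(Y ≤ intermediate) < ½ → high; else intermediate),
which handles the orientation automatically. Non-convergence (e.g.
separation, constant feature) is a structured "unfit" result; report tables
print a dash for it.

### Repeated-test evaluation

One test set = one biomarker sample per test drug (16 rows for the reference
panel), drawn uniformly; 10,000 sets by default, each from its own spawned
RNG substream so results are independent of iteration order. Per set and
class: one-vs-rest ROC AUC (midrank/Mann–Whitney; the score is the model's
predicted class probability), a 3×3 confusion matrix, sensitivity,
specificity, precision, accuracy, F1, LR+ and LR−. Likelihood ratios
undefined by zero division (specificity exactly 1 or 0) are reported missing
with a reason code rather than infinite. Summaries are median (min–max) over
repeats; the sweep never aborts on an undefined cell. The sweep is
vectorised internally (rank computations across all repeats at once) and is
verified in the tests against the scalar per-repeat operations.

Cross-dataset comparison (`compare_datasets`) is a two-sided variance-ratio
F test followed by Welch's unequal-variance t test with Welch–Satterthwaite
degrees of freedom.

## Synthetic data: what it emulates, what it does not

The generator provides every pipeline input offline.

**Surrogate myocyte.** An analytic one-beat generator, not a biophysical
model. Vm is rest (−88 mV) → linear upstroke → plateau (+33 mV) → linear
repolarisation; Cai is a triangular transient; the six net-charge currents
are triangles/trapezoids scaled by their conductance factors. Drug effects
enter through fixed, documented sensitivity constants:

    APD90 = 270 ms · F,  APD50 = 230 ms · F,
    F = 1 + 0.8(1−s_IKr) + 0.3(1−s_IKs) − 0.4(1−s_ICaL)

with analogous closed forms for upstroke duration (INa), peak Vm and Ca
amplitude (ICaL) and Ca-transient duration (IKr); every extracted feature
therefore has an exact expected value (`surrogate_expected_features`), which
is the end-to-end oracle of the test suite. The constants were chosen for
directional realism only (IKr block prolongs, ICaL block shortens, INa block
slows the upstroke, blocking IKr lowers qNet); they were *not* fitted to any
ionic model, and no test or acceptance value references ToR-ORd numbers.
Because the surrogate is memoryless, every paced beat is identical: the
pipeline exploits this by simulating a single beat per (drug, sample, dose)
— the worst-of-250-beats selection and the 1,000-beat protocol are exercised
on multi-beat bundles in the tests and are used verbatim with any
non-periodic backend. What the surrogate does **not** emulate: beat-to-beat
memory and restitution, early afterdepolarisations, alternans, spike-and-
dome morphology, rate dependence, or any quantitative ToR-ORd behaviour.
Passing tests therefore demonstrate the correctness of the pipeline
machinery on a model with known answers, not the fidelity of any particular
ionic model.

**Synthetic cohort.** The packaged 28-drug reference panel (real Cmax
values, risk labels and the 12-train/16-test split) receives synthetic
multichannel block fingerprints: per drug and channel, a true IC50 is drawn
lognormally around a class-conditional median (IKr: 1, 4, 16 × Cmax for
high/intermediate/low risk; graded ICaL/INaL/INa medians per class;
drug-level log-SD 0.7; h lognormal around 1, log-SD 0.15, clipped to
[0.4, 3]). Four assay doses at {0.3, 1, 3, 10} × true IC50 — a
concentration–response design spanning the active range — carry Gaussian
inhibition noise (SD 0.05, clipped to [0, 1]). Adjacent class medians sit
about two drug-level log-SDs apart so that class feature clouds *overlap*:
ordered-but-overlapping classes are what real CiPA feature distributions
look like, and without overlap the proportional-odds likelihood has no
finite maximiser (complete separation). Ground-truth parameters are retained
for recovery tests. The class-conditional recipe is deliberately simple; it
does not emulate torsade metabolites, multichannel correlation structure, or
lab-to-lab systematic differences between in vitro datasets.

**Feature banks.** For classifier tests independent of the simulator,
Gaussian per-drug clouds around class-mean feature vectors with drug-level
offsets.

## Numerical choices

- Hill fits: Levenberg–Marquardt on log parameters, tolerances 1e-15,
  IC50 accepted in (1e-9, 1e15) nM; residual SD uses n − 2 dof.
- Duration crossings: first grid sample below the level, then linear
  interpolation within that grid step; agreement with a brute-force grid
  scan is within one dt by construction.
- The trapezoidal charge integrals are exact for the piecewise-linear test
  fixtures with on-grid knots (assertions at 1e-12).
- Degenerate inputs raise early and specifically: empty drug tables, missing
  Cmax (naming the drug), unknown channel names (listing the accepted set),
  fewer than three distinct doses ("underdetermined"), flat responses ("no
  dose response"), flat traces ("no AP"/"no transient"), zero control
  charges ("degenerate control").
- Reproducibility: every stochastic stage draws from a named RNG stream
  derived from (master seed, stage, entity) via SHA-256, so per-drug and
  per-repeat results are order-independent and a rerun with the same
  configuration is bit-identical (the run manifest records config hash, seed
  and artifact checksums).

## Design choices made where the design was open

- Cell type: the CellML adapter defaults to whatever variant the supplied
  model file encodes (endocardial in the published ToR-ORd artifact); the
  surrogate has no cell-type notion.
- Worst-beat statistic: "maximal repolarisation velocity" is implemented as
  the steepest phase-3 descent (most negative post-peak slope), matching the
  sign of reported dVm/dt_max,repol thresholds; the selector is a standalone
  function and can be swapped for an EAD-specific criterion.
- ROC score for a three-class problem: the per-class predicted probability,
  one-vs-rest (the raw feature value would give identical rank AUCs only up
  to orientation per class).
- Evaluation draws are one-per-drug within a repeat and independent across
  repeats.
- The packaged pipeline fits each feature in its own single-feature model;
  multi-feature models are out of scope.

## Problem sizes used by the packaged runs

The full-scale run (acceptance script; also exercised once in the test
suite) uses the complete protocol bookkeeping: 28 drugs × 2,000 Hill samples
× 4 doses = 224,000 simulated beats, 24,000 training and 32,000 test feature
rows, 10,000 test repeats; it completes in roughly 10–15 minutes on one CPU.
Unit and property tests run on reduced sizes (tens of Hill samples, hundreds
of repeats) chosen to keep the suite fast while leaving every code path
identical.

## Known limitations

- The surrogate cannot produce EADs, so the "worst beat" is degenerate there
  (all beats identical); worst-beat selection is validated on constructed
  multi-beat fixtures instead.
- Threshold values fitted on synthetic cohorts are properties of the
  generator, not of any drug; only the pipeline's bookkeeping, recovery
  properties and discrimination ordering are meaningful outputs.
- The static Hill block ignores kinetic/state-dependent binding, which is
  known to matter for some hERG blockers.
- No calibration of the cell model to a given in vitro dataset is attempted.
- LR summaries on 16-item panels are coarse (metrics are lattice-valued);
  medians are stable only to one lattice step between seeds.
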