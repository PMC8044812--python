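# Methods

## Model

DSC-MRI measures the signal drop caused by a gadolinium bolus transiting the
brain. Under intact-vasculature assumptions the concentration is proportional
to the change in effective transverse relaxation rate,
ΔR2\*(t) = −(1/TE) ln(S(t)/S₀), and relative cerebral blood volume is the
area under the first-pass ΔR2\*(t) curve between the bolus entrance t₀ and
exit t₁, normalized to normal-appearing white matter (NAWM).

When the blood-brain barrier leaks, the voxel curve deviates from the shape
of the whole-brain reference curve ΔR̄2\*(t) (the average over nonenhancing
voxels). The unidirectional model writes the voxel curve as
K₁ ΔR̄2\*(t) − K₂ ∫₀ᵗ ΔR̄2\*(u) du: the integral term accumulates
monotonically, capturing the drifting tail that extravasated contrast
produces. The bidirectional model additionally lets contrast return from the
extravascular space with rate K_ep, turning the integral into a causal
exponentially-weighted one, ∫₀ᵗ ΔR̄2\*(u) e^(−K_ep (t−u)) du; at K_ep = 0 the
two models coincide. Fitted K₂ is negative when T2\* effects dominate the
leak (elevated tail, rCBV overestimated) and positive under T1 dominance.
Correction *adds* K₂ times the integral term back onto the measured curve,
cancelling the modelled leakage and leaving (up to residual) K₁ ΔR̄2\*(t).

Assumptions inherited from the models: a single global bolus window and
reference curve apply to all voxels (no per-voxel arrival-time correction);
leakage is fully described by the two-term linear expansion; masks are
co-registered and segmentation is trusted as given.

## Fitting

For fixed K_ep the problem is ordinary least squares in (K₁, K₂), solved
exactly from the 2×2 normal equations, vectorized over voxels. K_ep is found
by variable projection: an exhaustive coarse grid over [−0.2, 1.0] s⁻¹ (41
points, with 0 always inserted) followed by 40 golden-section iterations on
the best bracket (final bracket width ~2e−10 s⁻¹). The search is
unconstrained in sign; the grid bounds are a practical choice wide enough
for the rates seen in glioma. Residual sums of squares are computed from
explicit residuals (not the yᵀy − βᵀXᵀy shortcut) so that near-perfect fits
do not lose the minimum to cancellation. Ties against K_ep = 0 — any case
where the refined optimum is not strictly, measurably better than the nested
unidirectional solution — resolve to K_ep = 0, which makes the bidirectional
fit reproduce the unidirectional parameters exactly on K_ep-free data and
guarantees the nesting inequality SS_res(bidir) ≤ SS_res(unidir).

Both integral operators use the causal trapezoidal rule with step TR; the
exponential kernel is evaluated by the recursion
E[i] = e^(−K_ep ΔT) E[i−1] + (ΔT/2)(e^(−K_ep ΔT) y[i−1] + y[i]), whose
per-step exponent never overflows for sensible rates (a ±50 clip guards
absurd negative rates, with a warning). The synthetic phantom uses the same
operators, so noiseless recovery is exact rather than
discretization-limited. Fits use all retained time points, not just the
bolus window: the leakage signature lives in the tail.

Degenerate designs (zero reference, collinear columns) are flagged
non-converged; those voxels are NaN in all corrected maps and excluded from
VOI medians and NAWM means.

## Pipeline steps and thresholds

All thresholds live in `RunConfig`, serialized alongside every run. Defaults:

| parameter | default | meaning |
|---|---|---|
| `discard_leading` | 2 | leading frames dropped (pre-steady-state signal) |
| `drop_threshold_sd` | 5 | minimum bolus signal drop, in baseline SDs |
| `tail_points` | 10 | final time points forming the tail window |
| `tail_threshold_sd` | 1 | tail-vs-baseline criterion for reference voxels |
| `baseline_init_points` | 8 | seed points of the iterative baseline search |
| `baseline_threshold_sd` | 2 | arrival threshold on the averaged curve |
| `baseline_guard` | 1 | points excluded before arrival from the baseline |
| `bolus_exit_fraction` | 0.2 | t₁ = first fall below baseline + 20 % of peak |
| `kep_min`, `kep_max` | −0.2, 1.0 | K_ep search bounds (s⁻¹) |
| `clamp_fraction` | 1e−6 | floor for non-positive signal, × S₀ |
| `max_clamped_fraction` | 0.10 | in-window clamp fraction that excludes a voxel |
| `min_reference_voxels` | 100 | floor on reference-curve averaging |
| `alpha` | 0.05 | significance level |

Bolus delimitation: the baseline grows from the first 8 samples of the
whole-brain average curve while values stay within 2 SD of the running
baseline mean; arrival requires two consecutive supra-threshold points
(guards single-sample noise). t₀ is the last sub-threshold index before the
upslope; t₁ is the first post-peak index below baseline + 20 % of
(peak − baseline) or the pre-recirculation local minimum, whichever comes
first — isolating the first pass from recirculation. A provisional window
from the mean signal curve supplies per-voxel baselines; the final window is
relocated on the nonenhancing reference curve and applied globally.

Numerical edge cases: S(t) ≤ 0 is clamped to 1e−6 S₀ before the log and
flagged; a voxel with more than 10 % clamped in-window points is excluded.
Degenerate baselines (SD exactly 0, e.g. noiseless data) are handled by
thresholding with max(k·SD, ε) with ε = 1e−9 signal units, so the 5-SD drop
rule degenerates to "any drop at all" and the tail rule to near-exact
equality; this also avoids knife-edge behaviour when a constant baseline's
SD rounds to ~1e−13 instead of 0. Adjusted R² uses
1 − (1 − R²)(n − 1)/(n − k − 1) with k = 2 (unidirectional) or 3
(bidirectional) and n counting only unclamped retained time points; constant
observed curves (SS_tot = 0) yield NaN.

## Statistics

Per patient, the median of each normalized map and K-parameter map over the
tumor VOI. Per lesion group, the three paired map comparisons are tested
with the Wilcoxon signed-rank test (zero differences dropped, mid-ranks for
ties, exact null for small samples) and form one Holm-Bonferroni family;
percentage differences are computed per patient and then averaged — not
from group means, which gives visibly different values. Shapiro-Wilk
normality is computed and reported, but the workflow always proceeds
nonparametrically. Grade correlation is Spearman's rank correlation of
per-patient median rCBV against WHO grade.

## Synthetic phantom

The generator emulates exactly what the analysis consumes: a gamma-variate
reference bolus ΔR2\*(t) = A ((t−t₀)/(sσ))^s e^(s−(t−t₀)/σ) (peak-normalized;
defaults s = 3, σ = 3 s, A = 15 s⁻¹, arrival index 20), a delayed
recirculation bump (same shape, delayed by 2sσ, amplitude fraction 0.25),
and a steady-state plateau (0.3 s⁻¹) that ramps in with the cumulative first
pass — emulating elevated intravascular contrast after first passage. Voxel
curves come from the forward leakage models with per-voxel ground-truth
K₁/K₂/K_ep; the signal transform is S = S₀ e^(−TE ΔR2\*) with additive
Gaussian noise in signal space (matching the magnitude-MR regime at moderate
SNR and exercising the log transform; default S₀ = 600, SD = 12, i.e.
baseline SNR 50). Geometry is a box layout (background border, brain
interior, one tumor box, one ≥18-voxel NAWM box). Acquisition defaults
(TR 1.1 s, TE 30 ms, 100 dynamics, 16×16×4 grid) mirror a typical
gradient-echo EPI perfusion protocol at desk scale.

The bolus component is truncated to exactly zero once it falls below 1e−7 of
the peak. A gamma variate never reaches zero analytically; without
truncation a noiseless phantom tail would sit a microscopic but fixed offset
above baseline and the degenerate (zero-SD) tail criterion could never be
met, so noiseless unit tests would be meaningless.

Cohort ground truth is sampled per patient: WHO grade from a mix dominated
by grade IV for enhancing and grade II for nonenhancing lesions; tumor K₁
(relative blood volume) increasing with grade (means 1.5 / 2.5 / 3.2 for
grades II / III / IV); tumor K₂ negative — mean −0.04 s⁻¹ for enhancing,
−0.008 s⁻¹ for nonenhancing — and K_ep nonnegative (means 0.015 and
0.005 s⁻¹), magnitudes matching the K-parameter levels reported in glioma
DSC studies. These distributions were fixed once at design time. Percentage
rCBV decreases that follow from them on this phantom geometry are smaller
(~7–10 % for enhancing) than the 20–30 % seen in clinical studies; with a
gamma-variate first pass and K₂ of this magnitude, the leakage integral
inside the bolus window is simply a few percent of the K₁ term, so both the
K-parameter levels and large percentage drops cannot be matched
simultaneously by any self-consistent forward phantom. We kept the
K-parameter levels; signs, orderings and significance structure are
preserved.

What passing tests on the phantom do **not** show about real data: realistic
anatomy and partial-volume mixing, arterial input function variability,
per-voxel bolus delay and dispersion, motion, susceptibility dropout, and
Rician (rather than Gaussian) noise at low SNR are all absent. The phantom
validates the estimator and its numerics, not acquisition robustness.

## Problem sizes

The test suite and the acceptance script run entirely on desk-scale
phantoms: 16×16×4 voxels × 100 time points per case, 34-patient cohorts,
500-voxel recovery batches. These sizes give Monte-Carlo stability for the
asserted medians and orderings while keeping a full run in seconds; the
pipeline itself is vectorized over voxels and scales linearly to clinical
matrices.

## Known limitations

- No arrival-time correction (a deliberately different method family) and no
  SVD/residue-function leakage estimation.
- The K_ep grid bounds, although wide, are a practical constraint on an
  otherwise unconstrained fit.
- "Contralateral" NAWM selection is a segmentation-time concern; the
  pipeline trusts the provided mask.
- K₁ is reported as fitted (dimensionless scaling of the reference curve);
  no unit rescaling is applied.
- On short acquisitions the 10-point tail window can overlap recirculation,
  biasing reference-voxel selection; the window location is logged so this
  is auditable.
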