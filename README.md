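# dscleak

Leakage-corrected relative cerebral blood volume (rCBV) estimation from
dynamic susceptibility contrast (DSC) MRI, for researchers processing brain
tumor perfusion data.

## The problem

rCBV from DSC-MRI is the most widely used imaging biomarker of glioma
aggressiveness, but gadolinium extravasation through a disrupted blood-brain
barrier corrupts the signal: depending on whether T1 or T2\* effects dominate
in the leaky tissue, rCBV is over- or underestimated. `dscleak` implements
the model-based corrections that address this, end to end:

1. **Signal to relaxivity.** Each voxel's signal S(t) is converted with
   ΔR2\*(t) = −(1/TE) ln(S(t)/S₀), where S₀ is the pre-bolus baseline mean.
2. **Uncorrected rCBV** is the trapezoidal integral of ΔR2\*(t) between the
   bolus entrance t₀ and exit t₁ located on the whole-brain average curve.
3. **Unidirectional leakage correction** models each voxel as

   ΔR2\*(t) ≈ K₁ ΔR̄2\*(t) − K₂ ∫₀ᵗ ΔR̄2\*(u) du

   where ΔR̄2\*(t) is the average curve of nonenhancing brain voxels, K₁ is a
   susceptibility scaling factor and K₂ (s⁻¹) a permeability-related rate
   (negative when T2\* leakage effects dominate, positive for T1 dominance).
   The corrected curve is ΔR2\*(t) + K₂ ∫₀ᵗ ΔR̄2\*(u) du.
4. **Bidirectional correction** adds back-flux from the extravascular space
   with rate K_ep, replacing the integral with
   ∫₀ᵗ ΔR̄2\*(u) e^(−K_ep (t−u)) du; K_ep = 0 recovers the unidirectional
   model. All fits are unconstrained; (K₁, K₂) is solved exactly by linear
   least squares at each K_ep (variable projection with a grid plus
   golden-section refinement).
5. **QC and normalization.** Voxels must drop ≥ 5 baseline SDs during the
   bolus; nonenhancing reference voxels must return to within 1 baseline SD
   of baseline in the tail; the first two time frames are discarded; every
   rCBV map is divided by its own NAWM (normal-appearing white matter) mean.
6. **Statistics.** Per-patient VOI medians, Wilcoxon signed-rank tests with
   Holm-Bonferroni correction per lesion group, percentage differences
   averaged per patient, adjusted R² fit quality, and Spearman correlation of
   rCBV with WHO grade.

A seedable synthetic phantom (gamma-variate bolus, forward leakage models,
Gaussian signal noise) makes the whole pipeline testable without any data
download.

## Worked example

```python
import dscleak as dl

spec, grade = dl.make_phantom_spec(7, group="enhancing")   # WHO grade 4 draw
case = dl.simulate_case(spec)
result = dl.run_case(case.series, case.vois, dl.RunConfig())
for key, value in result.summary.items():
    print(f"{key}: {value:.4f}")
```

prints (seed 7):

```
median_rcbv: 3.6312
n_tumor_voxels: 32.0000
median_rcbv_unidir: 3.2797
median_rcbv_bidir: 3.1626
median_k2_unidir: -0.0319
median_k2_bidir: -0.0401
median_kep_bidir: 0.0063
mean_adj_r2_unidir: 0.9873
mean_adj_r2_bidir: 0.9912
```

The tumor's uncorrected rCBV (3.63, in NAWM-normalized units) falls after
unidirectional (3.28) and further after bidirectional (3.16) correction —
the expected behaviour when T2\*-dominant leakage (negative K₂, here median
−0.03 to −0.04 s⁻¹) inflates the uncorrected integral. The positive median
K_ep (0.006 s⁻¹) is the fitted back-transfer rate; adjusted R² near 0.99
says both models describe the curves well.

The same run is available from the shell:

```bash
dscleak simulate --seed 7 --out case7
dscleak run --dsc case7/dsc.nii.gz --brain case7/brain.nii.gz \
    --tumor case7/tumor.nii.gz --nawm case7/nawm.nii.gz \
    --tr 1.1 --te 0.03 --model all --out case7/maps
dscleak cohort --manifest manifest.tsv --out cohort_out   # many cases + stats
```

`run` writes eight NIfTI maps (rcbv, rcbv_unidir, rcbv_bidir, k2_unidir,
k2_bidir, kep_bidir, adj_r2_unidir, adj_r2_bidir) plus audit sidecars: the
resolved configuration, the bolus window and QC voxel counts, the reference
curve, and a summary row. Every threshold lives in a single YAML
configuration (`dscleak.RunConfig`) with defaults documented in
`docs/methods.md`; pass `--config my.yaml` to override any of them.

Real acquisitions are consumed as a 4-D NIfTI series plus three co-registered
binary masks (whole brain, tumor VOI, NAWM); segmentation and registration
are upstream concerns.

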