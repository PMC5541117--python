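# subqmri

Quantitative MRI analysis of aging in the human subcortex: T2*
relaxometry, quantitative susceptibility mapping (QSM), inter-rater
segmentation metrics, probabilistic atlasing, center-of-mass location
analysis, and the correlation statistics that tie them together — plus a
synthetic multi-echo phantom cohort with known ground truth so the entire
chain can be validated end to end.

The package is aimed at researchers studying age-related change in deep
gray-matter nuclei (striatum, globus pallidus externa/interna, red
nucleus, subthalamic nucleus, substantia nigra, periaqueductal grey) with
ultra-high-field multi-echo gradient-echo data, and at anyone who needs a
tested, self-contained reference implementation of the standard
single-orientation QSM chain.

## The models

**Relaxometry.** Voxelwise nonlinear least squares for the
single-component decay

    S(TE) = S0 · e^(−TE/T2*)

initialized from the log-linear closed form, with T2* ∈ [0.1, 500] ms and
explicit convergence flags.

**QSM.** First-echo phase → field in ppm (phase unwrapping, region-growing
or Laplacian) → SHARP background removal (spherical-mean-value filtering
with truncated deconvolution) → thresholded k-space division by the unit
dipole kernel D(k) = 1/3 − k_z²/|k|² (δ floor on the zero cone) →
zero-referencing to the mean of the eroded lateral-ventricle conjunction
mask. Forward simulation and inversion share one kernel convention, so
phantom round trips are exact adjoints.

**Segmentation metrics.** Dice coefficient 2|A∩B|/(|A|+|B|) between two
raters, conjunction (intersection) masks as the analysis ROI, and
CSF-upper-thresholded ROI means for structures abutting ventricles.

**Location analysis.** Mask centroids in template mm; per-structure PCA of
(X, Y, Z) with left-hemisphere X mirrored to positive, first-component
scores as the latent location variable; Diedrichsen-style probabilistic
atlases with maximum and mean percentage overlap.

**Statistics.** Two-sided Pearson correlations of each outcome with
continuous age; partial correlations by double residualization (Dice and
ventricle-volume covariates), df = n − 2 − k; Bonferroni correction within
declared families (11 structures for Dice/volume, 7 nuclei otherwise);
two-sample Fisher r-to-z comparisons Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)
+ 1/(n₂−3)); OLS conditional-mean confidence bands.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Simulate the default 53-subject cohort (30 young / 14 middle-aged / 9
elderly) and run the complete analysis:

```python
from subqmri.phantom import default_spec
from subqmri.pipeline import PipelineConfig, run_pipeline

spec = default_spec(seed=11)
report = run_pipeline(PipelineConfig(spec=spec, seed=11))
t2 = report.correlations.query("family == 't2star_age'")
cols = ["structure", "r", "df", "t", "p_corrected", "significant"]
print(t2[cols].round(3).to_string(index=False))
```

```
structure      r  df       t  p_corrected  significant
      STR -0.717 103 -10.447        0.000         True
      GPe  0.857 103  16.864        0.000         True
      GPi  0.858 103  16.977        0.000         True
       RN -0.450 103  -5.117        0.000         True
      STN -0.204 103  -2.120        0.255        False
       SN  0.887 103  19.537        0.000         True
      PAG  0.178  50   1.277        1.000        False
```

Each row is the partial correlation (Dice covariate) between a nucleus's
CSF-thresholded ROI-mean T2* and age, across 106 hemisphere observations
(53 for the midline PAG), Bonferroni-corrected within the 7-nucleus
family. The phantom's generating age models make striatal and red-nucleus
T2* fall with age (iron accumulation shortens T2*) and pallidal/nigral T2*
rise, and the pipeline recovers exactly that pattern from the simulated
k-space-level signal; the subthalamic nucleus and PAG stay correctly
non-significant.

The same `report` object carries the group summary tables
(`report.group_tables`), probabilistic-atlas overlap (`report.atlas_metrics`),
location PCA scores and correlations (`report.pca_scores`,
`report.correlations`), and a provenance log; `report.write(out_dir)`
saves everything as CSV/JSON.

A command-line interface wraps the same functionality:

```bash
subqmri simulate --out cohort/ --seed 1        # NIfTI phantom cohort
subqmri fit-t2star --echoes e1.nii e2.nii e3.nii --te 11.22 20.39 29.57 --out fit/
subqmri qsm --phase p.nii --te 11.22 --mask brain.nii --lv-mask lv.nii --out qsm/
subqmri all --out results/ --seed 1            # simulate + full analysis
```

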