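# taskoverlap

Within-participant analysis of neural overlap between two block-design fMRI
tasks (arithmetic verification and visual rhyming judgment), implemented as a
fully tested, seed-deterministic pipeline with a synthetic-data generator
providing known ground truth for every stage.

## What it does

1. **Synthetic data** (`taskoverlap.synthetic`) — two-task block designs
   (TR = 1 s, 244 volumes/run, 30 s blocks, jittered inter-block fixation),
   voxel patterns with a requested cross-condition correlation structure,
   AR(1) + spatially smooth noise, injectable motion artifacts; cohorts of
   2 arithmetic + 2 rhyming runs per subject.
2. **First level** (`taskoverlap.firstlevel`) — ART-style outlier flagging
   (FD > 1.5 mm, |z(global)| > 4, 20% run-exclusion rule), HRF-convolved
   design matrices with motion/spike/drift nuisances, voxelwise OLS,
   `[Small + Large > PlusOne]` and `[Rhyme > LetterMatch]` contrasts,
   6 mm FWHM Gaussian smoothing for the univariate route.
3. **Conjunction** (`taskoverlap.conjunction`) — group one-sample t-maps,
   minimum-statistic conjunction at voxelwise p < 0.001, Monte-Carlo
   cluster-extent thresholding (smooth Gaussian null fields), cluster tables
   with peaks.
4. **Similarity** (`taskoverlap.similarity`) — ROI pattern extraction from
   unsmoothed fits, Pearson + Fisher similarities, Steiger's Z for the two
   dependent rhyme–arithmetic correlations, group t-tests with Dunn–Šidák
   correction.
5. **Cross-validated similarity** (`taskoverlap.crossval`) — shrinkage noise
   covariance from GLM residuals, multivariate noise normalization, and
   split-half (run-wise) cross-validated correlations with a meaningful zero
   baseline, plus group tests against 0.
6. **IO / CLI / pipeline** (`taskoverlap.io`, `taskoverlap.pipeline`,
   `taskoverlap.cli`) — NIfTI/TSV/JSON/YAML formats, config hashing,
   deterministic end-to-end orchestration.

## CLI

```bash
# materialize a synthetic cohort on disk (NIfTI + events/motion TSV + truth JSON)
taskoverlap simulate --subjects 8 --seed 1 --out cohort/

# outlier QC for one run
taskoverlap qc --bold cohort/sub-01/sub-01_task-arithmetic_run-1_bold.nii.gz \
               --motion cohort/sub-01/sub-01_task-arithmetic_run-1_motion.tsv \
               --out qc.json

# subject-level contrast maps
taskoverlap fit-first-level --data cohort/ --sub sub-01 --out firstlevel/

# full pipeline: simulate -> QC -> GLM -> conjunction -> RSA -> crossval RSA
taskoverlap run-all --seed 1 --out results/
```

`run-all` writes `cluster_table.csv`, `rsa_group.csv` (Steiger contrasts),
`crossval_group.csv` (cross-validated similarities), group t-maps, the
conjunction mask, the cluster-sim null distribution and a provenance JSON;
every table carries the config hash. A YAML config (`--config`) controls
cohort size, grid, noise, thresholds and seeds; see
`taskoverlap.io.PipelineConfig` for the fields.

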