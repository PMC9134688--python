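# myelinquant

Quantitative analysis of accelerated developmental myelination in the
neonatal rat brain, rebuilt as a reusable Python pipeline. The package is
aimed at preclinical imaging and assay scientists who want to run — or
stress-test on synthetic data with known ground truth — the full analysis
chain of a two-group (thyroxine vs vehicle) promyelination study:

1. **Diffusion tensor imaging.** Per-voxel log-linear least-squares fit of
   the single-tensor model `S_i = S0·exp(−b_i gᵢᵀ D gᵢ)` from masked DWI
   volumes (NIfTI + FSL `bvals`/`bvecs`), and the standard scalar maps:
   FA, MD, AD = λ₁, RD = (λ₂+λ₃)/2.
2. **Forebrain FA-histogram shift analysis.** Per-subject normalized
   100-bin FA histograms (bin width 0.01 on [0, 1]) summarized by fitting
   the three-parameter Burr type XII distribution
   `F(x) = 1 − (1 + (x/α)^c)^(−k)`; the fitted (c, k, α) give closed-form
   mode/mean/median, and the treated-vs-vehicle shift in medians is tested
   with Welch's *t*-test.
3. **Regional white-matter statistics.** Mean FA/RD/AD/MD over ten labeled
   white-matter structures, Student's *t* per region with the
   Benjamini–Krieger–Yekutieli two-stage adaptive FDR at q = 0.1, plus
   Fisher's exact test, two-way ANOVA (treatment × age) with Tukey's
   post-hoc comparisons, and Pearson correlation.
4. **MBP quantification.** ELISA back-quantification of myelin basic
   protein through a four-parameter logistic standard curve with
   assay-acceptance metrics (LLOQ, spike-and-recovery, dilution linearity,
   all judged against the 70–120 % band), and IHC percent-positive-area
   scoring of stained sections within a hemisphere mask.
5. **Synthetic-data generator.** Every input above can be simulated with
   known ground truth: two-group tensor phantoms (30 directions, b = 0 and
   970 s/mm², Rician noise, partial-volume background), a logistic
   developmental MBP curve, 4PL plates, stained sections with an exactly
   constructed positive fraction, and tooth-eruption tables.

## Worked example

Run the full synthetic study end to end (also available as
`myelinquant run-all --seed 1 --out study_out`):

```python
from myelinquant.pipeline import RunConfig, run_full_study

report = run_full_study(RunConfig(out_dir="study_out", seed=1))
print(report.report_text)
```

Excerpts of the report this prints:

```
## Forebrain FA histogram shift (Burr fits)
- T4: median mean 0.4722 ± SEM 0.0009 (n=6)
- vehicle: median mean 0.3805 ± SEM 0.0009 (n=6)
- Welch's t = 71.0297, df = 9.97, p = 8.167e-15

## MBP vs Burr-median correlation
- Pearson r = 0.5769, r^2 = 0.3328, p = 0.04954, n = 12

## Tooth eruption (Fisher's exact test)
- counts [[11, 0], [1, 10]], p = 3.402e-05
```

The treated group's Burr-fit medians sit ~0.09 FA units above the vehicle
group's because the phantom reduces tract radial diffusivity by 25 % in
the treated animals — the imaging signature of faster myelination. The
positive Pearson correlation links each pup's in-vivo FA median to its
brain MBP concentration measured at the same age, and the Fisher test
picks up the accelerated tooth eruption in the treated litter. All
intermediate artifacts (FA maps as NIfTI, per-stage CSV tables,
`report.md`) are written to `study_out/`; re-running with the same seed
reproduces them byte for byte.

Individual stages are exposed both as library functions
(`fit_tensor_volume`, `build_histogram`, `fit_burr`, `bky_fdr`,
`fit_standard_curve`, `percent_positive_area`, …) and as CLI subcommands
(`simulate`, `fit-dti`, `histogram`, `stats`, `mbp`, `report`, `run-all`).

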