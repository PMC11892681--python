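# msipd — MSI-guided tumour pharmacodynamics

`msipd` maps heterogeneous drug response in tumour tissue from mass
spectrometry imaging (MSI). Bulk pharmacodynamic assays (western blots,
LC/MS) average over a whole tumour; MSI records a full mass spectrum at
every ~50 µm pixel, so the same tissue section reveals *where* a drug
acts and which regions resist it. The package implements the complete
analysis chain for multi-batch MALDI/DESI studies:

1. **Preprocessing** — imzML I/O, interpolation rebinning onto a uniform
   m/z axis (default bin width 0.001 Da), per-pixel RMS normalisation
   (intensities scaled so √(mean(I²)) = 1), per-experiment mean spectra.
2. **Peak pipeline** — gradient peak detection on the mean spectrum
   (apex at a + → − sign change of the first difference, bounds at the
   flanking minima), per-pixel peak integration into ion images,
   accurate-mass annotation with polarity-specific adducts ([M−H]⁻,
   [M+Cl]⁻ / [M+H]⁺, [M+Na]⁺, [M+K]⁺) under nested inclusion/accuracy
   ppm windows, and selection of the consensus peaks present in *every*
   independent experiment.
3. **Response statistics** — per-tissue mean ion intensities, normalised
   to the average of the vehicle tissues of the same experiment and
   expressed as log2 fold change (batch factors cancel exactly, so
   independent runs pool), two-sided Welch t-tests or two-way ANOVA
   between arms, boxplot summaries (25/75% box, 1/99% whiskers).
4. **Segmentation** — per experiment, all pixels are embedded by t-SNE
   (with a seeded subsample fit and an out-of-sample map) and partitioned
   by k-means (k = 2). Clusters are matched across runs by the Pearson
   correlation of their metabolite signatures; the family dominant in
   vehicle tissue is named **Region A** (high-nucleotide, poorly
   responding), its complement **Region B** (treatment-enriched).
   Region fractions per arm and pixel-occupancy overlap between
   segmentations quantify the response.
5. **Cross-modal quantification** — a landmark least-squares affine maps
   MSI coordinates onto ~1 µm imaging mass cytometry (IMC); region
   labels transfer per IMC pixel; cells are segmented from the DNA
   channel with a nuclear/cytoplasm model (nuclear gate 20–571 µm²,
   ≤ 4 µm cytoplasm ring, ≤ 600 µm² cell) and protein markers (pS6,
   Ki67, GLUT1, CD31, collagen I) are quantified per region and arm.

Because public datasets of this design do not exist, the package ships a
first-class **synthetic study generator** (`msipd.synthetic`): seeded
multi-experiment phantoms with two latent metabolic regions per tissue,
arm-dependent region prevalence, a 50-ion panel with programmed region
and treatment effects, per-batch intensity scales, multiplicative
lognormal noise, a treated-arms-only drug ion, and IMC marker images
related to the MSI grid by a known affine — all with full ground truth,
so every stage of the pipeline can be scored exactly.

## Worked example

```python
from msipd import RunConfig, StudyConfig, run_pipeline
from msipd.segment import SegmentationConfig

cfg = RunConfig(
    outdir="demo_run", seed=7,
    study=StudyConfig(n_experiments=2, tissues_per_arm=2, grid_shape=(24, 24),
                      batch_log2_scale=(0.0, 0.6), seed=7),
    segmentation=SegmentationConfig(embed_method="passthrough"),
)
summary = run_pipeline(cfg)
```

prints (from `summary`):

```
consensus peaks: 50
annotations retained: 50
significant ions (p<0.05) vs vehicle: {'drugA': 50, 'drugB': 50, 'combo': 50}
Region-A fraction per arm (%): {'combo': 10.0, 'drugA': 30.0, 'drugB': 50.0, 'vehicle': 80.0}
re-segmentation overlap (%): {'exp1': 100.0, 'exp2': 100.0}
registration residual (um): {'exp1_vehicle_t1': '3.89e-11', ...}
```

Reading: all 50 programmed ions were detected in both experiments and
annotated by accurate mass; every ion separates treated arms from
vehicle at p < 0.05; the recovered Region-A tissue fraction reproduces
the programmed prevalence ordering (vehicle 80% > drugB 50% > drugA 30%
> combination 10%) — the hallmark of deeper pathway inhibition shrinking
the non-responding region; re-segmenting a two-arm subset reproduces the
same pixel labels (100% overlap); and the affine registration refits the
known MSI→IMC transform to sub-nanometre residual. The run directory
contains the full tables (`log2fc.csv`, `segmentation.csv`,
`region_marker_stats.csv`, `cells.csv`, `summary.json`).

The same pipeline runs from the shell:

```bash
msipd simulate --outdir study --seed 7        # write an imzML + TIFF study
msipd run config.yaml --outdir out --seed 7   # full analysis
```

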