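# Methods

This note records the models, conventions and numerical choices behind
`msipd`, and what the synthetic phantom does and does not emulate.

## Spectral model and preprocessing

A pixel's spectrum is a pair of equal-length arrays (strictly ascending
m/z, non-negative intensity). Preprocessing follows the order *rebin →
normalise → mean/integrate*:

- **Interpolation rebinning.** The uniform axis is sampled at grid
  nodes `low + i·w`, anchored at the dataset's `mass_range.low`
  (default bin width `w` = 0.001 Da). Values are linear interpolations
  of the input and exactly zero outside its support. Sampling at nodes
  (rather than bin midpoints) makes rebinning idempotent and leaves
  input points that fall on nodes unchanged.
- **RMS normalisation.** Each pixel is divided by √(mean(I²)) taken
  over the *full* rebinned axis, zeros included. The alternative
  (nonzero bins only) was rejected as unstable for sparse centroid
  data: its denominator depends on how many bins a peak happens to
  touch. Whether the original workflow normalised per pixel or per
  tissue-mean spectrum is ambiguous; per pixel is this package's
  choice. An all-zero pixel cannot be normalised and is excluded.
- **Mean spectrum.** Arithmetic pixel-wise mean over all pixels of all
  tissues of one experiment, on the shared axis.

Pipeline-scale runs rebin at 0.01 Da rather than 0.001 Da: the phantom's
peaks have σ = 0.02 Da, so 0.01 Da bins fully resolve them while the
70–1000 Da axis stays at ~93,000 nodes. The per-pixel chain is streamed
(`integrate_dataset_streaming`): window intensities are interpolated
directly at the window nodes and the full-axis RMS is evaluated in
closed form per linear segment, so dense per-pixel spectra are never
materialised; tests verify exact agreement with the explicit
rebin→normalise→integrate chain.

## Peak detection, annotation, consensus

An apex is a strict local maximum of the (normalised) experiment mean
spectrum — a + → − sign change of the first difference. Bounds extend
to the nearest − → + sign change or the support edge; when two peaks
share a valley node it is assigned to the earlier peak so integration
windows are disjoint. The apex floor defaults to 3× the median absolute
deviation of the spectrum; the pipeline uses 1% of the spectrum maximum,
which is robust when most of the axis is empty baseline (MAD = 0).

Annotation computes, for each peak centre and each adduct of the
polarity ([M−H]⁻ −1.007276, [M+Cl]⁻ +34.969402 in negative mode;
[M+H]⁺ +1.007276, [M+Na]⁺ +22.989218, [M+K]⁺ +38.963158 in positive
mode, all Da), the ppm error against each database neutral mass. Two
nested filters apply: an inclusion window for candidate search and a
tighter accuracy window for retention (defaults 300/70 ppm for MALDI
negative, 10/10 ppm for DESI positive). Annotation is monotone:
shrinking the accuracy window never adds assignments.

Consensus selection chains peaks across experiments by nearest-neighbour
matching within `match_ppm` (default 300 ppm for MALDI-scale axes),
anchored on the first table; a consensus peak requires exactly one
member per experiment, and a table with two centres closer than the
tolerance is rejected as ambiguous. The consensus m/z is the unweighted
mean of the member centres (experiments are equal replicates). Each
experiment's pixels are integrated against *its own* member bounds, with
columns named by consensus m/z so experiments align.

## Fold-change statistics

The statistical unit is the tissue. Per-tissue mean intensities are
divided by the mean over the same experiment's vehicle tissues, then
log2-transformed. Two consequences are load-bearing:

- the plain ratios of each experiment's vehicle tissues average exactly
  1 by construction, and
- any global per-experiment scale factor cancels exactly, which is what
  makes tissues from independent runs poolable (verified to 0 shift
  under an 8× batch scaling).

Arm comparisons pool tissues across experiments (within-experiment
testing is a selectable alternative) and default to the two-sided Welch
t-test; the equal-variance Student variant and a two-way ANOVA (type-II
sums of squares, factors arm and experiment, no interaction — per-cell
n is small by design) are available. No multiplicity correction is
applied by default; Benjamini–Hochberg is available but off. Two
degenerate conventions: identical zero-variance groups return t = 0,
p = 1 (no evidence against the null), and peaks excluded for a zero
vehicle mean return NaN rather than erroring. Boxplot summaries use
linearly interpolated percentiles: 25/75% box, 1/99% whiskers, median,
and per-tissue points tagged by experiment.

## Segmentation and region matching

All pixels of one experiment (every arm, every tissue) are pooled. The
input is the consensus peak matrix, per-peak z-scored within the
experiment so high-abundance ions do not dominate distances. Drug-ion
columns are excluded: a compound present only in treated tissues is a
treatment label in disguise and would let the clustering split by arm
instead of by metabolic region.

The embedding contract is "neighbourhood-preserving with an
out-of-sample map": the reference implementation fits t-SNE
(Barnes–Hut, seeded, PCA initialisation) on at most
`max_pixels_for_fit` seeded-uniformly sampled pixels (50,000 by default;
3,000 in the pipeline configuration) and places remaining pixels at the
embedding of their nearest fitted neighbour in feature space. A
`passthrough` method returns the standardised matrix itself and is used
for oracle tests. k-means uses k-means++ with 10 seeded restarts, best
inertia kept; k = 2 throughout (choosing k is out of scope).

Cluster integer labels are arbitrary per run, so clusters are matched
across experiments by maximising the total Pearson correlation of their
signatures (per-cluster means of the z-scored matrix; optimal
assignment). A correlation tie within 1e-9 raises — more peaks are
needed. The matched family holding the larger pixel share of the
vehicle-arm tissues is named Region A; for k = 2 the naming is a
bijection. Region fractions are percentages of a tissue's retained
pixels; segmentation overlap is the percentage of shared pixels with
the same region on both maps, computed on the intersection of pixel
sets, with region names compared by sorted rank (so an A/B map is
directly comparable with a C/D map).

## MSI → IMC registration and the cell model

The transform is a full planar affine `x_imc = A·x_msi + t` (µm on both
sides), fitted by least squares from ≥ 3 non-collinear landmark pairs;
the residual report carries per-landmark errors. Coordinate conventions
are explicit to avoid half-pixel drift: an MSI pixel with index (i, j)
owns the square `[i·p, (i+1)·p) × [j·p, (j+1)·p)`; an IMC pixel centre
sits at `(i + 0.5)·p`. Label transfer sends each IMC pixel centre
through the inverse affine and floors to an MSI index; centres outside
the MSI footprint are "unassigned".

Cells are a simplified open nuclear/cytoplasm model: nuclei are
connected components of the thresholded DNA channel gated to
20–571 µm²; cytoplasm is every pixel within 4 µm of its *nearest*
nucleus (Euclidean distance transform, which yields the equidistant
partition between neighbours); cells exceeding 600 µm² keep only their
nearest pixels. The gates are hard postconditions. Per region, both
pixel-level marker means (over all labelled pixels) and cell-level
means (over per-cell means, cells assigned by nucleus centroid) are
emitted, since either reading of "intensity per region" is defensible;
cells whose centroid lands on an unassigned pixel are excluded and
counted. Positive-cell calls use per-marker thresholds supplied in
configuration (thresholds are a tuning choice, not a derived quantity).

## The synthetic study generator

The phantom emulates a three-batch preclinical study: arms vehicle,
drugA (an mTORC1/2-inhibitor analogue), drugB (a PI3Kβ-inhibitor
analogue) and their combination; two tissues per arm; 64×64 pixel grids
at 50 µm pitch; mass range 70–1000 Da, negative polarity.

- **Regions.** Each tissue holds a latent binary field: Region A
  (high-nucleotide, poorly responding) vs Region B (responding).
  Fields are Gaussian-smoothed white noise (σ = 4 px) rank-thresholded
  so the Region-A pixel count matches the arm's programmed prevalence
  exactly (±1 pixel): vehicle 0.8, drugA 0.3, drugB 0.5, combo 0.1 —
  deeper pathway inhibition shrinks the non-responding region.
- **Panel.** 50 ions as [M−H]⁻ adducts: six nucleotides high in Region
  A (region effects +1.2 to +1.6 log2, small direct treatment shifts of
  −0.25 to −0.6), six carnitines raised tissue-wide by treatment (+0.6
  to +1.2) with mild negative region effects, six region-structural
  ions (±0.9 to 1.2), null fillers, and one drug ion. Treatment shifts
  are deliberately modest relative to the regional contrast: the
  emulated phenomenon is two dominant metabolite-defined tissue
  classes, with treated tumours differing mainly through the prevalence
  of the responding class; the bulk nucleotide fold change therefore
  emerges mostly from the region mixture.
- **Intensities.** log2 amplitude = baseline + per-experiment batch
  scale + region effect + treatment shift; linear amplitude is
  multiplied by mean-one lognormal noise with CV = 0.2 (intensities are
  positive and heteroscedastic). Peak positions get 2 ppm Gaussian
  jitter. Peaks render as 7-sample Gaussians (σ = 0.02 Da) with
  flanking zero anchors so interpolation rebinning and gradient
  detection behave as on profile data; a centroid mode (one point per
  ion) exists for exact closed-form tests.
- **Drug ion.** Spatially uniform, present in treated arms; vehicle
  tissues carry a trace background 2⁻¹⁰ of the treated level so the
  vehicle-referenced fold change stays finite (expected +10 log2).
- **Ground-truth fold changes.** The emitted `true_log2fc` is the
  closed-form expectation of the quantity the pipeline estimates,
  including both the region-prevalence mixture and the per-region RMS
  coupling (normalisation divides every ion by the whole-spectrum RMS,
  so a shift in one block perturbs all normalised channels). An
  unnormalised closed form is kept for the exact zero-noise path.
- **IMC.** For the first tissue of each arm of experiment 1, a 600 µm
  field of view is placed over the window with the most balanced A/B
  mix (fields of view cover representative areas of both regions — a
  random window in a 10%-prevalence arm could miss Region A entirely).
  The per-tissue MSI→IMC affine composes a base transform (2° rotation,
  small translation) with that window origin; noiseless landmark pairs
  are emitted alongside. Nuclei are non-overlapping disks (radius 3–5
  µm, inside the nuclear gate); marker channels take programmed
  region/arm means inside cells plus Gaussian noise (σ = 0.1):
  pS6 drops in both regions under treatment, Ki67 and GLUT1 drop only
  in Region B and stay high in resistant Region A, CD31 and collagen I
  differ by region independent of treatment. Note that measured
  cell-level means sit below the programmed in-cell values because the
  4 µm cytoplasm ring overlaps background; direction checks compare
  treated against vehicle, which cancels the dilution.
- **Determinism.** Every tissue derives its generator from the master
  seed via `SeedSequence` spawn keys, so studies are bit-for-bit
  reproducible and independent of generation order, and any subset of
  the design regenerates identically.

What the phantom does *not* emulate: real histology, isotope envelopes,
matrix/ablation artefacts, spatially correlated noise, mass-drift
between runs beyond a global ppm jitter, 3-D structure, or cell-shape
variation. Recovery results on the phantom therefore demonstrate the
correctness and calibration of the pipeline's arithmetic and matching
logic — not robustness to every artefact of real acquisitions.

## Numerical and design notes

- Problem sizes: the default recovery analyses use the full 3×4×2
  study (98,304 pixels); the zero-noise exactness check uses 24×24
  grids and the IMC pattern check a one-experiment 16×16 study —
  exactness and direction checks are scale-free.
- The t-test calibration simulates 2,000 null endpoints with 12 tissues
  per arm, a size at which the Welch test attains its nominal level
  (at 6 per arm it is visibly conservative).
- t-SNE determinism holds for fixed seed and single-threaded runs;
  k-means ties are broken by restart order under a fixed seed.
- The pipeline summary is a flat JSON document validated against a
  shipped schema (seven stage blocks plus the seed); every stage output
  is a pure function of (inputs, config, seed), with per-stage seeds
  fanned out from the master seed by `SeedSequence` spawn keys.
- Known limitations: greedy consensus matching is anchor-order
  dependent in pathological near-tolerance configurations (the
  ambiguity check rejects these); `rms_normalise` on centroid-mode data
  depends on the bin count of the chosen axis; per-region cell counts
  become unstable when a region occupies only a few fields of view —
  the ROI placement mitigates but cannot eliminate this at extreme
  prevalences.
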