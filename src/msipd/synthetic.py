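"""Seeded multi-experiment MSI + IMC phantom studies with full ground truth.

The generator emulates a preclinical pharmacodynamic imaging study:
several independent experiments (batches), each with vehicle, two single
drugs and their combination, two latent metabolic tissue regions per
tumour whose prevalence depends on the arm, a metabolite panel with
region- and treatment-specific log2 effects plus per-experiment batch
scale and multiplicative lognormal noise, a drug ion present only in
treated tissues, and multichannel IMC marker images tied to the MSI grid
by a known affine transform.  Every latent quantity is emitted as ground
truth so downstream recoveries can be scored exactly.

Determinism: every tissue derives its own generator from the master seed
via ``numpy.random.SeedSequence`` spawn keys, so outputs are bit-for-bit
reproducible and independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .crossmodal import AffineTransform2D
from .masses import adduct_mz
from .msi_io import MSIDataset, Spectrum, write_imzml

VEHICLE = "vehicle"


@dataclass
class MetaboliteSpec:
    name: str
    neutral_mass: float
    adduct: str = "[M-H]-"
    baseline_log2: float = 5.0
    region_effect_log2: float = 0.0  # Region A minus Region B
    treatment_effect_log2: dict[str, float] = field(default_factory=dict)
    is_drug_ion: bool = False

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral_mass must be > 0")
        if self.is_drug_ion and self.region_effect_log2 != 0:
            raise ValueError("a drug ion must have region_effect_log2 = 0")

    @property
    def mz(self) -> float:
        return adduct_mz(self.neutral_mass, self.adduct)


def default_panel(n_metabolites: int = 50) -> list[MetaboliteSpec]:
    """The default 50-ion panel.

    A nucleotide-like block is high in Region A and depleted by treatment,
    a carnitine-like block rises under treatment, structural ions differ
    by region only, and one drug ion appears only in treated tissues.
    Up- and down-regulated blocks are balanced so whole-spectrum RMS
    normalisation stays comparable across arms.
    """
    # Tissue-wide treatment shifts are kept modest relative to the regional
    # contrast: the dominant axis of variation is the two metabolic tissue
    # classes, and treated tumours differ mainly through the prevalence of
    # the responding region (the bulk nucleotide fold change emerges from
    # the region mixture, with only a small direct pathway shift on top).
    down = {"drugA": -0.4, "drugB": -0.25, "combo": -0.6}
    up = {"drugA": 0.9, "drugB": 0.6, "combo": 1.2}
    named: list[MetaboliteSpec] = [
        # nucleotides: dominant in Region A, mildly reduced by treatment
        MetaboliteSpec("ATP", 506.9957, baseline_log2=6.0, region_effect_log2=1.6, treatment_effect_log2=dict(down)),
        MetaboliteSpec("ADP", 427.0294, baseline_log2=5.8, region_effect_log2=1.4, treatment_effect_log2=dict(down)),
        MetaboliteSpec("AMP", 347.0631, baseline_log2=5.6, region_effect_log2=1.2),
        MetaboliteSpec("UTP", 483.9685, baseline_log2=5.4, region_effect_log2=1.5, treatment_effect_log2=dict(down)),
        MetaboliteSpec("UDP", 404.0022, baseline_log2=5.2, region_effect_log2=1.3, treatment_effect_log2=dict(down)),
        MetaboliteSpec("GTP", 522.9907, baseline_log2=5.0, region_effect_log2=1.4, treatment_effect_log2=dict(down)),
        # carnitines: increase on treatment, mild region contrast
        MetaboliteSpec("carnitine", 161.1052, baseline_log2=5.9, region_effect_log2=-0.5, treatment_effect_log2=dict(up)),
        MetaboliteSpec("acetylcarnitine", 203.1158, baseline_log2=5.7, region_effect_log2=-0.6, treatment_effect_log2=dict(up)),
        MetaboliteSpec("propionylcarnitine", 217.1314, baseline_log2=5.5, region_effect_log2=-0.4, treatment_effect_log2=dict(up)),
        MetaboliteSpec("butyrylcarnitine", 231.1471, baseline_log2=5.3, region_effect_log2=-0.6, treatment_effect_log2=dict(up)),
        MetaboliteSpec("hexanoylcarnitine", 259.1784, baseline_log2=5.1, region_effect_log2=-0.5, treatment_effect_log2=dict(up)),
        MetaboliteSpec("palmitoylcarnitine", 399.3349, baseline_log2=4.9, region_effect_log2=-0.6, treatment_effect_log2=dict(up)),
        # region-structural ions, treatment-independent
        MetaboliteSpec("glucose", 180.0634, baseline_log2=5.8, region_effect_log2=1.1),
        MetaboliteSpec("lactate", 90.0317, baseline_log2=6.1, region_effect_log2=-1.2),
        MetaboliteSpec("glutamate", 147.0532, baseline_log2=5.6, region_effect_log2=0.9),
        MetaboliteSpec("taurine", 125.0147, baseline_log2=5.4, region_effect_log2=-1.1),
        MetaboliteSpec("succinate", 118.0266, baseline_log2=5.2, region_effect_log2=1.0),
        MetaboliteSpec("malate", 134.0215, baseline_log2=5.0, region_effect_log2=-0.9),
        # drug ion, treated arms only, spatially uniform
        MetaboliteSpec("drug_compound", 462.2379, baseline_log2=4.5, is_drug_ion=True),
    ]
    fillers = []
    n_fill = max(0, n_metabolites - len(named))
    masses = np.linspace(270.05, 950.05, n_fill) if n_fill else []
    for i, m in enumerate(masses):
        fillers.append(
            MetaboliteSpec(
                name=f"met_{i:03d}",
                neutral_mass=round(float(m), 4),
                baseline_log2=4.6 + 0.9 * ((i * 2654435761) % 97) / 97.0,
            )
        )
    return named + fillers


@dataclass
class StudyConfig:
    n_experiments: int = 3
    arms: tuple[str, ...] = (VEHICLE, "drugA", "drugB", "combo")
    tissues_per_arm: int = 2
    grid_shape: tuple[int, int] = (64, 64)  # (rows, cols)
    msi_pixel_pitch: float = 50.0
    imc_pixel_pitch: float = 1.0
    metabolite_panel: list[MetaboliteSpec] = field(default_factory=default_panel)
    batch_log2_scale: tuple[float, ...] = (0.0, 0.6, -0.5)
    noise_cv: float = 0.2
    mz_jitter_ppm: float = 2.0
    region_prevalence: dict[str, float] = field(
        default_factory=lambda: {VEHICLE: 0.8, "drugA": 0.3, "drugB": 0.5, "combo": 0.1}
    )
    region_smoothness: float = 4.0  # gaussian sigma, pixels
    peak_sigma_da: float = 0.02
    mass_range: tuple[float, float] = (70.0, 1000.0)
    polarity: str = "negative"
    modality: str = "MALDI"
    profile_points: int = 7  # samples across each rendered peak (0 = centroid mode)
    imc_roi_um: float = 600.0
    imc_cell_density: float = 6e-4  # nuclei per um^2
    imc_marker_noise_sd: float = 0.1
    imc_affine: AffineTransform2D = field(
        default_factory=lambda: AffineTransform2D.from_params(
            rotation_deg=2.0, translation=(-40.0, -25.0)
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if min(self.grid_shape) <= 0:
            raise ValueError("grid_shape must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for arm, p in self.region_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"region_prevalence[{arm!r}] must be in [0, 1]")
        if len(self.batch_log2_scale) < self.n_experiments:
            raise ValueError("need one batch_log2_scale per experiment")

    def experiment_ids(self) -> list[str]:
        return [f"exp{i + 1}" for i in range(self.n_experiments)]


def _tissue_rng(master_seed: int, *spawn_key: int) -> np.random.Generator:
    """Stable per-tissue generator: spawn-keyed SeedSequence off the master seed."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=spawn_key))


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def generate_tissue_regions(
    grid_shape: tuple[int, int],
    prevalence: float,
    smoothness: float = 4.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Spatially coherent binary region field (True = Region A).

    A Gaussian-smoothed white-noise field is rank-thresholded so that
    exactly ``round(prevalence * n_pixels)`` pixels fall in Region A
    (quantile thresholding up to single-pixel quantisation).
    """
    rows, cols = grid_shape
    if rows <= 0 or cols <= 0:
        raise ValueError("grid_shape must be positive")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = ndi.gaussian_filter(rng.standard_normal(grid_shape), sigma=smoothness)
    n = rows * cols
    k = int(round(prevalence * n))
    if k == 0:
        return np.zeros(grid_shape, dtype=bool)
    if k == n:
        return np.ones(grid_shape, dtype=bool)
    thresh = np.partition(f.ravel(), n - k)[n - k]
    field_a = f >= thresh
    # exact count under ties (measure zero for continuous fields, but be safe)
    if field_a.sum() != k:
        order = np.argsort(f.ravel(), kind="stable")
        field_a = np.zeros(n, dtype=bool)
        field_a[order[n - k :]] = True
        field_a = field_a.reshape(grid_shape)
    return field_a


# ---------------------------------------------------------------------------
# MSI
# ---------------------------------------------------------------------------

#: log2 offset of a drug ion's vehicle-arm background below its treated level
#: (a noise-floor trace keeps the vehicle-referenced fold change finite)
DRUG_BACKGROUND_LOG2_OFFSET = -10.0


def programmed_log2_intensity(
    config: StudyConfig, experiment_idx: int, arm: str, in_region_a: bool, spec: MetaboliteSpec
) -> float:
    """Closed-form noise-free log2 peak amplitude for one pixel.

    A drug ion in the vehicle arm sits at a trace background
    ``DRUG_BACKGROUND_LOG2_OFFSET`` below its treated level.
    """
    if spec.is_drug_ion and arm == VEHICLE:
        return spec.baseline_log2 + config.batch_log2_scale[experiment_idx] + DRUG_BACKGROUND_LOG2_OFFSET
    return (
        spec.baseline_log2
        + config.batch_log2_scale[experiment_idx]
        + (spec.region_effect_log2 if in_region_a else 0.0)
        + spec.treatment_effect_log2.get(arm, 0.0)
    )


def _amplitude_table(config: StudyConfig, arm: str) -> np.ndarray:
    """Noise-free linear peak amplitudes, shape (2 regions [B, A], n_panel),
    batch factor omitted (it cancels in every normalised or vehicle-referenced
    quantity)."""
    amps = np.empty((2, len(config.metabolite_panel)))
    for j, spec in enumerate(config.metabolite_panel):
        for r, in_a in enumerate((False, True)):
            amps[r, j] = 2.0 ** programmed_log2_intensity(config, 0, arm, in_a, spec) / (
                2.0 ** config.batch_log2_scale[0]
            )
    return amps


def expected_log2fc(
    config: StudyConfig, spec: MetaboliteSpec, arm: str, normalised: bool = True
) -> float:
    """Closed-form expected log2 fold change of the tissue mean vs vehicle.

    Tissue means are arithmetic means over pixels, so the two-region
    mixture enters through the arm's Region-A prevalence.  With
    ``normalised`` (the workflow default) each pixel is divided by its
    whole-spectrum RMS before averaging, which couples the panel: the
    per-region RMS ``sqrt(sum_k amp_k^2)`` enters the expectation.
    Without normalisation the expression reduces to
    ``t_arm + log2((p_a*2^r + 1-p_a) / (p_v*2^r + 1-p_v))``.
    """
    names = [s.name for s in config.metabolite_panel]
    j = names.index(spec.name)
    p = {a: config.region_prevalence[a] for a in (arm, VEHICLE)}

    def tissue_mean(a: str) -> float:
        amps = _amplitude_table(config, a)
        if normalised:
            r_b, r_a = np.sqrt(np.sum(amps**2, axis=1))
            return p[a] * amps[1, j] / r_a + (1 - p[a]) * amps[0, j] / r_b
        return p[a] * amps[1, j] + (1 - p[a]) * amps[0, j]

    return float(np.log2(tissue_mean(arm) / tissue_mean(VEHICLE)))


def generate_msi_dataset(
    config: StudyConfig,
    experiment_idx: int,
    arm: str,
    region_field: np.ndarray,
    rng: np.random.Generator,
    tissue_id: str = "",
) -> MSIDataset:
    """One tissue's MSI dataset on the study grid.

    Peak amplitude per pixel is ``2**programmed_log2_intensity`` times
    mean-one multiplicative lognormal noise of coefficient of variation
    ``noise_cv``; peak positions get ppm-scale jitter.  With
    ``profile_points > 0`` each peak is rendered as a narrow Gaussian
    (with flanking zero anchors) so interpolation rebinning and gradient
    detection behave as on profile data; ``profile_points = 0`` emits one
    centroid point per metabolite.
    """
    rows, cols = region_field.shape
    panel = config.metabolite_panel
    mzs = np.array([spec.mz for spec in panel])
    lo, hi = config.mass_range
    if np.any((mzs < lo) | (mzs > hi)):
        raise ValueError("metabolite adduct m/z outside the study mass_range")
    n_px = rows * cols
    in_a = region_field.ravel()
    log2_a = np.array(
        [programmed_log2_intensity(config, experiment_idx, arm, True, s) for s in panel]
    )
    log2_b = np.array(
        [programmed_log2_intensity(config, experiment_idx, arm, False, s) for s in panel]
    )
    base = np.where(in_a[:, None], log2_a[None, :], log2_b[None, :])  # (px, met)
    amp = np.exp2(base)
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=amp.shape))
        amp = amp * noise
    if config.mz_jitter_ppm > 0:
        jitter = 1.0 + rng.normal(0.0, config.mz_jitter_ppm * 1e-6, size=amp.shape)
        centres = mzs[None, :] * jitter
    else:
        centres = np.broadcast_to(mzs[None, :], amp.shape)
    npts = config.profile_points
    if npts > 0:
        s = config.peak_sigma_da
        offs = np.linspace(-3 * s, 3 * s, npts)
        shape = np.exp(-(offs**2) / (2 * s**2))
        pts_mz = centres[:, :, None] + np.concatenate(([-4 * s], offs, [4 * s]))
        zero_mask = np.zeros(npts + 2)
        zero_mask[1:-1] = shape
        pts_int = amp[:, :, None] * zero_mask
    else:
        pts_mz = centres[:, :, None]
        pts_int = amp[:, :, None]
    pixels = [(x, y) for y in range(rows) for x in range(cols)]
    spectra = []
    for i in range(n_px):
        finite = np.isfinite(pts_int[i].ravel())
        mz_i = pts_mz[i].ravel()[finite]
        int_i = pts_int[i].ravel()[finite]
        order = np.argsort(mz_i, kind="stable")
        spectra.append(Spectrum(mz_i[order], int_i[order]))
    return MSIDataset(
        pixels=pixels,
        spectra=spectra,
        pixel_pitch=config.msi_pixel_pitch,
        polarity=config.polarity,
        modality=config.modality,
        tissue_id=tissue_id,
        experiment_id=config.experiment_ids()[experiment_idx],
        arm=arm,
        mass_range=config.mass_range,
    )


# ---------------------------------------------------------------------------
# IMC
# ---------------------------------------------------------------------------

def default_marker_rules(arms: tuple[str, ...] = (VEHICLE, "drugA", "drugB", "combo")) -> dict:
    """Programmed per-marker, per-arm, per-region mean intensities.

    Encodes the pharmacodynamic pattern: pS6 falls in both regions under
    treatment (pathway suppression everywhere); Ki67 and GLUT1 fall only
    in Region B while staying high in resistant Region A; CD31 and
    collagen I differ by region but ignore treatment.
    """
    treated = [a for a in arms if a != VEHICLE]
    rules: dict[str, dict[str, dict[str, float]]] = {
        "pS6": {VEHICLE: {"A": 10.0, "B": 10.0}, **{a: {"A": 3.0, "B": 3.0} for a in treated}},
        "Ki67": {VEHICLE: {"A": 9.0, "B": 9.0}, **{a: {"A": 9.0, "B": 2.5} for a in treated}},
        "GLUT1": {VEHICLE: {"A": 10.0, "B": 9.0}, **{a: {"A": 10.0, "B": 2.0} for a in treated}},
        "CD31": {a: {"A": 3.0, "B": 7.0} for a in arms},
        "collagen1": {a: {"A": 2.0, "B": 6.0} for a in arms},
    }
    return rules


def generate_imc_images(
    region_field: np.ndarray,
    affine_true: AffineTransform2D,
    marker_rules: dict,
    arm: str,
    cell_density: float = 6e-4,
    rng: np.random.Generator | None = None,
    msi_pixel_pitch: float = 50.0,
    imc_pixel_pitch: float = 1.0,
    roi_um: float = 600.0,
    marker_noise_sd: float = 0.0,
    nucleus_radius_um: tuple[float, float] = (3.0, 5.0),
    background: float = 0.02,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Multichannel IMC phantom for one tissue ROI plus cell ground truth.

    The ROI covers [0, roi_um)^2 of the IMC frame; the MSI region under
    each IMC pixel is looked up through the inverse of ``affine_true``.
    The DNA channel holds disk nuclei (radii drawn from
    ``nucleus_radius_um``, areas within the 20-571 um^2 gate); marker
    channels take their programmed region/arm mean inside cells.  Raises
    if the requested density cannot be placed without overlaps.
    """
    rng = rng or np.random.default_rng(0)
    n_px = int(round(roi_um / imc_pixel_pitch))
    inv = affine_true.inverse()
    cc, rr = np.meshgrid(np.arange(n_px), np.arange(n_px))
    centres = np.column_stack(
        [(cc.ravel() + 0.5) * imc_pixel_pitch, (rr.ravel() + 0.5) * imc_pixel_pitch]
    )
    msi_um = inv.apply(centres)
    ix = np.clip(np.floor(msi_um[:, 0] / msi_pixel_pitch).astype(int), 0, region_field.shape[1] - 1)
    iy = np.clip(np.floor(msi_um[:, 1] / msi_pixel_pitch).astype(int), 0, region_field.shape[0] - 1)
    region_img = np.where(region_field[iy, ix], 1, 0).reshape(n_px, n_px)  # 1=A, 0=B

    n_cells = int(round(cell_density * roi_um**2))
    r_lo, r_hi = nucleus_radius_um
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = max(1000, 200 * n_cells)
    margin = r_hi + 5.0
    while len(placed) < n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"cell density {cell_density} exceeds the packing limit for roi {roi_um} um"
            )
        x = rng.uniform(margin, roi_um - margin)
        y = rng.uniform(margin, roi_um - margin)
        r = rng.uniform(r_lo, r_hi)
        if all((x - px) ** 2 + (y - py) ** 2 > (r + pr + 9.0) ** 2 for px, py, pr in placed):
            placed.append((x, y, r))

    dna = np.full((n_px, n_px), background, dtype=np.float32)
    cell_mask = np.zeros((n_px, n_px), dtype=bool)
    records = []
    yy, xx = np.meshgrid(
        (np.arange(n_px) + 0.5) * imc_pixel_pitch,
        (np.arange(n_px) + 0.5) * imc_pixel_pitch,
        indexing="ij",
    )
    for cid, (x, y, r) in enumerate(placed, start=1):
        d2 = (xx - x) ** 2 + (yy - y) ** 2
        nucleus = d2 <= r**2
        dna[nucleus] = 1.0
        cell = d2 <= (r + 2.0) ** 2
        cell_mask |= cell
        ry, rx = int(y / imc_pixel_pitch), int(x / imc_pixel_pitch)
        records.append(
            dict(
                cell_id=cid,
                x_um=x,
                y_um=y,
                radius_um=r,
                region="A" if region_img[ry, rx] == 1 else "B",
            )
        )
    images: dict[str, np.ndarray] = {"DNA": dna}
    for marker, per_arm in marker_rules.items():
        means = per_arm[arm]
        img = np.full((n_px, n_px), background, dtype=np.float32)
        vals = np.where(region_img == 1, means["A"], means["B"])
        img[cell_mask] = vals[cell_mask]
        if marker_noise_sd > 0:
            img = img + rng.normal(0.0, marker_noise_sd, size=img.shape).astype(np.float32)
            img = np.clip(img, 0.0, None)
        images[marker] = img.astype(np.float32)
    return images, pd.DataFrame.from_records(
        records, columns=["cell_id", "x_um", "y_um", "radius_um", "region"]
    )


def representative_roi_origin(
    region_field: np.ndarray, msi_pixel_pitch: float, roi_um: float
) -> tuple[float, float]:
    """MSI-frame origin (um) of the ROI window with the most balanced mix of
    the two regions — IMC fields of view are placed over representative
    areas of both tissue classes."""
    rows, cols = region_field.shape
    w = max(1, int(round(roi_um / msi_pixel_pitch)))
    if w >= rows or w >= cols:
        return (0.0, 0.0)
    f = region_field.astype(float)
    csum = np.cumsum(np.cumsum(np.pad(f, ((1, 0), (1, 0))), axis=0), axis=1)
    window = (
        csum[w:, w:] - csum[:-w, w:] - csum[w:, :-w] + csum[:-w, :-w]
    ) / (w * w)
    r, c = np.unravel_index(np.argmin(np.abs(window - 0.5)), window.shape)
    return (c * msi_pixel_pitch, r * msi_pixel_pitch)


def tissue_affine(
    base: AffineTransform2D, roi_origin_um: tuple[float, float]
) -> AffineTransform2D:
    """Per-tissue MSI->IMC affine: the base transform applied to coordinates
    relative to the tissue's ROI origin, so the IMC frame covers the ROI."""
    ox, oy = roi_origin_um
    return AffineTransform2D(base.A, base.t - base.A @ np.array([ox, oy]))


def generate_landmarks(
    affine_true: AffineTransform2D,
    extent_um: float,
    n: int = 8,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Noiseless fiducial pairs relating the MSI and IMC frames."""
    rng = rng or np.random.default_rng(0)
    msi = rng.uniform(0.0, extent_um, size=(n, 2))
    imc = affine_true.apply(msi)
    return pd.DataFrame(
        dict(x_msi_um=msi[:, 0], y_msi_um=msi[:, 1], x_imc_um=imc[:, 0], y_imc_um=imc[:, 1])
    )


# ---------------------------------------------------------------------------
# Whole study
# ---------------------------------------------------------------------------

@dataclass
class TissueData:
    tissue_id: str
    experiment_id: str
    arm: str
    region_field: np.ndarray
    dataset: MSIDataset
    imc_images: dict[str, np.ndarray] | None = None
    imc_cells: pd.DataFrame | None = None
    landmarks: pd.DataFrame | None = None


@dataclass
class GroundTruth:
    region_fields: dict[str, np.ndarray]  # tissue_id -> bool field (True = A)
    true_log2fc: pd.DataFrame  # metabolite x arm
    affine_true: dict[str, AffineTransform2D]  # per IMC tissue
    marker_rules: dict
    cell_tables: dict[str, pd.DataFrame]

    def region_a_fraction(self, tissue_id: str) -> float:
        f = self.region_fields[tissue_id]
        return float(f.mean())


@dataclass
class Study:
    config: StudyConfig
    tissues: list[TissueData]
    ground_truth: GroundTruth

    def datasets(self, experiment_id: str | None = None) -> list[MSIDataset]:
        return [
            t.dataset
            for t in self.tissues
            if experiment_id is None or t.experiment_id == experiment_id
        ]


def generate_study_in_memory(config: StudyConfig, imc: bool = True) -> Study:
    """Generate the full study without touching disk."""
    tissues: list[TissueData] = []
    region_fields: dict[str, np.ndarray] = {}
    cell_tables: dict[str, pd.DataFrame] = {}
    affines: dict[str, AffineTransform2D] = {}
    marker_rules = default_marker_rules(config.arms)
    for e in range(config.n_experiments):
        eid = config.experiment_ids()[e]
        for a, arm in enumerate(config.arms):
            for t in range(config.tissues_per_arm):
                tissue_id = f"{eid}_{arm}_t{t + 1}"
                rng = _tissue_rng(config.seed, e, a, t)
                field_a = generate_tissue_regions(
                    config.grid_shape,
                    config.region_prevalence[arm],
                    config.region_smoothness,
                    rng,
                )
                ds = generate_msi_dataset(config, e, arm, field_a, rng, tissue_id)
                td = TissueData(tissue_id, eid, arm, field_a, ds)
                # IMC on the first tissue of each arm of the first experiment,
                # with the field of view over a representative mix of regions
                if imc and e == 0 and t == 0:
                    origin = representative_roi_origin(
                        field_a, config.msi_pixel_pitch, config.imc_roi_um
                    )
                    affine = tissue_affine(config.imc_affine, origin)
                    images, cells = generate_imc_images(
                        field_a,
                        affine,
                        marker_rules,
                        arm,
                        cell_density=config.imc_cell_density,
                        rng=rng,
                        msi_pixel_pitch=config.msi_pixel_pitch,
                        imc_pixel_pitch=config.imc_pixel_pitch,
                        roi_um=config.imc_roi_um,
                        marker_noise_sd=config.imc_marker_noise_sd,
                    )
                    td.imc_images = images
                    td.imc_cells = cells
                    td.landmarks = generate_landmarks(
                        affine,
                        extent_um=config.grid_shape[1] * config.msi_pixel_pitch,
                        rng=rng,
                    )
                    cell_tables[tissue_id] = cells
                    affines[tissue_id] = affine
                tissues.append(td)
                region_fields[tissue_id] = field_a
    fc = pd.DataFrame(
        {
            arm: [expected_log2fc(config, s, arm) for s in config.metabolite_panel]
            for arm in config.arms
        },
        index=[s.name for s in config.metabolite_panel],
    )
    gt = GroundTruth(
        region_fields=region_fields,
        true_log2fc=fc,
        affine_true=affines,
        marker_rules=marker_rules,
        cell_tables=cell_tables,
    )
    return Study(config=config, tissues=tissues, ground_truth=gt)


def generate_study(config: StudyConfig, outdir: str | Path, imc: bool = True) -> Path:
    """Generate the study and serialise it: imzML + TIFF + CSV + JSON ground truth.

    Layout: one directory per experiment, one per tissue; a top-level
    ``manifest.csv`` linking every file to its experiment/arm, plus
    ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = generate_study_in_memory(config, imc=imc)
    manifest_rows = []
    for td in study.tissues:
        tdir = outdir / td.experiment_id / td.tissue_id
        tdir.mkdir(parents=True, exist_ok=True)
        imz = tdir / f"{td.tissue_id}.imzML"
        write_imzml(td.dataset, imz)
        row = dict(
            tissue_id=td.tissue_id,
            experiment=td.experiment_id,
            arm=td.arm,
            imzml=str(imz.relative_to(outdir)),
            has_imc=td.imc_images is not None,
        )
        if td.imc_images is not None:
            for marker, img in td.imc_images.items():
                tifffile.imwrite(tdir / f"imc_{marker}.tif", img.astype(np.float32))
            td.landmarks.to_csv(tdir / "landmarks.csv", index=False)
            td.imc_cells.to_csv(tdir / "cells_truth.csv", index=False)
        manifest_rows.append(row)
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
    gt = study.ground_truth
    payload = {
        "region_fields": {k: v.astype(int).tolist() for k, v in gt.region_fields.items()},
        "true_log2fc": gt.true_log2fc.replace([np.inf, -np.inf], None).to_dict(),
        "affine_true": {
            tid: {"A": a.A.tolist(), "t": a.t.tolist()} for tid, a in gt.affine_true.items()
        },
        "marker_rules": gt.marker_rules,
        "region_prevalence": config.region_prevalence,
        "seed": config.seed,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(payload))
    return outdir
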