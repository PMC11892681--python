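"""MSI-to-IMC registration, label transfer and per-region cell quantification.

The two modalities are relateable by an invertible planar affine map from
MSI micrometre coordinates to IMC micrometre coordinates, fitted by least
squares from landmark pairs.  MSI pixels are squares of side
``pixel_pitch`` anchored at index*pitch; IMC pixel centres sit at
(i + 0.5)*pitch.  Region labels are transferred by mapping each IMC pixel
centre through the inverse affine into the MSI grid.  Cells are a
simplified nuclear/cytoplasm model: nuclei are connected components of a
thresholded DNA channel gated to 20-571 um^2, the cytoplasm extends at
most 4 um from the nucleus with equidistant partition between competing
nuclei, and total cell area is capped at 600 um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .segment import SegmentationMap

UNASSIGNED = "unassigned"


@dataclass
class AffineTransform2D:
    """x_imc = A @ x_msi + t, coordinates in micrometres."""

    A: np.ndarray  # (2, 2)
    t: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.t = np.asarray(self.t, dtype=float).reshape(2)
        if abs(np.linalg.det(self.A)) < 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.A.T + self.t

    def inverse(self) -> "AffineTransform2D":
        Ainv = np.linalg.inv(self.A)
        return AffineTransform2D(Ainv, -Ainv @ self.t)

    @staticmethod
    def identity() -> "AffineTransform2D":
        return AffineTransform2D(np.eye(2), np.zeros(2))

    @staticmethod
    def from_params(
        rotation_deg: float = 0.0,
        scale: float | tuple[float, float] = 1.0,
        translation: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        sx, sy = (scale, scale) if np.isscalar(scale) else scale
        return AffineTransform2D(rot @ np.diag([sx, sy]), np.asarray(translation, float))


@dataclass
class AffineFitResult:
    transform: AffineTransform2D
    residuals: np.ndarray  # per-landmark Euclidean residual, um, IMC frame
    rms_residual: float


def fit_affine(landmarks_msi: np.ndarray, landmarks_imc: np.ndarray) -> AffineFitResult:
    """Least-squares affine from >= 3 non-collinear landmark pairs.

    Minimises the sum of squared residuals in the IMC frame and reports
    the per-landmark residuals.
    """
    src = np.atleast_2d(np.asarray(landmarks_msi, dtype=float))
    dst = np.atleast_2d(np.asarray(landmarks_imc, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("landmark arrays must both be (n, 2)")
    n = src.shape[0]
    if n < 3:
        raise ValueError("need at least 3 landmark pairs")
    centred = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max())) < 2:
        raise ValueError("landmarks are collinear; affine is underdetermined")
    design = np.hstack([src, np.ones((n, 1))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    A = coef[:2].T
    t = coef[2]
    tf = AffineTransform2D(A, t)
    res = np.linalg.norm(tf.apply(src) - dst, axis=1)
    return AffineFitResult(transform=tf, residuals=res, rms_residual=float(np.sqrt(np.mean(res**2))))


# ---------------------------------------------------------------------------
# Label transfer
# ---------------------------------------------------------------------------

@dataclass
class LabelImage:
    """Integer label image with a legend; 0 is always 'unassigned'."""

    image: np.ndarray  # int16, (rows, cols) on the IMC grid
    names: dict[int, str] = field(default_factory=dict)
    pixel_pitch: float = 1.0

    def name_at(self, row: int, col: int) -> str:
        return self.names[int(self.image[row, col])]


def region_grid(segmentation: SegmentationMap, tissue_id: str) -> tuple[np.ndarray, dict[int, str]]:
    """Matched region labels of one tissue as a 2-D integer grid (0 = no pixel)."""
    if not segmentation.matched:
        raise ValueError("segmentation has no matched regions")
    sub = segmentation.frame[segmentation.frame["tissue_id"] == tissue_id]
    if len(sub) == 0:
        raise ValueError(f"empty segmentation for tissue {tissue_id!r}")
    names = sorted(sub["region"].unique())
    code = {n: i + 1 for i, n in enumerate(names)}
    grid = np.zeros((sub["y"].max() + 1, sub["x"].max() + 1), dtype=np.int16)
    grid[sub["y"].to_numpy(int), sub["x"].to_numpy(int)] = sub["region"].map(code).to_numpy()
    legend = {0: UNASSIGNED, **{v: k for k, v in code.items()}}
    return grid, legend


def transfer_labels(
    segmentation: SegmentationMap,
    tissue_id: str,
    msi_pixel_pitch: float,
    affine: AffineTransform2D,
    imc_shape: tuple[int, int],
    imc_pixel_pitch: float = 1.0,
) -> LabelImage:
    """Label every IMC pixel with the MSI region its centre maps into.

    Each IMC pixel centre is sent through the inverse affine into MSI
    micrometre space and floored to an MSI grid index; centres landing
    outside the MSI footprint become 'unassigned' (code 0).
    """
    grid, legend = region_grid(segmentation, tissue_id)
    rows, cols = imc_shape
    inv = affine.inverse()
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    centres = np.column_stack(
        [(cc.ravel() + 0.5) * imc_pixel_pitch, (rr.ravel() + 0.5) * imc_pixel_pitch]
    )
    msi_um = inv.apply(centres)
    ix = np.floor(msi_um[:, 0] / msi_pixel_pitch).astype(np.int64)
    iy = np.floor(msi_um[:, 1] / msi_pixel_pitch).astype(np.int64)
    inside = (ix >= 0) & (iy >= 0) & (ix < grid.shape[1]) & (iy < grid.shape[0])
    out = np.zeros(rows * cols, dtype=np.int16)
    out[inside] = grid[iy[inside], ix[inside]]
    return LabelImage(image=out.reshape(rows, cols), names=legend, pixel_pitch=imc_pixel_pitch)


# ---------------------------------------------------------------------------
# Cell model
# ---------------------------------------------------------------------------

@dataclass
class CellParams:
    dna_threshold: float = 0.5
    nucleus_area_range: tuple[float, float] = (20.0, 571.0)
    max_cytoplasm_radius_um: float = 4.0
    max_cell_area_um2: float = 600.0
    pixel_pitch: float = 1.0  # um per IMC pixel


def segment_cells(
    dna_image: np.ndarray,
    params: CellParams | None = None,
    marker_images: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Detect cells from the DNA channel; returns (cell table, cell label image).

    Nuclei are connected components of ``dna_image > dna_threshold`` with
    area inside the nuclear gate.  Cytoplasm is the set of pixels within
    ``max_cytoplasm_radius_um`` of their *nearest* nucleus (equidistant
    partition); cells exceeding ``max_cell_area_um2`` keep only their
    pixels closest to the nucleus.  A threshold that finds no nuclei
    yields an empty table, not an error.
    """
    p = params or CellParams()
    dna = np.asarray(dna_image, dtype=float)
    if dna.size == 0:
        raise ValueError("empty DNA channel")
    px_area = p.pixel_pitch**2
    raw = measure.label(dna > p.dna_threshold, connectivity=1)
    lo, hi = p.nucleus_area_range
    nuclei = np.zeros_like(raw)
    next_id = 0
    kept_props = []
    for prop in measure.regionprops(raw):
        area = prop.area * px_area
        if lo <= area <= hi:
            next_id += 1
            nuclei[raw == prop.label] = next_id
            kept_props.append((next_id, prop))
    cells = np.zeros_like(nuclei)
    records = []
    if next_id > 0:
        dist, (iy, ix) = ndi.distance_transform_edt(
            nuclei == 0, sampling=p.pixel_pitch, return_indices=True
        )
        nearest = nuclei[iy, ix]
        cells = np.where(dist <= p.max_cytoplasm_radius_um, nearest, 0)
        max_px = int(np.floor(p.max_cell_area_um2 / px_area))
        for cid, prop in kept_props:
            mask = cells == cid
            n_px = int(mask.sum())
            if n_px > max_px:
                d = np.where(mask, dist, np.inf)
                flat = np.argsort(d, axis=None, kind="stable")[:max_px]
                keep = np.zeros(cells.size, dtype=bool)
                keep[flat] = True
                cells[mask & ~keep.reshape(cells.shape)] = 0
                mask = cells == cid
                n_px = max_px
            cy, cx = prop.centroid
            rec = dict(
                cell_id=cid,
                centroid_x_um=(cx + 0.5) * p.pixel_pitch,
                centroid_y_um=(cy + 0.5) * p.pixel_pitch,
                nucleus_area_um2=prop.area * px_area,
                cell_area_um2=n_px * px_area,
            )
            if marker_images:
                for name, img in marker_images.items():
                    rec[f"mean_{name}"] = float(np.asarray(img, float)[mask].mean())
            records.append(rec)
    columns = ["cell_id", "centroid_x_um", "centroid_y_um", "nucleus_area_um2", "cell_area_um2"]
    if marker_images:
        columns += [f"mean_{m}" for m in marker_images]
    table = pd.DataFrame.from_records(records, columns=columns)
    return table, cells


# ---------------------------------------------------------------------------
# Region quantification
# ---------------------------------------------------------------------------

@dataclass
class RegionMarkerStats:
    """Per (region, marker) pixel/cell means and positive-cell counts."""

    table: pd.DataFrame
    excluded_cells: int


def quantify_by_region(
    marker_images: dict[str, np.ndarray],
    cell_table: pd.DataFrame,
    label_image: LabelImage,
    positive_thresholds: dict[str, float] | None = None,
) -> RegionMarkerStats:
    """Marker statistics inside each transferred MSI region.

    Pixel-level: mean marker intensity over each region's labelled pixels.
    Cell-level: a cell belongs to the region containing its nucleus
    centroid; it is positive for a marker iff its per-cell mean is >= the
    marker's threshold.  Cells whose centroid falls on an unassigned pixel
    are excluded and counted.
    """
    positive_thresholds = positive_thresholds or {}
    img = label_image.image
    regions = [name for code, name in sorted(label_image.names.items()) if code != 0]
    # assign cells to regions via centroid pixel
    excluded = 0
    cell_region: list[str] = []
    for _, row in cell_table.iterrows():
        r = int(row["centroid_y_um"] / label_image.pixel_pitch)
        c = int(row["centroid_x_um"] / label_image.pixel_pitch)
        if 0 <= r < img.shape[0] and 0 <= c < img.shape[1] and img[r, c] != 0:
            cell_region.append(label_image.names[int(img[r, c])])
        else:
            cell_region.append(UNASSIGNED)
            excluded += 1
    cells = cell_table.copy()
    cells["region"] = cell_region
    rows = []
    for region in regions:
        code = next(k for k, v in label_image.names.items() if v == region)
        mask = img == code
        in_region = cells[cells["region"] == region]
        for marker, mimg in marker_images.items():
            mimg = np.asarray(mimg, dtype=float)
            if mimg.shape != img.shape:
                raise ValueError(f"marker {marker!r} image shape mismatch")
            col = f"mean_{marker}"
            cell_means = in_region[col] if col in in_region.columns else pd.Series(dtype=float)
            thr = positive_thresholds.get(marker, None)
            n_pos = int((cell_means >= thr).sum()) if thr is not None else int(len(cell_means))
            rows.append(
                dict(
                    region=region,
                    marker=marker,
                    mean_intensity=float(mimg[mask].mean()) if mask.any() else np.nan,
                    cell_mean_intensity=float(cell_means.mean()) if len(cell_means) else np.nan,
                    positive_cells=n_pos,
                    total_cells=int(len(in_region)),
                    positive_fraction=(n_pos / len(in_region)) if len(in_region) else np.nan,
                )
            )
    return RegionMarkerStats(table=pd.DataFrame(rows), excluded_cells=excluded)
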