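"""Peak detection, integration, annotation and cross-experiment matching.

Peaks are detected on the (RMS-normalised) experiment mean spectrum by a
gradient approach: an apex is a strict local maximum of the rebinned
spectrum; its integration bounds extend to the nearest gradient
sign-change minima (or the support edge).  Per-pixel ion intensities are
the sums of rebinned, normalised intensities under each peak's bounds.
Accurate-mass annotation applies two nested ppm filters (an inclusion
window for candidate search and a tighter accuracy window for retention),
and only peaks present in every experiment enter the consensus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masses import POLARITY_ADDUCTS, adduct_mz, ppm_error
from .msi_io import MSIDataset, Spectrum, rms, uniform_axis

#: metadata columns of a PeakMatrix frame; the rest are peak columns
META_COLUMNS = ("tissue_id", "experiment", "arm", "x", "y")


@dataclass(frozen=True)
class Peak:
    center_mz: float
    left_mz: float
    right_mz: float
    apex_intensity: float
    left_idx: int = -1
    apex_idx: int = -1
    right_idx: int = -1

    def __post_init__(self) -> None:
        if not (self.left_mz < self.center_mz < self.right_mz):
            raise ValueError("require left_mz < center_mz < right_mz")


@dataclass
class PeakTable:
    experiment_id: str
    peaks: list[Peak]
    bin_width: float
    mass_range: tuple[float, float]

    def __post_init__(self) -> None:
        centres = [p.center_mz for p in self.peaks]
        if centres != sorted(centres):
            raise ValueError("peaks must be sorted by center_mz")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center_mz for p in self.peaks])


@dataclass
class ConsensusPeak:
    consensus_mz: float
    members: dict[str, Peak]  # experiment_id -> member peak


@dataclass
class MatchedPeakSet:
    """Peaks common to all experiments, one member per experiment each."""

    peaks: list[ConsensusPeak]
    experiment_ids: list[str]

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def consensus_mz(self) -> np.ndarray:
        return np.array([p.consensus_mz for p in self.peaks])

    def table_for(self, experiment_id: str) -> list[Peak]:
        return [p.members[experiment_id] for p in self.peaks]


@dataclass
class AnnotationConfig:
    database: pd.DataFrame  # columns: name, neutral_mass
    inclusion_ppm: float = 300.0
    accuracy_ppm: float = 70.0
    adducts: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(POLARITY_ADDUCTS)
    )

    def __post_init__(self) -> None:
        if self.accuracy_ppm > self.inclusion_ppm:
            raise ValueError("accuracy_ppm must be <= inclusion_ppm")
        if not {"name", "neutral_mass"}.issubset(self.database.columns):
            raise ValueError("database needs columns name, neutral_mass")
        if (self.database["neutral_mass"] <= 0).any():
            raise ValueError("neutral masses must be > 0")


@dataclass
class PeakMatrix:
    """Pixels x consensus-peaks intensities with grid and tissue metadata.

    ``frame`` has the metadata columns in :data:`META_COLUMNS` followed by
    one column per peak (named ``mz_<center>``).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        if (self.frame[self.peak_columns] < 0).any().any():
            raise ValueError("peak intensities must be non-negative")

    @property
    def peak_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    @property
    def values(self) -> np.ndarray:
        return self.frame[self.peak_columns].to_numpy(dtype=float)

    @staticmethod
    def concat(matrices: list["PeakMatrix"]) -> "PeakMatrix":
        return PeakMatrix(pd.concat([m.frame for m in matrices], ignore_index=True))


def peak_column_name(center_mz: float) -> str:
    return f"mz_{center_mz:.4f}"


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _check_uniform(mz: np.ndarray) -> float:
    d = np.diff(mz)
    if d.size == 0 or not np.allclose(d, d[0], rtol=1e-6, atol=0):
        raise ValueError("spectrum axis must be uniform (rebinned)")
    return float(d[0])


def default_min_apex(spectrum: Spectrum) -> float:
    """Noise floor: 3 x median absolute deviation of the spectrum."""
    v = spectrum.intensity
    return 3.0 * float(np.median(np.abs(v - np.median(v))))


def detect_peaks_gradient(
    mean_spec: Spectrum,
    min_apex: float | None = None,
    experiment_id: str = "",
    mass_range: tuple[float, float] | None = None,
) -> PeakTable:
    """Detect peaks as gradient sign changes on a uniform-axis spectrum.

    Apexes are strict local maxima (first difference + -> -); bounds run to
    the nearest - -> + sign change (local minimum) or the support edge.
    Apexes below ``min_apex`` are discarded.
    """
    w = _check_uniform(mean_spec.mz)
    v = mean_spec.intensity
    if min_apex is None:
        min_apex = default_min_apex(mean_spec)
    apexes = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1
    peaks: list[Peak] = []
    prev_right = -1
    for a in apexes:
        if v[a] < min_apex:
            continue
        left = a
        while left > 0 and v[left - 1] <= v[left]:
            left -= 1
        right = a
        n = v.size
        while right < n - 1 and v[right + 1] <= v[right]:
            right += 1
        if left <= prev_right:  # shared valley bin belongs to the earlier peak
            left = prev_right + 1
        if left >= a or right <= a:
            continue
        prev_right = right
        peaks.append(
            Peak(
                center_mz=float(mean_spec.mz[a]),
                left_mz=float(mean_spec.mz[left]),
                right_mz=float(mean_spec.mz[right]),
                apex_intensity=float(v[a]),
                left_idx=int(left),
                apex_idx=int(a),
                right_idx=int(right),
            )
        )
    if mass_range is None:
        mass_range = (float(mean_spec.mz[0]), float(mean_spec.mz[-1]))
    return PeakTable(experiment_id=experiment_id, peaks=peaks, bin_width=w, mass_range=mass_range)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate_peaks(dataset: MSIDataset, peak_table: PeakTable) -> PeakMatrix:
    """Sum intensities under each peak's bounds, per pixel.

    The dataset's spectra must already be rebinned (and normalised) on the
    same axis the peak table was detected on.
    """
    axis = dataset.spectra[0].mz
    w = _check_uniform(axis)
    if not np.isclose(w, peak_table.bin_width, rtol=1e-9):
        raise ValueError("dataset axis does not match peak table bin width")
    cols = {c: [] for c in META_COLUMNS}
    values = np.empty((dataset.n_pixels, len(peak_table)))
    windows = [(p.left_idx, p.right_idx) for p in peak_table.peaks]
    for i, ((x, y), spec) in enumerate(zip(dataset.pixels, dataset.spectra)):
        if spec.mz.shape != axis.shape or not np.allclose(spec.mz, axis):
            raise ValueError("all spectra must share the peak table's axis")
        for j, (lo, hi) in enumerate(windows):
            values[i, j] = spec.intensity[lo : hi + 1].sum()
        cols["tissue_id"].append(dataset.tissue_id)
        cols["experiment"].append(dataset.experiment_id)
        cols["arm"].append(dataset.arm)
        cols["x"].append(x)
        cols["y"].append(y)
    frame = pd.DataFrame(cols)
    for j, p in enumerate(peak_table.peaks):
        frame[peak_column_name(p.center_mz)] = values[:, j]
    return PeakMatrix(frame)


def integrate_dataset_streaming(
    dataset: MSIDataset,
    peak_table: PeakTable,
    normalise: bool = True,
    peak_names: list[str] | None = None,
) -> PeakMatrix:
    """Rebin + RMS-normalise + integrate each pixel without materialising
    the dense per-pixel spectra.

    Equivalent to ``rebin -> rms_normalise -> integrate_peaks`` (verified in
    tests); windows are interpolated directly and the full-axis RMS is
    computed in closed form per linear segment.
    """
    low, high = peak_table.mass_range
    w = peak_table.bin_width
    n_bins = int(np.floor((high - low) / w + 1e-9)) + 1
    windows = [low + np.arange(p.left_idx, p.right_idx + 1) * w for p in peak_table.peaks]
    all_nodes = np.concatenate(windows) if windows else np.empty(0)
    bounds = np.cumsum([0] + [len(c) for c in windows])[:-1]
    rows = np.empty((dataset.n_pixels, len(windows)))
    meta = {c: [] for c in META_COLUMNS}
    for i, ((x, y), spec) in enumerate(zip(dataset.pixels, dataset.spectra)):
        vals = np.interp(all_nodes, spec.mz, spec.intensity, left=0.0, right=0.0)
        sums = np.add.reduceat(vals, bounds) if len(windows) else np.empty(0)
        if normalise:
            ss = _interp_sum_squares(spec.mz, spec.intensity, low, w, n_bins)
            scale = np.sqrt(ss / n_bins)
            if scale == 0:
                raise ValueError(f"all-zero spectrum at pixel {(x, y)}")
            sums = sums / scale
        rows[i] = sums
        meta["tissue_id"].append(dataset.tissue_id)
        meta["experiment"].append(dataset.experiment_id)
        meta["arm"].append(dataset.arm)
        meta["x"].append(x)
        meta["y"].append(y)
    frame = pd.DataFrame(meta)
    if peak_names is None:
        peak_names = [peak_column_name(p.center_mz) for p in peak_table.peaks]
    for j, name in enumerate(peak_names):
        frame[name] = rows[:, j]
    return PeakMatrix(frame)


def _interp_sum_squares(
    mz: np.ndarray, intensity: np.ndarray, low: float, w: float, n_bins: int
) -> float:
    """Sum over all bin centres of the squared linear interpolant (zero
    outside the support), without evaluating the dense axis."""
    if mz.size < 2:
        return 0.0
    # first grid node with low + i*w >= x is i = ceil((x - low)/w)
    starts = np.ceil((mz - low) / w - 1e-9).astype(np.int64)
    starts = np.clip(starts, 0, n_bins)
    total = 0.0
    x0, y0 = mz[:-1], intensity[:-1]
    x1, y1 = mz[1:], intensity[1:]
    i0 = starts[:-1]
    i1 = starts[1:]
    m = (y1 - y0) / (x1 - x0)
    n = i1 - i0
    c0 = low + i0 * w
    a = y0 + m * (c0 - x0)
    d = m * w
    nf = n.astype(float)
    s1 = nf * (nf - 1) / 2.0
    s2 = (nf - 1) * nf * (2 * nf - 1) / 6.0
    seg = nf * a**2 + 2 * a * d * s1 + d**2 * s2
    total = float(np.sum(seg[n > 0]))
    # grid node coinciding exactly with the last input point
    last = starts[-1]
    if last < n_bins:
        c = low + last * w
        if np.isclose(c, mz[-1], rtol=0, atol=w * 1e-6):
            total += float(intensity[-1] ** 2)
    return total


# ---------------------------------------------------------------------------
# Ion images
# ---------------------------------------------------------------------------

def render_ion_image(
    matrices: list[PeakMatrix],
    peak_column: str,
    percentile: float = 95.0,
) -> dict[str, np.ndarray]:
    """Per-tissue 2-D ion images clipped at the pooled percentile.

    The clipping percentile is computed across all pixels of all tissues of
    the experiment (display convention; statistics use unclipped values).
    Returns a map tissue_id -> image (NaN outside acquired pixels).
    """
    pooled = np.concatenate([m.frame[peak_column].to_numpy(dtype=float) for m in matrices])
    if pooled.size == 0:
        raise ValueError("no pixels pooled for percentile")
    cap = float(np.percentile(pooled, percentile))
    images: dict[str, np.ndarray] = {}
    for m in matrices:
        for tissue_id, sub in m.frame.groupby("tissue_id"):
            xs = sub["x"].to_numpy(int)
            ys = sub["y"].to_numpy(int)
            img = np.full((ys.max() + 1, xs.max() + 1), np.nan)
            img[ys, xs] = np.minimum(sub[peak_column].to_numpy(dtype=float), cap)
            images[str(tissue_id)] = img
    return images


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_peaks(
    peak_table: PeakTable | np.ndarray,
    config: AnnotationConfig,
    polarity: str,
) -> pd.DataFrame:
    """Accurate-mass annotation of peak centres against a metabolite table.

    For each peak, database entries whose theoretical adduct m/z falls
    within ``inclusion_ppm`` are candidates; candidates within
    ``accuracy_ppm`` are flagged retained.  Rows are sorted by peak then
    by absolute ppm error.
    """
    if polarity not in config.adducts or not config.adducts[polarity]:
        raise ValueError(f"no adducts configured for polarity {polarity!r}")
    centers = peak_table.centers if isinstance(peak_table, PeakTable) else np.asarray(peak_table, float)
    records = []
    theo = []
    for _, row in config.database.iterrows():
        for adduct in config.adducts[polarity]:
            theo.append((str(row["name"]), adduct, adduct_mz(float(row["neutral_mass"]), adduct)))
    for c in centers:
        for name, adduct, tmz in theo:
            ppm = ppm_error(float(c), tmz)
            if abs(ppm) <= config.inclusion_ppm:
                records.append(
                    dict(
                        peak_mz=float(c),
                        name=name,
                        adduct=adduct,
                        theoretical_mz=tmz,
                        ppm=ppm,
                        retained=bool(abs(ppm) <= config.accuracy_ppm),
                    )
                )
    df = pd.DataFrame.from_records(
        records,
        columns=["peak_mz", "name", "adduct", "theoretical_mz", "ppm", "retained"],
    )
    if len(df):
        df["abs_ppm"] = df["ppm"].abs()
        df = df.sort_values(["peak_mz", "abs_ppm"], kind="stable").drop(columns="abs_ppm")
        df = df.reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Cross-experiment matching
# ---------------------------------------------------------------------------

def match_peaks_across_experiments(
    peak_tables: list[PeakTable], match_ppm: float = 300.0
) -> MatchedPeakSet:
    """Consensus peaks present in every experiment within ``match_ppm``.

    Greedy nearest-neighbour chaining anchored on the first table; a
    consensus peak is kept only if every experiment contributes exactly one
    member.  Duplicate centres within one table inside the tolerance make
    the table ambiguous and raise.
    """
    if len(peak_tables) < 2:
        raise ValueError("need at least two peak tables to match")
    for t in peak_tables:
        c = t.centers
        if c.size >= 2:
            rel = np.diff(c) / c[:-1] * 1e6
            if np.any(rel <= match_ppm):
                raise ValueError(
                    f"table {t.experiment_id!r} has peaks closer than {match_ppm} ppm (ambiguous)"
                )
    experiment_ids = [t.experiment_id for t in peak_tables]
    consensus: list[ConsensusPeak] = []
    used: dict[str, set[int]] = {t.experiment_id: set() for t in peak_tables}
    anchor = peak_tables[0]
    for i, p in enumerate(anchor.peaks):
        members = {anchor.experiment_id: p}
        member_idx = {anchor.experiment_id: i}
        ok = True
        for t in peak_tables[1:]:
            c = t.centers
            if c.size == 0:
                ok = False
                break
            j = int(np.argmin(np.abs(c - p.center_mz)))
            if abs(ppm_error(c[j], p.center_mz)) > match_ppm or j in used[t.experiment_id]:
                ok = False
                break
            members[t.experiment_id] = t.peaks[j]
            member_idx[t.experiment_id] = j
        if not ok:
            continue
        for eid, j in member_idx.items():
            used[eid].add(j)
        cmz = float(np.mean([m.center_mz for m in members.values()]))
        consensus.append(ConsensusPeak(consensus_mz=cmz, members=members))
    return MatchedPeakSet(peaks=consensus, experiment_ids=experiment_ids)
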