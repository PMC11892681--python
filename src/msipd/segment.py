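"""Pixel-level metabolic segmentation and cross-run region matching.

All pixels of one experiment (every tissue, every arm) are pooled,
embedded into a low-dimensional space (t-SNE with an out-of-sample map,
or a passthrough for oracle tests) and partitioned by k-means (k=2 by
default).  Cluster identities are arbitrary per run, so clusters are
matched across experiments by the Pearson correlation of their
metabolite signatures, and the matched family occupying the larger pixel
share of the *vehicle* tissues is named Region A (the region dominant in
control tumours); the treatment-enriched family is Region B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .peaks import PeakMatrix


@dataclass
class SegmentationConfig:
    k: int = 2
    embed_method: str = "tsne_exact"  # tsne_exact | tsne_parametric | passthrough
    embed_dims: int = 2
    perplexity: float = 30.0
    max_pixels_for_fit: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.embed_method not in ("tsne_exact", "tsne_parametric", "passthrough"):
            raise ValueError(f"unknown embed_method {self.embed_method!r}")


@dataclass
class SegmentationMap:
    """Per-pixel cluster labels (and matched region names once assigned)."""

    frame: pd.DataFrame  # columns: tissue_id, experiment, arm, x, y, cluster[, region]
    experiment_id: str

    @property
    def matched(self) -> bool:
        return "region" in self.frame.columns and self.frame["region"].notna().all()

    def region_counts(self) -> pd.Series:
        if not self.matched:
            raise ValueError("segmentation has no matched regions yet")
        return self.frame["region"].value_counts()


def drop_peaks_near(peak_matrix: PeakMatrix, mzs: list[float], ppm: float = 50.0) -> PeakMatrix:
    """Remove peak columns within ``ppm`` of any m/z in ``mzs``.

    Used to keep drug ions out of the metabolite segmentation input: a
    compound present only in treated tissues is an arm label in disguise
    and would let the clustering split by treatment instead of by
    metabolic region.
    """
    if not mzs:
        return peak_matrix
    drop = []
    for c in peak_matrix.peak_columns:
        center = float(c.split("_", 1)[1])
        if any(abs((center - m) / m) * 1e6 <= ppm for m in mzs):
            drop.append(c)
    if not drop:
        return peak_matrix
    return PeakMatrix(peak_matrix.frame.drop(columns=drop))


def zscore_peaks(peak_matrix: PeakMatrix) -> np.ndarray:
    """Per-peak z-score of the intensity matrix (within one experiment)."""
    x = peak_matrix.values
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def embed_pixels(peak_matrix: PeakMatrix, config: SegmentationConfig) -> np.ndarray:
    """Embed every pixel of an experiment's pooled peak matrix.

    ``passthrough`` returns the standardised peak matrix itself (identity
    contract for oracle tests).  The t-SNE methods fit on at most
    ``max_pixels_for_fit`` seeded-uniformly sampled pixels and place the
    remaining pixels at the embedding of their nearest fitted neighbour in
    the standardised feature space.
    """
    x = zscore_peaks(peak_matrix)
    if config.embed_method == "passthrough":
        return x
    n = x.shape[0]
    if n < config.perplexity + 1:
        raise ValueError(f"pixel count {n} must exceed perplexity {config.perplexity}")
    rng = np.random.default_rng(config.seed)
    if n > config.max_pixels_for_fit:
        fit_idx = np.sort(rng.choice(n, size=config.max_pixels_for_fit, replace=False))
    else:
        fit_idx = np.arange(n)
    tsne = TSNE(
        n_components=config.embed_dims,
        perplexity=min(config.perplexity, (len(fit_idx) - 1) / 3),
        random_state=config.seed,
        init="pca",
        n_jobs=1,
    )
    fitted = tsne.fit_transform(x[fit_idx])
    if len(fit_idx) == n:
        return fitted
    out = np.empty((n, config.embed_dims))
    out[fit_idx] = fitted
    rest = np.setdiff1d(np.arange(n), fit_idx)
    nn = NearestNeighbors(n_neighbors=1).fit(x[fit_idx])
    _, ind = nn.kneighbors(x[rest])
    out[rest] = fitted[ind[:, 0]]
    return out


def cluster_kmeans(
    embedding: np.ndarray, config: SegmentationConfig, peak_matrix: PeakMatrix
) -> SegmentationMap:
    """k-means (k-means++ init, 10 seeded restarts, best inertia) on the embedding."""
    if not np.all(np.isfinite(embedding)):
        raise ValueError("embedding must be finite")
    if config.k > embedding.shape[0]:
        raise ValueError("k exceeds the number of pixels")
    km = KMeans(n_clusters=config.k, n_init=10, random_state=config.seed)
    labels = km.fit_predict(embedding)
    frame = peak_matrix.frame[["tissue_id", "experiment", "arm", "x", "y"]].copy()
    frame["cluster"] = labels
    exp_ids = frame["experiment"].unique()
    return SegmentationMap(frame=frame, experiment_id=str(exp_ids[0]) if len(exp_ids) == 1 else "")


def segment_experiment(peak_matrix: PeakMatrix, config: SegmentationConfig) -> SegmentationMap:
    """Embed + cluster one experiment's pooled pixels."""
    emb = embed_pixels(peak_matrix, config)
    return cluster_kmeans(emb, config, peak_matrix)


# ---------------------------------------------------------------------------
# Cross-run matching
# ---------------------------------------------------------------------------

def cluster_signatures(
    segmentation: SegmentationMap, peak_matrix: PeakMatrix
) -> pd.DataFrame:
    """Per-cluster mean of the z-scored peak matrix (clusters x peaks)."""
    z = zscore_peaks(peak_matrix)
    labels = segmentation.frame["cluster"].to_numpy()
    rows = {}
    for c in np.unique(labels):
        rows[int(c)] = z[labels == c].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=peak_matrix.peak_columns)


def match_clusters(
    segmentations: list[SegmentationMap],
    peak_matrices: list[PeakMatrix],
    vehicle_arm: str = "vehicle",
    region_names: tuple[str, str] = ("A", "B"),
    tie_tol: float = 1e-9,
) -> list[SegmentationMap]:
    """Match clusters across experiments by signature correlation and name regions.

    Clusters of each experiment are assigned to the first experiment's
    clusters by maximising total Pearson correlation of their metabolite
    signatures (optimal assignment).  The matched family with the larger
    pixel share in vehicle-arm tissues is named ``region_names[0]``
    (Region A, dominant in controls).  Invariant to cluster label
    permutation and experiment order up to region names.
    """
    if len(segmentations) == 0:
        raise ValueError("no segmentations given")
    if len(segmentations) != len(peak_matrices):
        raise ValueError("one peak matrix per segmentation required")
    sigs = [cluster_signatures(s, m) for s, m in zip(segmentations, peak_matrices)]
    ref = sigs[0]
    k = ref.shape[0]
    # family id = cluster index of the reference experiment
    assignments: list[dict[int, int]] = [{int(c): int(c) for c in ref.index}]
    for sig in sigs[1:]:
        corr = np.empty((sig.shape[0], k))
        for i, ci in enumerate(sig.index):
            for j, cj in enumerate(ref.index):
                corr[i, j] = np.corrcoef(sig.loc[ci], ref.loc[cj])[0, 1]
        rows, cols = linear_sum_assignment(-corr)
        total = corr[rows, cols].sum()
        # ambiguity check: any alternative full assignment within tie_tol
        if k == 2:
            alt = corr[0, 1] + corr[1, 0] if (cols[0] == 0) else corr[0, 0] + corr[1, 1]
            if abs(total - alt) < tie_tol:
                raise ValueError("signature correlation tie; need more peaks to match clusters")
        assignments.append(
            {int(sig.index[r]): int(ref.index[c]) for r, c in zip(rows, cols)}
        )
    # vehicle pixel share per family, pooled over experiments
    family_vehicle = {int(c): 0 for c in ref.index}
    vehicle_total = 0
    for seg, amap in zip(segmentations, assignments):
        veh = seg.frame[seg.frame["arm"] == vehicle_arm]
        vehicle_total += len(veh)
        for cl, fam in amap.items():
            family_vehicle[fam] += int((veh["cluster"] == cl).sum())
    if vehicle_total == 0:
        raise ValueError(f"no pixels in arm {vehicle_arm!r} to anchor Region A")
    order = sorted(family_vehicle, key=lambda f: -family_vehicle[f])
    if len(region_names) < len(order):
        raise ValueError("need one region name per cluster")
    fam_to_region = {fam: region_names[i] for i, fam in enumerate(order)}
    out = []
    for seg, amap in zip(segmentations, assignments):
        frame = seg.frame.copy()
        frame["region"] = frame["cluster"].map(lambda c: fam_to_region[amap[int(c)]])
        out.append(SegmentationMap(frame=frame, experiment_id=seg.experiment_id))
    return out


def region_fraction(
    segmentation: SegmentationMap, tissue_id: str, region: str = "A"
) -> float:
    """Percentage of a tissue's retained pixels labelled with ``region``."""
    if not segmentation.matched:
        raise ValueError("segmentation has no matched regions")
    sub = segmentation.frame[segmentation.frame["tissue_id"] == tissue_id]
    if len(sub) == 0:
        raise ValueError(f"tissue {tissue_id!r} has no retained pixels")
    return 100.0 * float((sub["region"] == region).sum()) / len(sub)


def segmentation_overlap(seg1: SegmentationMap, seg2: SegmentationMap) -> float:
    """Pixel-occupancy overlap (%) between two matched segmentations.

    Computed on the intersection of pixels present in both maps; region
    names are compared by their sorted rank within each map, so an A/B map
    is directly comparable with a C/D map of the same two families.
    """
    for seg in (seg1, seg2):
        if not seg.matched:
            raise ValueError("both segmentations must have matched regions")

    def ranked(seg: SegmentationMap) -> pd.DataFrame:
        f = seg.frame[["tissue_id", "x", "y", "region"]].copy()
        names = sorted(f["region"].unique())
        f["rank"] = f["region"].map({n: i for i, n in enumerate(names)})
        return f

    merged = ranked(seg1).merge(
        ranked(seg2), on=["tissue_id", "x", "y"], suffixes=("_1", "_2")
    )
    if len(merged) == 0:
        raise ValueError("segmentations share no pixels")
    return 100.0 * float((merged["rank_1"] == merged["rank_2"]).sum()) / len(merged)
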