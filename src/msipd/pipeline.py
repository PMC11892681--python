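"""End-to-end study orchestration: simulate -> preprocess -> peaks ->
annotate -> respond -> segment -> register -> quantify -> report.

Every stage is a pure function of (inputs, config, seed); the summary is
a plain JSON-serialisable dict validated against a shipped schema.  The
master seed is fanned out per stage/tissue through
``numpy.random.SeedSequence`` spawn keys.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crossmodal import (
    CellParams,
    fit_affine,
    quantify_by_region,
    segment_cells,
    transfer_labels,
)
from .msi_io import MSIDataset, Spectrum, read_imzml, uniform_axis
from .peaks import (
    AnnotationConfig,
    MatchedPeakSet,
    PeakMatrix,
    PeakTable,
    annotate_peaks,
    detect_peaks_gradient,
    integrate_dataset_streaming,
    match_peaks_across_experiments,
    peak_column_name,
)
from .segment import (
    SegmentationConfig,
    SegmentationMap,
    drop_peaks_near,
    match_clusters,
    region_fraction,
    segment_experiment,
    segmentation_overlap,
)
from .stats import boxplot_summary, compare_arms, drug_ion_report, log2fc_vs_vehicle, tissue_means
from .synthetic import Study, StudyConfig, generate_study_in_memory

log = logging.getLogger("msipd")

STAGES = ("simulate", "preprocess", "annotate", "respond", "segment", "register", "quantify")

SUMMARY_SCHEMA: dict = {
    "type": "object",
    "required": list(STAGES) + ["seed"],
    "properties": {s: {"type": "object"} for s in STAGES},
}


def validate_summary(summary: dict) -> None:
    """Check the summary against the shipped schema (required stage blocks)."""
    missing = [k for k in SUMMARY_SCHEMA["required"] if k not in summary]
    if missing:
        raise ValueError(f"summary is missing required blocks: {missing}")
    for s in STAGES:
        if not isinstance(summary[s], dict):
            raise ValueError(f"summary block {s!r} must be an object")


@dataclass
class RunConfig:
    outdir: str = "msipd_run"
    seed: int = 0
    study: StudyConfig = field(default_factory=StudyConfig)
    bin_width: float = 0.01
    min_apex_rel: float = 0.01  # apex floor as a fraction of the mean-spectrum max
    match_ppm: float = 300.0
    inclusion_ppm: float = 300.0
    accuracy_ppm: float = 70.0
    vehicle_arm: str = "vehicle"
    segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(max_pixels_for_fit=3000)
    )
    overlap_arms: tuple[str, ...] = ("vehicle", "drugA")  # re-segmentation subset
    positive_thresholds: dict[str, float] = field(
        default_factory=lambda: {"pS6": 5.0, "Ki67": 5.0, "GLUT1": 5.0, "CD31": 4.0, "collagen1": 3.0}
    )
    dna_threshold: float = 0.5

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        study = StudyConfig(**raw.pop("study", {}))
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        known = RunConfig.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(study=study, segmentation=seg, **raw)


def preprocess_experiment(
    datasets: list[MSIDataset],
    bin_width: float,
    mass_range: tuple[float, float],
    normalise: bool = True,
    min_apex_rel: float = 0.01,
) -> tuple[Spectrum, PeakTable]:
    """Streamed rebin + RMS-normalise + mean spectrum + gradient peak detection."""
    axis = uniform_axis(mass_range, bin_width)
    total = np.zeros_like(axis)
    n = 0
    for ds in datasets:
        for spec in ds.spectra:
            v = np.interp(axis, spec.mz, spec.intensity, left=0.0, right=0.0)
            if normalise:
                r = np.sqrt(np.mean(v * v))
                if r == 0:
                    continue
                v = v / r
            total += v
            n += 1
    if n == 0:
        raise ValueError("no usable pixels in experiment")
    mean = Spectrum(axis, total / n)
    eid = datasets[0].experiment_id
    table = detect_peaks_gradient(
        mean,
        min_apex=min_apex_rel * float(mean.intensity.max()),
        experiment_id=eid,
        mass_range=mass_range,
    )
    return mean, table


def consensus_peak_matrices(
    study_datasets: dict[str, list[MSIDataset]],
    matched: MatchedPeakSet,
    bin_width: float,
    mass_range: tuple[float, float],
    normalise: bool = True,
) -> PeakMatrix:
    """Integrate every tissue against its experiment's member peaks, with
    columns named by consensus m/z so experiments align."""
    names = [peak_column_name(mz) for mz in matched.consensus_mz]
    parts = []
    for eid, datasets in study_datasets.items():
        members = matched.table_for(eid)
        order = np.argsort([p.center_mz for p in members], kind="stable")
        table = PeakTable(
            experiment_id=eid,
            peaks=[members[i] for i in order],
            bin_width=bin_width,
            mass_range=mass_range,
        )
        ordered_names = [names[i] for i in order]
        for ds in datasets:
            parts.append(
                integrate_dataset_streaming(ds, table, normalise=normalise, peak_names=ordered_names)
            )
    pm = PeakMatrix.concat(parts)
    return PeakMatrix(pm.frame[list(pm.frame.columns[:5]) + names])


def run_pipeline(config: RunConfig, study: Study | None = None) -> dict:
    """Run the full analysis; writes tables + summary under ``config.outdir``.

    ``study`` may be supplied (e.g. pre-generated or loaded from disk);
    otherwise the simulate stage generates it from ``config.study`` with
    the master seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed}
    try:
        t0 = time.time()
        if study is None:
            cfg = config.study
            if cfg.seed != config.seed:
                cfg = StudyConfig(**{**asdict_shallow(cfg), "seed": config.seed})
            study = generate_study_in_memory(cfg)
        summary["simulate"] = {
            "n_experiments": study.config.n_experiments,
            "n_tissues": len(study.tissues),
            "arms": list(study.config.arms),
            "seed": study.config.seed,
        }
        log.info("simulate: %d tissues (%.1fs)", len(study.tissues), time.time() - t0)

        # --- preprocess + peak detection per experiment
        t0 = time.time()
        exp_ids = study.config.experiment_ids()
        by_exp = {eid: study.datasets(eid) for eid in exp_ids}
        mass_range = study.config.mass_range
        tables = {}
        for eid in exp_ids:
            _, table = preprocess_experiment(
                by_exp[eid], config.bin_width, mass_range, min_apex_rel=config.min_apex_rel
            )
            tables[eid] = table
        matched = (
            match_peaks_across_experiments(list(tables.values()), config.match_ppm)
            if len(tables) > 1
            else None
        )
        if matched is None:
            t = tables[exp_ids[0]]
            from .peaks import ConsensusPeak

            matched = MatchedPeakSet(
                peaks=[
                    ConsensusPeak(consensus_mz=p.center_mz, members={exp_ids[0]: p})
                    for p in t.peaks
                ],
                experiment_ids=[exp_ids[0]],
            )
        if len(matched) == 0:
            raise ValueError("empty consensus peak set; downstream stages cannot run")
        summary["preprocess"] = {
            "bin_width": config.bin_width,
            "peaks_per_experiment": {eid: len(t) for eid, t in tables.items()},
            "n_consensus_peaks": len(matched),
        }
        log.info("preprocess: %d consensus peaks (%.1fs)", len(matched), time.time() - t0)

        # --- annotation
        t0 = time.time()
        db = pd.DataFrame(
            {
                "name": [s.name for s in study.config.metabolite_panel],
                "neutral_mass": [s.neutral_mass for s in study.config.metabolite_panel],
            }
        )
        ann_cfg = AnnotationConfig(
            database=db, inclusion_ppm=config.inclusion_ppm, accuracy_ppm=config.accuracy_ppm
        )
        ann = annotate_peaks(matched.consensus_mz, ann_cfg, study.config.polarity)
        ann.to_csv(outdir / "annotations.csv", index=False)
        summary["annotate"] = {
            "n_candidates": int(len(ann)),
            "n_retained": int(ann["retained"].sum()) if len(ann) else 0,
        }
        log.info("annotate: %d retained (%.1fs)", summary["annotate"]["n_retained"], time.time() - t0)

        # --- peak matrix + response statistics
        t0 = time.time()
        pm = consensus_peak_matrices(by_exp, matched, config.bin_width, mass_range)
        means = tissue_means(pm)
        fc = log2fc_vs_vehicle(means, vehicle_arm=config.vehicle_arm)
        means.to_csv(outdir / "tissue_means.csv", index=False)
        fc.to_csv(outdir / "log2fc.csv", index=False)
        tests = {}
        arm_sizes = means.groupby("arm").size()
        for arm in study.config.arms:
            if arm == config.vehicle_arm:
                continue
            if arm_sizes.get(arm, 0) < 2 or arm_sizes.get(config.vehicle_arm, 0) < 2:
                tests[arm] = None  # too few tissues for a between-arm test
                continue
            res = compare_arms(fc, arm, config.vehicle_arm)
            res.table.to_csv(outdir / f"ttest_{arm}_vs_{config.vehicle_arm}.csv", index=False)
            tests[arm] = int((res.table["pvalue"] < 0.05).sum())
        box = boxplot_summary(fc, grouping="arm")
        box.summary.to_csv(outdir / "boxplot_summary.csv", index=False)
        summary["respond"] = {
            "n_significant_vs_vehicle_p05": tests,
            "n_peaks_tested": len(pm.peak_columns),
        }
        log.info("respond (%.1fs)", time.time() - t0)

        # --- segmentation per experiment + matching + fractions + overlap
        # (drug ions are treatment labels, not metabolic signal: excluded)
        t0 = time.time()
        drug_mzs = [s.mz for s in study.config.metabolite_panel if s.is_drug_ion]
        pm_seg = drop_peaks_near(pm, drug_mzs)
        seg_cfg = config.segmentation
        segs, mats = [], []
        for i, eid in enumerate(exp_ids):
            sub = PeakMatrix(pm_seg.frame[pm_seg.frame["experiment"] == eid].reset_index(drop=True))
            cfg_i = SegmentationConfig(**{**asdict_shallow(seg_cfg), "seed": int(
                np.random.SeedSequence(config.seed, spawn_key=(101, i)).generate_state(1)[0] % (2**31)
            )})
            segs.append(segment_experiment(sub, cfg_i))
            mats.append(sub)
        segs = match_clusters(segs, mats, vehicle_arm=config.vehicle_arm)
        frame_all = pd.concat([s.frame for s in segs], ignore_index=True)
        frame_all.to_csv(outdir / "segmentation.csv", index=False)
        fractions = {}
        for seg in segs:
            for tid in seg.frame["tissue_id"].unique():
                fractions[str(tid)] = region_fraction(seg, tid)
        arm_fraction = (
            frame_all.assign(is_a=frame_all["region"] == "A")
            .groupby("arm")["is_a"]
            .mean()
            .mul(100.0)
            .to_dict()
        )
        # re-segmentation on an arm subset, overlap on shared pixels
        overlaps = {}
        for i, eid in enumerate(exp_ids):
            sub = mats[i]
            keep = sub.frame["arm"].isin(config.overlap_arms)
            if keep.sum() == 0 or keep.all():
                continue
            sub2 = PeakMatrix(sub.frame[keep].reset_index(drop=True))
            cfg_i = SegmentationConfig(**{**asdict_shallow(seg_cfg), "seed": int(
                np.random.SeedSequence(config.seed, spawn_key=(102, i)).generate_state(1)[0] % (2**31)
            )})
            seg2 = segment_experiment(sub2, cfg_i)
            (seg2_m,) = match_clusters([seg2], [sub2], vehicle_arm=config.vehicle_arm)
            overlaps[eid] = segmentation_overlap(segs[i], seg2_m)
        summary["segment"] = {
            "region_a_fraction_per_tissue": fractions,
            "region_a_fraction_per_arm": arm_fraction,
            "resegmentation_overlap_pct": overlaps,
        }
        log.info("segment (%.1fs)", time.time() - t0)

        # --- registration + label transfer + quantification (IMC tissues)
        t0 = time.time()
        reg, quant_rows, cell_rows = {}, [], []
        imc_tissues = [t for t in study.tissues if t.imc_images is not None]
        for td in imc_tissues:
            fit = fit_affine(
                td.landmarks[["x_msi_um", "y_msi_um"]].to_numpy(),
                td.landmarks[["x_imc_um", "y_imc_um"]].to_numpy(),
            )
            reg[td.tissue_id] = {"rms_residual_um": fit.rms_residual}
            seg = next(s for s in segs if s.experiment_id == td.experiment_id)
            n_px = td.imc_images["DNA"].shape[0]
            labels = transfer_labels(
                seg,
                td.tissue_id,
                study.config.msi_pixel_pitch,
                fit.transform,
                (n_px, n_px),
                study.config.imc_pixel_pitch,
            )
            markers = {k: v for k, v in td.imc_images.items() if k != "DNA"}
            cell_table, _ = segment_cells(
                td.imc_images["DNA"],
                CellParams(dna_threshold=config.dna_threshold,
                           pixel_pitch=study.config.imc_pixel_pitch),
                marker_images=markers,
            )
            stats = quantify_by_region(markers, cell_table, labels, config.positive_thresholds)
            t_stats = stats.table.assign(arm=td.arm, tissue_id=td.tissue_id)
            quant_rows.append(t_stats)
            cell_rows.append(cell_table.assign(arm=td.arm, tissue_id=td.tissue_id))
        summary["register"] = reg
        if quant_rows:
            quant = pd.concat(quant_rows, ignore_index=True)
            quant.to_csv(outdir / "region_marker_stats.csv", index=False)
            cells_all = pd.concat(cell_rows, ignore_index=True)
            cells_all.to_csv(outdir / "cells.csv", index=False)
            summary["quantify"] = {
                "n_rows": int(len(quant)),
                "markers": sorted(quant["marker"].unique()),
                "n_cells": int(len(cells_all)),
                "nucleus_area_min_um2": float(cells_all["nucleus_area_um2"].min()),
                "nucleus_area_max_um2": float(cells_all["nucleus_area_um2"].max()),
                "cell_area_max_um2": float(cells_all["cell_area_um2"].max()),
            }
        else:
            summary["quantify"] = {"n_rows": 0, "markers": []}
        log.info("register+quantify (%.1fs)", time.time() - t0)

        validate_summary(summary)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def asdict_shallow(obj) -> dict:
    """Shallow dataclass -> dict (keeps nested objects as-is)."""
    return {f: getattr(obj, f) for f in obj.__dataclass_fields__}


def load_study_datasets(study_dir: str | Path) -> dict[str, list[MSIDataset]]:
    """Read a generated study's imzML files back, grouped by experiment."""
    study_dir = Path(study_dir)
    manifest = pd.read_csv(study_dir / "manifest.csv")
    out: dict[str, list[MSIDataset]] = {}
    for _, row in manifest.iterrows():
        ds = read_imzml(
            study_dir / row["imzml"],
            tissue_id=row["tissue_id"],
            experiment_id=row["experiment"],
            arm=row["arm"],
        )
        out.setdefault(row["experiment"], []).append(ds)
    return out
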