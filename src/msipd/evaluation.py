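"""Scoring of pipeline recoveries against synthetic-study ground truth.

Only meaningful for studies produced by :mod:`msipd.synthetic`, where the
latent region fields, programmed fold changes and marker rules are known.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .masses import ppm_error
from .peaks import PeakMatrix, match_peaks_across_experiments
from .segment import (
    SegmentationConfig,
    SegmentationMap,
    drop_peaks_near,
    match_clusters,
    segment_experiment,
)
from .synthetic import VEHICLE, Study, StudyConfig, expected_log2fc, generate_study_in_memory


def segmentation_ari(segmentation: SegmentationMap, study: Study) -> float:
    """Adjusted Rand index between matched regions and the true region fields,
    over all pixels of the segmentation's experiment."""
    truth, pred = [], []
    f = segmentation.frame
    for tid, sub in f.groupby("tissue_id"):
        gt = study.ground_truth.region_fields[str(tid)]
        truth.extend(gt[sub["y"].to_numpy(int), sub["x"].to_numpy(int)].astype(int))
        pred.extend((sub["region"] == "A").astype(int))
    return float(adjusted_rand_score(truth, pred))


def match_peaks_to_panel(
    peak_columns: list[str], study: Study, tol_ppm: float = 70.0
) -> dict[str, str]:
    """Map consensus peak columns to panel metabolite names by accurate mass."""
    centers = np.array([float(c.split("_", 1)[1]) for c in peak_columns])
    out: dict[str, str] = {}
    for spec in study.config.metabolite_panel:
        errs = np.abs([ppm_error(c, spec.mz) for c in centers])
        j = int(np.argmin(errs))
        if errs[j] <= tol_ppm:
            out[spec.name] = peak_columns[j]
    return out


def fc_recovery(fc_table: pd.DataFrame, study: Study, tol_ppm: float = 70.0) -> pd.DataFrame:
    """Recovered vs programmed log2 fold change per (metabolite, arm).

    Recovered value = mean over tissues (pooled across experiments) of the
    tissue-level log2FC.  Programmed value is the closed-form expectation
    including the region-prevalence mixture term.  Drug ions are skipped
    (no finite vehicle reference).
    """
    mapping = match_peaks_to_panel(
        [c for c in fc_table.columns if c not in ("tissue_id", "experiment", "arm")],
        study,
        tol_ppm,
    )
    by_name = {s.name: s for s in study.config.metabolite_panel}
    rows = []
    for name, col in mapping.items():
        spec = by_name[name]
        if spec.is_drug_ion:
            continue
        for arm in study.config.arms:
            if arm == VEHICLE:
                continue
            sub = fc_table[fc_table["arm"] == arm]
            rec = float(sub[col].mean())
            prog = expected_log2fc(study.config, spec, arm)
            rows.append(
                dict(
                    metabolite=name,
                    arm=arm,
                    recovered=rec,
                    programmed=prog,
                    error=rec - prog,
                    responding=bool(spec.treatment_effect_log2.get(arm, 0.0) != 0.0),
                )
            )
    return pd.DataFrame(rows)


def marker_direction_checks(quant: pd.DataFrame, vehicle_arm: str = VEHICLE) -> pd.DataFrame:
    """Programmed pharmacodynamic directions on the region/arm marker means.

    Checks, per treated arm, on cell-level means: pS6 down in both regions;
    Ki67 and GLUT1 down in Region B but retained (not substantially
    reduced) in Region A.
    """
    def mean_of(arm: str, region: str, marker: str) -> float:
        sub = quant[(quant["arm"] == arm) & (quant["region"] == region) & (quant["marker"] == marker)]
        return float(sub["cell_mean_intensity"].mean())

    rows = []
    treated = [a for a in quant["arm"].unique() if a != vehicle_arm]
    for arm in treated:
        for marker, region, direction in [
            ("pS6", "A", "down"),
            ("pS6", "B", "down"),
            ("Ki67", "B", "down"),
            ("Ki67", "A", "retained"),
            ("GLUT1", "B", "down"),
            ("GLUT1", "A", "retained"),
        ]:
            v = mean_of(vehicle_arm, region, marker)
            t = mean_of(arm, region, marker)
            if direction == "down":
                ok = t < 0.7 * v
            else:  # retained: within 20% of vehicle
                ok = t > 0.8 * v
            rows.append(dict(arm=arm, marker=marker, region=region,
                             direction=direction, vehicle=v, treated=t, ok=bool(ok)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-study analyses used for recovery scoring
# ---------------------------------------------------------------------------

def analyse_study(
    study: Study,
    bin_width: float = 0.01,
    match_ppm: float = 300.0,
    embed_method: str = "tsne_exact",
    seg_fit_cap: int = 3000,
    seed: int = 0,
    normalise: bool = True,
) -> dict:
    """Run the MSI analysis chain on a generated study and score recoveries.

    Returns a dict with the peak matrix, per-tissue log2FC table, fold-change
    recovery table, matched segmentations, per-experiment ARI and per-arm
    Region-A fractions.
    """
    from .pipeline import consensus_peak_matrices, preprocess_experiment
    from .stats import log2fc_vs_vehicle, tissue_means

    cfg = study.config
    exp_ids = cfg.experiment_ids()
    by_exp = {e: study.datasets(e) for e in exp_ids}
    tables = [
        preprocess_experiment(by_exp[e], bin_width, cfg.mass_range, normalise=normalise)[1]
        for e in exp_ids
    ]
    if len(tables) > 1:
        matched = match_peaks_across_experiments(tables, match_ppm)
    else:
        from .peaks import ConsensusPeak, MatchedPeakSet

        matched = MatchedPeakSet(
            peaks=[ConsensusPeak(p.center_mz, {exp_ids[0]: p}) for p in tables[0].peaks],
            experiment_ids=exp_ids,
        )
    pm = consensus_peak_matrices(by_exp, matched, bin_width, cfg.mass_range, normalise=normalise)
    fc = log2fc_vs_vehicle(tissue_means(pm), vehicle_arm=VEHICLE)
    recovery = fc_recovery(fc, study)
    if not normalise:
        # rescore against the unnormalised closed form
        by_name = {s.name: s for s in cfg.metabolite_panel}
        recovery["programmed"] = [
            expected_log2fc(cfg, by_name[r.metabolite], r.arm, normalised=False)
            for r in recovery.itertuples()
        ]
        recovery["error"] = recovery["recovered"] - recovery["programmed"]
    drug_mzs = [s.mz for s in cfg.metabolite_panel if s.is_drug_ion]
    pm_seg = drop_peaks_near(pm, drug_mzs)
    segs, mats = [], []
    for i, e in enumerate(exp_ids):
        sub = PeakMatrix(pm_seg.frame[pm_seg.frame["experiment"] == e].reset_index(drop=True))
        seg_seed = int(np.random.SeedSequence(seed, spawn_key=(7, i)).generate_state(1)[0] % (2**31))
        seg_cfg = SegmentationConfig(
            embed_method=embed_method, max_pixels_for_fit=seg_fit_cap, seed=seg_seed
        )
        segs.append(segment_experiment(sub, seg_cfg))
        mats.append(sub)
    segs = match_clusters(segs, mats, vehicle_arm=VEHICLE)
    aris = {e: segmentation_ari(s, study) for e, s in zip(exp_ids, segs)}
    frame_all = pd.concat([s.frame for s in segs], ignore_index=True)
    arm_fractions = (
        frame_all.assign(is_a=frame_all["region"] == "A").groupby("arm")["is_a"].mean().mul(100.0).to_dict()
    )
    return dict(
        study=study,
        peak_matrix=pm,
        matched=matched,
        log2fc=fc,
        fc_recovery=recovery,
        segmentations=segs,
        ari=aris,
        arm_fractions=arm_fractions,
    )


def batch_equivariance_shift(peak_matrix: PeakMatrix, experiment_id: str, factor: float = 8.0) -> float:
    """Largest change in any log2FC entry after scaling one experiment's
    intensities by ``factor`` (should be ~0: batch factors cancel)."""
    from .stats import log2fc_vs_vehicle, tissue_means

    fc0 = log2fc_vs_vehicle(tissue_means(peak_matrix))
    scaled = PeakMatrix(peak_matrix.frame.copy())
    mask = scaled.frame["experiment"] == experiment_id
    for c in scaled.peak_columns:
        scaled.frame.loc[mask, c] *= factor
    fc1 = log2fc_vs_vehicle(tissue_means(scaled))
    cols = peak_matrix.peak_columns
    return float(np.nanmax(np.abs(fc0[cols].to_numpy() - fc1[cols].to_numpy())))


def null_ttest_rejection_rate(
    seed: int, n_endpoints: int = 2000, n_per_arm: int = 12, alpha: float = 0.05
) -> float:
    """Monte-Carlo type-I error of the two-sided Welch test on per-tissue
    log2FC endpoints drawn from a common null distribution."""
    from .stats import compare_arms

    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    cols = {f"mz_{100 + i}.0000": rng.normal(0.0, 0.5, n) for i in range(n_endpoints)}
    tab = pd.DataFrame(cols)
    tab.insert(0, "tissue_id", [f"t{i}" for i in range(n)])
    tab.insert(1, "experiment", ["e1"] * n)
    tab.insert(2, "arm", [VEHICLE] * n_per_arm + ["drugA"] * n_per_arm)
    res = compare_arms(tab, "drugA", VEHICLE)
    return float((res.table["pvalue"] < alpha).mean())


def zero_noise_passthrough_ari(seed: int, grid: int = 24) -> float:
    """Minimum per-experiment ARI of the noise-free study analysed with the
    passthrough embedding (exactness check: should be 1)."""
    cfg = StudyConfig(
        grid_shape=(grid, grid), noise_cv=0.0, mz_jitter_ppm=0.0, seed=seed
    )
    study = generate_study_in_memory(cfg, imc=False)
    res = analyse_study(study, embed_method="passthrough", seed=seed)
    return float(min(res["ari"].values()))
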