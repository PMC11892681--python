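"""Vehicle-normalised fold-change statistics on tissue means.

The statistical unit is the tissue, not the pixel: per-tissue mean ion
intensities are normalised to the average of the vehicle-arm tissues of
the *same experiment* and expressed as log2 fold change.  Because each
experiment is normalised internally, any global per-experiment scale
(batch factor) cancels exactly — the mechanism that allows tissues from
independent runs to be pooled.  Group comparisons use a two-sided t-test
(Welch by default) or a two-way ANOVA with factors arm and experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .peaks import META_COLUMNS, PeakMatrix

TISSUE_META = ["tissue_id", "experiment", "arm"]


def tissue_means(
    peak_matrix: PeakMatrix, expected_tissues: list[str] | None = None
) -> pd.DataFrame:
    """Mean intensity for each ion per tissue.

    Returns one row per tissue with columns ``tissue_id, experiment, arm``
    followed by the peak columns.
    """
    frame = peak_matrix.frame
    peaks = peak_matrix.peak_columns
    out = (
        frame.groupby(TISSUE_META, as_index=False, sort=True)[peaks]
        .mean()
    )
    if expected_tissues is not None:
        missing = sorted(set(expected_tissues) - set(out["tissue_id"]))
        if missing:
            raise ValueError(f"tissues with zero retained pixels: {missing}")
    return out


def log2fc_vs_vehicle(
    tissue_mean_table: pd.DataFrame, vehicle_arm: str = "vehicle"
) -> pd.DataFrame:
    """Log2 fold change of each tissue mean vs its experiment's vehicle average.

    Within each experiment every peak is divided by the mean over that
    experiment's vehicle tissues; peaks whose vehicle mean is zero are set
    to NaN for that experiment (flagged with a warning).  By construction
    the ratio-scale vehicle values of each experiment average exactly 1.
    """
    peaks = [c for c in tissue_mean_table.columns if c not in TISSUE_META]
    out = tissue_mean_table.copy()
    for exp, idx in out.groupby("experiment").groups.items():
        sub = out.loc[idx]
        veh = sub[sub["arm"] == vehicle_arm]
        if len(veh) == 0:
            raise ValueError(f"experiment {exp!r} has no {vehicle_arm!r} tissues")
        ref = veh[peaks].mean(axis=0)
        bad = ref[ref <= 0].index.tolist()
        if bad:
            warnings.warn(
                f"experiment {exp!r}: zero vehicle mean for {len(bad)} peak(s); excluded"
            )
            ref[bad] = np.nan
        out.loc[idx, peaks] = np.log2(sub[peaks].to_numpy() / ref.to_numpy())
    return out


@dataclass
class GroupTestResult:
    table: pd.DataFrame  # per peak: statistic, pvalue (+ pvalue_adj optional)
    method: str
    arm_a: str
    arm_b: str


def _welch_or_student(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    # degenerate zero-variance, zero-difference case: no evidence against the null
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def compare_arms(
    log2fc_table: pd.DataFrame,
    arm_a: str,
    arm_b: str,
    method: str = "two_sided_t",
    equal_var: bool = False,
    adjust: str | None = None,
) -> GroupTestResult:
    """Per-peak comparison of two arms on per-tissue log2 fold changes.

    Tissues are pooled across experiments.  ``method`` is ``two_sided_t``
    (Welch unless ``equal_var``) or ``two_way_anova`` (type-II sums of
    squares, factors arm and experiment, no interaction; the reported
    p-value is the arm effect).  ``adjust='bh'`` applies Benjamini-Hochberg
    across peaks (off by default).
    """
    peaks = [c for c in log2fc_table.columns if c not in TISSUE_META]
    ga = log2fc_table[log2fc_table["arm"] == arm_a]
    gb = log2fc_table[log2fc_table["arm"] == arm_b]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need at least 2 tissues per arm")
    rows = []
    if method == "two_sided_t":
        for pk in peaks:
            a = ga[pk].dropna().to_numpy(float)
            b = gb[pk].dropna().to_numpy(float)
            if a.size < 2 or b.size < 2:  # peak excluded (e.g. zero vehicle mean)
                rows.append(dict(peak=pk, statistic=np.nan, pvalue=np.nan))
                continue
            t, p = _welch_or_student(a, b, equal_var)
            rows.append(dict(peak=pk, statistic=t, pvalue=p))
    elif method == "two_way_anova":
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        both = log2fc_table[log2fc_table["arm"].isin([arm_a, arm_b])]
        for pk in peaks:
            d = both[TISSUE_META + [pk]].rename(columns={pk: "value"}).dropna()
            model = ols("value ~ C(arm) + C(experiment)", data=d).fit()
            table = sm.stats.anova_lm(model, typ=2)
            rows.append(
                dict(
                    peak=pk,
                    statistic=float(table.loc["C(arm)", "F"]),
                    pvalue=float(table.loc["C(arm)", "PR(>F)"]),
                )
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    out = pd.DataFrame(rows)
    if adjust == "bh" and len(out):
        from statsmodels.stats.multitest import multipletests

        out["pvalue_adj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    elif adjust is not None and adjust != "bh":
        raise ValueError(f"unknown adjustment {adjust!r}")
    name = "welch_t" if (method == "two_sided_t" and not equal_var) else method
    out["test"] = name
    return GroupTestResult(table=out, method=name, arm_a=arm_a, arm_b=arm_b)


@dataclass
class BoxplotSummary:
    """Quantile summary per group (box 25/75, whiskers 1/99, median) plus
    the per-tissue points with their experiment tag."""

    summary: pd.DataFrame
    points: pd.DataFrame


def boxplot_summary(
    log2fc_table: pd.DataFrame, grouping: list[str] | str = "arm"
) -> BoxplotSummary:
    if isinstance(grouping, str):
        grouping = [grouping]
    peaks = [c for c in log2fc_table.columns if c not in TISSUE_META]
    long = log2fc_table.melt(
        id_vars=TISSUE_META, value_vars=peaks, var_name="peak", value_name="value"
    ).dropna(subset=["value"])
    rows = []
    for keys, sub in long.groupby(grouping + ["peak"], sort=True):
        vals = sub["value"].to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"empty group {keys}")
        q = np.percentile(vals, [1, 25, 50, 75, 99])  # linear interpolation
        rec = dict(zip(grouping + ["peak"], keys if isinstance(keys, tuple) else (keys,)))
        rec.update(q01=q[0], q25=q[1], median=q[2], q75=q[3], q99=q[4], n=vals.size)
        rows.append(rec)
    return BoxplotSummary(summary=pd.DataFrame(rows), points=long)


def drug_ion_report(
    peak_matrix: PeakMatrix,
    drug_mz: float,
    ppm: float = 10.0,
    vehicle_arm: str = "vehicle",
) -> pd.DataFrame:
    """Per-tissue mean intensity and log2FC-vs-vehicle of the drug ion.

    Locates the consensus peak within ``ppm`` of ``drug_mz``; raises if no
    peak is close enough.
    """
    from .masses import ppm_error

    cols = peak_matrix.peak_columns
    centers = np.array([float(c.split("_", 1)[1]) for c in cols])
    errs = np.abs((centers - drug_mz) / drug_mz * 1e6)
    j = int(np.argmin(errs))
    if errs[j] > ppm:
        raise ValueError(
            f"no consensus peak within {ppm} ppm of {drug_mz} (closest {errs[j]:.1f} ppm)"
        )
    col = cols[j]
    sub = PeakMatrix(peak_matrix.frame[list(META_COLUMNS) + [col]].copy())
    means = tissue_means(sub)
    fc = log2fc_vs_vehicle(means, vehicle_arm=vehicle_arm)
    report = means.rename(columns={col: "drug_intensity"})
    report["log2fc_vs_vehicle"] = fc[col].to_numpy()
    report["peak_column"] = col
    return report
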