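"""Differential regulation calling and descriptive dynamics summaries.

Stage comparisons are two-sided t tests (Student pooled-variance by default,
Welch/Satterthwaite as an option) on log2-transformed calibrated values,
followed by Benjamini-Hochberg adjustment per comparison.  A site is
*significant* in a comparison when adjusted p < ``padj_max`` and the fold
change (ratio of arithmetic stage means of calibrated values) exceeds
``fc_min_phospho`` in either direction, and *regulated* when it is
significant in at least one configured comparison.  Label-free (DIA) protein
comparisons use the raw p value and a lower fold-change gate, matching
common practice for that acquisition mode.
"""

from __future__ import annotations

import math
import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import AnalysisThresholds, StudyDesign
from .normalize import CalibratedMatrix

__all__ = [
    "TestResult",
    "two_group_test",
    "bh_adjust",
    "differential_sites",
    "call_regulated",
    "differential_proteins_dia",
    "stage_means",
    "standardize_profiles",
    "temporal_profiles",
    "summarize_multiplicity",
    "residue_distribution",
    "direction_summary",
    "rounded_percent",
    "DEFAULT_COMPARISONS",
]

DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("GVBD", "GV"),
    ("MII", "GV"),
    ("MII", "GVBD"),
)


class TestResult(NamedTuple):
    statistic: float | None
    pvalue: float | None
    reason: str | None


def two_group_test(x, y, variant: str = "student") -> TestResult:
    """Two-sided two-sample t test on the given values.

    ``variant='student'`` pools variances; ``'welch'`` uses the
    Satterthwaite degrees of freedom.  Groups with fewer than two non-null
    values are untestable and yield null statistics with reason code
    ``"untestable"``.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown test variant {variant!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        return TestResult(None, None, "untestable")
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return TestResult(float(res.statistic), float(res.pvalue), None)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, null-aware.

    Null (NaN/None) entries are skipped and returned null; the effective
    number of tests is the number of non-null p values.  Values outside
    [0, 1] are rejected.
    """
    arr = np.asarray(
        [np.nan if v is None else float(v) for v in np.ravel(np.asarray(p, dtype=object))],
        dtype=float,
    )
    mask = np.isfinite(arr)
    if ((arr[mask] < 0) | (arr[mask] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return out


def _masked_log2(values: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.log2(values)
    logged[~np.isfinite(logged)] = np.nan
    return logged


def _group_arrays(matrix: pd.DataFrame, design: StudyDesign, stage: str) -> np.ndarray:
    cols = design.samples(stage)
    if not cols:
        raise ValueError(f"unknown stage label {stage!r}")
    return matrix[cols].to_numpy(dtype=float)


def _vector_ttest(a: np.ndarray, b: np.ndarray, variant: str) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided t test with pairwise NaN omission.

    Degenerate rows (zero variance, too few values) are tolerated here and
    masked by the caller; the zero-variance, nonzero-difference limit yields
    p = 0 as the noise-free limit of the t statistic.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            a, b, axis=1, equal_var=(variant == "student"), nan_policy="omit"
        )
    return np.asarray(res.statistic, dtype=float), np.asarray(res.pvalue, dtype=float)


def differential_sites(
    calibrated: CalibratedMatrix | pd.DataFrame,
    design: StudyDesign,
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    thresholds: AnalysisThresholds | None = None,
    variant: str = "student",
) -> pd.DataFrame:
    """Call differential regulation per site per stage comparison.

    Returns one row per (site, comparison) with ``log2fc`` (log2 ratio of
    arithmetic stage means of calibrated values), ``p_raw``, ``p_adj`` (BH
    per comparison across testable sites), ``significant`` and ``direction``.
    Sites with fewer than two non-null values in either stage are untestable
    (null p, not significant).
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown test variant {variant!r}")
    thresholds = thresholds or AnalysisThresholds()
    values = calibrated.values if isinstance(calibrated, CalibratedMatrix) else calibrated
    values = values.astype(float)
    frames = []
    for test_stage, ref_stage in comparisons:
        a = _group_arrays(values, design, test_stage)
        b = _group_arrays(values, design, ref_stage)
        testable = (np.isfinite(a).sum(axis=1) >= 2) & (np.isfinite(b).sum(axis=1) >= 2)
        with np.errstate(invalid="ignore"):
            mean_a = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=1)
            mean_b = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log2fc = np.log2(mean_a / mean_b)
        t, p = _vector_ttest(_masked_log2(a), _masked_log2(b), variant)
        p = np.where(testable, p, np.nan)
        t = np.where(testable, t, np.nan)
        p_adj = bh_adjust(p)
        significant = (
            np.isfinite(p_adj)
            & (p_adj < thresholds.padj_max)
            & (np.abs(log2fc) > math.log2(thresholds.fc_min_phospho))
        )
        direction = np.where(
            significant, np.where(log2fc > 0, "up", "down"), "none"
        )
        frames.append(
            pd.DataFrame(
                {
                    "site_id": values.index,
                    "comparison": f"{test_stage}_vs_{ref_stage}",
                    "log2fc": log2fc,
                    "t": t,
                    "p_raw": p,
                    "p_adj": p_adj,
                    "significant": significant,
                    "direction": direction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_regulated(calls: pd.DataFrame) -> pd.Series:
    """Per-site regulated flag: significant in at least one comparison."""
    flags = calls.groupby("site_id", sort=False)["significant"].any()
    flags.name = "regulated"
    return flags


def differential_proteins_dia(
    matrix: pd.DataFrame,
    design: StudyDesign,
    comparison: tuple[str, str],
    thresholds: AnalysisThresholds | None = None,
) -> pd.DataFrame:
    """Two-group label-free protein comparison: raw p < dia_p_max, FC > dia_fc_min."""
    thresholds = thresholds or AnalysisThresholds()
    test_stage, ref_stage = comparison
    values = matrix.astype(float)
    a = _group_arrays(values, design, test_stage)
    b = _group_arrays(values, design, ref_stage)
    testable = (np.isfinite(a).sum(axis=1) >= 2) & (np.isfinite(b).sum(axis=1) >= 2)
    mean_a = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=1)
    mean_b = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_a / mean_b)
    t, p = _vector_ttest(_masked_log2(a), _masked_log2(b), "student")
    p = np.where(testable, p, np.nan)
    significant = (
        np.isfinite(p)
        & (p < thresholds.dia_p_max)
        & (np.abs(log2fc) > math.log2(thresholds.dia_fc_min))
    )
    direction = np.where(significant, np.where(log2fc > 0, "up", "down"), "none")
    return pd.DataFrame(
        {
            "protein_id": values.index,
            "comparison": f"{test_stage}_vs_{ref_stage}",
            "log2fc": log2fc,
            "p_raw": p,
            "significant": significant,
            "direction": direction,
        }
    )


def stage_means(matrix: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Per-stage mean over non-null samples, one column per stage."""
    values = matrix.astype(float)
    return pd.DataFrame(
        {stage: values[design.samples(stage)].mean(axis=1, skipna=True) for stage in design.stages}
    )


def standardize_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each row to mean 0, population SD 1.

    Constant (or incomplete) rows cannot be standardized and are dropped;
    their ids are returned as diagnostics.
    """
    if profiles.shape[1] < 2:
        raise ValueError("standardization needs at least two stages")
    values = profiles.astype(float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    keep = (sd > 0) & values.notna().all(axis=1)
    dropped = values.index[~keep].tolist()
    z = values.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return z, dropped


def temporal_profiles(
    calibrated_values: pd.DataFrame,
    design: StudyDesign,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Standardized per-site temporal profiles for clustering.

    Stage means are computed on log2 calibrated values (so a stage mean is a
    log geometric mean, consistent with the scale the significance tests run
    on) and each site's profile is standardized to mean 0, SD 1 across
    stages.  Constant profiles are dropped with diagnostics.
    """
    values = calibrated_values.astype(float)
    if log_transform:
        values = pd.DataFrame(
            _masked_log2(values.to_numpy()), index=values.index, columns=values.columns
        )
    return standardize_profiles(stage_means(values, design))


def summarize_multiplicity(sites: pd.DataFrame) -> dict:
    """Sites-per-protein counts and the multi-site percentages.

    Returns the per-protein count Series plus the rounded percent of
    phosphoproteins carrying >= 2 sites and > 6 sites.
    """
    if len(sites) == 0:
        raise ValueError("site table is empty")
    counts = sites.groupby("protein_id", sort=False).size()
    n_proteins = int(len(counts))
    n_ge2 = int((counts >= 2).sum())
    n_gt6 = int((counts > 6).sum())
    return {
        "counts": counts,
        "n_proteins": n_proteins,
        "n_multisite": n_ge2,
        "pct_multisite": rounded_percent(n_ge2, n_proteins),
        "n_gt6": n_gt6,
        "pct_gt6": rounded_percent(n_gt6, n_proteins),
    }


def residue_distribution(sites: pd.DataFrame) -> dict[str, float]:
    """Fractions of phospho-serine, -threonine and -tyrosine among sites."""
    if len(sites) == 0:
        raise ValueError("site table is empty")
    frac = sites["residue"].value_counts(normalize=True)
    return {r: float(frac.get(r, 0.0)) for r in ("S", "T", "Y")}


def direction_summary(calls: pd.DataFrame) -> dict:
    """Counts and rounded percent upregulated among significant calls of one comparison."""
    comparisons = calls["comparison"].unique()
    if len(comparisons) != 1:
        raise ValueError(f"expected calls for exactly one comparison, got {list(comparisons)}")
    significant = calls[calls["significant"]]
    n_sig = int(len(significant))
    n_up = int((significant["direction"] == "up").sum())
    return {
        "comparison": str(comparisons[0]),
        "n_significant": n_sig,
        "n_up": n_up,
        "pct_up": rounded_percent(n_up, n_sig) if n_sig else None,
    }


def rounded_percent(numerator: int, denominator: int) -> int:
    """Integer percent, rounded half away from zero (the convention used in print)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))
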