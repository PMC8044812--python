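"""Per-patient VOI summaries and group-level nonparametric statistics.

Each patient contributes the median of every normalized map and K-parameter
map within the tumor VOI (CET for enhancing, NCET for nonenhancing lesions).
Within each lesion group the three paired map comparisons (uncorrected vs
unidirectional, uncorrected vs bidirectional, unidirectional vs
bidirectional) are tested with the Wilcoxon signed-rank test; the three
p-values of one group form a Holm-Bonferroni family. Normality (Shapiro-
Wilk) is computed and reported but the workflow always proceeds
nonparametrically. A proof-of-principle Spearman rank correlation relates
per-patient median rCBV to WHO grade.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

COMPARISONS = (
    ("uncorrected_vs_unidir", "median_rcbv", "median_rcbv_unidir"),
    ("uncorrected_vs_bidir", "median_rcbv", "median_rcbv_bidir"),
    ("unidir_vs_bidir", "median_rcbv_unidir", "median_rcbv_bidir"),
)


@dataclass
class CohortRecord:
    """One patient's VOI summary row."""

    patient_id: str
    group: str  # "enhancing" or "nonenhancing"
    voi: str  # "CET" or "NCET"
    median_rcbv: float
    median_rcbv_unidir: float = np.nan
    median_rcbv_bidir: float = np.nan
    median_k2_unidir: float = np.nan
    median_k2_bidir: float = np.nan
    median_kep_bidir: float = np.nan
    mean_adj_r2_unidir: float = np.nan
    mean_adj_r2_bidir: float = np.nan
    grade: int | None = None


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def voi_median(map_3d: np.ndarray, mask: np.ndarray) -> float:
    """Sample median (midpoint convention) over the mask's non-missing voxels."""
    map_3d = np.asarray(map_3d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = map_3d[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        logger.warning("voi_median: no usable voxels in VOI; returning NaN")
        return float("nan")
    return float(np.median(vals))


def percent_difference(uncorrected: float, corrected: float) -> float:
    """100 (uncorrected - corrected) / uncorrected; positive = decrease."""
    if uncorrected == 0:
        raise ValidationError("percent difference undefined for a zero reference")
    return 100.0 * (uncorrected - corrected) / uncorrected


def group_percent_difference(
    uncorrected: np.ndarray, corrected: np.ndarray
) -> float:
    """Mean over patients of the per-patient percentage difference.

    Patients with a zero uncorrected median are excluded with a warning.
    """
    unc = np.asarray(uncorrected, dtype=float)
    cor = np.asarray(corrected, dtype=float)
    ok = np.isfinite(unc) & np.isfinite(cor) & (unc != 0)
    if np.any(np.isfinite(unc) & (unc == 0)):
        logger.warning("group_percent_difference: zero uncorrected medians excluded")
    if not np.any(ok):
        return float("nan")
    return float(np.mean(100.0 * (unc[ok] - cor[ok]) / unc[ok]))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped, tied absolute differences get mid-ranks,
    and the exact null distribution is used for small samples (falling back
    to the normal approximation with ties). Identical samples give p = 1 by
    convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    diff = x - y
    diff = diff[np.isfinite(diff)]
    if diff.size == 0 or np.all(diff == 0):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided",
                             method="auto")
    return float(res.pvalue)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def shapiro_normality(values: np.ndarray) -> float:
    """Shapiro-Wilk p-value; NaN when the sample is too small or constant."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 3 or np.ptp(vals) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(vals).pvalue)


def paired_group_tests(
    records: pd.DataFrame, alpha: float = 0.05, min_pairs: int = 6
) -> pd.DataFrame:
    """The three paired rCBV comparisons per group, Holm-adjusted per family.

    Returns one row per (group, comparison) with the raw and adjusted
    p-value, the Shapiro-Wilk p of the paired differences, and a
    significance flag at ``alpha``.
    """
    rows = []
    for group, sub in records.groupby("group", sort=False):
        raws, metas = [], []
        for name, col_a, col_b in COMPARISONS:
            a = sub[col_a].to_numpy(dtype=float)
            b = sub[col_b].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < min_pairs:
                raise ValidationError(
                    f"comparison {name!r} in group {group!r} has "
                    f"{int(ok.sum())} pairs (< {min_pairs})"
                )
            raws.append(wilcoxon_signed_rank(a[ok], b[ok]))
            metas.append((name, int(ok.sum()), shapiro_normality(a[ok] - b[ok])))
        adj = holm_adjust(np.asarray(raws))
        for (name, n, shap), p_raw, p_adj in zip(metas, raws, adj):
            rows.append(
                {
                    "group": group,
                    "comparison": name,
                    "n_pairs": n,
                    "shapiro_p": shap,
                    "p_raw": p_raw,
                    "p_adjusted": float(p_adj),
                    "significant": bool(p_adj < alpha),
                }
            )
    return pd.DataFrame(rows)


def grade_correlation(records: pd.DataFrame, min_records: int = 5) -> pd.DataFrame:
    """Spearman rank correlation of per-patient median rCBV vs WHO grade.

    Computed for each of the three maps over patients with a known grade;
    mid-ranks are used for ties. Constant grades make the correlation
    undefined and raise.
    """
    sub = records.dropna(subset=["grade"])
    if len(sub) < min_records:
        raise ValidationError(
            f"grade correlation needs >= {min_records} graded patients, "
            f"got {len(sub)}"
        )
    grades = sub["grade"].to_numpy(dtype=float)
    if np.ptp(grades) == 0:
        raise ValidationError("grade correlation undefined for constant grades")
    rows = []
    for label, col in (
        ("uncorrected", "median_rcbv"),
        ("unidir", "median_rcbv_unidir"),
        ("bidir", "median_rcbv_bidir"),
    ):
        vals = sub[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        rs, p = stats.spearmanr(vals[ok], grades[ok])
        rows.append({"map": label, "n": int(ok.sum()), "rs": float(rs), "p": float(p)})
    return pd.DataFrame(rows)


def cohort_table(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Group summary: mean +/- SD of each rCBV variant, percent differences
    and Holm-adjusted p-values, one row per lesion group.

    Single-patient groups report SD = 0 with a warning.
    """
    if records.empty:
        raise ValidationError("no records to summarize")
    tests = paired_group_tests(records, alpha=alpha) if all(
        records.groupby("group")["median_rcbv"].count() >= 6
    ) else None
    rows = []
    for group, sub in records.groupby("group", sort=False):
        if len(sub) == 1:
            logger.warning("group %r has a single patient; SD reported as 0", group)
        row = {"group": group, "n_patients": len(sub)}
        for label, col in (
            ("uncorrected", "median_rcbv"),
            ("unidir", "median_rcbv_unidir"),
            ("bidir", "median_rcbv_bidir"),
        ):
            vals = sub[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"rcbv_{label}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"rcbv_{label}_sd"] = (
                float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            )
        unc = sub["median_rcbv"].to_numpy(dtype=float)
        row["pct_diff_unidir"] = group_percent_difference(
            unc, sub["median_rcbv_unidir"].to_numpy(dtype=float)
        )
        row["pct_diff_bidir"] = group_percent_difference(
            unc, sub["median_rcbv_bidir"].to_numpy(dtype=float)
        )
        if tests is not None:
            gt = tests[tests["group"] == group].set_index("comparison")
            row["p_adj_unidir"] = float(gt.loc["uncorrected_vs_unidir", "p_adjusted"])
            row["p_adj_bidir"] = float(gt.loc["uncorrected_vs_bidir", "p_adjusted"])
            row["p_adj_unidir_vs_bidir"] = float(gt.loc["unidir_vs_bidir", "p_adjusted"])
        rows.append(row)
    return pd.DataFrame(rows)
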