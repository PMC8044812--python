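"""End-to-end orchestration: per-case rCBV pipeline and cohort runs.

Per case: discard leading volumes -> provisional bolus window from the
whole-brain average curve -> per-voxel baseline and QC -> nonenhancing-voxel
selection -> reference curve -> final bolus window -> per-voxel leakage fits
-> corrected curves -> trapezoidal integration -> NAWM normalization ->
maps and a VOI summary row. Voxel counts surviving every QC rule are logged
at INFO; they are the first debugging surface on real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats
from .cbv_maps import CBVMapSet, integrate_rcbv, normalize_to_nawm
from .config import RunConfig
from .dsc_io import DSCSeries, VOISet, load_case, write_maps
from .errors import DSCLeakError, NumericalError
from .fit_quality import adjusted_r_squared, r_squared
from .leakage_models import cumulative_integral, exp_weighted_integral, fit_stack
from .relaxometry import (
    AcquisitionWindow,
    ReferenceCurve,
    build_reference_curve,
    discard_leading_volumes,
    estimate_baseline,
    locate_bolus_window,
    qc_sufficient_drop,
    select_nonenhancing_voxels,
    signal_to_relaxivity,
)

logger = logging.getLogger(__name__)


@dataclass
class CaseResult:
    """Everything one case produces, in memory."""

    maps: dict[str, np.ndarray]
    map_set: CBVMapSet
    window: AcquisitionWindow
    reference: ReferenceCurve
    qc_counts: dict[str, int]
    summary: dict[str, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def _fit_models(config: RunConfig) -> tuple[bool, bool]:
    run_uni = config.model in ("unidir", "all")
    run_bi = config.model in ("bidir", "all")
    return run_uni, run_bi


def run_case(series: DSCSeries, vois: VOISet, config: RunConfig | None = None) -> CaseResult:
    """Run the full single-case pipeline on in-memory inputs."""
    config = config or RunConfig()
    if series.grid_shape != vois.grid_shape:
        raise NumericalError("series and masks do not share a grid")
    series = discard_leading_volumes(series, config.discard_leading)
    sig = series.signal
    tr, te = series.tr_seconds, series.te_seconds
    brain = vois.brain
    T = series.n_timepoints

    # provisional window from the whole-brain average curve
    mean_sig = sig[brain].mean(axis=0)
    s0_prov = mean_sig[: config.baseline_init_points].mean()
    prov_vals, _ = signal_to_relaxivity(mean_sig, s0_prov, te, config.clamp_fraction)
    prov_window = locate_bolus_window(ReferenceCurve(prov_vals, tr), config)

    s0_map, sd_map = estimate_baseline(sig, prov_window, config.baseline_min_points)
    nonenh = select_nonenhancing_voxels(sig, brain, prov_window, config)

    positive = brain & (s0_map > 0)
    relax = np.full(sig.shape, np.nan)
    vals, clamped = signal_to_relaxivity(
        sig[positive], s0_map[positive], te, config.clamp_fraction
    )
    relax[positive] = vals

    reference = build_reference_curve(relax, nonenh, tr)
    if reference.n_voxels_averaged < config.min_reference_voxels:
        raise NumericalError(
            f"only {reference.n_voxels_averaged} reference voxels "
            f"(floor {config.min_reference_voxels})"
        )
    window = locate_bolus_window(reference, config)

    drop_ok = qc_sufficient_drop(
        sig, s0_map, sd_map, window, config.drop_threshold_sd, config.sd_epsilon
    )
    clamp_frac = np.zeros(series.grid_shape)
    width = window.t1 - window.t0 + 1
    clamp_frac[positive] = clamped[:, window.bolus].sum(axis=-1) / width
    usable = positive & drop_ok & (clamp_frac <= config.max_clamped_fraction)
    qc_counts = {
        "brain": int(brain.sum()),
        "positive_baseline": int(positive.sum()),
        "sufficient_drop": int((positive & drop_ok).sum()),
        "clamp_excluded": int((positive & drop_ok & ~usable).sum()),
        "usable": int(usable.sum()),
        "nonenhancing_reference": reference.n_voxels_averaged,
    }
    for name, count in qc_counts.items():
        logger.info("QC voxel count [%s] = %d", name, count)
    if qc_counts["usable"] == 0:
        raise NumericalError("no voxels survived QC")

    V = relax[usable]  # (n, T)
    n_unclamped = T - clamped[usable[positive]].sum(axis=-1)

    def scatter(values: np.ndarray, where: np.ndarray | None = None) -> np.ndarray:
        out = np.full(series.grid_shape, np.nan)
        if where is None:
            out[usable] = values
        else:
            tmp = np.full(values.shape, np.nan)
            tmp[where] = values[where]
            out[usable] = tmp
        return out

    run_uni, run_bi = _fit_models(config)
    maps: dict[str, np.ndarray] = {}

    raw_unc = integrate_rcbv(V, window, tr)
    rcbv_unc, div_unc = normalize_to_nawm(scatter(raw_unc), vois.nawm & usable)
    maps["rcbv"] = rcbv_unc
    nawm_means = {"rcbv": div_unc}
    rcbv_uni3 = rcbv_bi3 = None

    if run_uni or run_bi:
        fits = fit_stack(
            V,
            reference.values,
            tr,
            model="all" if run_bi else "unidir",
            kep_min=config.kep_min,
            kep_max=config.kep_max,
            kep_grid_points=config.kep_grid_points,
        )
        conv = fits["converged"]
        ss_tot = r_squared(V, np.broadcast_to(V.mean(-1, keepdims=True), V.shape))[2]

        def adj_map(fitted: np.ndarray, k: int) -> np.ndarray:
            r2 = r_squared(V, fitted)[0]
            ok = conv & (n_unclamped > k + 1) & (ss_tot > 0)
            out = np.full(V.shape[0], np.nan)
            if np.any(ok):
                out[ok] = adjusted_r_squared(r2[ok], n_unclamped[ok], k)
            return scatter(out, ok)

        cum = cumulative_integral(reference.values, tr)
        if run_uni:
            k2u = fits["k2_unidir"]
            corrected = V + k2u[:, None] * cum[None, :]
            raw = integrate_rcbv(corrected, window, tr)
            rcbv_uni3, div = normalize_to_nawm(scatter(raw, conv), vois.nawm & usable)
            maps["rcbv_unidir"] = rcbv_uni3
            maps["k2_unidir"] = scatter(k2u, conv)
            fitted = fits["k1"][:, None] * reference.values[None, :] - k2u[:, None] * cum
            maps["adj_r2_unidir"] = adj_map(fitted, k=2)
            nawm_means["rcbv_unidir"] = div
        if run_bi:
            k2b, kepb = fits["k2_bidir"], fits["kep_bidir"]
            leak = exp_weighted_integral(reference.values, tr, kepb)
            corrected = V + k2b[:, None] * leak
            raw = integrate_rcbv(corrected, window, tr)
            rcbv_bi3, div = normalize_to_nawm(scatter(raw, conv), vois.nawm & usable)
            maps["rcbv_bidir"] = rcbv_bi3
            maps["k2_bidir"] = scatter(k2b, conv)
            maps["kep_bidir"] = scatter(kepb, conv)
            fitted = fits["k1_bidir"][:, None] * reference.values[None, :] - k2b[:, None] * leak
            maps["adj_r2_bidir"] = adj_map(fitted, k=3)
            nawm_means["rcbv_bidir"] = div

    map_set = CBVMapSet(
        rcbv_uncorrected=maps["rcbv"],
        rcbv_unidir=rcbv_uni3,
        rcbv_bidir=rcbv_bi3,
        nawm_mean_raw=nawm_means,
        window=window,
    )

    tumor = vois.tumor
    summary = {
        "median_rcbv": cohort_stats.voi_median(maps["rcbv"], tumor),
        "n_tumor_voxels": int(tumor.sum()),
    }
    for key, col in (
        ("rcbv_unidir", "median_rcbv_unidir"),
        ("rcbv_bidir", "median_rcbv_bidir"),
        ("k2_unidir", "median_k2_unidir"),
        ("k2_bidir", "median_k2_bidir"),
        ("kep_bidir", "median_kep_bidir"),
    ):
        if key in maps:
            summary[col] = cohort_stats.voi_median(maps[key], tumor)
    for key, col in (
        ("adj_r2_unidir", "mean_adj_r2_unidir"),
        ("adj_r2_bidir", "mean_adj_r2_bidir"),
    ):
        if key in maps:
            vals3 = maps[key][tumor]
            vals3 = vals3[np.isfinite(vals3)]
            summary[col] = float(vals3.mean()) if vals3.size else float("nan")

    return CaseResult(
        maps=maps,
        map_set=map_set,
        window=window,
        reference=reference,
        qc_counts=qc_counts,
        summary=summary,
        affine=series.affine,
    )


def write_case_outputs(result: CaseResult, config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Write one case's maps plus the audit sidecars (config, window, curve)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = write_maps(result.maps, result.affine, out_dir)
    config.to_yaml(out_dir / "config_used.yaml")
    ref_df = pd.DataFrame(
        {
            "time_s": np.arange(result.reference.values.size) * result.reference.time_step,
            "reference_dr2s": result.reference.values,
        }
    )
    ref_df.to_csv(out_dir / "reference_curve.tsv", sep="\t", index=False)
    win = result.window
    sidecar = {
        "baseline_end": int(win.baseline_end),
        "t0": int(win.t0),
        "t1": int(win.t1),
        "tail_start": int(win.tail[0]),
        "n_timepoints": int(win.n_timepoints),
        "n_reference_voxels": int(result.reference.n_voxels_averaged),
        "qc_counts": {k: int(v) for k, v in result.qc_counts.items()},
    }
    (out_dir / "window.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    pd.DataFrame([result.summary]).to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    return manifest


def run_case_files(
    dsc_path, brain_path, tumor_path, nawm_path,
    tr_seconds: float, te_seconds: float,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> CaseResult:
    """Load one case from NIfTI files, run it, optionally write outputs."""
    config = config or RunConfig()
    series, vois = load_case(
        dsc_path, brain_path, tumor_path, nawm_path, tr_seconds, te_seconds
    )
    result = run_case(series, vois, config)
    if out_dir is not None:
        write_case_outputs(result, config, out_dir)
    return result


def record_from_result(
    result: CaseResult, patient_id: str, group: str, grade: int | None
) -> cohort_stats.CohortRecord:
    s = result.summary
    return cohort_stats.CohortRecord(
        patient_id=patient_id,
        group=group,
        voi="CET" if group == "enhancing" else "NCET",
        median_rcbv=s.get("median_rcbv", np.nan),
        median_rcbv_unidir=s.get("median_rcbv_unidir", np.nan),
        median_rcbv_bidir=s.get("median_rcbv_bidir", np.nan),
        median_k2_unidir=s.get("median_k2_unidir", np.nan),
        median_k2_bidir=s.get("median_k2_bidir", np.nan),
        median_kep_bidir=s.get("median_kep_bidir", np.nan),
        mean_adj_r2_unidir=s.get("mean_adj_r2_unidir", np.nan),
        mean_adj_r2_bidir=s.get("mean_adj_r2_bidir", np.nan),
        grade=grade,
    )


def run_cohort_cases(
    cases: list[dict], config: RunConfig | None = None
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run many in-memory cases and compute the cohort statistics.

    ``cases`` entries need ``patient_id``, ``group``, ``series``, ``vois``
    and optionally ``grade``. Returns the per-patient records plus the
    summary / paired-test / grade-correlation tables (the last only when
    enough graded patients exist).
    """
    config = config or RunConfig()
    records = []
    for case in cases:
        result = run_case(case["series"], case["vois"], config)
        records.append(
            record_from_result(
                result, case["patient_id"], case["group"], case.get("grade")
            )
        )
    frame = cohort_stats.records_to_frame(records)
    tables: dict[str, pd.DataFrame] = {"records": frame}
    tables["summary"] = cohort_stats.cohort_table(frame, alpha=config.alpha)
    try:
        tables["paired_tests"] = cohort_stats.paired_group_tests(frame, alpha=config.alpha)
    except DSCLeakError as exc:
        logger.warning("paired tests skipped: %s", exc)
    try:
        tables["grade_correlation"] = cohort_stats.grade_correlation(frame)
    except DSCLeakError as exc:
        logger.info("grade correlation skipped: %s", exc)
    return frame, tables


def run_cohort_manifest(
    manifest: pd.DataFrame, config: RunConfig | None = None, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Cohort run from a manifest table of file paths.

    Required columns: patient_id, dsc, brain, tumor, nawm, group, tr, te;
    optional: grade. Per-case failures are logged and skipped; surviving
    cases are summarized. Tables are written as TSV when ``out_dir`` is set.
    """
    config = config or RunConfig()
    if manifest.empty:
        raise NumericalError("empty cohort manifest")
    records = []
    for _, row in manifest.iterrows():
        pid = str(row["patient_id"])
        try:
            case_out = None
            if out_dir is not None:
                case_out = Path(out_dir) / pid
            result = run_case_files(
                row["dsc"], row["brain"], row["tumor"], row["nawm"],
                float(row["tr"]), float(row["te"]),
                config=config, out_dir=case_out,
            )
        except DSCLeakError as exc:
            logger.error("case %s failed: %s", pid, exc)
            continue
        grade = row.get("grade")
        grade = int(grade) if grade is not None and np.isfinite(float(grade)) else None
        records.append(record_from_result(result, pid, str(row["group"]), grade))
    if not records:
        raise NumericalError("every case in the cohort failed")
    frame = cohort_stats.records_to_frame(records)
    tables: dict[str, pd.DataFrame] = {"records": frame}
    try:
        tables["summary"] = cohort_stats.cohort_table(frame, alpha=config.alpha)
        tables["paired_tests"] = cohort_stats.paired_group_tests(frame, alpha=config.alpha)
    except DSCLeakError as exc:
        logger.warning("group statistics limited: %s", exc)
    try:
        tables["grade_correlation"] = cohort_stats.grade_correlation(frame)
    except DSCLeakError as exc:
        logger.info("grade correlation skipped: %s", exc)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out_dir / f"cohort_{name}.tsv", sep="\t", index=False)
        config.to_yaml(out_dir / "config_used.yaml")
    return frame, tables
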