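"""Seedable synthetic DSC phantom generator.

The phantom emulates exactly the statistical structure the analysis assumes:
a gamma-variate whole-brain reference bolus (the standard first-pass
surrogate), optional dispersed recirculation and an elevated post-bolus
steady-state level; per-voxel relaxivity curves produced by the forward
leakage models with chosen ground-truth K1/K2/Kep; the exponential signal
transform S(t) = S0 exp(-TE dR2*(t)); additive Gaussian baseline noise in
signal space; and a simple label geometry (background / normal brain / NAWM /
tumor). It does not model anatomy, an arterial input function, motion or any
k-space physics.

The forward simulator uses the very same causal trapezoidal integral
operators as the fitting module, so noiseless parameter recovery is exact.

Default acquisition mirrors a typical 1.5-3 T gradient-echo EPI perfusion
protocol (TR 1.1 s, TE 30 ms) at a desk-scale 16 x 16 x 4 grid with 100
dynamics. Ground-truth K-parameter distributions for the enhancing /
nonenhancing cohorts follow the magnitudes reported for glioma DSC studies:
tumor K2 of order -0.05...-0.01 1/s (T2*-dominant leakage), Kep of order
0.01-0.02 1/s, and NAWM-relative blood volume (K1) near 3 for enhancing and
near 1.4 for nonenhancing lesions, increasing with WHO grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import RunConfig
from .dsc_io import DSCSeries, VOISet, save_volume
from .errors import ValidationError
from .leakage_models import cumulative_integral, exp_weighted_integral
from .relaxometry import ReferenceCurve, locate_bolus_window
from . import cbv_maps

# label volume codes
BACKGROUND, NORMAL_BRAIN, NAWM, TUMOR = 0, 1, 2, 3

_TRUNCATION_REL = 1e-7  # bolus support cut-off relative to peak


@dataclass
class GammaParams:
    """Shape of the synthetic whole-brain reference bolus."""

    arrival_index: int = 20
    shape: float = 3.0
    scale_seconds: float = 3.0
    peak_amplitude: float = 15.0  # 1/s
    recirculation_fraction: float = 0.25
    steady_state_level: float = 0.3  # 1/s

    def validate(self) -> None:
        if self.shape <= 0 or self.scale_seconds <= 0:
            raise ValidationError("gamma shape and scale must be positive")
        if self.arrival_index < 5:
            raise ValidationError("arrival_index must be >= 5 so a baseline exists")
        if not 0 <= self.recirculation_fraction <= 1:
            raise ValidationError("recirculation_fraction must be in [0, 1]")
        if self.steady_state_level < 0 or self.peak_amplitude < 0:
            raise ValidationError("amplitudes must be nonnegative")


@dataclass
class PhantomSpec:
    """Ground truth and geometry of one synthetic case."""

    grid_shape: tuple[int, int, int] = (16, 16, 4)
    n_timepoints: int = 100
    tr_seconds: float = 1.1
    te_seconds: float = 0.030
    s0_mean: float = 600.0
    noise_sd: float = 12.0
    gamma_params: GammaParams = field(default_factory=GammaParams)
    k1_map: np.ndarray | None = None
    k2_map: np.ndarray | None = None
    kep_map: np.ndarray | None = None
    mask_layout: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mask_layout is None:
            self.mask_layout = default_mask_layout(self.grid_shape)
        self.mask_layout = np.asarray(self.mask_layout)
        if self.k1_map is None:
            self.k1_map = np.where(self.mask_layout > BACKGROUND, 1.0, 0.0)
        if self.k2_map is None:
            self.k2_map = np.zeros(self.grid_shape)
        if self.kep_map is None:
            self.kep_map = np.zeros(self.grid_shape)
        for name in ("k1_map", "k2_map", "kep_map"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValidationError("grid_shape must be 3 positive integers")
        if self.n_timepoints < 20:
            raise ValidationError("n_timepoints must be >= 20")
        if self.tr_seconds <= 0 or self.te_seconds <= 0 or self.s0_mean <= 0:
            raise ValidationError("TR, TE and s0_mean must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        self.gamma_params.validate()
        if self.gamma_params.arrival_index >= self.n_timepoints - 10:
            raise ValidationError("bolus arrival too late for the series length")
        for name in ("k1_map", "k2_map", "kep_map", "mask_layout"):
            if getattr(self, name).shape != tuple(self.grid_shape):
                raise ValidationError(f"{name} does not match grid_shape")
        labels = self.mask_layout
        if not np.isin(np.unique(labels), (BACKGROUND, NORMAL_BRAIN, NAWM, TUMOR)).all():
            raise ValidationError("mask_layout contains unknown labels")
        quiescent = np.isin(labels, (NORMAL_BRAIN, NAWM))
        if np.any(self.k2_map[quiescent] != 0) or np.any(self.kep_map[quiescent] != 0):
            raise ValidationError(
                "normal brain and NAWM voxels must have K2 = Kep = 0"
            )


def default_mask_layout(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Simple box geometry: brain interior, one tumor box, one NAWM box."""
    nx, ny, nz = grid_shape
    if nx < 10 or ny < 10 or nz < 2:
        raise ValidationError("default layout needs a grid of at least 10 x 10 x 2")
    labels = np.zeros(grid_shape, dtype=np.uint8)
    labels[1 : nx - 1, 1 : ny - 1, :] = NORMAL_BRAIN
    tw = max(2, nx // 4)
    labels[2 : 2 + tw, 2 : 2 + tw, 0:2] = TUMOR
    labels[nx - 5 : nx - 2, ny - 5 : ny - 2, 0:2] = NAWM
    return labels


def gamma_variate(
    t_seconds: np.ndarray, shape: float, scale_seconds: float, amplitude: float
) -> np.ndarray:
    """Peak-normalized gamma variate A ((u / s sigma)^s) exp(s - u / sigma).

    ``t_seconds`` is time since bolus arrival; values at u <= 0 are zero and
    the peak value ``amplitude`` occurs at u = shape * scale_seconds.
    """
    if shape <= 0 or scale_seconds <= 0:
        raise ValidationError("gamma shape and scale must be positive")
    u = np.asarray(t_seconds, dtype=float)
    out = np.zeros_like(u)
    pos = u > 0
    x = u[pos] / scale_seconds
    out[pos] = amplitude * (x / shape) ** shape * np.exp(shape - x)
    return out


def make_reference_curve(spec: PhantomSpec) -> ReferenceCurve:
    """Synthetic whole-brain average relaxivity-time curve dR2*(t) in 1/s.

    First-pass gamma variate plus a delayed recirculation bump (same shape
    and scale, scaled by the recirculation fraction) plus a
    steady-state plateau that ramps in with the cumulative first pass. The
    bolus component is truncated to exactly zero once it falls below 1e-7 of
    the peak so that noiseless tails return identically to baseline.
    """
    g = spec.gamma_params
    g.validate()
    dt = spec.tr_seconds
    t = np.arange(spec.n_timepoints) * dt
    u = t - g.arrival_index * dt
    first = gamma_variate(u, g.shape, g.scale_seconds, g.peak_amplitude)
    delay = 2.0 * g.shape * g.scale_seconds
    recirc = g.recirculation_fraction * gamma_variate(
        u - delay, g.shape, g.scale_seconds, g.peak_amplitude
    )
    bolus = first + recirc
    bolus[bolus < _TRUNCATION_REL * g.peak_amplitude] = 0.0

    if g.steady_state_level > 0 and first.any():
        ramp = cumulative_integral(first, dt)
        ramp = ramp / ramp[-1]
        values = bolus + g.steady_state_level * ramp
    else:
        values = bolus
    return ReferenceCurve(values=values, time_step=dt, n_voxels_averaged=1)


def simulate_voxel_signal(
    ref_values: np.ndarray,
    time_step: float,
    k1: float,
    k2: float,
    kep: float,
    s0: float,
    noise_sd: float,
    te_seconds: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward-model one voxel's signal trace from the reference curve.

    dR2*(t) = k1 R(t) - k2 * exp-weighted integral of R (kep = 0 reduces to
    the plain cumulative integral), then S(t) = s0 exp(-TE dR2*(t)) plus
    additive Gaussian noise of SD ``noise_sd`` in signal units.
    """
    if te_seconds <= 0 or s0 <= 0:
        raise ValidationError("s0 and te_seconds must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    ref_values = np.asarray(ref_values, dtype=float)
    leak = exp_weighted_integral(ref_values, time_step, kep)
    model = k1 * ref_values - k2 * leak
    signal = s0 * np.exp(-te_seconds * model)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return signal


@dataclass
class SimulatedCase:
    """One simulated patient: data, masks and ground truth."""

    series: DSCSeries
    vois: VOISet
    labels: np.ndarray
    truth_k1: np.ndarray
    truth_k2: np.ndarray
    truth_kep: np.ndarray
    truth_table: pd.DataFrame
    reference: ReferenceCurve


def simulate_case(spec: PhantomSpec) -> SimulatedCase:
    """Generate one case, fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    ref = make_reference_curve(spec)
    dt, te = spec.tr_seconds, spec.te_seconds
    labels = spec.mask_layout
    brain = labels > BACKGROUND
    T = spec.n_timepoints

    # per-voxel baseline signal: mild multiplicative heterogeneity
    s0_map = spec.s0_mean * np.exp(rng.normal(0.0, 0.02, size=spec.grid_shape))

    signal = np.empty(spec.grid_shape + (T,), dtype=float)
    signal[~brain] = 0.05 * spec.s0_mean

    k1 = spec.k1_map[brain]
    k2 = spec.k2_map[brain]
    kep = spec.kep_map[brain]
    leak = exp_weighted_integral(ref.values, dt, kep)  # (n_brain, T)
    model = k1[:, None] * ref.values[None, :] - k2[:, None] * leak
    signal[brain] = s0_map[brain, None] * np.exp(-te * model)

    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)

    series = DSCSeries(signal=signal, tr_seconds=dt, te_seconds=te)
    vois = VOISet(brain=brain, tumor=labels == TUMOR, nawm=labels == NAWM)

    window = locate_bolus_window(ref, RunConfig())
    bolus_area = cbv_maps.integrate_rcbv(ref.values, window, dt)
    nawm_k1 = spec.k1_map[labels == NAWM].mean()
    rows = []
    for name, code in (("tumor", TUMOR), ("nawm", NAWM), ("normal_brain", NORMAL_BRAIN)):
        sel = labels == code
        rows.append(
            {
                "region": name,
                "n_voxels": int(sel.sum()),
                "mean_k1": float(spec.k1_map[sel].mean()),
                "mean_k2": float(spec.k2_map[sel].mean()),
                "mean_kep": float(spec.kep_map[sel].mean()),
                "truth_rcbv_normalized": float(
                    (spec.k1_map[sel] / nawm_k1).mean()
                ),
                "bolus_area": float(bolus_area),
            }
        )
    truth_table = pd.DataFrame(rows)
    return SimulatedCase(
        series=series,
        vois=vois,
        labels=labels,
        truth_k1=spec.k1_map,
        truth_k2=spec.k2_map,
        truth_kep=spec.kep_map,
        truth_table=truth_table,
        reference=ref,
    )


def simulate_cohort(spec: PhantomSpec, out_dir: str | Path) -> dict[str, Path]:
    """Simulate one case and write it to disk; returns the file manifest.

    Writes the 4-D signal, the label volume, the three binary masks, the
    three ground-truth K maps (NIfTI), the per-region truth table (TSV) and
    the scalar part of the spec (YAML).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    case = simulate_case(spec)
    affine = case.series.affine
    paths: dict[str, Path] = {}
    paths["dsc"] = save_volume(case.series.signal, affine, out_dir / "dsc.nii.gz")
    paths["labels"] = save_volume(case.labels.astype(np.uint8), affine, out_dir / "labels.nii.gz")
    for name in ("brain", "tumor", "nawm"):
        mask = getattr(case.vois, name).astype(np.uint8)
        paths[name] = save_volume(mask, affine, out_dir / f"{name}.nii.gz")
    for name, data in (
        ("truth_k1", case.truth_k1), ("truth_k2", case.truth_k2), ("truth_kep", case.truth_kep),
    ):
        paths[name] = save_volume(data, affine, out_dir / f"{name}.nii.gz")
    table_path = out_dir / "truth_table.tsv"
    case.truth_table.to_csv(table_path, sep="\t", index=False)
    paths["truth_table"] = table_path

    scalars = {
        "grid_shape": list(spec.grid_shape),
        "n_timepoints": spec.n_timepoints,
        "tr_seconds": spec.tr_seconds,
        "te_seconds": spec.te_seconds,
        "s0_mean": spec.s0_mean,
        "noise_sd": spec.noise_sd,
        "gamma_params": asdict(spec.gamma_params),
        "seed": spec.seed,
        "truth_maps": "see truth_*.nii.gz",
    }
    spec_path = out_dir / "spec.yaml"
    spec_path.write_text(yaml.safe_dump(scalars, sort_keys=False))
    paths["spec"] = spec_path
    return paths


# ---------------------------------------------------------------------------
# cohort-level ground-truth sampling

_K1_BY_GRADE = {2: 1.5, 3: 2.5, 4: 3.2}
_GRADE_P = {
    "enhancing": ([2, 3, 4], [4 / 35, 1 / 35, 30 / 35]),
    "nonenhancing": ([2, 3, 4], [9 / 14, 4 / 14, 1 / 14]),
}


def make_phantom_spec(
    seed: int,
    group: str = "enhancing",
    grade: int | None = None,
    **overrides,
) -> tuple[PhantomSpec, int]:
    """Draw one patient's ground-truth phantom for the given lesion group.

    Tumor K1 scales with WHO grade (sampled from the group's grade mix when
    not given); tumor K2 is negative (T2*-dominant leakage), strong for
    enhancing and near zero for nonenhancing lesions; tumor Kep is a small
    nonnegative back-transfer rate. Returns the spec and the grade used.
    """
    if group not in ("enhancing", "nonenhancing"):
        raise ValidationError("group must be 'enhancing' or 'nonenhancing'")
    rng = np.random.default_rng(seed)
    grades, probs = _GRADE_P[group]
    if grade is None:
        grade = int(rng.choice(grades, p=probs))
    if grade not in _K1_BY_GRADE:
        raise ValidationError("grade must be 2, 3 or 4")

    base = PhantomSpec(seed=seed, **overrides)
    labels = base.mask_layout
    shape = tuple(base.grid_shape)

    k1_p = max(0.5, rng.normal(_K1_BY_GRADE[grade], 0.6))
    if group == "enhancing":
        k2_p = min(-0.005, rng.normal(-0.04, 0.015))
        kep_p = float(np.clip(rng.normal(0.015, 0.008), 0.002, 0.08))
    else:
        k2_p = float(np.clip(rng.normal(-0.008, 0.006), -0.03, -0.0005))
        kep_p = float(np.clip(rng.normal(0.005, 0.004), 0.0, 0.03))

    k1 = np.zeros(shape)
    k2 = np.zeros(shape)
    kep = np.zeros(shape)
    normal = labels == NORMAL_BRAIN
    nawm = labels == NAWM
    tumor = labels == TUMOR
    k1[normal] = rng.normal(1.1, 0.12, size=int(normal.sum())).clip(0.5)
    k1[nawm] = rng.normal(1.0, 0.05, size=int(nawm.sum())).clip(0.5)
    k1[tumor] = rng.normal(k1_p, 0.15 * k1_p, size=int(tumor.sum())).clip(0.1)
    k2[tumor] = np.minimum(
        rng.normal(k2_p, 0.3 * abs(k2_p), size=int(tumor.sum())), -1e-4
    )
    kep[tumor] = rng.normal(kep_p, 0.5 * kep_p + 1e-9, size=int(tumor.sum())).clip(0.0, 0.2)

    spec = PhantomSpec(
        grid_shape=shape,
        n_timepoints=base.n_timepoints,
        tr_seconds=base.tr_seconds,
        te_seconds=base.te_seconds,
        s0_mean=base.s0_mean,
        noise_sd=base.noise_sd,
        gamma_params=base.gamma_params,
        k1_map=k1,
        k2_map=k2,
        kep_map=kep,
        mask_layout=labels,
        seed=seed,
    )
    return spec, grade


def cohort_specs(
    n_enhancing: int, n_nonenhancing: int, seed: int, **overrides
) -> list[dict]:
    """Phantom specs for a two-group cohort; one entry per patient.

    Each entry carries ``patient_id``, ``group``, ``grade`` and ``spec``.
    Sub-seeds stay below 2**31.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for group, count in (("enhancing", n_enhancing), ("nonenhancing", n_nonenhancing)):
        for i in range(count):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec, grade = make_phantom_spec(sub_seed, group=group, **overrides)
            entries.append(
                {
                    "patient_id": f"{group[:3]}-{i + 1:03d}",
                    "group": group,
                    "grade": grade,
                    "spec": spec,
                }
            )
    return entries
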