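"""Run configuration.

Every threshold the pipeline applies is named here with its default, so a run
can be audited from the single YAML file that is written next to its outputs.
Defaults follow the standard DSC-MRI post-processing constants: a 5-SD signal
drop for voxel inclusion, the final 10 time points as the tail, a 1-SD
tail-versus-baseline criterion for nonenhancing-voxel selection, and two
discarded leading volumes to let the gradient-echo signal reach steady state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

VALID_MODELS = ("none", "unidir", "bidir", "all")


@dataclass
class RunConfig:
    """All tunable thresholds of a pipeline run.

    Parameters
    ----------
    discard_leading : int
        Leading time frames dropped before any analysis (non-steady-state
        signal), default 2.
    baseline_init_points : int
        Number of initial points seeding the iterative baseline search on the
        whole-brain average curve.
    baseline_guard : int
        Points excluded between the detected bolus arrival and the end of the
        baseline window.
    baseline_threshold_sd : float
        Bolus arrival is declared where the averaged curve exceeds
        baseline mean + this many baseline SDs (two consecutive points).
    baseline_min_points : int
        Minimum length of the baseline window.
    drop_threshold_sd : float
        A voxel must drop at least this many baseline SDs below baseline
        during bolus passage to be analysed (contrast-to-noise QC).
    tail_points : int
        Number of final time points forming the tail window.
    tail_threshold_sd : float
        Nonenhancing voxels satisfy |mean(tail) - S0| < this many baseline SDs.
    bolus_exit_fraction : float
        Bolus exit t1 is the first post-peak index where the curve falls below
        baseline + this fraction of (peak - baseline), unless a
        pre-recirculation local minimum occurs earlier.
    peak_min_sd : float
        Minimum reference-curve peak height in baseline SDs; below this no
        bolus is detectable.
    kep_min, kep_max : float
        Bounds of the Kep search grid (1/s) for the bidirectional fit.
    kep_grid_points : int
        Coarse grid size over [kep_min, kep_max]; 0 is always added.
    clamp_fraction : float
        Non-positive signal samples are clamped to this fraction of S0 before
        the log transform.
    max_clamped_fraction : float
        Voxels with more than this fraction of clamped in-window samples are
        excluded from all maps.
    min_reference_voxels : int
        Minimum number of voxels averaged into the reference curve.
    sd_epsilon : float
        Absolute epsilon replacing "1 SD" when a baseline SD is exactly zero
        (noiseless data), in signal units.
    alpha : float
        Significance level for the cohort statistics.
    model : str
        Which leakage corrections to run: none / unidir / bidir / all.
    seed : int
        Seed for any stochastic step.
    """

    discard_leading: int = 2
    baseline_init_points: int = 8
    baseline_guard: int = 1
    baseline_threshold_sd: float = 2.0
    baseline_min_points: int = 5
    drop_threshold_sd: float = 5.0
    tail_points: int = 10
    tail_threshold_sd: float = 1.0
    bolus_exit_fraction: float = 0.2
    peak_min_sd: float = 5.0
    kep_min: float = -0.2
    kep_max: float = 1.0
    kep_grid_points: int = 41
    clamp_fraction: float = 1e-6
    max_clamped_fraction: float = 0.10
    min_reference_voxels: int = 100
    sd_epsilon: float = 1e-9
    alpha: float = 0.05
    model: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "baseline_threshold_sd",
            "drop_threshold_sd",
            "tail_threshold_sd",
            "bolus_exit_fraction",
            "peak_min_sd",
            "clamp_fraction",
            "sd_epsilon",
            "alpha",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name!r} must be positive")
        if self.discard_leading < 0:
            raise ValidationError("discard_leading must be >= 0")
        if self.tail_points < 1:
            raise ValidationError("tail_points must be >= 1")
        if self.kep_min > self.kep_max:
            raise ValidationError("kep_min must not exceed kep_max")
        if self.kep_grid_points < 3:
            raise ValidationError("kep_grid_points must be >= 3")
        if self.model not in VALID_MODELS:
            raise ValidationError(
                f"model must be one of {VALID_MODELS}, got {self.model!r}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
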