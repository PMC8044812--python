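"""NIfTI input/output and the in-memory containers for a DSC case.

Masks are consumed as given and assumed co-registered to the DSC grid; the
loader only verifies that grids and affines agree. Affines are carried
through untouched to every written map — no resampling ever happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError

# the full set of per-case output maps, in manifest order
MAP_NAMES = (
    "rcbv",
    "rcbv_unidir",
    "rcbv_bidir",
    "k2_unidir",
    "k2_bidir",
    "kep_bidir",
    "adj_r2_unidir",
    "adj_r2_bidir",
)

_AFFINE_TOL = 1e-3


@dataclass
class DSCSeries:
    """A 4-D DSC signal time series with its acquisition timing.

    ``signal`` is (x, y, z, t) in arbitrary MR signal units; ``tr_seconds``
    is the dynamic sampling interval and ``te_seconds`` the echo time.
    """

    signal: np.ndarray
    tr_seconds: float
    te_seconds: float
    discarded_leading_volumes: int = 0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValidationError(
                f"DSC series must be 4-D (x, y, z, t), got {self.signal.ndim}-D"
            )
        if self.signal.shape[-1] < 20:
            raise ValidationError("DSC series must retain at least 20 time points")
        if self.tr_seconds <= 0 or self.te_seconds <= 0:
            raise ValidationError("TR and TE must be strictly positive")
        if self.discarded_leading_volumes < 0:
            raise ValidationError("discarded_leading_volumes must be >= 0")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[-1]


@dataclass
class VOISet:
    """Binary brain / tumor / NAWM masks on the DSC grid.

    ``tumor`` is the contrast-enhancing VOI (CET) for enhancing lesions or
    the non-enhancing VOI (NCET) otherwise; ``nawm`` is the
    normal-appearing-white-matter normalization region.
    """

    brain: np.ndarray
    tumor: np.ndarray
    nawm: np.ndarray
    min_nawm_voxels: int = 10

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("brain", "tumor", "nawm"):
            arr = np.asarray(getattr(self, name))
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError(
                    f"{name} mask must be binary, found values {vals[:5]}"
                )
            arrays[name] = arr.astype(bool)
        if not (arrays["brain"].shape == arrays["tumor"].shape == arrays["nawm"].shape):
            raise ValidationError("masks must share one grid")
        if np.any(arrays["nawm"] & arrays["tumor"]):
            raise ValidationError("NAWM and tumor masks overlap")
        if np.any(arrays["nawm"] & ~arrays["brain"]):
            raise ValidationError("NAWM mask extends outside the brain mask")
        if int(arrays["nawm"].sum()) < self.min_nawm_voxels:
            raise ValidationError(
                f"NAWM mask has {int(arrays['nawm'].sum())} voxels "
                f"(< {self.min_nawm_voxels}); normalization would be unstable"
            )
        self.brain, self.tumor, self.nawm = (
            arrays["brain"], arrays["tumor"], arrays["nawm"],
        )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.brain.shape


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing input file: {path}")
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.affine)


def load_case(
    dsc_path: str | Path,
    brain_path: str | Path,
    tumor_path: str | Path,
    nawm_path: str | Path,
    tr_seconds: float,
    te_seconds: float,
) -> tuple[DSCSeries, VOISet]:
    """Load one case: 4-D DSC series plus its three co-registered masks.

    Leading-volume discard is *not* applied here (that is a relaxometry
    step). Grid or affine mismatches between any pair of inputs raise a
    :class:`~dscleak.errors.ValidationError`.
    """
    signal, affine = _load_nifti(dsc_path)
    if signal.ndim != 4:
        raise ValidationError(
            f"DSC input must be a 4-D time series, got {signal.ndim}-D: {dsc_path}"
        )
    masks = {}
    for name, path in (("brain", brain_path), ("tumor", tumor_path), ("nawm", nawm_path)):
        data, aff = _load_nifti(path)
        if data.shape != signal.shape[:3]:
            raise ValidationError(
                f"{name} mask grid {data.shape} does not match DSC grid "
                f"{signal.shape[:3]}"
            )
        if np.max(np.abs(aff - affine)) > _AFFINE_TOL:
            raise ValidationError(f"{name} mask affine differs from the DSC affine")
        masks[name] = data
    series = DSCSeries(signal=signal, tr_seconds=tr_seconds, te_seconds=te_seconds,
                       affine=affine)
    vois = VOISet(brain=masks["brain"], tumor=masks["tumor"], nawm=masks["nawm"])
    return series, vois


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a single volume as NIfTI, preserving float64 values exactly."""
    path = Path(path)
    data = np.asarray(data)
    dtype = data.dtype if data.dtype in (np.uint8, np.int16, np.int32) else np.float64
    img = nib.Nifti1Image(data.astype(dtype), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path


def write_maps(
    maps: dict[str, np.ndarray], affine: np.ndarray, out_dir: str | Path
) -> list[Path]:
    """Write per-case 3-D maps as NIfTI files and return the file manifest.

    ``maps`` is keyed by names from :data:`MAP_NAMES`; only the maps present
    are written (a model that was not run produces no files). Voxels excluded
    by QC are NaN in every map.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise ValidationError(f"cannot create output directory {out_dir}: {exc}")
    unknown = set(maps) - set(MAP_NAMES)
    if unknown:
        raise ValidationError(f"unknown map names: {sorted(unknown)}")
    manifest = []
    for name in MAP_NAMES:
        if name in maps:
            manifest.append(save_volume(maps[name], affine, out_dir / f"{name}.nii.gz"))
    return manifest
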