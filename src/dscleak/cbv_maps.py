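"""rCBV map computation: bolus-window integration and NAWM normalization.

rCBV is the trapezoidal integral of the relaxivity-time curve between the
bolus entrance and exit time points. Each map (uncorrected, unidirectionally
and bidirectionally corrected) is normalized by dividing every voxel by that
map's own mean over the NAWM mask, computed over usable (non-NaN) voxels
only; voxels excluded by QC or failed fits stay NaN so they cannot bias VOI
medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, ValidationError
from .relaxometry import AcquisitionWindow


def integrate_rcbv(
    values: np.ndarray, window: AcquisitionWindow, time_step: float
) -> np.ndarray:
    """Trapezoidal integral over [t0, t1] along the last axis.

    Negative results (pathological voxels) are preserved, not clipped.
    Returns a scalar for a single trace, an array for a stack.
    """
    values = np.asarray(values, dtype=float)
    if window.t1 >= values.shape[-1]:
        raise ValidationError("bolus window exceeds the curve length")
    seg = values[..., window.bolus]
    out = np.trapezoid(seg, dx=time_step, axis=-1)
    return float(out) if out.ndim == 0 else out


def normalize_to_nawm(
    raw_map: np.ndarray, nawm_mask: np.ndarray
) -> tuple[np.ndarray, float]:
    """Divide a raw map by its own NAWM mean; returns (map, divisor).

    NaN voxels pass through; the divisor is computed over finite NAWM voxels
    only and must be strictly positive.
    """
    raw_map = np.asarray(raw_map, dtype=float)
    nawm = np.asarray(nawm_mask, dtype=bool)
    vals = raw_map[nawm]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise NumericalError("no usable NAWM voxels to normalize against")
    divisor = float(vals.mean())
    if divisor <= 0:
        raise NumericalError(
            f"NAWM mean of the raw map is {divisor:g} (<= 0); cannot normalize"
        )
    return raw_map / divisor, divisor


@dataclass
class CBVMapSet:
    """Normalized rCBV maps of one case (NaN where a voxel was excluded)."""

    rcbv_uncorrected: np.ndarray
    rcbv_unidir: np.ndarray | None
    rcbv_bidir: np.ndarray | None
    nawm_mean_raw: dict[str, float]
    window: AcquisitionWindow

    def as_dict(self) -> dict[str, np.ndarray]:
        out = {"rcbv": self.rcbv_uncorrected}
        if self.rcbv_unidir is not None:
            out["rcbv_unidir"] = self.rcbv_unidir
        if self.rcbv_bidir is not None:
            out["rcbv_bidir"] = self.rcbv_bidir
        return out
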