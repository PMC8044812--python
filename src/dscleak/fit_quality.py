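"""Goodness of fit: voxelwise R-squared and its adjusted form.

R2 = 1 - SS_res / SS_tot compares a model-fitted relaxivity curve with the
observed one; the adjusted value penalizes model size k (2 parameters for
the unidirectional model, 3 for the bidirectional). A constant observed
trace has SS_tot = 0 and an undefined R2, returned as NaN.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def r_squared(observed: np.ndarray, fitted: np.ndarray):
    """Coefficient of determination along the last axis.

    Returns ``(r2, ss_res, ss_tot)``; r2 is NaN where the observed trace is
    constant (ss_tot = 0).
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValidationError("observed and fitted traces must share a shape")
    if observed.shape[-1] < 3:
        raise ValidationError("need at least 3 time points for R-squared")
    resid = fitted - observed
    ss_res = np.sum(resid * resid, axis=-1)
    centered = observed - observed.mean(axis=-1, keepdims=True)
    ss_tot = np.sum(centered * centered, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), np.nan)
    if r2.ndim == 0:
        return float(r2), float(ss_res), float(ss_tot)
    return r2, ss_res, ss_tot


def adjusted_r_squared(r2, n, k):
    """Adjusted R2 = 1 - (1 - R2)(n - 1)/(n - k - 1); may be negative.

    ``n`` is the number of time points actually used in the fit and ``k``
    the number of model parameters. Requires n > k + 1. Accepts arrays.
    """
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n)
    k = np.asarray(k)
    if np.any(n <= k + 1):
        raise ValidationError("adjusted R-squared requires n > k + 1")
    out = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return float(out) if out.ndim == 0 else out
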