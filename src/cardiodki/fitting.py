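"""Weighted linear least-squares (WLS) estimation of DTI and DKI parameters.

The log-linearised model ln S = X beta is first solved by ordinary least
squares; a second pass solves the weighted normal equations with weights equal
to the squared *predicted* signals from the first pass.  Squared-signal
weights undo the heteroscedasticity introduced by the log transform and,
using predictions rather than observations, stay robust to noisy samples.

No positivity or kurtosis-range constraints are imposed; nonphysical voxels
are flagged downstream rather than clipped.  Non-positive signals (possible
for phase-corrected real-valued data at low SNR) are excluded per measurement
rather than floored, preserving the symmetry of the noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionScheme
from .model import DiffusionTensor, KurtosisTensor, design_matrix

__all__ = ["DkiFit", "fit_dti_wls", "fit_dki_wls", "fit_image"]


@dataclass
class DkiFit:
    """Per-voxel fit result.

    ``W`` is ``None`` for DTI-only fits.  ``residuals`` are log-signal
    residuals, defined only over ``included`` measurements.  ``ok`` is False
    when the design was rank-deficient or the fitted S0 was non-positive.
    """

    s0: float
    D: DiffusionTensor | None
    W: KurtosisTensor | None
    residuals: np.ndarray
    included: np.ndarray
    ok: bool
    reason: str = ""
    n_excluded_nonpositive: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def md(self) -> float:
        return float(np.trace(self.D.matrix)) / 3.0


def _wls_solve(X: np.ndarray, logy: np.ndarray) -> np.ndarray:
    """Two-pass WLS: OLS on ln S, then weights = squared predicted signals."""
    beta_ols, *_ = np.linalg.lstsq(X, logy, rcond=None)
    w = np.exp(2.0 * (X @ beta_ols))          # predicted S^2
    sw = np.sqrt(w)[:, None]
    beta, *_ = np.linalg.lstsq(X * sw, logy * sw[:, 0], rcond=None)
    return beta

def _fit_linear(signals: np.ndarray, X: np.ndarray,
                min_rows: int) -> DkiFit:
    signals = np.asarray(signals, dtype=float)
    included = np.isfinite(signals) & (signals > 0)
    n_excl = int(np.sum(~included))
    n_params = X.shape[1]
    resid = np.full(len(signals), np.nan)
    if included.sum() < max(min_rows, n_params):
        return DkiFit(np.nan, None, None, resid, included, False,
                      reason=f"only {included.sum()} usable measurements",
                      n_excluded_nonpositive=n_excl)
    Xi = X[included]
    if np.linalg.matrix_rank(Xi) < n_params:
        return DkiFit(np.nan, None, None, resid, included, False,
                      reason="rank-deficient design",
                      n_excluded_nonpositive=n_excl)
    logy = np.log(signals[included])
    beta = _wls_solve(Xi, logy)
    resid[included] = logy - Xi @ beta
    s0 = float(np.exp(beta[0]))
    D = DiffusionTensor.from_elements(*beta[1:7])
    if n_params == 7:
        W = None
    else:
        md = float(np.trace(D.matrix)) / 3.0
        if md <= 0:
            return DkiFit(s0, D, None, resid, included, False,
                          reason="non-positive fitted MD, W unrecoverable",
                          n_excluded_nonpositive=n_excl)
        W = KurtosisTensor(beta[7:22] / md ** 2)
    ok = np.isfinite(s0) and s0 > 0
    return DkiFit(s0, D, W, resid, included, ok,
                  reason="" if ok else "non-positive fitted S0",
                  n_excluded_nonpositive=n_excl)


def fit_dti_wls(signals: np.ndarray, scheme: AcquisitionScheme,
                subset_bvals=None) -> DkiFit:
    """DTI WLS fit (7 parameters: ln S0 and the 6 tensor elements).

    *subset_bvals* restricts the fit to the named shells, e.g. ``{100, 450}``;
    the subset must span >= 2 distinct b-values.  Non-positive signals are
    excluded (count reported on the fit).
    """
    signals = np.asarray(signals, dtype=float)
    if subset_bvals is not None:
        sub, sel = scheme.subset(subset_bvals)
    else:
        sub, sel = scheme, np.ones(len(scheme), dtype=bool)
    if len(sub.unique_bvals) < 2:
        raise ValueError("DTI subset needs >= 2 distinct b-values "
                         f"(got {sub.unique_bvals.tolist()})")
    X = design_matrix(sub, check=False)[:, :7]
    fit = _fit_linear(signals[sel], X, min_rows=7)
    # map inclusion/residuals back onto the full measurement axis
    included = np.zeros(len(scheme), dtype=bool)
    included[sel] = fit.included
    resid = np.full(len(scheme), np.nan)
    resid[sel] = fit.residuals
    fit.included, fit.residuals = included, resid
    fit.meta["subset_bvals"] = None if subset_bvals is None else sorted(subset_bvals)
    return fit


def fit_dki_wls(signals: np.ndarray, scheme: AcquisitionScheme,
                subset_bvals=None) -> DkiFit:
    """DKI WLS fit (22 parameters); W is recovered from the MD^2-scaled
    coefficients by dividing by the fitted MD^2."""
    if subset_bvals is not None:
        sub, sel = scheme.subset(subset_bvals)
    else:
        sub, sel = scheme, np.ones(len(scheme), dtype=bool)
    X = design_matrix(sub)  # raises on < 2 distinct nonzero shells
    fit = _fit_linear(np.asarray(signals, float)[sel], X, min_rows=22)
    included = np.zeros(len(scheme), dtype=bool)
    included[sel] = fit.included
    resid = np.full(len(scheme), np.nan)
    resid[sel] = fit.residuals
    fit.included, fit.residuals = included, resid
    fit.meta["subset_bvals"] = None if subset_bvals is None else sorted(subset_bvals)
    return fit


def fit_image(data: np.ndarray, scheme: AcquisitionScheme, mask: np.ndarray,
              model: str = "dki", subset_bvals=None,
              measurement_mask: np.ndarray | None = None) -> dict:
    """Voxelwise independent fits over a mask.

    Parameters
    ----------
    data : (..., N) real-valued image stack, last axis = measurements.
    mask : (...) boolean; voxels outside are skipped.
    model : "dti" or "dki".
    subset_bvals : optional shell restriction passed to the fitter.
    measurement_mask : optional (N,) boolean from outlier rejection; excluded
        frames are dropped for every voxel.

    Returns a dict of maps: ``s0`` (...), ``D`` (..., 3, 3), ``W``
    (..., 15) (DKI only), ``ok`` (...) boolean.  Voxels that fail keep
    NaN and ok=False; the pipeline continues.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    spatial = data.shape[:-1]
    out_s0 = np.full(spatial, np.nan)
    out_D = np.full(spatial + (3, 3), np.nan)
    out_ok = np.zeros(spatial, dtype=bool)
    out_W = np.full(spatial + (15,), np.nan) if model == "dki" else None
    fitter = fit_dki_wls if model == "dki" else fit_dti_wls

    if measurement_mask is not None:
        keep = np.asarray(measurement_mask, dtype=bool)
        sub = AcquisitionScheme(scheme.bvals[keep], scheme.bvecs[keep],
                                scheme.shell_id[keep], scheme.repeat_id[keep])
        data = data[..., keep]
        scheme = sub

    for idx in zip(*np.nonzero(mask)):
        fit = fitter(data[idx], scheme, subset_bvals=subset_bvals)
        if fit.ok:
            out_s0[idx] = fit.s0
            out_D[idx] = fit.D.matrix
            if model == "dki":
                out_W[idx] = fit.W.w15
        out_ok[idx] = fit.ok
    result = {"s0": out_s0, "D": out_D, "ok": out_ok, "model": model}
    if model == "dki":
        result["W"] = out_W
    return result
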