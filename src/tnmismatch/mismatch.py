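"""Per-ROI robust regression of metabolism on tau and residual discretization.

For each ROI, FDG SUVR is regressed on log tau SUVR across participants with
an M-estimator using Tukey's bisquare weight function (tuning constant 4.685,
normalized-MAD scale), so gross outliers get zero weight.  The mismatch
residual is observed minus predicted FDG SUVR: positive residuals mean more
metabolism than the cohort line predicts at that tau level (resilience
direction), negative residuals mean less (susceptibility direction).

Residuals are discretized per ROI at a cutpoint of ``threshold_sd`` (default
0.6) times the ROI's residual SD: +1 above, -1 below, 0 within.  Under a
Gaussian residual law the 0.6 SD rule flags the farthest ~27% of points on
each side.  The "SD" is the ordinary sample SD of the fitted residuals; the
robust MAD scale is retained on each fit for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rois import RoiMeta

__all__ = [
    "DegenerateFitError",
    "RoiFit",
    "ResidualSet",
    "fit_robust_roi_regression",
    "compute_residual_matrix",
    "discretize_residuals",
]

BISQUARE_C = 4.685
MAX_ITER = 50
COEF_TOL = 1e-8


class DegenerateFitError(ValueError):
    """Raised when a regression cannot be identified (constant predictor)."""


@dataclass
class RoiFit:
    """One ROI's fitted line and residual scales."""

    roi_id: str
    alpha: float  # FDG SUVR intercept
    beta: float  # FDG SUVR change per unit log tau
    scale: float  # robust (MAD-based) residual scale
    residual_sd: float  # ordinary sample SD of residuals
    n_used: int
    converged: bool


@dataclass
class ResidualSet:
    """Per-ROI fits plus the continuous and discretized residual matrices."""

    fits: list
    residuals: pd.DataFrame  # participant x ROI, FDG SUVR units
    discretized: pd.DataFrame | None = None  # entries in {-1, 0, +1}
    threshold_sd: float | None = None

    @property
    def residual_sd(self) -> pd.Series:
        return pd.Series({f.roi_id: f.residual_sd for f in self.fits})

    def fits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "roi_id": f.roi_id,
                    "alpha": f.alpha,
                    "beta": f.beta,
                    "scale": f.scale,
                    "residual_sd": f.residual_sd,
                    "n_used": f.n_used,
                    "converged": f.converged,
                }
                for f in self.fits
            ]
        )


def fit_robust_roi_regression(fdg: np.ndarray, tau: np.ndarray,
                              roi_id: str = "") -> RoiFit:
    """Bisquare M-estimation of ``fdg ~ log(tau)`` for one ROI.

    Iteratively reweighted least squares with Tukey bisquare weights
    (c=4.685), scale estimated by normalized median absolute deviation,
    at most 50 iterations, coefficient-change tolerance 1e-8.

    Raises
    ------
    DegenerateFitError
        If fewer than 10 complete pairs remain or log tau is constant.
    """
    fdg = np.asarray(fdg, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if fdg.shape != tau.shape:
        raise ValueError("fdg and tau must have the same length")
    keep = np.isfinite(fdg) & np.isfinite(tau)
    fdg, tau = fdg[keep], tau[keep]
    if fdg.size < 10:
        raise DegenerateFitError(f"ROI {roi_id!r}: need >= 10 complete pairs, got {fdg.size}")
    if np.any(tau <= 0):
        raise ValueError(f"ROI {roi_id!r}: tau SUVR must be strictly positive")
    x = np.log(tau)
    if np.ptp(x) < 1e-12:
        raise DegenerateFitError(f"ROI {roi_id!r}: log tau has zero variance")

    exog = sm.add_constant(x)
    model = sm.RLM(fdg, exog, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # scale_est="mad" (the default) is the normalized median absolute deviation
        res = model.fit(maxiter=MAX_ITER, tol=COEF_TOL, conv="coefs", scale_est="mad")
    converged = bool(getattr(res, "converged", True))
    if not converged:
        warnings.warn(f"ROI {roi_id!r}: robust fit did not converge in {MAX_ITER} iterations")
    resid = fdg - res.fittedvalues
    sd = float(np.std(resid, ddof=1))
    return RoiFit(
        roi_id=roi_id,
        alpha=float(res.params[0]),
        beta=float(res.params[1]),
        scale=float(res.scale),
        residual_sd=sd,
        n_used=int(fdg.size),
        converged=converged,
    )


def compute_residual_matrix(tau: pd.DataFrame, fdg: pd.DataFrame,
                            rois: list[RoiMeta] | None = None) -> ResidualSet:
    """Fit every ROI and assemble the continuous residual matrix.

    ``tau`` and ``fdg`` are participant x ROI DataFrames with identical index
    and columns.  Participants with a missing value in either modality are
    dropped from that ROI's fit and get a missing residual there.
    """
    if not tau.index.equals(fdg.index) or not tau.columns.equals(fdg.columns):
        raise ValueError("tau and fdg tables must share row and column ordering")
    if rois is not None:
        roi_ids = [r.roi_id for r in rois]
        if list(tau.columns) != roi_ids:
            raise ValueError("ROI metadata does not match table columns")
    fits: list[RoiFit] = []
    degenerate: list[str] = []
    resid = pd.DataFrame(np.nan, index=tau.index, columns=tau.columns)
    for roi_id in tau.columns:
        t = tau[roi_id].to_numpy(dtype=float)
        f = fdg[roi_id].to_numpy(dtype=float)
        try:
            fit = fit_robust_roi_regression(f, t, roi_id=roi_id)
        except DegenerateFitError as exc:
            degenerate.append(str(exc))
            continue
        fits.append(fit)
        ok = np.isfinite(t) & np.isfinite(f)
        r = np.full(t.shape, np.nan)
        r[ok] = f[ok] - (fit.alpha + fit.beta * np.log(t[ok]))
        resid[roi_id] = r
    if degenerate:
        raise DegenerateFitError("degenerate ROI fits: " + "; ".join(degenerate))
    return ResidualSet(fits=fits, residuals=resid)


def discretize_residuals(rset: ResidualSet, threshold_sd: float = 0.6) -> ResidualSet:
    """Fill the {-1, 0, +1} discretization at ``threshold_sd`` x residual SD.

    Strict inequalities: a residual exactly at the cutpoint codes 0.  Missing
    residuals code 0 (direction unknown; neutral).
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    sd = rset.residual_sd.reindex(rset.residuals.columns)
    cut = threshold_sd * sd.to_numpy()
    r = rset.residuals.to_numpy()
    disc = np.zeros(r.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        disc[r > cut] = 1
        disc[r < -cut] = -1
    n_missing = int(np.isnan(r).sum())
    if n_missing:
        warnings.warn(f"{n_missing} missing residual(s) coded 0 in discretization")
    rset.discretized = pd.DataFrame(disc, index=rset.residuals.index,
                                    columns=rset.residuals.columns)
    rset.threshold_sd = float(threshold_sd)
    return rset
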