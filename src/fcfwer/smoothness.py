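"""Image smoothness estimation and resel counting.

Two FWHM estimators are provided:

* ``fwhm_from_roughness`` — from the covariance matrix Lambda of the spatial
  partial derivatives of a standardized field: FWHM = sqrt(4 ln 2) *
  |Lambda|^(-1/4).  For white noise convolved with a Gaussian kernel this
  recovers the *kernel* FWHM, the quantity resel formulas assume.
* ``fwhm_from_autocorrelation`` — the width of the 1-D spatial
  autocorrelation at 1/2, the convention of an earlier open-source toolbox.
  For a Gaussian-smoothed field this width is sqrt(2) times the kernel FWHM,
  so the two methods deliberately disagree; the historical off-by-one
  (origin counted twice, inflating the width by exactly one pixel) can be
  replicated with a flag.

Resel (resolution element) counts follow the Worsley lattice approximation:
pixels P, lattice edges E, 2x2 faces F give R0 = P - E + F (the Euler
characteristic of the region), R1 = (E - 2F)/FWHM and R2 = F/FWHM^2.

``bartlett_dof`` gives the effective number of independent frames of two
autocorrelated time series, eta = n / sum_k rho_a(k) rho_b(k).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from statsmodels.tsa.stattools import acf

__all__ = [
    "RoughnessEstimate",
    "ReselCounts",
    "spatial_partial_derivatives",
    "roughness_matrix",
    "fwhm_from_roughness",
    "estimate_fwhm_roughness",
    "fwhm_from_autocorrelation",
    "resel_counts",
    "bartlett_dof",
]

_SQRT_4LN2 = math.sqrt(4.0 * math.log(2.0))


@dataclass
class RoughnessEstimate:
    """Derivative (co)variances of a standardized field, in pixel^-2 units."""

    Vxx: float
    Vyy: float
    Vxy: float
    det_lambda: float
    fwhm: float
    n_pixels_used: int
    eta: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class ReselCounts:
    P: int            # in-mask pixels
    E: int            # in-mask lattice edges
    F: int            # fully in-mask 2x2 faces
    R0: int           # Euler characteristic of the search region
    R1: float         # 1-D resels
    R2: float         # 2-D resels
    fwhm_used: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


# ---------------------------------------------------------------------------
# Roughness-based FWHM
# ---------------------------------------------------------------------------

def spatial_partial_derivatives(image: np.ndarray, mask: np.ndarray):
    """Forward differences u(x+1,y)-u(x,y) and u(x,y+1)-u(x,y).

    x indexes columns and y indexes rows.  A difference is defined only where
    both pixels lie in the mask; undefined entries are NaN.  Returns
    ``(du_x, du_y)`` with the same shape as ``image``.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not np.all(np.isfinite(image[mask])):
        raise ValueError("image must be finite inside the mask")

    du_x = np.full(image.shape, np.nan)
    du_y = np.full(image.shape, np.nan)
    vx = mask[:, :-1] & mask[:, 1:]
    vy = mask[:-1, :] & mask[1:, :]
    du_x[:, :-1][vx] = (image[:, 1:] - image[:, :-1])[vx]
    du_y[:-1, :][vy] = (image[1:, :] - image[:-1, :])[vy]

    if vx.sum() + vy.sum() < 4:
        raise ValueError("fewer than 4 in-mask difference pairs; roughness undefined")
    return du_x, du_y


def roughness_matrix(
    du_x: np.ndarray, du_y: np.ndarray, eta: float = np.inf, N: int | None = None
) -> RoughnessEstimate:
    """Mean-centered derivative (co)variances with the small-sample factor.

    Each moment is ``(1/N) * (eta-2)/(eta-1) * sum (du - <du>)^2`` over the
    common support (pixels where both derivatives are defined), which makes
    Lambda a genuine sample covariance matrix (so |Lambda| >= 0).  As
    ``eta -> inf`` the factor tends to 1/N, the plain sample moment.
    """
    if eta <= 2:
        raise ValueError(f"eta must exceed 2, got {eta}")
    both = np.isfinite(du_x) & np.isfinite(du_y)
    n_used = int(both.sum())
    if N is None:
        N = n_used
    dx = du_x[both] - du_x[both].mean()
    dy = du_y[both] - du_y[both].mean()
    factor = (1.0 / N) if np.isinf(eta) else (eta - 2.0) / (eta - 1.0) / N
    Vxx = float(factor * np.sum(dx * dx))
    Vyy = float(factor * np.sum(dy * dy))
    Vxy = float(factor * np.sum(dx * dy))
    det = Vxx * Vyy - Vxy * Vxy
    fwhm = _SQRT_4LN2 * det ** (-0.25) if det > 0 else float("inf")
    return RoughnessEstimate(Vxx, Vyy, Vxy, float(det), float(fwhm), n_used,
                             float(eta))


def fwhm_from_roughness(rough: RoughnessEstimate) -> float:
    """FWHM = sqrt(4 ln 2) |Lambda|^(-1/4) (2D form)."""
    if rough.det_lambda <= 0:
        raise ValueError("det_lambda must be positive (field is infinitely smooth)")
    return _SQRT_4LN2 * rough.det_lambda ** (-0.25)


def estimate_fwhm_roughness(
    image: np.ndarray, mask: np.ndarray, eta: float = np.inf,
    standardize: bool = True,
) -> float:
    """Convenience pipeline: standardize, differentiate, and estimate FWHM."""
    image = np.asarray(image, dtype=float)
    if standardize:
        vals = image[mask]
        image = (image - vals.mean()) / vals.std()
    du_x, du_y = spatial_partial_derivatives(image, mask)
    return fwhm_from_roughness(roughness_matrix(du_x, du_y, eta=eta))


# ---------------------------------------------------------------------------
# Autocorrelation-width FWHM
# ---------------------------------------------------------------------------

def _axis_acf_width(image: np.ndarray, mask: np.ndarray, axis: int) -> float:
    """Width at half maximum of the pooled 1-D autocorrelation along an axis."""
    img = np.where(mask, image - image[mask].mean(), 0.0)
    m = mask.astype(float)
    if axis == 0:
        img, m = img.T, m.T
    n_lines, n = img.shape
    max_lag = n - 1
    num = np.zeros(max_lag + 1)
    den = np.zeros(max_lag + 1)
    for lag in range(max_lag + 1):
        a = img[:, : n - lag] * img[:, lag:]
        w = m[:, : n - lag] * m[:, lag:]
        num[lag] = np.sum(a * w)
        den[lag] = np.sum(w)
    with np.errstate(invalid="ignore"):
        rho = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    rho = rho / rho[0]
    below = np.where(rho < 0.5)[0]
    below = below[np.isfinite(rho[below])]
    if below.size == 0:
        raise ValueError("autocorrelation never crosses 1/2 within available lags")
    k = int(below[0])  # first lag below 1/2; interpolate between k-1 and k
    r_hi, r_lo = rho[k - 1], rho[k]
    frac = (r_hi - 0.5) / (r_hi - r_lo)
    return 2.0 * ((k - 1) + frac)


def fwhm_from_autocorrelation(
    image: np.ndarray, mask: np.ndarray, replicate_origin_bug: bool = False
) -> float:
    """FWHM as the width of the spatial autocorrelation at 1/2.

    Autocorrelations are pooled over in-mask pixel pairs along rows and along
    columns, the half-height crossing is located by linear interpolation, and
    the two axis widths are averaged.  With ``replicate_origin_bug`` the
    result is exactly one pixel larger, reproducing the historical fault in
    which the origin was counted twice.
    """
    wx = _axis_acf_width(np.asarray(image, float), np.asarray(mask, bool), axis=1)
    wy = _axis_acf_width(np.asarray(image, float), np.asarray(mask, bool), axis=0)
    width = 0.5 * (wx + wy)
    return width + 1.0 if replicate_origin_bug else width


# ---------------------------------------------------------------------------
# Resel counting
# ---------------------------------------------------------------------------

def resel_counts(mask: np.ndarray, fwhm: float) -> ReselCounts:
    """Worsley lattice resel counts of a masked search region."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    mask = np.asarray(mask, dtype=bool)
    P = int(mask.sum())
    if P == 0:
        raise ValueError("empty mask")
    E = int((mask[:, :-1] & mask[:, 1:]).sum() + (mask[:-1, :] & mask[1:, :]).sum())
    F = int((mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]).sum())
    R0 = P - E + F
    R1 = (E - 2 * F) / fwhm
    R2 = F / fwhm**2
    return ReselCounts(P, E, F, R0, float(R1), float(R2), float(fwhm))


# ---------------------------------------------------------------------------
# Bartlett effective temporal degrees of freedom
# ---------------------------------------------------------------------------

def bartlett_dof(trace_a: np.ndarray, trace_b: np.ndarray,
                 max_lag: int | None = None) -> float:
    """Effective dof of the correlation between two autocorrelated series.

    eta = n / sum_{|k| <= K} rho_a(k) * rho_b(k), with K = n/4 by default and
    the result capped at n.  Positive shared autocorrelation inflates the
    denominator and shrinks the effective sample size.
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be 1-D and of equal length")
    n = a.size
    if n < 20:
        raise ValueError("traces must have length >= 20")
    K = n // 4 if max_lag is None else int(max_lag)
    rho_a = acf(a, nlags=K, fft=True)
    rho_b = acf(b, nlags=K, fft=True)
    denom = rho_a[0] * rho_b[0] + 2.0 * float(np.sum(rho_a[1:] * rho_b[1:]))
    if denom <= 0:
        raise ValueError("Bartlett denominator is non-positive")
    return float(min(n / denom, n))
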