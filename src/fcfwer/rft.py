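"""Random field theory inference for 2D statistic images.

Expected Euler characteristic (EC) densities for Gaussian and t fields give
the expected number of suprathreshold clusters in a search region,

    mu(T) = s * sum_d R_d * f_d(T),

with R_d the d-dimensional resel counts and s the sidedness correction (2 for
a two-sided comparison of symmetric null fields).  Pixel-wise inference
solves mu(T) = alpha for the critical statistic; cluster-extent inference
models cluster sizes as exponential with per-pixel rate lambda, so a cluster
of k pixels has tail probability beta = exp(-lambda k) and familywise
p-value p = 1 - exp(-mu * beta).

The EC densities follow the canonical Worsley forms.  Two documented faults
of an earlier toolbox are replicable by flags: the "simplified" lambda (a
large-T Gaussian approximation, lambda = 2 ln 2 T^2 / (pi FWHM^2)) and the
cluster-forming-threshold bug (clusters formed at p = 0.05 while mu, lambda
and the extent threshold are computed at the nominal cluster-defining p).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import optimize, special, stats

from .smoothness import ReselCounts

__all__ = [
    "RFTConfig",
    "ClusterRecord",
    "ec_density_gaussian",
    "ec_density_t",
    "ec_density",
    "expected_cluster_count",
    "solve_pixel_threshold",
    "pixel_pvalue",
    "cluster_defining_threshold",
    "cluster_lambda",
    "cluster_size_threshold",
    "cluster_pvalue",
    "rft_cluster_inference",
]

_TWO_PI = 2.0 * math.pi
_LN2 = math.log(2.0)


@dataclass
class RFTConfig:
    """Every modeling choice of an RFT analysis."""

    distribution: str = "gaussian"      # {"gaussian", "t"}
    nu: float | None = None             # t degrees of freedom
    sidedness: int = 2                  # s in the EC-count formula
    mu_terms: str = "unified"           # {"2d_only", "unified"}
    lambda_form: str = "full"           # {"full", "simplified"}
    search_region: str = "mask"         # {"full_frame", "mask"}
    cluster_defining_p: float = 0.001
    alpha: float = 0.05
    replicate_threshold_bug: bool = False
    fwhm: float = 10.0

    def __post_init__(self):
        if self.distribution not in ("gaussian", "t"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "t":
            if self.nu is None or self.nu < 3:
                raise ValueError("t distribution requires nu >= 3")
        if self.sidedness not in (1, 2):
            raise ValueError("sidedness must be 1 or 2")
        if not 0 < self.cluster_defining_p < self.alpha < 1:
            raise ValueError("require 0 < cluster_defining_p < alpha < 1")


@dataclass
class ClusterRecord:
    label: int
    size: int           # k, pixels
    sign: str           # "+" or "-"
    peak_abs_t: float
    p_value: float


# ---------------------------------------------------------------------------
# Euler characteristic densities
# ---------------------------------------------------------------------------

def ec_density_gaussian(T: float, d: int) -> float:
    """Expected EC per resel of dimension d for a unit Gaussian field."""
    if d == 0:
        return float(stats.norm.sf(T))
    if d == 1:
        return math.sqrt(_LN2) / math.pi * math.exp(-T * T / 2.0)
    if d == 2:
        return 4.0 * _LN2 / _TWO_PI**1.5 * T * math.exp(-T * T / 2.0)
    raise ValueError(f"dimension must be 0, 1 or 2, got {d}")


def ec_density_t(T: float, d: int, nu: float) -> float:
    """Expected EC per resel of dimension d for a t field with nu dof.

    Converges to the Gaussian densities as nu -> infinity.
    """
    if nu < 1:
        raise ValueError("nu must be >= 1")
    if d == 0:
        return float(stats.t.sf(T, nu))
    shape = (1.0 + T * T / nu) ** (-(nu - 1.0) / 2.0)
    if d == 1:
        return math.sqrt(_LN2) / math.pi * shape
    if d == 2:
        # Gamma((nu+1)/2) / (sqrt(nu/2) Gamma(nu/2)) -> 1 as nu -> inf
        gam = math.exp(special.gammaln((nu + 1.0) / 2.0) - special.gammaln(nu / 2.0))
        gam /= math.sqrt(nu / 2.0)
        return 4.0 * _LN2 / _TWO_PI**1.5 * gam * T * shape
    raise ValueError(f"dimension must be 0, 1 or 2, got {d}")


def ec_density(T: float, d: int, cfg: RFTConfig) -> float:
    if cfg.distribution == "gaussian":
        return ec_density_gaussian(T, d)
    return ec_density_t(T, d, cfg.nu)


# ---------------------------------------------------------------------------
# Expected cluster count and pixel-wise inference
# ---------------------------------------------------------------------------

def expected_cluster_count(resels: ReselCounts, T: float, cfg: RFTConfig) -> float:
    """mu = s * sum_d R_d f_d(T) (or the 2D term alone)."""
    if cfg.mu_terms == "2d_only":
        mu = resels.R2 * ec_density(T, 2, cfg)
    elif cfg.mu_terms == "unified":
        mu = (
            resels.R0 * ec_density(T, 0, cfg)
            + resels.R1 * ec_density(T, 1, cfg)
            + resels.R2 * ec_density(T, 2, cfg)
        )
    else:
        raise ValueError(f"unknown mu_terms {cfg.mu_terms!r}")
    return cfg.sidedness * mu


def solve_pixel_threshold(resels: ReselCounts, cfg: RFTConfig) -> float:
    """The statistic threshold at which mu equals the nominal FWER."""
    if not 0 < cfg.alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")

    def f(T):
        return expected_cluster_count(resels, T, cfg) - cfg.alpha

    # mu(T) is guaranteed strictly decreasing only above the f2 mode at T=1
    lo, hi = 1.0, 50.0
    if f(lo) <= 0 or f(hi) >= 0:
        raise ValueError("no root for mu(T) = alpha in [1, 50]")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def pixel_pvalue(T: float, resels: ReselCounts, cfg: RFTConfig) -> float:
    """Pixel-wise corrected p-value: min(1, mu(|T|))."""
    return min(1.0, expected_cluster_count(resels, abs(T), cfg))


# ---------------------------------------------------------------------------
# Cluster-extent inference
# ---------------------------------------------------------------------------

def cluster_defining_threshold(p: float, cfg: RFTConfig) -> float:
    """One-tailed inverse upper-tail threshold of the configured distribution."""
    if cfg.distribution == "gaussian":
        return float(stats.norm.isf(p))
    return float(stats.t.isf(p, cfg.nu))


def cluster_lambda(mu: float, V: int, T: float, cfg: RFTConfig) -> float:
    """Per-pixel rate of the exponential cluster-size law.

    full:       lambda = Gamma(2) mu / (s V f0(T))   (Gamma(2) = 1)
    simplified: lambda = 2 ln 2 T^2 / (pi FWHM^2)
    """
    if cfg.lambda_form == "simplified":
        lam = 2.0 * _LN2 * T * T / (math.pi * cfg.fwhm**2)
    elif cfg.lambda_form == "full":
        if mu <= 0 or V <= 0:
            raise ValueError("full lambda requires mu > 0 and V > 0")
        f0 = ec_density(T, 0, cfg)
        if f0 <= 0:
            raise ValueError("f0(T) underflowed to zero")
        lam = mu / (cfg.sidedness * V * f0)
    else:
        raise ValueError(f"unknown lambda_form {cfg.lambda_form!r}")
    return float(lam)


def cluster_size_threshold(mu: float, lam: float, alpha: float,
                           integer: bool = True) -> float:
    """Minimum cluster extent k with familywise p-value alpha.

    k = (1/lambda) ln(-mu / ln(1 - alpha)); reported rounded to the nearest
    integer unless ``integer=False``.  If mu <= -ln(1-alpha), any cluster is
    already significant and k = 1 is returned with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    bound = -math.log1p(-alpha)
    if mu <= bound:
        warnings.warn(
            "expected cluster count below -ln(1-alpha); every cluster significant",
            stacklevel=2,
        )
        return 1
    k = math.log(-mu / math.log1p(-alpha)) / lam
    return int(round(k)) if integer else float(k)


def cluster_pvalue(k: float, mu: float, lam: float) -> float:
    """p = 1 - exp(-mu * exp(-lambda k))."""
    beta = math.exp(-lam * k)
    return float(-math.expm1(-mu * beta))


def cluster_decision_rule(resels: ReselCounts, V: int, cfg: RFTConfig):
    """Forming threshold and extent threshold of a cluster-wise RFT analysis.

    Returns ``(T_form, mu, lam, k_threshold)``; clusters of extent
    >= ``k_threshold`` formed at ``T_form`` are declared significant.
    """
    T_def = cluster_defining_threshold(cfg.cluster_defining_p, cfg)
    T_form = cluster_defining_threshold(0.05, cfg) if cfg.replicate_threshold_bug else T_def
    mu = expected_cluster_count(resels, T_def, cfg)
    lam = cluster_lambda(mu, V, T_def, cfg)
    k = cluster_size_threshold(mu, lam, cfg.alpha)
    return T_form, mu, lam, k


def rft_cluster_inference(stat_map, resels: ReselCounts, cfg: RFTConfig):
    """Cluster-extent RFT on a statistic map; one p-value per cluster.

    Clusters are 8-connected excursions of ``t > T_form`` and (two-sided) of
    ``t < -T_form`` inside the analysis mask.  With
    ``cfg.replicate_threshold_bug`` the forming threshold corresponds to
    p = 0.05 while mu, lambda and the extent threshold are still computed at
    ``cfg.cluster_defining_p``, reproducing the documented fault.

    Returns ``(records, k_threshold)`` where ``records`` is a list of
    :class:`ClusterRecord` and significance means ``size >= k_threshold``.
    """
    from .connectivity import label_clusters  # local import: no cycle at module load

    if stat_map.t_values.shape != stat_map.analysis_mask.shape:
        raise ValueError("statistic map and analysis mask shapes differ")
    if cfg.search_region == "full_frame":
        V = int(np.prod(stat_map.analysis_mask.shape))
    else:
        V = int(stat_map.analysis_mask.sum())

    T_form, mu, lam, k_thresh = cluster_decision_rule(resels, V, cfg)
    if mu > 1:
        warnings.warn("expected cluster count exceeds 1; high-threshold "
                      "approximation is unreliable", stacklevel=2)

    clusters = label_clusters(stat_map, T_form, sidedness=cfg.sidedness)
    records = []
    for i, (size, sign, peak) in enumerate(clusters, start=1):
        records.append(
            ClusterRecord(
                label=i,
                size=size,
                sign=sign,
                peak_abs_t=peak,
                p_value=cluster_pvalue(size, mu, lam),
            )
        )
    return records, k_thresh
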