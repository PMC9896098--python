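"""Mass-empirical familywise error rate audit on null data.

Every configured inference method is applied to the two-group t-map of every
subject split of null data; a split counts as a familywise false positive if
the method declares *any* pixel or cluster significant, and the empirical
FWER is the fraction of such splits.  Because the data are null by
construction, a well-calibrated method should land within Monte-Carlo noise
of its nominal alpha; parametric methods whose assumptions fail (Gaussian
random field theory applied to low-dof t fields, bugged thresholds, wrong
sidedness) reveal themselves as inflated rates.

Diagnostics mirror the observed-vs-expected comparisons that expose the
failure mode: the mean number of suprathreshold clusters as a function of the
threshold, against the Gaussian and t-field predictions, and the empirical
cluster-size distribution against the exponential model.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import rft
from .connectivity import group_tmaps_for_splits, label_excursions
from .permutation import (
    MaxNullDistribution,
    SplitPlan,
    critical_value,
    max_stat_distribution,
)
from .smoothness import ReselCounts, resel_counts

__all__ = [
    "MethodSpec",
    "FWERResult",
    "ClusterCountCurve",
    "run_mass_fwer",
    "cluster_count_curve",
    "cluster_size_pdf",
    "summarize_fwer",
    "mc_standard_error",
    "is_nominal",
]


@dataclass
class MethodSpec:
    """One cell of the method sweep.

    ``family`` is one of ``rft_pixel``, ``rft_cluster``, ``perm_pixel``,
    ``perm_cluster``.  RFT families carry an :class:`~fcfwer.rft.RFTConfig`;
    permutation families a calibration split count and (cluster kind) a
    cluster-defining threshold.  Whatever the family, detection is applied
    two-tailed to the t-map, as a two-group comparison demands.
    """

    method_id: str
    family: str
    rft_config: rft.RFTConfig | None = None
    cluster_threshold: float | None = None   # permutation cluster-defining |T|
    alpha: float = 0.05

    def __post_init__(self):
        families = ("rft_pixel", "rft_cluster", "perm_pixel", "perm_cluster")
        if self.family not in families:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family.startswith("rft") and self.rft_config is None:
            raise ValueError(f"{self.method_id}: RFT family requires rft_config")
        if self.family == "perm_cluster" and self.cluster_threshold is None:
            raise ValueError(f"{self.method_id}: perm_cluster requires cluster_threshold")

    @classmethod
    def from_dict(cls, d: dict) -> "MethodSpec":
        d = dict(d)
        if "rft_config" in d and isinstance(d["rft_config"], dict):
            d["rft_config"] = rft.RFTConfig(**d["rft_config"])
        return cls(**d)


@dataclass
class FWERResult:
    method_id: str
    seed_name: str
    n_false_positive_splits: int
    M: int

    @property
    def fwer(self) -> float:
        return self.n_false_positive_splits / self.M

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fwer"] = self.fwer
        return d


@dataclass
class ClusterCountCurve:
    thresholds: np.ndarray
    observed: np.ndarray
    expected_gaussian_1s: np.ndarray
    expected_gaussian_2s: np.ndarray
    expected_t_1s: np.ndarray
    expected_t_2s: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "observed": self.observed,
                "expected_gaussian_1s": self.expected_gaussian_1s,
                "expected_gaussian_2s": self.expected_gaussian_2s,
                "expected_t_1s": self.expected_t_1s,
                "expected_t_2s": self.expected_t_2s,
            }
        )


def mc_standard_error(alpha: float, M: int) -> float:
    """Binomial Monte-Carlo standard error of an empirical rate."""
    return math.sqrt(alpha * (1.0 - alpha) / M)


def is_nominal(fwer: float, alpha: float, M: int) -> bool:
    """Within 2 Monte-Carlo standard errors of nominal."""
    return abs(fwer - alpha) <= 2.0 * mc_standard_error(alpha, M)


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------

class _Decision:
    """A method reduced to a per-t-map yes/no false-positive test."""

    def __init__(self, spec: MethodSpec, mask: np.ndarray,
                 calibration: MaxNullDistribution | None = None):
        self.spec = spec
        shape = mask.shape
        if spec.family.startswith("rft"):
            cfg = spec.rft_config
            if cfg.search_region == "full_frame":
                region = np.ones(shape, dtype=bool)
            else:
                region = mask
            resels = resel_counts(region, cfg.fwhm)
            self.region = region
            if spec.family == "rft_pixel":
                self.t_crit = rft.solve_pixel_threshold(resels, cfg)
            else:
                V = int(region.sum())
                self.t_form, _, _, self.k = rft.cluster_decision_rule(resels, V, cfg)
        else:
            if calibration is None:
                raise ValueError(f"{spec.method_id}: permutation method needs a "
                                 "calibration distribution")
            self.region = mask
            self.crit = critical_value(calibration, spec.alpha)
            self.t_form = spec.cluster_threshold

    def any_positive(self, tmap: np.ndarray) -> bool:
        fam = self.spec.family
        if fam == "rft_pixel":
            return bool(np.any(np.abs(tmap[self.region]) > self.t_crit))
        if fam == "perm_pixel":
            return bool(np.max(np.abs(tmap[self.region])) > self.crit)
        if fam == "rft_cluster":
            clusters = label_excursions(tmap, self.region, self.t_form, sidedness=2)
            return any(size >= self.k for size, _, _ in clusters)
        clusters = label_excursions(tmap, self.region, self.t_form, sidedness=2)
        return any(size > self.crit for size, _, _ in clusters)


def _calibrate(spec: MethodSpec, maps: np.ndarray, plan: SplitPlan,
               mask: np.ndarray) -> MaxNullDistribution | None:
    if not spec.family.startswith("perm"):
        return None
    statistic = "pixel_abs_t" if spec.family == "perm_pixel" else "cluster_size"
    return max_stat_distribution(
        maps, plan, statistic=statistic, analysis_mask=mask,
        cluster_threshold=spec.cluster_threshold, alpha=spec.alpha,
    )


# ---------------------------------------------------------------------------
# The audit
# ---------------------------------------------------------------------------

def run_mass_fwer(
    maps_per_seed: dict | np.ndarray,
    plan: SplitPlan,
    methods: list[MethodSpec],
    mask: np.ndarray,
    calibration_plan: SplitPlan | None = None,
) -> list[FWERResult]:
    """Empirical FWER of every method over every split and seed.

    ``maps_per_seed`` maps a seed name to per-subject 2D maps
    ``(n_subjects, rows, cols)`` (a bare array is treated as one unnamed
    seed).  ``plan`` provides the evaluation splits; permutation methods are
    calibrated on ``calibration_plan`` (kept disjoint from evaluation by the
    caller where desired).  A split counts once, no matter how many false
    positives it contains.
    """
    if not isinstance(maps_per_seed, dict):
        maps_per_seed = {"seed": np.asarray(maps_per_seed)}
    needs_cal = [m for m in methods if m.family.startswith("perm")]
    if needs_cal and calibration_plan is None:
        raise ValueError("permutation methods require a calibration_plan")

    results = []
    for seed_name, maps in maps_per_seed.items():
        maps = np.asarray(maps, dtype=float)
        decisions = []
        for spec in methods:
            cal = _calibrate(spec, maps, calibration_plan, mask) if spec in needs_cal else None
            decisions.append(_Decision(spec, mask, calibration=cal))
        tmaps = group_tmaps_for_splits(maps, plan.iter_assignments())
        counts = np.zeros(len(methods), dtype=int)
        for t in tmaps:
            for j, dec in enumerate(decisions):
                if dec.any_positive(t):
                    counts[j] += 1
        for spec, n_fp in zip(methods, counts):
            results.append(FWERResult(spec.method_id, seed_name, int(n_fp), plan.M))
    return results


def summarize_fwer(results: list[FWERResult]) -> pd.DataFrame:
    """Tidy per-seed table plus per-method median and range across seeds."""
    df = pd.DataFrame([r.to_dict() for r in results])
    agg = df.groupby("method_id")["fwer"].agg(
        median="median", low="min", high="max", n_seeds="count"
    )
    return agg.reset_index()


def results_to_csv(results: list[FWERResult], path: str) -> None:
    pd.DataFrame([r.to_dict() for r in results]).to_csv(path, index=False)


def results_to_json(results: list[FWERResult], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)


def permutation_generalization_study(
    n_subjects: int = 16,
    grid_shape: tuple = (64, 64),
    fwhm: float = 10.0,
    n_channels: int = 14,
    cluster_threshold: float = 3.79,
    m_calibration: int = 1000,
    m_evaluation: int = 2000,
    seed: int = 0,
) -> list[FWERResult]:
    """Held-out FWER of cluster-wise permutation inference on a null cohort.

    Simulates one cohort of smooth unit-variance null fields (``n_channels``
    independent map channels per subject, mirroring a multi-seed
    functional-connectivity study), calibrates the max-cluster-size
    distribution on ``m_calibration`` balanced splits per channel, and
    evaluates the resulting extent threshold on ``m_evaluation`` disjoint
    splits.  Returns one :class:`FWERResult` per channel; the study's summary
    statistic is the median FWER across channels.
    """
    from .permutation import sample_splits
    from .synthetic_data import SyntheticConfig, make_brain_mask, simulate_null_subject_maps

    cfg = SyntheticConfig(grid_shape=grid_shape, n_subjects=n_subjects,
                          fwhm_true=fwhm, rng_seed=seed)
    mask = make_brain_mask(cfg)
    maps = simulate_null_subject_maps(cfg, n_channels)
    plan_all = sample_splits(n_subjects, n_subjects // 2,
                             m_calibration + m_evaluation, rng_seed=seed + 1)
    cal = SplitPlan(n_subjects, n_subjects // 2, "sampled", m_calibration,
                    None, plan_all.assignments[:m_calibration])
    ev = SplitPlan(n_subjects, n_subjects // 2, "sampled", m_evaluation,
                   None, plan_all.assignments[m_calibration:])
    spec = MethodSpec("perm_cluster", "perm_cluster",
                      cluster_threshold=cluster_threshold)
    per_channel = {f"channel-{j:02d}": maps[:, j] for j in range(n_channels)}
    return run_mass_fwer(per_channel, ev, [spec], mask, calibration_plan=cal)


# ---------------------------------------------------------------------------
# Observed-vs-expected diagnostics
# ---------------------------------------------------------------------------

def cluster_count_curve(
    maps_per_seed: dict | np.ndarray,
    plan: SplitPlan,
    thresholds: np.ndarray,
    resels: ReselCounts,
    nu: float,
    mask: np.ndarray,
) -> ClusterCountCurve:
    """Mean two-sided cluster count per t-map at each |T|, with predictions."""
    if not isinstance(maps_per_seed, dict):
        maps_per_seed = {"seed": np.asarray(maps_per_seed)}
    thresholds = np.asarray(thresholds, dtype=float)
    counts = np.zeros(thresholds.size)
    n_maps = 0
    for maps in maps_per_seed.values():
        tmaps = group_tmaps_for_splits(np.asarray(maps, float), plan.iter_assignments())
        n_maps += tmaps.shape[0]
        for t in tmaps:
            for i, thr in enumerate(thresholds):
                counts[i] += len(label_excursions(t, mask, thr, sidedness=2))
    observed = counts / n_maps

    def expected(distribution, s):
        cfg = rft.RFTConfig(distribution=distribution,
                            nu=nu if distribution == "t" else None,
                            sidedness=s, mu_terms="unified",
                            fwhm=resels.fwhm_used)
        return np.array([rft.expected_cluster_count(resels, T, cfg) for T in thresholds])

    return ClusterCountCurve(
        thresholds=thresholds,
        observed=observed,
        expected_gaussian_1s=expected("gaussian", 1),
        expected_gaussian_2s=expected("gaussian", 2),
        expected_t_1s=expected("t", 1),
        expected_t_2s=expected("t", 2),
    )


def cluster_size_pdf(
    maps_per_seed: dict | np.ndarray,
    plan: SplitPlan,
    T: float,
    resels: ReselCounts,
    nu: float,
    mask: np.ndarray,
) -> pd.DataFrame:
    """Observed cluster-size histogram vs the exponential size model.

    Returns a table with the empirical probability mass at each size k and
    the model density lambda*exp(-lambda*k) for mu computed under Gaussian
    and t assumptions (both two-sided).
    """
    if not isinstance(maps_per_seed, dict):
        maps_per_seed = {"seed": np.asarray(maps_per_seed)}
    sizes = []
    for maps in maps_per_seed.values():
        tmaps = group_tmaps_for_splits(np.asarray(maps, float), plan.iter_assignments())
        for t in tmaps:
            sizes.extend(s for s, _, _ in label_excursions(t, mask, T, sidedness=2))
    V = int(mask.sum())
    ks = np.arange(1, max(sizes) + 1) if sizes else np.arange(1, 2)
    if sizes:
        hist = np.bincount(sizes, minlength=ks.size + 1)[1:]
        pmf = hist / hist.sum()
    else:
        pmf = np.zeros(ks.size)

    out = {"size": ks, "observed_pmf": pmf}
    for distribution in ("gaussian", "t"):
        cfg = rft.RFTConfig(distribution=distribution,
                            nu=nu if distribution == "t" else None,
                            sidedness=2, mu_terms="unified", lambda_form="full",
                            fwhm=resels.fwhm_used)
        mu = rft.expected_cluster_count(resels, T, cfg)
        lam = rft.cluster_lambda(mu, V, T, cfg)
        model = lam * np.exp(-lam * ks)
        out[f"model_{distribution}"] = model / model.sum()
    return pd.DataFrame(out)
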