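"""Seed-based functional connectivity maps and group t-statistic images.

Pipeline: per-subject time-series stacks are global-signal regressed and
band-passed, a seed trace is averaged over a small disk, per-pixel Pearson
correlation gives an r-map, and Fisher's transformation with a
Bartlett-corrected effective sample size gives an approximately unit-variance
z-map under the null, z = atanh(r) * sqrt(eta - 3).  Two-group comparisons
are pooled-variance Student t-tests per pixel, with per-pixel degrees of
freedom (subjects with valid data vary across pixels) and a minimum-subject
analysis mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .synthetic_data import SubjectDataset

__all__ = [
    "SeedSpec",
    "FCMaps",
    "StatMap",
    "global_signal_regress",
    "bandpass_filter",
    "seed_disk",
    "extract_seed_trace",
    "seed_correlation_map",
    "fisher_z",
    "groupwise_tmap",
    "group_tmaps_for_splits",
    "label_clusters",
    "label_excursions",
    "read_seed_table",
]

_CONN8 = np.ones((3, 3), dtype=int)
_CONN4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class SeedSpec:
    """A seed location in millimetres relative to bregma."""

    name: str
    ml_offset: float   # lateral (+ right of midline), mm
    ap_offset: float   # anterior (+) / posterior (-), mm
    radius: int = 5    # pixels

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("seed radius must be >= 1 pixel")


@dataclass
class FCMaps:
    subject_id: str
    seed_name: str
    r_map: np.ndarray
    z_map: np.ndarray
    eta: float


@dataclass
class StatMap:
    """A two-group t field with per-pixel dof and analysis mask."""

    t_values: np.ndarray
    dof_map: np.ndarray
    analysis_mask: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray


# ---------------------------------------------------------------------------
# Time-series preprocessing
# ---------------------------------------------------------------------------

def global_signal_regress(ds: SubjectDataset) -> SubjectDataset:
    """Remove the mask-mean time trace from every pixel by OLS.

    The frame-wise mask mean of the residual data is zero (OLS property).
    """
    mask = ds.valid_mask
    X = ds.stack[:, mask]                       # (frames, pixels)
    g = X.mean(axis=1)
    gc = g - g.mean()
    denom = float(gc @ gc)
    if denom == 0:
        raise ValueError("global trace is constant; regression undefined")
    beta = (gc @ (X - X.mean(axis=0))) / denom  # per-pixel slope
    resid = X - X.mean(axis=0) - np.outer(gc, beta)
    out = np.zeros_like(ds.stack)
    out[:, mask] = resid
    return SubjectDataset(ds.subject_id, out, mask, ds.frame_rate)


def bandpass_filter(ds: SubjectDataset, low: float = 0.01, high: float = 0.1,
                    order: int = 3) -> SubjectDataset:
    """Zero-phase Butterworth band-pass, per pixel."""
    nyq = ds.frame_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz invalid for frame rate {ds.frame_rate} Hz")
    sos = signal.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    mask = ds.valid_mask
    out = np.zeros_like(ds.stack)
    out[:, mask] = signal.sosfiltfilt(sos, ds.stack[:, mask], axis=0)
    return SubjectDataset(ds.subject_id, out, mask, ds.frame_rate)


# ---------------------------------------------------------------------------
# Seed extraction and correlation
# ---------------------------------------------------------------------------

def seed_pixel(seed: SeedSpec, mm_per_pixel: float, bregma_pixel: tuple) -> tuple:
    """Resolve a bregma-relative mm offset to a (row, col) pixel.

    Anterior is decreasing row index; lateral offset is applied along columns.
    """
    row = bregma_pixel[0] - seed.ap_offset / mm_per_pixel
    col = bregma_pixel[1] + seed.ml_offset / mm_per_pixel
    return (int(round(row)), int(round(col)))


def seed_disk(center: tuple, radius: int, shape: tuple) -> np.ndarray:
    """Boolean disk of pixels within Euclidean distance ``radius`` of center."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def extract_seed_trace(ds: SubjectDataset, seed: SeedSpec, mm_per_pixel: float,
                       bregma_pixel: tuple) -> np.ndarray:
    """Unweighted mean trace over the in-mask seed disk."""
    center = seed_pixel(seed, mm_per_pixel, bregma_pixel)
    if not (0 <= center[0] < ds.stack.shape[1] and 0 <= center[1] < ds.stack.shape[2]):
        raise ValueError(f"seed {seed.name!r} resolves outside the grid at {center}")
    disk = seed_disk(center, seed.radius, ds.valid_mask.shape) & ds.valid_mask
    if not disk.any():
        raise ValueError(f"seed {seed.name!r}: no valid pixels in seed disk")
    return ds.stack[:, disk].mean(axis=1)


def seed_correlation_map(ds: SubjectDataset, trace: np.ndarray) -> np.ndarray:
    """Pearson correlation of every in-mask pixel's series with the seed trace."""
    mask = ds.valid_mask
    X = ds.stack[:, mask]
    Xc = X - X.mean(axis=0)
    tc = trace - trace.mean()
    denom = np.sqrt(np.sum(Xc**2, axis=0) * float(tc @ tc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tc @ Xc) / denom
    r = np.clip(np.nan_to_num(r), -1.0, 1.0)
    out = np.full(mask.shape, np.nan)
    out[mask] = r
    return out


def fisher_z(r_map: np.ndarray, eta: float) -> np.ndarray:
    """Standardized Fisher transform, z = atanh(r) * sqrt(eta - 3)."""
    if eta <= 3:
        raise ValueError("eta must exceed 3")
    r = np.asarray(r_map, dtype=float)
    if np.nanmax(np.abs(r)) >= 1.0 - 1e-7:
        warnings.warn("|r| at or near 1; clipping before atanh", stacklevel=2)
    r = np.clip(r, -(1.0 - 1e-7), 1.0 - 1e-7)
    return np.arctanh(r) * np.sqrt(eta - 3.0)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def groupwise_tmap(maps_a, maps_b, min_per_group: int = 6) -> StatMap:
    """Pixel-wise pooled-variance two-sample t, with per-pixel dof.

    ``maps_a``/``maps_b`` are stacks of per-subject 2D maps (lists or arrays);
    NaN marks pixels where a subject has no data.  At each pixel only
    subjects with valid data enter, dof = nA + nB - 2, and the analysis mask
    keeps pixels with at least ``min_per_group`` subjects per group.
    Zero-pooled-variance pixels get t = 0 with a warning.
    """
    A = np.asarray(maps_a, dtype=float)
    B = np.asarray(maps_b, dtype=float)
    va, vb = np.isfinite(A), np.isfinite(B)
    n_a, n_b = va.sum(axis=0), vb.sum(axis=0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(np.where(va, A, np.nan), axis=0)
        mean_b = np.nanmean(np.where(vb, B, np.nan), axis=0)
        ss_a = np.nansum((A - mean_a) ** 2 * va, axis=0)
        ss_b = np.nansum((B - mean_b) ** 2 * vb, axis=0)

    dof = n_a + n_b - 2
    ok = (n_a >= 2) & (n_b >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = np.where(ok & (dof > 0), (ss_a + ss_b) / np.maximum(dof, 1), np.nan)
        se = np.sqrt(sp2 * (1.0 / np.maximum(n_a, 1) + 1.0 / np.maximum(n_b, 1)))
        t = (mean_a - mean_b) / se
    degenerate = ok & (sp2 == 0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} pixels with zero pooled variance; t set to 0",
                      stacklevel=2)
        t[degenerate] = 0.0
    t[~ok] = np.nan
    analysis_mask = (n_a >= min_per_group) & (n_b >= min_per_group)
    return StatMap(t, dof.astype(float), analysis_mask, n_a, n_b)


def group_tmaps_for_splits(maps: np.ndarray, assignments) -> np.ndarray:
    """Pooled-variance t-maps for many balanced splits at once.

    ``maps`` is ``(n_subjects, rows, cols)`` with complete data (shared mask);
    ``assignments`` is an iterable of group-A index tuples.  Returns
    ``(n_splits, rows, cols)``.  This is the vectorized fast path used by the
    permutation and audit machinery; it is numerically identical to
    :func:`groupwise_tmap` on complete data.
    """
    X = np.asarray(maps, dtype=float)
    n, rows, cols = X.shape
    flat = X.reshape(n, -1)
    sq = flat**2
    assignments = list(assignments)
    M = len(assignments)
    k = len(assignments[0])
    n_b = n - k
    dof = n - 2
    tot = flat.sum(axis=0)
    tot_sq = sq.sum(axis=0)

    out = np.empty((M, rows * cols))
    batch = max(1, int(2.5e7 // flat.shape[1]))
    for start in range(0, M, batch):
        idx = assignments[start : start + batch]
        W = np.zeros((len(idx), n))
        for i, a in enumerate(idx):
            W[i, list(a)] = 1.0
        sum_a = W @ flat
        sumsq_a = W @ sq
        sum_b = tot - sum_a
        sumsq_b = tot_sq - sumsq_a
        mean_a, mean_b = sum_a / k, sum_b / n_b
        ss = (sumsq_a - k * mean_a**2) + (sumsq_b - n_b * mean_b**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(ss / dof * (1.0 / k + 1.0 / n_b))
            t = (mean_a - mean_b) / se
        out[start : start + len(idx)] = np.nan_to_num(t)
    return out.reshape(M, rows, cols)


# ---------------------------------------------------------------------------
# Cluster labeling
# ---------------------------------------------------------------------------

def label_excursions(t: np.ndarray, mask: np.ndarray, T: float,
                     sidedness: int = 2, connectivity: int = 8):
    """Connected components of {t > T} and, if two-sided, of {t < -T}.

    Positive and negative excursions are labeled separately and never merged.
    Returns a list of ``(size, sign, peak_abs_t)`` tuples.
    """
    structure = _CONN8 if connectivity == 8 else _CONN4
    vals = np.where(mask, t, 0.0)
    out = []
    signs = [("+", vals > T)]
    if sidedness == 2:
        signs.append(("-", vals < -T))
    for sign, excursion in signs:
        lab, n = ndimage.label(excursion, structure=structure)
        for i in range(1, n + 1):
            sel = lab == i
            out.append((int(sel.sum()), sign, float(np.max(np.abs(vals[sel])))))
    return out


def label_clusters(stat_map: StatMap, T: float, sidedness: int = 2,
                   connectivity: int = 8):
    """Cluster components of a :class:`StatMap` above ``T`` (and below ``-T``)."""
    return label_excursions(stat_map.t_values, stat_map.analysis_mask, T,
                            sidedness=sidedness, connectivity=connectivity)


def read_seed_table(path: str) -> list[SeedSpec]:
    """Read seeds from CSV with columns name, ml_mm, ap_mm [, radius]."""
    df = pd.read_csv(path)
    radius = df["radius"] if "radius" in df else [5] * len(df)
    return [
        SeedSpec(str(n), float(ml), float(ap), int(r))
        for n, ml, ap, r in zip(df["name"], df["ml_mm"], df["ap_mm"], radius)
    ]
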