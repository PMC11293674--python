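"""Outlier screening, Kennard-Stone partitioning, and descriptive statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectra import NiTable, SpectrumSet

__all__ = ["SplitResult", "DescriptiveStats", "remove_outliers", "kennard_stone",
           "describe", "standardize_columns"]


@dataclass
class SplitResult:
    """Disjoint calibration/validation partition of the sample ids."""

    calibration_ids: list
    validation_ids: list
    fraction: float


@dataclass
class DescriptiveStats:
    """Summary of a concentration vector (sd with the n-1 denominator)."""

    n: int
    min: float
    max: float
    mean: float
    sd: float
    cv_percent: float


def remove_outliers(ni: NiTable, spectra: SpectrumSet, sd_factor: float = 3.0):
    """Iterative mean +/- sd_factor*SD screen on Ni until stable.

    Returns the filtered ``(NiTable, SpectrumSet, removed_ids)``; spectra and
    concentrations must cover the same samples.
    """
    if set(ni.sample_ids) != set(spectra.sample_ids):
        raise ValueError("Ni table and spectra cover different samples")
    if len(ni) < 3:
        raise ValueError("need at least 3 samples to screen for outliers")
    ids = list(ni.sample_ids)
    vals = ni.ni_mg_per_kg.copy()
    removed = []
    while True:
        m, s = vals.mean(), vals.std(ddof=1)
        keep = np.abs(vals - m) <= sd_factor * s
        if keep.all() or keep.sum() < 3:
            break
        removed.extend([i for i, k in zip(ids, keep) if not k])
        ids = [i for i, k in zip(ids, keep) if k]
        vals = vals[keep]
    return ni.subset(ids), spectra.subset(ids), removed


def kennard_stone(X: np.ndarray, fraction: float = 0.7, ids=None) -> SplitResult:
    """Deterministic Kennard-Stone calibration/validation split.

    Seeds with the two most distant samples (Euclidean), then repeatedly adds
    the candidate whose minimum distance to the selected set is largest, until
    round(fraction * n) samples are selected.  Ties break toward the lowest
    sample position, so the split is reproducible even with duplicate rows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if ids is None:
        ids = list(range(n))
    ids = [str(i) for i in ids]
    if len(ids) != n:
        raise ValueError("one id per row required")
    n_cal = int(math.floor(fraction * n + 0.5))
    n_cal = max(2, min(n_cal, n - 1))

    sq = (X**2).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2 * (X @ X.T)
    np.maximum(D, 0, out=D)
    # seed pair: maximal distance; np.argmax returns the first (lowest i, j)
    a, b = np.unravel_index(int(np.argmax(D)), D.shape)
    selected = [min(a, b), max(a, b)]
    in_sel = np.zeros(n, dtype=bool)
    in_sel[selected] = True
    mindist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_cal:
        cand = np.where(in_sel, -np.inf, mindist)
        nxt = int(np.argmax(cand))
        selected.append(nxt)
        in_sel[nxt] = True
        np.minimum(mindist, D[nxt], out=mindist)
    cal = sorted(selected)
    val = [i for i in range(n) if not in_sel[i]]
    return SplitResult(
        calibration_ids=[ids[i] for i in cal],
        validation_ids=[ids[i] for i in val],
        fraction=float(fraction),
    )


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Per-column z-scores (constant columns map to 0) — the default feature
    space handed to Kennard-Stone."""
    X = np.asarray(X, dtype=float)
    m = X.mean(axis=0)
    s = X.std(axis=0, ddof=1)
    s = np.where(s > 0, s, 1.0)
    return (X - m) / s


def describe(values) -> DescriptiveStats:
    """min/max/mean/SD (n-1) and CV% = 100*SD/mean of a vector (n >= 2)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(v.std(ddof=1))
    mean = float(v.mean())
    return DescriptiveStats(
        n=int(v.size),
        min=float(v.min()),
        max=float(v.max()),
        mean=mean,
        sd=sd,
        cv_percent=100.0 * sd / mean,
    )
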