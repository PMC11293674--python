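"""Two-band spectral indices, exhaustive pair-correlation maps, and feature
selection.

Six classical two-band indices are searched: brightness BI = sqrt(R1^2+R2^2),
normalized difference NDI = (R1-R2)/(R1+R2), ratio RI = R1/R2, difference
DI = R1-R2, product PI = R1*R2 and sum SI = R1+R2.  For every derivative
order, the Pearson correlation between each index at every band pair and the
soil Ni concentration is mapped over the full (lambda1, lambda2) grid; the
k strongest |r| combinations per index — mixing orders freely — become the
predictor set for regression.

Undefined index values (zero denominators, which the fractional derivative
can produce) are carried as NaN and excluded from correlation and ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fod import DerivativeSet
from .spectra import NiTable

__all__ = [
    "INDEX_NAMES",
    "INDEX_SYMMETRY",
    "CorrelationMap",
    "BandCombo",
    "FeatureTable",
    "compute_index",
    "correlation_map",
    "select_top_combos",
    "build_feature_table",
    "combos_to_frame",
    "map_to_long_frame",
    "render_combo",
]

INDEX_NAMES = ("BI", "NDI", "RI", "DI", "PI", "SI")

#: How each index behaves under swapping its two bands.
INDEX_SYMMETRY = {
    "BI": "symmetric",
    "PI": "symmetric",
    "SI": "symmetric",
    "NDI": "antisymmetric",
    "DI": "antisymmetric",
    "RI": "reciprocal",
}


def compute_index(name: str, r1, r2):
    """Evaluate one two-band index; zero denominators yield NaN, not errors."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if name == "BI":
        out = np.sqrt(r1**2 + r2**2)
    elif name == "NDI":
        den = r1 + r2
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den != 0, (r1 - r2) / np.where(den != 0, den, 1.0), np.nan)
    elif name == "RI":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r2 != 0, r1 / np.where(r2 != 0, r2, 1.0), np.nan)
    elif name == "DI":
        out = r1 - r2
    elif name == "PI":
        out = r1 * r2
    elif name == "SI":
        out = r1 + r2
    else:
        raise ValueError(f"unknown spectral index {name!r}")
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class CorrelationMap:
    """Pearson r between one index and Ni over all strided band pairs.

    ``r_matrix[i, j]`` corresponds to the ordered pair (lambda_i as R1,
    lambda_j as R2); undefined entries are NaN.
    """

    index_name: str
    order_v: float
    wavelengths_nm: np.ndarray
    r_matrix: np.ndarray
    stride_nm: int
    n_samples_used: int


@dataclass
class BandCombo:
    """One selected feature: an index at two bands of one derivative order."""

    index_name: str
    order_v: float
    lambda1_nm: float
    lambda2_nm: float
    r: float


@dataclass
class FeatureTable:
    """Per-sample values of an ordered list of selected band combinations."""

    sample_ids: list
    combos: list
    values: np.ndarray


def _pearson_columns(V: np.ndarray, y: np.ndarray, min_finite_fraction: float) -> np.ndarray:
    """Pearson r of each column of V against y, masking NaN entries per column.

    Columns with fewer than ``min_finite_fraction * n`` finite values, or zero
    variance on either side, come back NaN.
    """
    n = y.size
    mask = np.isfinite(V)
    cnt = mask.sum(axis=0)
    ok = cnt >= 2
    safe_cnt = np.where(cnt > 0, cnt, 1)
    V0 = np.where(mask, V, 0.0)
    Y = y[:, None]
    xbar = V0.sum(axis=0) / safe_cnt
    ybar = (mask * Y).sum(axis=0) / safe_cnt
    Vc = np.where(mask, V - xbar, 0.0)
    Yc = np.where(mask, Y - ybar, 0.0)
    sxy = (Vc * Yc).sum(axis=0)
    sxx = (Vc * Vc).sum(axis=0)
    syy = (Yc * Yc).sum(axis=0)
    denom = np.sqrt(sxx * syy)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, sxy / np.where(denom > 0, denom, 1.0), np.nan)
    r[~ok] = np.nan
    r[cnt < min_finite_fraction * n] = np.nan
    return r


def correlation_map(dset: DerivativeSet, ni: NiTable, name: str,
                    stride_nm: int = 1, min_finite_fraction: float = 0.8) -> CorrelationMap:
    """Full band-pair correlation map for one index at one derivative order.

    Computed in row chunks (one R1 band at a time against all R2 bands), so
    peak memory stays O(n_samples x n_bands) rather than the full pair cube.
    Requires matching sample ids (>= 3 samples); a constant Ni vector gives
    an all-NaN map with a warning.
    """
    if name not in INDEX_NAMES:
        raise ValueError(f"unknown spectral index {name!r}")
    if stride_nm < 1:
        raise ValueError("stride_nm must be a positive integer")
    if set(dset.sample_ids) != set(ni.sample_ids):
        raise ValueError("sample ids of spectra and Ni table do not match")
    if dset.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation map")
    y = ni.aligned_to(dset.sample_ids)
    step = int(stride_nm)
    wl = dset.wavelengths_nm[::step]
    D = dset.reflectance[:, ::step]
    B = wl.size
    r = np.empty((B, B))
    if np.ptp(y) == 0:
        warnings.warn("Ni is constant; correlation map is undefined everywhere")
        r.fill(np.nan)
    else:
        for i in range(B):
            V = compute_index(name, D[:, [i]], D)
            r[i, :] = _pearson_columns(V, y, min_finite_fraction)
    return CorrelationMap(
        index_name=name,
        order_v=float(dset.derivative_order),
        wavelengths_nm=wl,
        r_matrix=r,
        stride_nm=step,
        n_samples_used=int(y.size),
    )


def select_top_combos(maps, k: int = 4) -> list:
    """The k strongest-|r| band combinations for one index across all orders.

    Only the canonical lambda1 < lambda2 entry of each swap-related pair
    competes (diagonal excluded); the same pair may recur at different orders.
    Ties break toward (lower order, lower lambda1, lower lambda2).
    """
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one correlation map")
    names = {m.index_name for m in maps}
    if len(names) > 1:
        raise ValueError(f"maps mix indices: {sorted(names)}")
    name = maps[0].index_name

    absr, orders, l1, l2, rs = [], [], [], [], []
    for m in maps:
        iu, ju = np.triu_indices(m.wavelengths_nm.size, k=1)
        vals = m.r_matrix[iu, ju]
        fin = np.isfinite(vals)
        absr.append(np.abs(vals[fin]))
        rs.append(vals[fin])
        orders.append(np.full(fin.sum(), m.order_v))
        l1.append(m.wavelengths_nm[iu[fin]])
        l2.append(m.wavelengths_nm[ju[fin]])
    absr = np.concatenate(absr)
    if absr.size == 0:
        warnings.warn("no defined correlation entries; returning no combos")
        return []
    orders, l1, l2, rs = map(np.concatenate, (orders, l1, l2, rs))
    # lexsort: last key is primary
    rank = np.lexsort((l2, l1, orders, -absr))
    if k > absr.size:
        warnings.warn(f"only {absr.size} defined combinations available; returning all")
    take = rank[: min(k, absr.size)]
    return [
        BandCombo(name, float(orders[t]), float(l1[t]), float(l2[t]), float(rs[t]))
        for t in take
    ]


def build_feature_table(combos, derivative_sets, sample_ids=None) -> FeatureTable:
    """Evaluate each selected combination on its derivative set.

    ``derivative_sets`` is an iterable of DerivativeSet covering every order
    appearing in ``combos``; NaN index values propagate into the table.
    """
    combos = list(combos)
    by_order = {}
    for d in derivative_sets:
        by_order[round(float(d.derivative_order), 9)] = d
    if sample_ids is None:
        if not by_order:
            raise ValueError("no derivative sets supplied")
        sample_ids = next(iter(by_order.values())).sample_ids
    cols = []
    for c in combos:
        key = round(float(c.order_v), 9)
        if key not in by_order:
            raise KeyError(f"no derivative set at order {c.order_v} for combo {c}")
        d = by_order[key].subset(sample_ids)
        i1 = d.band_index(c.lambda1_nm)
        i2 = d.band_index(c.lambda2_nm)
        cols.append(compute_index(c.index_name, d.reflectance[:, i1], d.reflectance[:, i2]))
    values = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    n_bad = int(np.sum(~np.isfinite(values)))
    if n_bad:
        warnings.warn(f"feature table contains {n_bad} undefined entries")
    return FeatureTable(sample_ids=list(sample_ids), combos=combos, values=values)


def render_combo(combo: BandCombo) -> str:
    """Human-readable form, e.g. ``(R_709, R_1631) 1.9``."""
    return (f"(R_{combo.lambda1_nm:g}, R_{combo.lambda2_nm:g}) {combo.order_v:.1f}")


def combos_to_frame(combos) -> pd.DataFrame:
    """Selected combinations as a table (one row per combo, ranked)."""
    return pd.DataFrame(
        {
            "index": [c.index_name for c in combos],
            "rank": np.arange(1, len(combos) + 1),
            "order": [c.order_v for c in combos],
            "lambda1_nm": [c.lambda1_nm for c in combos],
            "lambda2_nm": [c.lambda2_nm for c in combos],
            "r": [c.r for c in combos],
            "rendered": [render_combo(c) for c in combos],
        }
    )


def map_to_long_frame(cmap: CorrelationMap) -> pd.DataFrame:
    """Long-format (lambda1_nm, lambda2_nm, r) export of one map."""
    B = cmap.wavelengths_nm.size
    i, j = np.meshgrid(np.arange(B), np.arange(B), indexing="ij")
    return pd.DataFrame(
        {
            "lambda1_nm": cmap.wavelengths_nm[i.ravel()],
            "lambda2_nm": cmap.wavelengths_nm[j.ravel()],
            "r": cmap.r_matrix.ravel(),
        }
    )
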