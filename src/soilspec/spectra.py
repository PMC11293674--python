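"""Containers and preprocessing for laboratory Vis-NIR soil reflectance spectra.

The central container is :class:`SpectrumSet`: a set of samples measured on a
common, strictly increasing wavelength grid (nm).  Raw reflectance lives in
(0, 1]; after fractional differentiation the values are unbounded, which the
``derivative_order`` field records.  Preprocessing follows the usual
laboratory chain for ASD-style spectrometers: replicate averaging with
abnormal-replicate removal, trimming of the noisy grid edges, correction of
the detector splice discontinuity near 1000 nm, Savitzky-Golay smoothing, and
resampling to a uniform 1-nm grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d
from scipy.signal import savgol_filter

__all__ = [
    "SpectrumSet",
    "NiTable",
    "read_spectra",
    "write_spectra",
    "read_ni",
    "write_ni",
    "average_replicates",
    "trim_wavelengths",
    "splice_correct",
    "savitzky_golay",
    "resample_to_unit_grid",
]


@dataclass
class SpectrumSet:
    """Reflectance spectra for a set of samples on one wavelength grid.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``reflectance``.
    wavelengths_nm : ndarray
        Strictly increasing band positions in nm.
    reflectance : ndarray, shape (n_samples, n_bands)
        Reflectance values; unitless.  Nominally in (0, 1] at derivative
        order 0, unbounded in sign and scale after differentiation.
    derivative_order : float
        0 for raw data; set by the fractional-derivative transform.
    preprocessing_log : list of str
        Ordered descriptors of the steps already applied.
    """

    sample_ids: list
    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    derivative_order: float = 0.0
    preprocessing_log: list = field(default_factory=list)

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if self.wavelengths_nm.ndim != 1:
            raise ValueError("wavelengths must be a 1-D vector")
        d = np.diff(self.wavelengths_nm)
        if d.size and not np.all(d > 0):
            bad = self.wavelengths_nm[1:][d <= 0][0]
            raise ValueError(
                f"wavelengths must be strictly increasing (offending value {bad} nm)"
            )
        if self.reflectance.shape != (len(self.sample_ids), self.wavelengths_nm.size):
            raise ValueError(
                f"reflectance shape {self.reflectance.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavelengths_nm.size} bands"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if self.derivative_order < 0:
            raise ValueError("derivative_order must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size

    def with_(self, *, reflectance=None, wavelengths_nm=None, derivative_order=None,
              log_entry: str | None = None) -> "SpectrumSet":
        """Return a copy with selected fields replaced and a log entry appended."""
        log = list(self.preprocessing_log)
        if log_entry is not None:
            log.append(log_entry)
        return SpectrumSet(
            sample_ids=list(self.sample_ids),
            wavelengths_nm=self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm,
            reflectance=self.reflectance.copy() if reflectance is None else reflectance,
            derivative_order=self.derivative_order if derivative_order is None else derivative_order,
            preprocessing_log=log,
        )

    def subset(self, ids) -> "SpectrumSet":
        """Rows restricted to ``ids``, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [str(s) for s in ids if str(s) not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        idx = [pos[str(s)] for s in ids]
        return SpectrumSet(
            sample_ids=[str(s) for s in ids],
            wavelengths_nm=self.wavelengths_nm.copy(),
            reflectance=self.reflectance[idx],
            derivative_order=self.derivative_order,
            preprocessing_log=list(self.preprocessing_log),
        )

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band at ``wavelength_nm`` (must lie on the grid)."""
        i = int(np.searchsorted(self.wavelengths_nm, wavelength_nm))
        if i >= self.n_bands or abs(self.wavelengths_nm[i] - wavelength_nm) > 1e-9:
            raise KeyError(f"wavelength {wavelength_nm} nm is not on the grid")
        return i


@dataclass
class NiTable:
    """Per-sample soil Ni concentration in mg/kg (the model's response)."""

    sample_ids: list
    ni_mg_per_kg: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.ni_mg_per_kg = np.asarray(self.ni_mg_per_kg, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if self.ni_mg_per_kg.shape != (len(self.sample_ids),):
            raise ValueError("one concentration per sample id required")
        if not np.all(np.isfinite(self.ni_mg_per_kg)) or np.any(self.ni_mg_per_kg <= 0):
            raise ValueError("Ni concentrations must be positive and finite")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids) -> "NiTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [str(s) for s in ids if str(s) not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        idx = [pos[str(s)] for s in ids]
        return NiTable([str(s) for s in ids], self.ni_mg_per_kg[idx])

    def aligned_to(self, sample_ids) -> np.ndarray:
        """Concentrations reordered to match ``sample_ids``."""
        return self.subset(sample_ids).ni_mg_per_kg


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: one comment line "# derivative_order=<v>" (optional on read), then
# a header row "sample_id,<wl>,<wl>,..." with wavelengths in nm and one row
# per sample.  A transposed layout (samples as columns, wavelengths in the
# first column) is auto-detected.
# ---------------------------------------------------------------------------

def _read_comment_order(path) -> float:
    order = 0.0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "derivative_order=" in line:
                order = float(line.split("derivative_order=")[1].strip())
    return order


def read_spectra(path, layout: str = "auto") -> SpectrumSet:
    """Read a wide-format reflectance CSV.

    ``layout`` is one of ``samples-as-rows``, ``samples-as-columns`` or
    ``auto``; auto-detection treats an all-numeric header (past the first
    cell) as wavelengths, hence samples as rows.
    """
    # header parsed by hand: pandas would silently de-duplicate repeated
    # wavelength columns, hiding a format error we must report
    raw = pd.read_csv(path, comment="#", header=None, dtype=str,
                      skip_blank_lines=True)
    if raw.shape[1] < 2 or raw.shape[0] < 2:
        raise ValueError("spectra CSV needs an id axis and at least one band")
    header = [str(v) for v in raw.iloc[0]]
    df = raw.iloc[1:].reset_index(drop=True)
    df.columns = header

    def _numeric_header(cols) -> bool:
        try:
            [float(c) for c in cols]
            return True
        except ValueError:
            return False

    if layout == "auto":
        layout = "samples-as-rows" if _numeric_header(df.columns[1:]) else "samples-as-columns"
    if layout == "samples-as-columns":
        ids = [str(c) for c in df.columns[1:]]
        try:
            wl = np.array([float(v) for v in df.iloc[:, 0]])
        except ValueError as e:
            raise ValueError(f"non-numeric wavelength cell: {e}") from None
        values = df.iloc[:, 1:].to_numpy().T
    elif layout == "samples-as-rows":
        ids = [str(v) for v in df.iloc[:, 0]]
        try:
            wl = np.array([float(c) for c in df.columns[1:]])
        except ValueError as e:
            raise ValueError(f"non-numeric wavelength header cell: {e}") from None
        values = df.iloc[:, 1:].to_numpy()
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if np.unique(wl).size != wl.size:
        dup = wl[pd.Series(wl).duplicated().to_numpy()][0]
        raise ValueError(f"duplicate wavelength {dup} nm in header")
    order = np.argsort(wl)
    wl, values = wl[order], values[:, order]

    refl = np.empty(values.shape, dtype=float)
    for j in range(values.shape[1]):
        for i in range(values.shape[0]):
            try:
                refl[i, j] = float(values[i, j])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric reflectance cell {values[i, j]!r} at "
                    f"sample {ids[i]!r}, wavelength {wl[j]} nm"
                ) from None
    return SpectrumSet(ids, wl, refl, derivative_order=_read_comment_order(path))


def write_spectra(sset: SpectrumSet, path) -> None:
    """Write samples-as-rows CSV at full float precision, with the derivative
    order recorded on a leading comment line."""
    if sset.n_samples == 0 or sset.n_bands == 0:
        raise ValueError("refusing to write an empty SpectrumSet")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# derivative_order={float(sset.derivative_order)!r}\n")
        fh.write("sample_id," + ",".join(repr(float(w)) for w in sset.wavelengths_nm) + "\n")
        for sid, row in zip(sset.sample_ids, sset.reflectance):
            fh.write(str(sid) + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_ni(path) -> NiTable:
    df = pd.read_csv(path, comment="#")
    if not {"sample_id", "ni_mg_per_kg"}.issubset(df.columns):
        raise ValueError('Ni CSV must have columns "sample_id" and "ni_mg_per_kg"')
    return NiTable(df["sample_id"].astype(str).tolist(), df["ni_mg_per_kg"].to_numpy(float))


def write_ni(table: NiTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id,ni_mg_per_kg\n")
        for sid, v in zip(table.sample_ids, table.ni_mg_per_kg):
            fh.write(f"{sid},{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Preprocessing chain
# ---------------------------------------------------------------------------

def average_replicates(replicates, min_corr: float = 0.98):
    """Average replicate scans of one sample after dropping abnormal ones.

    A replicate is abnormal when its Pearson correlation with the pointwise
    median replicate falls below ``min_corr``.  If every replicate would be
    dropped, the one closest to the median (L2) is kept and a warning issued.

    Returns ``(spectrum, kept_indices)``.
    """
    reps = np.atleast_2d(np.asarray(replicates, dtype=float))
    if reps.ndim != 2 or reps.shape[0] < 1:
        raise ValueError("need at least one replicate on a shared grid")
    if not 0 < min_corr < 1:
        raise ValueError("min_corr must lie in (0, 1)")
    median = np.median(reps, axis=0)
    med_c = median - median.mean()
    denom_m = np.sqrt((med_c**2).sum())
    corrs = np.empty(reps.shape[0])
    for k, rep in enumerate(reps):
        rep_c = rep - rep.mean()
        denom = np.sqrt((rep_c**2).sum()) * denom_m
        if denom == 0:  # constant replicate and/or constant median
            corrs[k] = 1.0 if np.allclose(rep, median) else -np.inf
        else:
            corrs[k] = float(rep_c @ med_c / denom)
    keep = np.flatnonzero(corrs >= min_corr)
    if keep.size == 0:
        warnings.warn("all replicates flagged abnormal; keeping the median-closest one")
        keep = np.array([int(np.argmin(((reps - median) ** 2).sum(axis=1)))])
    return reps[keep].mean(axis=0), keep


def trim_wavelengths(sset: SpectrumSet, lo_nm: float = 401.0, hi_nm: float = 2400.0) -> SpectrumSet:
    """Drop the low-SNR grid edges, keeping bands with lo <= lambda <= hi."""
    if not lo_nm < hi_nm:
        raise ValueError(f"lo_nm ({lo_nm}) must be < hi_nm ({hi_nm})")
    mask = (sset.wavelengths_nm >= lo_nm) & (sset.wavelengths_nm <= hi_nm)
    if not mask.any():
        raise ValueError(f"no bands remain in [{lo_nm}, {hi_nm}] nm")
    return sset.with_(
        wavelengths_nm=sset.wavelengths_nm[mask],
        reflectance=sset.reflectance[:, mask],
        log_entry=f"trim_wavelengths({lo_nm}, {hi_nm})",
    )


def splice_correct(sset: SpectrumSet, junction_nm: float = 1000.0,
                   mode: str = "additive") -> SpectrumSet:
    """Remove the detector-splice discontinuity at ``junction_nm``.

    The segment at wavelengths >= junction is shifted (additive, default) or
    scaled (multiplicative) so that its first band matches the value linearly
    extrapolated from the two bands just below the junction.  Idempotent.
    """
    wl = sset.wavelengths_nm
    j = int(np.searchsorted(wl, junction_nm, side="left"))
    if j < 2 or j >= wl.size:
        raise ValueError(
            f"junction {junction_nm} nm must lie strictly inside the grid with "
            "at least two bands below it"
        )
    R = sset.reflectance.copy()
    slope = (R[:, j - 1] - R[:, j - 2]) / (wl[j - 1] - wl[j - 2])
    extrap = R[:, j - 1] + slope * (wl[j] - wl[j - 1])
    if mode == "additive":
        R[:, j:] += (extrap - R[:, j])[:, None]
    elif mode == "multiplicative":
        if np.any(R[:, j] == 0):
            raise ValueError("multiplicative splice correction undefined: zero at junction")
        R[:, j:] *= (extrap / R[:, j])[:, None]
    else:
        raise ValueError(f"unknown splice mode {mode!r}")
    return sset.with_(reflectance=R, log_entry=f"splice_correct({junction_nm}, {mode})")


def savitzky_golay(sset: SpectrumSet, window: int = 11, polyorder: int = 2) -> SpectrumSet:
    """Savitzky-Golay least-squares smoothing, mirror-padded at the edges."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    smoothed = savgol_filter(sset.reflectance, window, polyorder, axis=1, mode="mirror")
    return sset.with_(reflectance=smoothed, log_entry=f"savitzky_golay({window}, {polyorder})")


def resample_to_unit_grid(sset: SpectrumSet) -> SpectrumSet:
    """Linearly interpolate onto the integer-nm grid spanning the input range.

    Identity (no-op copy) when the data already sit on a 1-nm integer grid.
    """
    if sset.n_bands < 2:
        raise ValueError("need at least two bands to resample")
    wl = sset.wavelengths_nm
    target = np.arange(np.ceil(wl[0]), np.floor(wl[-1]) + 1.0)
    if target.size == wl.size and np.array_equal(target, wl):
        return sset.with_(log_entry="resample_to_unit_grid (already 1-nm grid)")
    interp = interp1d(wl, sset.reflectance, axis=1, kind="linear", assume_sorted=True)
    return sset.with_(
        wavelengths_nm=target,
        reflectance=interp(target),
        log_entry="resample_to_unit_grid",
    )
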