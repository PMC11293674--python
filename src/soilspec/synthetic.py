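"""Synthetic soil Vis-NIR spectra with a planted, weak Ni-linked signal.

The generator emulates the qualitative anatomy of dried-soil reflectance:

* a smooth continuum rising through the visible (sigmoid over ~400-800 nm)
  that flattens in the NIR,
* water absorption valleys near 1400, 1900 and 2200 nm,
* an iron-oxide doublet — a small valley near 490 nm and peak near 550 nm,
* per-sample baseline drift (multiplicative gain + additive offset),
* a detector-splice step at 1000 nm,
* white measurement noise,

plus a phenomenological Ni co-absorption: a narrow Gaussian dip on the
1900-nm shoulder (default center 1930 nm) whose depth is proportional to the
sample's Ni concentration.  The effect amplitude is deliberately small so
that no single raw band correlates strongly with Ni, while derivative
preprocessing plus a two-band index recovers the signal — the regime the
method is designed for.

Ni concentrations follow a truncated lognormal targeting mean 28.83 and
SD 8.33 mg/kg on [12, 75] mg/kg, the moments of the field survey this
simulation stands in for.  Everything is driven by one seed; identical
configs give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .spectra import NiTable, SpectrumSet

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "ground_truth"]


@dataclass
class SyntheticConfig:
    n_samples: int = 108
    wl_min_nm: float = 350.0
    wl_max_nm: float = 2500.0

    # response distribution (mg/kg)
    ni_mean: float = 28.83
    ni_sd: float = 8.33
    ni_min: float = 12.0
    ni_max: float = 75.0

    # continuum: base + rise * sigmoid((lambda - center)/scale)
    continuum_base: float = 0.12
    continuum_rise: float = 0.38
    continuum_center_nm: float = 600.0
    continuum_scale_nm: float = 90.0

    # fixed absorption features: (center nm, mean depth, width nm);
    # negative depth = reflection peak
    water_bands: tuple = ((1400.0, 0.050, 28.0), (1900.0, 0.090, 45.0),
                          (2200.0, 0.045, 30.0))
    iron_bands: tuple = ((490.0, 0.020, 18.0), (550.0, -0.015, 22.0))
    #: per-sample relative jitter of feature depths, uniform on +/- this
    #: fraction.  ``feature_jitter`` is a common factor across all features
    #: (moisture / organic-matter-like co-variation); ``feature_jitter_indep``
    #: perturbs each feature independently on top of it.
    feature_jitter: float = 0.25
    feature_jitter_indep: float = 0.05

    # per-sample baseline drift: multiplicative gain, additive offset, and a
    # smooth random curve (sum of broad cosine/sine modes with 1/m decay) —
    # the scattering/particle-size baseline that derivative preprocessing is
    # designed to remove
    drift_gain_sd: float = 0.05
    drift_offset_sd: float = 0.045
    drift_curve_amp: float = 0.05
    drift_curve_modes: int = 10

    # planted Ni co-absorption; center may be a scalar or a tuple of centers
    # (width/amp broadcast across centers when scalar)
    ni_effect_center_nm: float | tuple = 1930.0
    ni_effect_width_nm: float | tuple = 14.0
    ni_effect_amp_per_unit: float | tuple = 3.0e-3

    #: measurement noise sd; spectrally correlated over ``noise_corr_nm``
    #: (the instrument's optical resolution), not white at the 1-nm grid
    noise_sd: float = 0.0015
    noise_corr_nm: float = 3.0
    splice_jump: float = 0.015
    splice_junction_nm: float = 1000.0

    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.wl_min_nm < self.wl_max_nm:
            raise ValueError("wavelength range is empty")
        if not 0 < self.ni_min < self.ni_max:
            raise ValueError("Ni truncation range invalid")
        if min(self.ni_mean, self.ni_sd) <= 0:
            raise ValueError("Ni mean and SD must be positive")
        for name in ("feature_jitter", "feature_jitter_indep", "drift_gain_sd",
                     "drift_offset_sd", "drift_curve_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        centers, widths, amps = self.ni_effects()
        if np.any(widths <= 0):
            raise ValueError("ni_effect_width_nm must be > 0")
        if np.any(amps < 0):
            raise ValueError("ni_effect_amp_per_unit must be >= 0")

    def ni_effects(self):
        """Planted-effect (centers, widths, amps) broadcast to equal length."""
        centers = np.atleast_1d(np.asarray(self.ni_effect_center_nm, dtype=float))
        widths = np.broadcast_to(
            np.atleast_1d(np.asarray(self.ni_effect_width_nm, dtype=float)),
            centers.shape)
        amps = np.broadcast_to(
            np.atleast_1d(np.asarray(self.ni_effect_amp_per_unit, dtype=float)),
            centers.shape)
        return centers, widths, amps


@dataclass
class GroundTruth:
    """What was planted: the Ni-linked bands and the nuisance amplitudes."""

    effects: list = field(default_factory=list)  # dicts: center/width/amp per unit Ni
    splice_jump: float = 0.0
    drift_gain_sd: float = 0.0
    drift_offset_sd: float = 0.0
    drift_curve_amp: float = 0.0
    noise_sd: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _sample_ni(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Truncated lognormal with the target (untruncated) mean and SD.

    The [12, 75] truncation clips well under 1% of the mass at the default
    moments, so no moment correction is applied.
    """
    sigma2 = np.log1p((cfg.ni_sd / cfg.ni_mean) ** 2)
    mu = np.log(cfg.ni_mean) - sigma2 / 2.0
    sigma = np.sqrt(sigma2)
    out = np.empty(cfg.n_samples)
    filled = 0
    while filled < cfg.n_samples:
        draw = rng.lognormal(mu, sigma, size=cfg.n_samples - filled)
        ok = draw[(draw >= cfg.ni_min) & (draw <= cfg.ni_max)]
        out[filled:filled + ok.size] = ok
        filled += ok.size
    return out


def ground_truth(cfg: SyntheticConfig) -> GroundTruth:
    """The planted-effect description for a config (no randomness involved)."""
    cfg.validate()
    effects = []
    for c, w, a in zip(*cfg.ni_effects()):
        if a > 0:
            effects.append(
                {"center_nm": float(c), "width_nm": float(w),
                 "amp_per_unit_ni": float(a)}
            )
    return GroundTruth(
        effects=effects,
        splice_jump=cfg.splice_jump,
        drift_gain_sd=cfg.drift_gain_sd,
        drift_offset_sd=cfg.drift_offset_sd,
        drift_curve_amp=cfg.drift_curve_amp,
        noise_sd=cfg.noise_sd,
    )


def generate(cfg: SyntheticConfig):
    """Draw one synthetic dataset.

    Returns ``(SpectrumSet, NiTable, GroundTruth)``.  The model is

        R_i(l) = gain_i * C(l) + offset_i + drift_i(l)
                 - sum_j depth_ij * G(l; c_j, s_j)
                 - amp * Ni_i * G(l; c_Ni, s_Ni)
                 + jump * 1[l >= 1000 nm] + eps_il,

    with C the sigmoid continuum, drift_i a smooth random baseline curve,
    G unit-height Gaussians, depth_ij the jittered fixed-feature depths, and
    eps white noise.  Reflectance is clipped into (0, 1).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    wl = np.arange(cfg.wl_min_nm, cfg.wl_max_nm + 0.5)
    n = cfg.n_samples

    ni = _sample_ni(cfg, rng)
    gains = 1.0 + rng.normal(0.0, cfg.drift_gain_sd, size=n) if cfg.drift_gain_sd > 0 \
        else np.ones(n)
    offsets = rng.normal(0.0, cfg.drift_offset_sd, size=n) if cfg.drift_offset_sd > 0 \
        else np.zeros(n)

    # smooth per-sample baseline curve: red-spectrum cosine/sine modes over
    # the full range, coefficients ~ N(0, (amp/m)^2)
    M = int(cfg.drift_curve_modes)
    baseline = np.zeros((n, wl.size))
    if cfg.drift_curve_amp > 0 and M > 0:
        u = 2.0 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1.0
        a = rng.normal(0.0, 1.0, size=(n, M))
        b = rng.normal(0.0, 1.0, size=(n, M))
        for m in range(1, M + 1):
            scale = cfg.drift_curve_amp / m
            baseline += scale * (
                a[:, [m - 1]] * np.cos(np.pi * m * u)[None, :]
                + b[:, [m - 1]] * np.sin(np.pi * m * u)[None, :]
            )

    continuum = cfg.continuum_base + cfg.continuum_rise / (
        1.0 + np.exp(-(wl - cfg.continuum_center_nm) / cfg.continuum_scale_nm)
    )

    bands = list(cfg.water_bands) + list(cfg.iron_bands)
    shapes = np.stack([_gauss(wl, c, s) for (c, _d, s) in bands])  # (n_feat, n_wl)
    base_depths = np.array([d for (_c, d, _s) in bands])
    common = rng.uniform(-cfg.feature_jitter, cfg.feature_jitter, size=(n, 1))
    indep = rng.uniform(-cfg.feature_jitter_indep, cfg.feature_jitter_indep,
                        size=(n, len(bands)))
    depths = base_depths[None, :] * (1.0 + common) * (1.0 + indep)

    R = gains[:, None] * continuum[None, :] + offsets[:, None] + baseline
    R -= depths @ shapes
    for c, w, a in zip(*cfg.ni_effects()):
        if a > 0:
            R -= a * ni[:, None] * _gauss(wl, c, w)[None, :]
    R += cfg.splice_jump * (wl >= cfg.splice_junction_nm)[None, :]
    if cfg.noise_sd > 0:
        eps = rng.normal(0.0, 1.0, size=R.shape)
        if cfg.noise_corr_nm > 0:
            from scipy.ndimage import gaussian_filter1d
            eps = gaussian_filter1d(eps, cfg.noise_corr_nm, axis=1, mode="reflect")
            # restore unit variance after the low-pass
            k = np.arange(-int(4 * cfg.noise_corr_nm), int(4 * cfg.noise_corr_nm) + 1)
            g = np.exp(-0.5 * (k / cfg.noise_corr_nm) ** 2)
            eps /= np.sqrt(((g / g.sum()) ** 2).sum())
        R += cfg.noise_sd * eps
    np.clip(R, 1e-6, 1.0 - 1e-6, out=R)

    ids = [f"S{i + 1:03d}" for i in range(n)]
    sset = SpectrumSet(
        sample_ids=ids,
        wavelengths_nm=wl,
        reflectance=R,
        derivative_order=0.0,
        preprocessing_log=[f"synthetic(seed={cfg.seed}, n={n})"],
    )
    return sset, NiTable(ids, ni), ground_truth(cfg)
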