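"""End-to-end orchestration: preprocess -> screen -> split -> derivative grid
-> index search -> feature tables -> PLS models -> evaluation tables.

The pipeline proper is deterministic; the only randomness is synthetic data
generation, driven by one master seed.  Every stage error is re-raised with
the stage name so a failed run points at the offending step.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fod, indices, plsr, sampling, spectra, synthetic

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config",
           "preprocess", "search_indices", "fit_and_evaluate"]


@dataclass
class PipelineConfig:
    # inputs: CSV paths, or a synthetic config when both are None
    spectra_csv: str | None = None
    ni_csv: str | None = None
    synthetic: synthetic.SyntheticConfig | None = None

    # preprocessing
    trim_lo_nm: float = 401.0
    trim_hi_nm: float = 2400.0
    splice_junction_nm: float = 1000.0
    splice_mode: str = "additive"
    splice_before_smoothing: bool = True
    sg_window: int = 11
    sg_polyorder: int = 2

    # screening & split
    outlier_sd_factor: float = 3.0
    split_fraction: float = 0.7
    ks_space: str = "zscore"  # zscore | raw | ni

    # search
    orders: tuple = tuple(float(v) for v in fod.default_order_grid())
    indices: tuple = indices.INDEX_NAMES
    stride_nm: int = 5
    k_combos: int = 4
    correlation_subset: str = "calibration"  # calibration | all
    min_finite_fraction: float = 0.8

    # modelling
    max_components: int = 4
    rpd_denominator: str = "calibration_sd"

    # outputs
    out_dir: str | None = None
    export_maps: bool = False
    make_heatmaps: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    stats: pd.DataFrame
    combos: dict
    evaluation: pd.DataFrame
    split: sampling.SplitResult
    removed_ids: list
    best_index: str
    max_r_by_order: pd.DataFrame
    preprocessed: spectra.SpectrumSet
    ni: spectra.NiTable
    feature_tables: dict = field(default_factory=dict)


class StageError(RuntimeError):
    pass


def _stage(name):
    def wrap(fn):
        def inner(*a, **k):
            try:
                return fn(*a, **k)
            except StageError:
                raise
            except Exception as e:
                raise StageError(f"pipeline stage '{name}' failed: {e}") from e
        return inner
    return wrap


def load_config(path) -> PipelineConfig:
    """Read a flat YAML mapping into a PipelineConfig (unknown keys rejected)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    syn = raw.pop("synthetic", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if syn is not None:
        cfg.synthetic = synthetic.SyntheticConfig(**syn)
    return cfg


@_stage("load")
def _load_inputs(cfg: PipelineConfig):
    if cfg.spectra_csv is not None and cfg.ni_csv is not None:
        return spectra.read_spectra(cfg.spectra_csv), spectra.read_ni(cfg.ni_csv), None
    # the master seed always wins, so one pipeline seed drives all randomness
    syn = dataclasses.replace(cfg.synthetic or synthetic.SyntheticConfig(),
                              seed=cfg.seed)
    sset, ni, truth = synthetic.generate(syn)
    return sset, ni, truth


@_stage("preprocess")
def preprocess(sset: spectra.SpectrumSet, cfg: PipelineConfig) -> spectra.SpectrumSet:
    """Trim -> splice-correct -> smooth (order configurable) -> unit grid."""
    s = spectra.trim_wavelengths(sset, cfg.trim_lo_nm, cfg.trim_hi_nm)
    steps = [
        lambda x: spectra.splice_correct(x, cfg.splice_junction_nm, cfg.splice_mode),
        lambda x: spectra.savitzky_golay(x, cfg.sg_window, cfg.sg_polyorder),
    ]
    if not cfg.splice_before_smoothing:
        steps.reverse()
    for step in steps:
        s = step(s)
    return spectra.resample_to_unit_grid(s)


@_stage("split")
def _split(s: spectra.SpectrumSet, ni: spectra.NiTable, cfg: PipelineConfig):
    if cfg.ks_space == "zscore":
        X = sampling.standardize_columns(s.reflectance)
    elif cfg.ks_space == "raw":
        X = s.reflectance
    elif cfg.ks_space == "ni":
        X = ni.aligned_to(s.sample_ids)[:, None]
    else:
        raise ValueError(f"unknown ks_space {cfg.ks_space!r}")
    return sampling.kennard_stone(X, cfg.split_fraction, ids=s.sample_ids)


@_stage("index search")
def search_indices(derivative_sets, ni: spectra.NiTable, cfg: PipelineConfig,
                   subset_ids=None):
    """Correlation maps for every (index, order) and the top-k combos per index.

    Returns ``(combos_by_index, max_r_frame, maps_by_index)`` where the maps
    dict is only populated when ``cfg.export_maps`` or ``cfg.make_heatmaps``
    asks for it.
    """
    keep_maps = cfg.export_maps or cfg.make_heatmaps
    combos, rows, maps_by_index = {}, [], {}
    for name in cfg.indices:
        maps = []
        for dset in derivative_sets:
            d = dset.subset(subset_ids) if subset_ids is not None else dset
            m = indices.correlation_map(
                d, ni.subset(d.sample_ids), name,
                stride_nm=cfg.stride_nm,
                min_finite_fraction=cfg.min_finite_fraction,
            )
            maps.append(m)
            with np.errstate(invalid="ignore"):
                mx = np.nanmax(np.abs(m.r_matrix)) if np.isfinite(m.r_matrix).any() else np.nan
            rows.append({"index": name, "order": m.order_v, "max_abs_r": mx})
        combos[name] = indices.select_top_combos(maps, k=cfg.k_combos)
        if keep_maps:
            maps_by_index[name] = maps
    return combos, pd.DataFrame(rows), maps_by_index


@_stage("modelling")
def fit_and_evaluate(combos_by_index, derivative_sets, ni, split, cfg):
    """PLS model per index dataset; evaluation table ranked by RPD."""
    rows, ftabs = [], {}
    for name, combos in combos_by_index.items():
        ft_c = indices.build_feature_table(combos, derivative_sets, split.calibration_ids)
        ft_v = indices.build_feature_table(combos, derivative_sets, split.validation_ids)
        ftabs[name] = (ft_c, ft_v)
        yc = ni.aligned_to(split.calibration_ids)
        yv = ni.aligned_to(split.validation_ids)
        Xc, Xv = ft_c.values, ft_v.values
        if not (np.all(np.isfinite(Xc)) and np.all(np.isfinite(Xv))):
            raise ValueError(f"index dataset {name} contains undefined feature values")
        n_comp = plsr.select_components(Xc, yc, cfg.max_components)
        model = plsr.fit_plsr(Xc, yc, n_comp, ids=split.calibration_ids)
        rep = plsr.evaluate(model, Xc, yc, Xv, yv, rpd_denominator=cfg.rpd_denominator)
        rows.append({
            "index": name, "n_components": rep.n_components,
            "rcv2": rep.rcv2, "rmsec": rep.rmsec,
            "rp2": rep.rp2, "rmsep": rep.rmsep,
            "rpd": rep.rpd, "rpd_class": rep.rpd_class,
        })
    ev = pd.DataFrame(rows).sort_values("rpd", ascending=False).reset_index(drop=True)
    return ev, ftabs


def _stats_table(ni: spectra.NiTable, split: sampling.SplitResult) -> pd.DataFrame:
    rows = []
    for label, ids in (("entire", ni.sample_ids),
                       ("calibration", split.calibration_ids),
                       ("validation", split.validation_ids)):
        d = sampling.describe(ni.aligned_to(ids))
        rows.append({"dataset": label, "n": d.n, "min": d.min, "max": d.max,
                     "mean": d.mean, "sd": d.sd, "cv_percent": d.cv_percent})
    return pd.DataFrame(rows)


def _write_outputs(cfg, result: PipelineResult, maps_by_index, truth, t0):
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.stats.to_csv(out / "ni_stats.csv", index=False)
    pd.concat(
        [indices.combos_to_frame(c) for c in result.combos.values()],
        ignore_index=True,
    ).to_csv(out / "selected_combos.csv", index=False)
    result.evaluation.to_csv(out / "evaluation.csv", index=False)
    result.max_r_by_order.to_csv(out / "max_abs_r_by_order.csv", index=False)
    split_df = pd.DataFrame(
        {"sample_id": result.split.calibration_ids + result.split.validation_ids,
         "subset": ["calibration"] * len(result.split.calibration_ids)
                   + ["validation"] * len(result.split.validation_ids)})
    split_df.to_csv(out / "split.csv", index=False)
    pd.DataFrame({"sample_id": result.removed_ids}).to_csv(
        out / "removed_outliers.csv", index=False)
    if truth is not None:
        truth.to_json(out / "ground_truth.json")
    if cfg.export_maps:
        mdir = out / "maps"
        mdir.mkdir(exist_ok=True)
        for name, maps in maps_by_index.items():
            for m in maps:
                indices.map_to_long_frame(m).to_csv(
                    mdir / f"{name}_order_{m.order_v:.1f}.csv", index=False)
    if cfg.make_heatmaps:
        _write_heatmaps(maps_by_index, out / "figures")
    with open(out / "run_log.txt", "w", encoding="utf-8") as fh:
        fh.write("resolved pipeline configuration\n")
        for f in dataclasses.fields(cfg):
            fh.write(f"  {f.name} = {getattr(cfg, f.name)!r}\n")
        fh.write(f"seed = {cfg.seed}\n")
        fh.write(f"best index = {result.best_index}\n")
        fh.write(f"elapsed_s = {time.time() - t0:.1f}\n")


def _write_heatmaps(maps_by_index, figdir: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir.mkdir(parents=True, exist_ok=True)
    for name, maps in maps_by_index.items():
        for m in maps:
            fig, ax = plt.subplots(figsize=(4, 3.4))
            wl = m.wavelengths_nm
            im = ax.imshow(m.r_matrix, origin="lower", cmap="RdBu_r",
                           vmin=-1, vmax=1,
                           extent=[wl[0], wl[-1], wl[0], wl[-1]])
            ax.set_xlabel("$\\lambda_2$ (nm)")
            ax.set_ylabel("$\\lambda_1$ (nm)")
            ax.set_title(f"{name}, order {m.order_v:.1f}")
            fig.colorbar(im, ax=ax, label="r")
            fig.tight_layout()
            fig.savefig(figdir / f"{name}_order_{m.order_v:.1f}.png", dpi=110)
            plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full workflow; writes report files when ``out_dir`` is set."""
    t0 = time.time()
    raw, ni, truth = _load_inputs(cfg)

    missing = set(raw.sample_ids) ^ set(ni.sample_ids)
    if missing:
        raise StageError(
            f"pipeline stage 'load' failed: spectra/Ni id mismatch for {sorted(missing)}")

    pre = preprocess(raw, cfg)
    ni, pre, removed = sampling.remove_outliers(ni, pre, cfg.outlier_sd_factor)
    split = _split(pre, ni, cfg)

    dsets = fod.fod_grid(pre, cfg.orders)
    subset = split.calibration_ids if cfg.correlation_subset == "calibration" else None
    combos, max_r, maps_by_index = search_indices(dsets, ni, cfg, subset_ids=subset)
    evaluation, ftabs = fit_and_evaluate(combos, dsets, ni, split, cfg)

    result = PipelineResult(
        stats=_stats_table(ni, split),
        combos=combos,
        evaluation=evaluation,
        split=split,
        removed_ids=removed,
        best_index=str(evaluation.iloc[0]["index"]),
        max_r_by_order=max_r,
        preprocessed=pre,
        ni=ni,
        feature_tables=ftabs,
    )
    if cfg.out_dir is not None:
        _write_outputs(cfg, result, maps_by_index, truth, t0)
    return result
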