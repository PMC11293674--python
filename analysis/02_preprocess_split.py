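#!/usr/bin/env python
"""Preprocess the raw spectra (trim to 401-2400 nm, correct the 1000-nm
detector splice, Savitzky-Golay smooth), screen Ni outliers, and partition
the samples 70/30 with Kennard-Stone.

Reads results/data/, writes results/{preprocessed.csv, split.csv,
ni_stats.csv} and prints the per-subset Ni statistics table.
"""

from pathlib import Path

import pandas as pd

from soilspec import (describe, kennard_stone, read_ni, read_spectra,
                      remove_outliers, standardize_columns, write_spectra)
from soilspec.pipeline import PipelineConfig, preprocess

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = PipelineConfig()
    sset = read_spectra(ROOT / "data" / "spectra.csv")
    ni = read_ni(ROOT / "data" / "ni.csv")

    pre = preprocess(sset, cfg)
    ni, pre, removed = remove_outliers(ni, pre, cfg.outlier_sd_factor)
    print(f"preprocessing: {' -> '.join(pre.preprocessing_log[1:])}")
    print(f"outlier screen removed {len(removed)} sample(s): {removed}")

    split = kennard_stone(standardize_columns(pre.reflectance),
                          cfg.split_fraction, ids=pre.sample_ids)
    rows = []
    for label, ids in (("entire", ni.sample_ids),
                       ("calibration", split.calibration_ids),
                       ("validation", split.validation_ids)):
        d = describe(ni.aligned_to(ids))
        rows.append({"dataset": label, "n": d.n, "min": d.min, "max": d.max,
                     "mean": d.mean, "sd": d.sd, "cv_percent": d.cv_percent})
    stats = pd.DataFrame(rows)
    print(stats.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

    write_spectra(pre, ROOT / "preprocessed.csv")
    pd.DataFrame({
        "sample_id": split.calibration_ids + split.validation_ids,
        "subset": ["calibration"] * len(split.calibration_ids)
                  + ["validation"] * len(split.validation_ids),
    }).to_csv(ROOT / "split.csv", index=False)
    stats.to_csv(ROOT / "ni_stats.csv", index=False)
    print(f"wrote preprocessed spectra, split and stats under {ROOT}")


if __name__ == "__main__":
    main()
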