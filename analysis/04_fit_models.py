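#!/usr/bin/env python
"""PLS1 models on the top-4 band combinations of each spectral index, with
leave-one-out component selection and R2 / RMSE / RPD evaluation.

Reads results/{preprocessed.csv, data/ni.csv, split.csv, selected_combos.csv};
writes results/evaluation.csv and prints the ranked evaluation table.
"""

from pathlib import Path

import pandas as pd

from soilspec import BandCombo, fod_grid, read_ni, read_spectra
from soilspec.pipeline import PipelineConfig, fit_and_evaluate
from soilspec.sampling import SplitResult

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = PipelineConfig(stride_nm=5)
    pre = read_spectra(ROOT / "preprocessed.csv")
    ni = read_ni(ROOT / "data" / "ni.csv").subset(pre.sample_ids)
    split_df = pd.read_csv(ROOT / "split.csv")
    split = SplitResult(
        calibration_ids=split_df.loc[split_df.subset == "calibration",
                                     "sample_id"].tolist(),
        validation_ids=split_df.loc[split_df.subset == "validation",
                                    "sample_id"].tolist(),
        fraction=cfg.split_fraction)

    combos_df = pd.read_csv(ROOT / "selected_combos.csv")
    combos = {
        name: [BandCombo(r["index"], r.order, r.lambda1_nm, r.lambda2_nm, r.r)
               for _, r in grp.iterrows()]
        for name, grp in combos_df.groupby("index", sort=False)
    }

    dsets = fod_grid(pre, cfg.orders)
    evaluation, _ = fit_and_evaluate(combos, dsets, ni, split, cfg)
    print(evaluation.to_string(index=False,
                               float_format=lambda v: f"{v:.3f}"))
    top = evaluation.iloc[0]
    print(f"best index dataset: {top['index']} "
          f"(validation R2={top.rp2:.3f}, RMSE={top.rmsep:.3f} mg/kg, "
          f"RPD={top.rpd:.2f} -> {top.rpd_class})")
    evaluation.to_csv(ROOT / "evaluation.csv", index=False)
    print(f"wrote evaluation table under {ROOT}")


if __name__ == "__main__":
    main()
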