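#!/usr/bin/env python
"""Fit the temperature-virulence models and pick the best by AIC.

Abbott-corrects the end-point bioassay counts against their matched
controls, fits Logan-1, Logan-4 and Briere-1 to the corrected mortality
proportions, and ranks them (ascending AIC; adjusted R2 and RMSE break
ties).  Writes results/virulence_fits.csv and the winning model block
results/best_model.txt consumed by the spatial projection step.
"""

from pathlib import Path

import pandas as pd

from thermovir import bioassay, fitting, tpc_models
from thermovir.cli import write_kv

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    counts = pd.read_csv(ROOT / "sim" / "virulence.csv")
    corrected = bioassay.corrected_final_mortality(counts, use_abbott=True)
    data = fitting.ResponseDataset(
        corrected["temperature_c"].to_numpy(),
        corrected["mortality"].to_numpy(),
        corrected["replicate"].to_numpy(),
        response_kind="mortality_proportion",
        isolate=str(corrected["isolate"].iloc[0]),
    )

    fits = [fitting.fit_nonlinear(data, m, seed=SEED)
            for m in ("logan1", "logan4", "briere1")]
    ranking = fitting.select_best(fits)

    rows = []
    for rank, f in enumerate(ranking.fits, start=1):
        for k, v in tpc_models.params_to_dict(f.params).items():
            if k != "model":
                rows.append((rank, f.model, k, v))
        for k in ("rss", "r2", "adj_r2", "rmse", "aic", "msc"):
            rows.append((rank, f.model, k, getattr(f.gof, k)))
    pd.DataFrame(rows, columns=["rank", "model", "parameter", "value"]).to_csv(
        ROOT / "virulence_fits.csv", index=False
    )
    best = ranking.best
    write_kv(tpc_models.params_to_dict(best.params), ROOT / "best_model.txt")

    print("model ranking (AIC ascending):")
    for rank, f in enumerate(ranking.fits, start=1):
        print(f"  {rank}. {f.model:8s} AIC {f.gof.aic:8.2f}  adj R2 {f.gof.adj_r2:6.3f}  "
              f"RMSE {f.gof.rmse:.4f}")
    print(f"best model: {best.model} -> {ROOT / 'best_model.txt'}")


if __name__ == "__main__":
    main()
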