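"""End-to-end recovery harness: multi-seed simulated studies.

Runs the full image-to-statistics pipeline (simulate, render, call
particles, segment, normalise, pool, test) over a batch of seeds at the
module defaults and collects per-seed fold changes, organ-vs-placenta
deficits and exact Mann-Whitney p-values.  Used by the reproduction
script and by the recovery test-suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import RunConfig, run_pipeline


def run_recovery_batch(seeds) -> pd.DataFrame:
    """One row per seed x organ: fold ratio, deficit, Mann-Whitney p."""
    rows = []
    for seed in seeds:
        rep = run_pipeline(RunConfig(seed=int(seed)))
        fc = rep["results"]["fold_changes"]
        od = rep["results"]["organ_deficits"]
        for organ, row in fc.items():
            rows.append(
                dict(
                    seed=int(seed),
                    organ=organ,
                    fold=row["ratio"],
                    p_value=row["p_value"],
                    deficit=od.get(organ, {}).get("deficit", np.nan),
                )
            )
    return pd.DataFrame(rows)


def summarise_recovery(batch: pd.DataFrame) -> pd.DataFrame:
    """Seed-averaged fold / deficit / significance rates per organ."""
    out = (
        batch.groupby("organ")
        .agg(
            mean_fold=("fold", "mean"),
            sd_fold=("fold", "std"),
            mean_deficit=("deficit", "mean"),
            rate_p_below_05=("p_value", lambda p: float((p < 0.05).mean())),
            rate_p_above_05=("p_value", lambda p: float((p > 0.05).mean())),
            n_seeds=("seed", "nunique"),
        )
        .reset_index()
    )
    return out
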