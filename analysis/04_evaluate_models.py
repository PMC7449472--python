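#!/usr/bin/env python
"""Evaluate predictive accuracy and rank candidate score models.

Calibrates each candidate (the geometric score and the two
power-containing alternatives) on the first nine devices, predicts all
twelve, and ranks the candidates by out-of-sample R² (predictions taken
as-is against the identity line, so a candidate can score negative).
Writes results/model_ranking.csv and results/predictions.csv.
"""

from pathlib import Path

import pandas as pd

from coiltox.calibration import rank_models
from coiltox.device_model import read_devices
from coiltox.emissions import read_sessions, summarize_fleet
from coiltox.scoring import builtin_models

ROOT = Path(__file__).resolve().parent.parent / "results"
N_TRAIN = 9


def main() -> None:
    fleet = read_devices(ROOT / "benchmark" / "devices.csv")
    sessions = read_sessions(ROOT / "benchmark" / "sessions.csv")
    summaries = summarize_fleet(sessions)
    results = rank_models(
        builtin_models(), fleet[:N_TRAIN], summaries, fleet, summaries
    )
    rows, pair_rows = [], []
    for r in results:
        if r.failed:
            rows.append({"model": r.model.name, "status": "failed", "error": r.error})
            continue
        rows.append({
            "model": r.model.name, "status": "ok", "a": r.fit.a, "b": r.fit.b,
            "fit_r2": r.fit_r2, "predictive_r2": r.predictive_r2,
        })
        for device_id, observed, predicted in r.evaluation.pairs:
            pair_rows.append({"model": r.model.name, "device_id": device_id,
                              "observed": observed, "predicted": predicted})
    pd.DataFrame(rows).to_csv(ROOT / "model_ranking.csv", index=False)
    pd.DataFrame(pair_rows).to_csv(ROOT / "predictions.csv", index=False)
    print(f"wrote {ROOT / 'model_ranking.csv'} and {ROOT / 'predictions.csv'}")
    for row in rows:
        if row["status"] == "ok":
            print(f"{row['model']}: predictive R² = {row['predictive_r2']:.4f} "
                  f"(fit R² = {row['fit_r2']:.4f})")
        else:
            print(f"{row['model']}: failed ({row['error']})")


if __name__ == "__main__":
    main()
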