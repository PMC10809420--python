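#!/usr/bin/env python
"""Markov lag selection from the sweep's t2 curves.

For every trial the log-log gradient |d ln t2 / d ln tau| is evaluated on the
lag grid from the bootstrap medians; the selected lag is the smallest grid lag
at which the worst trial's gradient is below the threshold and stays below it.
Run 03_hyperparameter_sweep.py first.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from msmselect.lag_select import LagGrid, select_lag, timescale_gradient

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
THRESHOLD = 0.1


def main():
    sweep_csv = ROOT / "scratch" / "sweep.csv"
    if not sweep_csv.exists():
        raise SystemExit("run analysis/03_hyperparameter_sweep.py first")
    df = pd.read_csv(sweep_csv)
    t2 = df[df["observable"] == "t_2"]
    lags = tuple(int(x) for x in sorted(t2["lag"].unique()))
    grid = LagGrid(lags=lags, threshold=THRESHOLD)
    gradients, used = [], []
    for tid, grp in t2.groupby("trial_id"):
        curve = grp.set_index("lag")["median"].reindex(lags).to_numpy()
        if np.isfinite(curve).sum() >= 2:
            gradients.append(timescale_gradient(curve, lags))
            used.append(int(tid))
    tau = select_lag(np.array(gradients), grid)
    print(f"lag grid (frames): {lags}; threshold {THRESHOLD}")
    print(f"{len(used)} trials with usable t2 curves")
    print(f"selected Markov lag: {tau} frames"
          if tau is not None else "no lag satisfies the convergence criterion")
    payload = {"selected_lag": tau, "threshold": THRESHOLD, "lags": list(lags),
               "trials_used": used,
               "median_gradients": [list(map(float, g)) for g in gradients]}
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "lag_selection.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {RESULTS / 'lag_selection.json'}")


if __name__ == "__main__":
    main()
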