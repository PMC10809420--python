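#!/usr/bin/env python
"""Does the choice of Markov lag or of the number of scored eigenvectors k
change which hyperparameters win?

Trials from the sweep are ranked by bootstrap-median VAMP2_eq(k) at every lag
(fixed k) and at every k (fixed lag); pairwise Spearman matrices quantify how
consistent the rankings are.  Run 03_hyperparameter_sweep.py first.
"""

from pathlib import Path

import pandas as pd

from msmselect.experiments import HyperTrial, rank_consistency
from msmselect.resampling import BootstrapSummary

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def load_trials(sweep_csv):
    df = pd.read_csv(sweep_csv)
    trials = []
    for tid, grp in df.groupby("trial_id"):
        t = HyperTrial(trial_id=int(tid), theta={})
        for _, row in grp.iterrows():
            t.observables.setdefault(int(row["lag"]), {})[row["observable"]] = (
                BootstrapSummary(row["median"], row["ci_low"], row["ci_high"],
                                 int(row["n_valid"])))
        trials.append(t)
    lags = sorted(int(x) for x in df["lag"].unique())
    return trials, lags


def main():
    sweep_csv = ROOT / "scratch" / "sweep.csv"
    if not sweep_csv.exists():
        raise SystemExit("run analysis/03_hyperparameter_sweep.py first")
    trials, lags = load_trials(sweep_csv)
    RESULTS.mkdir(exist_ok=True)

    for k in (2, 10):
        cm = rank_consistency(trials, vary="lag", lags=lags, fixed_k=k)
        cm.to_frame().to_csv(RESULTS / f"consistency_lag_k{k}.csv")
        off = cm.rho[~(cm.rho == 1.0)]
        print(f"rank consistency across lags at k={k}: "
              f"min off-diagonal rho = {cm.rho.min():.3f}")

    ks = list(range(2, 11))
    cm = rank_consistency(trials, vary="k", ks=ks, fixed_lag=lags[-1])
    cm.to_frame().to_csv(RESULTS / "consistency_k.csv")
    print(f"rank consistency across k at lag {lags[-1]}: "
          f"min off-diagonal rho = {cm.rho.min():.3f}")
    print(f"wrote consistency matrices to {RESULTS}")


if __name__ == "__main__":
    main()
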