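#!/usr/bin/env python
"""The three-state inversion experiment.

1000 reversible MSMs are estimated from independent 20-step trajectories of
the same three-state chain.  Ranking models by VAMP2_eq(2) = 1 + lambda_2^2
agrees with ranking by t2 exactly (both are monotone in lambda_2); ranking by
the whitened VAMP2(2) — reversible eigenvectors scored against the raw count
matrices — does not: finite sampling makes the counts inconsistent with the
detailed-balance eigenvectors, producing inverted pairs.  A long-trajectory
control shows the inconsistency vanishing with data.
"""

import json
from pathlib import Path

from msmselect.experiments import toy_inversion_experiment

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 7


def main():
    RESULTS.mkdir(exist_ok=True)
    table, report = toy_inversion_experiment(n_replicates=1000, traj_length=20,
                                             lag=1, seed=SEED)
    _, long_report = toy_inversion_experiment(n_replicates=150, traj_length=100_000,
                                              lag=1, seed=SEED + 1)
    print(f"20-step sampling ({report['n_valid']} valid replicates):")
    print(f"  Spearman(t2, VAMP2_eq(2)) = {report['spearman_t2_vamp2eq']:.4f}  (exact)")
    print(f"  Spearman(t2, VAMP2(2))    = {report['spearman_t2_vamp2']:.4f}  "
          f"with {report['discordant_pairs_vamp2']} inverted pairs")
    print(f"1e5-step control ({long_report['n_valid']} replicates):")
    print(f"  Spearman(t2, VAMP2(2))    = {long_report['spearman_t2_vamp2']:.6f}")
    (ROOT / "scratch").mkdir(exist_ok=True)
    table.to_csv(ROOT / "scratch" / "toy_inversion_table.csv", index=False)
    (RESULTS / "toy_inversion_report.json").write_text(
        json.dumps({"short": report, "long": long_report}, indent=2))
    print(f"wrote {RESULTS / 'toy_inversion_report.json'}")


if __name__ == "__main__":
    main()
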