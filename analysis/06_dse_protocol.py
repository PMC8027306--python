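#!/usr/bin/env python
"""Design-space exploration and the majority-vote ensemble, desk scale.

DSE1 sweeps the learning rate and threshold step over the protocol's
logarithmic grid (12 cells for the rate-regime system) on a reduced
dataset; DSE2 re-runs the winner across network sizes with eta and
d_theta rescaled linearly by size.  Finally six independently seeded
networks vote on each test pattern.  Problem sizes here are deliberately
small — the point is the protocol, not the absolute numbers.
"""

import pathlib
import sys
from dataclasses import replace

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from tempocode.pipelines import (NMNIST_DSE_GRID, default_rate_run_config,
                                 dse1, dse2, ensemble_majority,
                                 prepare_dataset, run_rdstdp)
from tempocode.synth import (RateCodedGenConfig, gen_rate_coded_dataset,
                             make_templates, raised_cosine_envelope)

BASE = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    templates = make_templates(4, 24, 24)
    envelope = raised_cosine_envelope(105)
    train = prepare_dataset(gen_rate_coded_dataset(
        templates, envelope, RateCodedGenConfig(n_per_class=30, seed=1)))
    test = prepare_dataset(gen_rate_coded_dataset(
        templates, envelope, RateCodedGenConfig(n_per_class=15, seed=2)))

    base = {"rdstdp": default_rate_run_config(seed=1, N_e=36)}
    table1, best = dse1(NMNIST_DSE_GRID, base, train, test)
    table1.to_csv(BASE / "dse1_rdstdp.csv", index=False)
    top = table1.loc[table1.accuracy.idxmax()]
    print(f"DSE1 ({len(table1)} cells): best eta={top.eta}, "
          f"d_theta={top.d_theta} -> {100 * top.accuracy:.1f}%")

    table2 = dse2(best["rdstdp"], (16, 25, 36, 49, 64, 81), train, test)
    table2.to_csv(BASE / "dse2_rdstdp.csv", index=False)
    print("DSE2 size sweep:")
    for _, row in table2.iterrows():
        print(f"  N_e={int(row.N_e):3d}  accuracy {100 * row.accuracy:.1f}%")

    # 6-member ensemble: independently seeded networks, majority vote
    members = [run_rdstdp(train, test, replace(best["rdstdp"], seed=seed))
               for seed in range(1, 7)]
    votes = ensemble_majority(
        np.stack([m.extras["predictions"] for m in members]))
    acc = float(np.mean(votes == test.labels))
    single = float(np.mean([m.accuracy for m in members]))
    print(f"mean single-network accuracy: {100 * single:.1f}%")
    print(f"6-network majority vote:      {100 * acc:.1f}%")


if __name__ == "__main__":
    main()
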