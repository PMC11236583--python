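#!/usr/bin/env python
"""Target-phase analysis: does the contour rate persist into the visual sentence?

Computes sensor power spectra of one-cycle epochs after sentence onset and
the 0.6-vs-0.9 Hz cluster contrasts.  Writes results/03_target_power/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from deltrain import pipeline as pl
from deltrain import simulate as sim
from deltrain import spectral, stats
from deltrain.spectral import SpectralGrid, peak_frequency
from deltrain.stimuli import FAST, SLOW

OUT = Path(__file__).resolve().parent.parent / "results" / "03_target_power"
N_SUBJECTS, N_TRIALS, SEED = 10, 96, 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sim.SimConfig(n_subjects=N_SUBJECTS, n_trials=N_TRIALS, seed=SEED)
    model = sim.build_sensor_model(seed=cfg.seed)
    grid = SpectralGrid()

    pow_ = {SLOW: [], FAST: []}
    for s, rng in enumerate(sim.subject_seeds(cfg.seed, cfg.n_subjects)):
        plan = sim.generate_plan_for(cfg, s)
        rec, _ = sim.simulate_subject(cfg, plan, model, rng)
        for cond in (SLOW, FAST):
            ep = spectral.extract_epochs(rec, phase="target", condition=cond)
            ep, _ = pl.reject_trials_qc(ep, pl.QCConfig())
            pow_[cond].append(spectral.power_spectrum(ep, grid).values)
        print(f"subject {s}: done")

    rows = []
    for cond in (SLOW, FAST):
        group = np.array(pow_[cond]).mean(axis=(0, 1))
        peak = peak_frequency(group, (0.1, 1.5), grid.frequencies)
        print(f"{cond}: group target-phase power peak {peak:.1f} Hz")
        rows += [
            {"condition": cond, "frequency": f, "power": v}
            for f, v in zip(grid.frequencies, group)
        ]
    pd.DataFrame(rows).to_csv(OUT / "group_power.tsv", sep="\t", index=False)

    foi = {
        (cond, f): np.array(pow_[cond])[:, :, grid.bin_of(f)]
        for cond in (SLOW, FAST)
        for f in (0.6, 0.9)
    }
    for name, (a, b) in {
        "slow_06_vs_09": (foi[(SLOW, 0.6)], foi[(SLOW, 0.9)]),
        "fast_06_vs_09": (foi[(FAST, 0.6)], foi[(FAST, 0.9)]),
        "interaction": (
            foi[(SLOW, 0.6)] - foi[(SLOW, 0.9)],
            foi[(FAST, 0.6)] - foi[(FAST, 0.9)],
        ),
    }.items():
        clusters = stats.cluster_permutation(
            a, b, model.neighborhood, n_perm=5000, seed=SEED
        )
        stats.clusters_to_json(clusters, OUT / f"clusters_{name}.json")
        sig = sum(c.significant for c in clusters)
        print(f"{name}: {len(clusters)} cluster(s), {sig} significant")


if __name__ == "__main__":
    main()
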