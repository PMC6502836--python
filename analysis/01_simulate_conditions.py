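#!/usr/bin/env python
"""Simulate the study's experimental regimes as synthetic photon-trace datasets.

Four conditions at the agonist-binding-domain labeling site:

* ``apo_na``      — resting receptor, one coupled conformation (E = 0.89)
* ``antagonist``  — antagonist-locked, one rigid conformation (E = 0.95)
* ``glu_na``      — agonist-bound, five-state efficiency ladder biased toward
                    the coupled (high-E) states
* ``glu_cs``      — the same ladder with occupancy shifted toward the
                    decoupled (low-E) states, emulating ion modulation

Traces go to scratch/data/<condition>/ (regenerable, not part of the
repository); a per-condition summary lands in results/conditions.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fretscape import simulate_dataset
from fretscape.presets import (FIVE_STATE_EFFICIENCIES, five_state_config,
                               nearest_neighbor_rates, single_state_config)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

SEED = 2026
N_MOLECULES = {"apo_na": 57, "antagonist": 28, "glu_na": 66, "glu_cs": 52}

NA_WEIGHTS = np.array([0.30, 0.25, 0.20, 0.15, 0.10])   # coupled states favored
CS_WEIGHTS = NA_WEIGHTS[::-1]                           # decoupled states favored


def condition_configs():
    return {
        "apo_na": single_state_config(0.89),
        "antagonist": single_state_config(0.95),
        "glu_na": five_state_config(
            rate_matrix=nearest_neighbor_rates(5, 150.0, NA_WEIGHTS)),
        "glu_cs": five_state_config(
            rate_matrix=nearest_neighbor_rates(5, 150.0, CS_WEIGHTS)),
    }


def main():
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for i, (name, cfg) in enumerate(condition_configs().items()):
        n = N_MOLECULES[name]
        out = DATA / name
        simulate_dataset(cfg, n, seed=SEED + i, out_dir=out, condition=name)
        rows.append({
            "condition": name,
            "n_molecules": n,
            "n_states": cfg.n_states,
            "efficiencies": ",".join(f"{e:g}" for e in cfg.state_efficiencies),
            "seed": SEED + i,
        })
        print(f"{name}: {n} molecules, {cfg.n_states} states -> {out}")
    pd.DataFrame(rows).to_csv(RESULTS / "conditions.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / 'conditions.tsv'}")


if __name__ == "__main__":
    main()
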