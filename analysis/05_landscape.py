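#!/usr/bin/env python
"""Transition maps and free-energy diagrams for the dynamic conditions.

For each multi-state condition: bin-to-bin transition counts between fitted
states (within molecules only), per-state standard free energies
dG = -kBT ln(p/p_max), and Arrhenius activation barriers from the per-bin
transition probabilities at A = 10 /ms.  Tables land under
results/landscape_<condition>/.
"""

import importlib
import sys
from pathlib import Path

import numpy as np

from fretscape import build_histogram, build_landscape, distance_table, stasi_fit
from fretscape.io import write_results

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "analysis"))
load_efficiency_traces = importlib.import_module(
    "03_efficiency_histograms").load_efficiency_traces

DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main():
    for cond_dir in sorted(DATA.iterdir()):
        ets = load_efficiency_traces(cond_dir)
        model = stasi_fit(ets)
        if model.n_states < 2:
            print(f"{cond_dir.name}: single state, no transition map")
            continue
        scape = build_landscape(model, bin_width=5.0)
        out = RESULTS / f"landscape_{cond_dir.name}"
        write_results(model, scape, out,
                      histogram=build_histogram(ets),
                      distance_table=distance_table(model.state_efficiencies))
        counts = scape.transition_counts
        adjacent = sum(counts[i, j] for i in range(model.n_states)
                       for j in range(model.n_states) if abs(i - j) == 1)
        print(f"{cond_dir.name}: {counts.sum()} transitions, "
              f"{100 * adjacent / counts.sum():.1f}% adjacent; "
              f"dG = {np.round(scape.delta_G, 2)} kBT")


if __name__ == "__main__":
    main()
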