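# fretscape

Conformational and energy landscapes of membrane receptors from
single-molecule FRET photon traces.

Single-molecule FRET reports the distance between a donor and an acceptor
fluorophore attached to one protein: the transfer efficiency falls with the
sixth power of their separation, so a time series of efficiencies is a time
series of conformations. `fretscape` implements the full trace-analysis
chain used for glutamate-receptor (GluK2 kainate receptor) smFRET
experiments — from raw two-channel photon counts to state models, distances,
transition maps and free-energy diagrams — together with a photon-level
simulator that generates statistically faithful synthetic datasets with
ground truth, so every stage is testable as a parameter-recovery problem.

It is aimed at people who analyze surface-isolated smFRET intensity traces
(1 ms photon counting, micro- to millisecond conformational dynamics) and
want a scripted, reproducible alternative to interactive MATLAB tooling.

## The analysis

1. **QC / molecule selection.** Only molecules carrying exactly one donor and
   one acceptor report a single distance. Bleach steps are counted by
   change-point detection on state-invariant series (the summed
   donor-excitation intensity for donor bleaches; the direct-excitation
   channel for acceptor bleaches), and candidate molecules must show
   donor/acceptor anticorrelation (Pearson r ≤ −0.3). The FRETing region
   ends at the first bleach.
2. **Efficiency.** Counts are rebinned from 1 ms to 5 ms and converted to
   the background-subtracted proximity ratio E = I_A / (I_D + I_A), then
   denoised with translation-invariant Haar wavelet thresholding.
3. **State identification (STaSI).** Recursive t-test change-point splitting
   segments each trace into constant levels; segment means from all
   molecules of a condition are merged hierarchically, and the number of
   states K is chosen by a minimum-description-length criterion. An
   independent Gaussian-emission hidden Markov model (EM with restarts, BIC)
   is fit to the raw efficiencies as a cross-check.
4. **Distances.** Each state efficiency maps to a distance through the
   Förster relation E = 1 / (1 + (R/R₀)⁶), i.e. R = R₀·(1/E − 1)^(1/6),
   with R₀ = 51 Å for the Alexa 555/647 pair (configurable).
5. **Energetics.** State occupancies give standard free energies
   ΔG⁰ = −k_BT ln K_eq (most populated state ≡ 0); bin-to-bin transition
   probabilities give first-order rates k = p/Δt and Arrhenius barriers
   E_a = −k_BT ln(k/A) with attempt frequency A = 10 ms⁻¹, forward and
   reverse barriers averaged.

## Worked example

Simulate an agonist-bound-like condition (five states with nearest-neighbor
kinetics), run the pipeline, and read off the landscape:

```python
import fretscape as fs
from fretscape.presets import five_state_config

traces = fs.simulate_dataset(five_state_config(), 66, seed=7, out_dir="demo")
bundle = fs.run_pipeline(fs.RunConfig(manifest="demo", seed=0), fit_hmm=False)
print(bundle.counts)
print(bundle.state_model.state_efficiencies.round(3))
print(bundle.distances.distance_A_rounded.tolist())
```

prints

```
{'input': 66, 'accepted': 48, 'analyzed': 48, 'states': 5}
[0.928 0.82  0.699 0.579 0.39 ]
[33, 40, 44, 48, 55]
```

— 48 of 66 molecules pass QC, STaSI recovers the five simulated states
(truth: 0.93/0.82/0.70/0.58/0.39) to within 0.002, and the distance table
converts them to ångström at R₀ = 51 Å.

The numbered scripts under `analysis/` run the same machinery over four
synthetic conditions (resting, antagonist-locked, and two agonist-bound
ion regimes differing only in state occupancy), writing histograms, state
tables, transition maps and ΔG/E_a tables under `results/`. On the default
seeds the two agonist-bound regimes yield the same five-state ladder within
|ΔE| ≤ 0.003 while shifting 0.26 of the total occupancy toward the
low-efficiency states, and ≥ 94% of detected transitions connect adjacent
states.

## Layout

```
src/fretscape/   library: sim, io, qc, fret (efficiency), states, landscape,
                 pipeline, presets, cli
analysis/        numbered narrative drivers writing tables to results/
scripts/         acceptance.py
tests/           pytest suite (unit, property and end-to-end checks)
docs/methods.md  model and algorithm notes, parameter defaults, limitations
```

A `fretscape` console command exposes the stages (`simulate`, `qc`, `fret`,
`states`, `landscape`, `run`, `compare`) for shell use.
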