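# Methods notes

This document records the models, algorithmic choices and parameter defaults
behind `fretscape`, and what the synthetic benchmarks do and do not
establish about real data.

## Generative model (module `sim`)

A molecule is a set of fluorophores on one receptor. The conformational
coordinate is a continuous-time Markov chain over K discrete states with
generator Q (ms⁻¹), sampled exactly by Gillespie simulation and then binned
to the 1 ms acquisition grid; per-bin emission intensities use the
time-weighted mean efficiency within the bin, so sub-bin dwells contribute
partial mixing exactly as finite integration time does in an experiment.

Per 1 ms bin, with I = `total_intensity` photons per donor and background b
per channel:

* donor channel ~ Poisson(I·n_D·(1 − E·f_A) + b)
* acceptor channel ~ Poisson(I·n_D·E·f_A + b)
* direct-excitation channel ~ Poisson(I_direct·n_A + b)

where n_D, n_A are the numbers of alive donors/acceptors and f_A is the
fraction of the bin before the last acceptor bleach. Fluorophores bleach
independently with exponential hazards. Total detected intensity is
conserved under energy transfer, so donor bleaches (and only donor bleaches)
step the summed donor-excitation intensity, while acceptor bleaches (and
only acceptor bleaches) step the direct-excitation channel — the QC stage
relies on both facts.

Labeling stoichiometry: a molecule draws 1–4 fluorophores with weights
(0.05, 0.35, 0.50, 0.10), matching the observed one-to-four bleach-step
distribution in the receptor datasets; k fluorophores are realized as
⌈k/2⌉ donors and ⌊k/2⌋ acceptors, which makes the two-fluorophore class
exactly the analyzable donor/acceptor pairs. Multi-acceptor molecules pool
their FRET emission (no per-acceptor spectral resolution); this is
sufficient for selection tests, which reject such molecules from the donor
side.

Defaults: I = 50 counts/ms, b = 2 counts/ms/channel — chosen to give
5 ms-binned efficiency histograms with widths (FWHM ≈ 0.08–0.12) typical of
receptor smFRET data; bleach hazards 2×10⁻⁴ (donor) and 4×10⁻⁴ ms⁻¹
(acceptor, red dyes bleach faster), giving FRETing regions averaging
≈ 1.7 s, inside the 1–3 s range these acquisitions produce; trace length
20 s so both labels almost always bleach in-trace. The five-state benchmark
preset lowers I to 20 counts/ms so the per-5 ms-bin efficiency noise is
σ ≈ 0.05, the regime the state-identification benchmark is defined in.

Not modeled: blinking, triplet shelving, spectral crosstalk, γ-factor
asymmetries, diffusing background. Passing recovery tests on this generator
therefore shows the analysis is correct for shot-noise-limited, bleach-
terminated traces, not that it is robust to those additional artifacts.

## Molecule selection (module `qc`)

Bleach steps are change points found by recursive binary segmentation with a
two-sample t statistic (threshold |t| ≥ 5, minimum segment 10 bins). Photon
counts are heteroscedastic (variance = mean), so each series is first
variance-stabilized with the Anscombe transform 2√(x + 3/8), after which the
noise scale is unity at any intensity; the robust scale estimate is floored
at 1. At these settings the false change-point rate on constant-mean Poisson
series of 2×10⁴ bins is below 10⁻² per trace.

Because conformational transitions also step the individual FRET channels,
step *counting* runs on state-invariant series: the summed donor-excitation
intensity (donor bleaches) and the direct-excitation channel (acceptor
bleaches). Without a direct-excitation channel the acceptor-channel fallback
is reliable only for conformationally quiet molecules.

Acceptance requires exactly one step of each kind plus donor/acceptor
anticorrelation r ≤ −0.3 over the FRETing region. For a static molecule the
FRETing region alone carries no anticorrelation (Poisson noise in the two
channels is independent), so when the acceptor bleaches first the window is
extended 100 bins past the bleach to include the donor-rise signature —
the standard manual-inspection criterion, made explicit. Static molecules
whose donor bleaches first genuinely lack any anticorrelation evidence and
are rejected; dynamic molecules pass either way. This asymmetry slightly
disfavors static molecules in mixed datasets and is the main known bias of
the selection stage.

## Efficiency and denoising (module `fret`)

Efficiency is the uncorrected proximity ratio on background-subtracted,
5 ms-binned counts. No γ, leakage or direct-excitation corrections are
applied; the distance calibration (R₀ below) absorbs ratio-level offsets.
Bins with non-positive total signal are flagged invalid and excluded.

Denoising is translation-invariant Haar wavelet thresholding: decomposition
depth min(4, ⌊log₂ n⌋ − 1), universal threshold σ√(2 ln n) with σ from the
median absolute deviation of the finest detail coefficients, **hard**
thresholding, averaged over 8 circular shifts. Soft thresholding was
evaluated and rejected: it shrinks the (few, large) step coefficients by the
threshold and on Markovian two-state benchmarks failed to reduce RMSE at
all, whereas hard thresholding with cycle spinning cuts RMSE by ≈ 50%.
The procedure is deterministic and mean-preserving on dyadic lengths.

## State identification (module `states`)

**STaSI.** Each trace is segmented by recursive t-test splitting
(threshold |t| ≥ 3, minimum segment 3 bins, noise σ pooled from finest-scale
differences of the raw efficiencies). Detection always scans the raw
series; with `use_denoised` (default) the denoised series is scanned too and
the union kept. Two empirical findings drive this: the wavelet's coarsest
scale suppresses dwells shorter than ~8 bins, and every missed dwell becomes
a mixed segment whose mean sits between true states — at scale, these mixed
segments masquerade as extra states. For the same reason segment statistics
(means, residuals) are taken on the raw series with one boundary bin trimmed
from each interior segment edge, and the split threshold is liberal:
over-segmentation is repaired by the merging step, under-segmentation is
not.

Segment means from all molecules are agglomerated greedily by nearest mean;
each level of the merge path is a candidate state set scored by the
description length

    MDL(k) = (N/2)·log₂(RSS_k/N) + (k/2)·log₂N + m_cp·log₂N + m_seg·log₂k

(unknown-variance Gaussian code length + state means + change-point
positions + segment-to-state membership). The unknown-variance form makes
the criterion self-calibrating against the photon-noise floor, and the
membership term is what keeps selection consistent when a condition
contributes hundreds of segments. The selected model is post-processed by
two physical constraints: states closer than 0.03 efficiency units are
merged (unresolvable at these noise levels), and states holding under 0.5%
of the bins are dissolved into their nearest neighbor (isolated outlier
segments are not conformations). On the five-state benchmark (66 molecules,
σ = 0.05, 150 ms dwells) the selected K equals 5 across seeds with state
efficiencies recovered to ±0.005, and the greedy-path minimum coincides
with exhaustive partition search on small instances.

**HMM cross-check.** A Gaussian-emission HMM is fit to the *raw*
efficiencies (the denoised data never enter, so agreement between the two
routes also validates the denoising): 10 deterministically seeded short EM
restarts per candidate K ≤ 6, one long refinement of the best restart, K by
BIC. Because Gaussian emissions understate the tails of shot-noise
efficiency distributions, BIC reliably splits one state into two strongly
overlapping components; decoded states are therefore merged when their means
are closer than the larger of 0.03 and the smaller emission σ, with the same
0.5% occupancy floor. After post-processing the HMM agrees with STaSI to
±0.005 per state on the benchmark.

Histograms pool one count per 5 ms bin over all molecules of a condition
(bin width 0.01 over [0, 1.05], normalized to fractions); Gaussian mixture
peaks are fit by bounded least squares with the state efficiencies as
initial means.

## Distances and energetics (module `landscape`)

R = R₀·(1/E − 1)^(1/6), reported rounded to whole ångström. R₀ defaults to
51 Å: a brute-force scan showed this single value reproduces, after
rounding, all eight reported peak-efficiency/distance pairs for the
Alexa 555/647 pair at both labeling sites, so it is frozen as the default
and exposed as configuration. Absolute distances inherit all the usual
smFRET caveats (κ² ≈ 2/3 assumption, dye-linker excursions); relative
distances between states are more trustworthy than absolute ones.

Transitions are counted between consecutive 5 ms bins within molecules only;
p_ij divides by total bins spent in state i, honoring occupancy as the
"concentration of the starting state". ΔG⁰_i = −ln(p_i/p_max) in k_BT
(most populated state ≡ 0; unvisited states → +∞, flagged). Rates use the
small-p first-order limit k = p/Δt by default (−ln(1−p)/Δt behind a flag);
barriers E_a = −ln(k/A) with A = 10 ms⁻¹, forward/reverse averaged, pairs
with unobserved transitions omitted from the symmetrized output. Energies
are k_BT at 298 K; a kcal/mol conversion (0.5925 kcal/mol per k_BT) is
provided for convenience. Both T and R₀ are configuration with documented
defaults, not measured values.

Note that bin-level transition probabilities undercount fast exchange
(multiple jumps per bin) and misassigned boundary bins add a small
non-adjacent-transition floor; on the nearest-neighbor benchmark ≥ 94% of
detected transitions are adjacent.

## Pipeline and reproducibility

Every stage is a pure function of (inputs, config, seed); a run writes its
config hash, software version and per-stage molecule counts to
`provenance.json`, and reruns are byte-identical. Dataset simulation derives
per-molecule seeds from one master seed. The analysis scripts use 28–66
molecules per condition and 20 s traces (tens of thousands of 5 ms analysis
bins per condition), sizes at which all benchmark recoveries are stable and
a full condition runs in seconds (STaSI) to under a minute (HMM) on one
core.

## Known limitations

* The QC anticorrelation gate rejects ~⅓ of conformationally static
  molecules (donor-first bleaches); selection is unbiased only across
  molecules with the acceptor bleaching first or with visible dynamics.
* Mixed 5 ms bins at state transitions put a small mass of intermediate
  efficiencies in the histograms; STaSI absorbs it via boundary trimming,
  but Gaussian-mixture FWHM estimates inherit a slight broadening.
* The HMM route's state count relies on post-hoc merging; its dwell/rate
  estimates are not used for the energy landscape (STaSI assignments are).
* No correction factors (γ, crosstalk, direct excitation) — distances are
  calibrated at the proximity-ratio level through R₀.
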