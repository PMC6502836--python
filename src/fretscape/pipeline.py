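"""End-to-end orchestration: traces -> QC -> efficiency -> states -> landscape.

Every stage is a pure function of (inputs, config, seed); a run writes all
stage products plus a provenance record (config hash, version, per-stage
molecule counts) so identical configs and inputs give identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import fret, io, landscape as landscape_mod, qc, states as states_mod

__all__ = ["RunConfig", "ResultBundle", "PipelineError", "run_pipeline",
           "compare_conditions"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage (and molecule)."""


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one analysis run; defaults mirror the standard protocol."""

    manifest: str | None = None        # input manifest/directory of traces
    condition: str = ""
    analysis_bin_ms: float = 5.0
    hist_bin_width: float = 0.01
    background_d: float = 2.0          # per acquisition bin
    background_a: float = 2.0
    qc_t_threshold: float = 5.0
    qc_min_segment: int = 10
    qc_r_threshold: float = -0.3
    stasi_t_threshold: float = 3.0
    stasi_min_segment: int = 3
    hmm_max_states: int = 6
    hmm_restarts: int = 10
    R0: float = landscape_mod.DEFAULT_R0
    pre_exponential_A: float = landscape_mod.DEFAULT_PREEXPONENTIAL
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.analysis_bin_ms <= 0 or self.hist_bin_width <= 0:
            raise ValueError("bin widths must be positive")
        if not (-1.0 <= self.qc_r_threshold <= 1.0):
            raise ValueError("qc_r_threshold must be a correlation value")
        if self.hmm_max_states < 1 or self.hmm_restarts < 1:
            raise ValueError("HMM settings out of range")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    config: RunConfig
    qc_reports: list
    efficiency_traces: list
    state_model: states_mod.StateModel
    hmm_model: states_mod.StateModel | None
    landscape: landscape_mod.EnergyLandscape
    histogram: tuple
    distances: pd.DataFrame
    counts: dict[str, int]            # per-stage molecule counts


def run_pipeline(config: RunConfig, traces=None, fit_hmm: bool = True) -> ResultBundle:
    """Run QC, efficiency calculation, state identification and landscape
    construction over ``traces`` (or the traces named by ``config.manifest``).

    Writes stage outputs and a provenance file when ``config.out_dir`` is set.
    Raises :class:`PipelineError` naming the failing stage.
    """
    if traces is None:
        if config.manifest is None:
            raise PipelineError("input: no traces and no manifest configured")
        try:
            traces = io.read_traces(config.manifest)
        except Exception as exc:
            raise PipelineError(f"input: {exc}") from exc
    n_input = len(traces)

    reports, accepted = [], []
    for trace in traces:
        try:
            rep = qc.select_molecule(
                trace, t_threshold=config.qc_t_threshold,
                min_segment=config.qc_min_segment,
                r_threshold=config.qc_r_threshold)
        except Exception as exc:
            raise PipelineError(f"qc: molecule {trace.molecule_id}: {exc}") from exc
        reports.append(rep)
        if rep.accepted:
            accepted.append((trace, rep))
    if not accepted:
        raise PipelineError("qc: no molecules passed QC")

    eff_traces = []
    for trace, rep in accepted:
        try:
            et = fret.efficiency_trace(
                trace, rep, analysis_bin=config.analysis_bin_ms,
                background_d=config.background_d,
                background_a=config.background_a)
        except Exception as exc:
            raise PipelineError(f"fret: molecule {trace.molecule_id}: {exc}") from exc
        if et.n_bins >= 8:
            eff_traces.append(et)
    if not eff_traces:
        raise PipelineError("fret: no molecule retained enough analysis bins")

    try:
        model = states_mod.stasi_fit(
            eff_traces, use_denoised=True,
            t_threshold=config.stasi_t_threshold,
            min_segment=config.stasi_min_segment)
    except Exception as exc:
        raise PipelineError(f"states: STaSI failed: {exc}") from exc
    hmm_model = None
    if fit_hmm:
        try:
            hmm_model = states_mod.hmm_fit(
                eff_traces, n_states_max=config.hmm_max_states,
                n_restarts=config.hmm_restarts, seed=config.seed)
        except Exception as exc:
            raise PipelineError(f"states: HMM failed: {exc}") from exc

    hist = states_mod.build_histogram(eff_traces,
                                      bin_width=config.hist_bin_width)
    scape = landscape_mod.build_landscape(
        model, bin_width=config.analysis_bin_ms, A=config.pre_exponential_A)
    dist = landscape_mod.distance_table(model.state_efficiencies, R0=config.R0)

    counts = {"input": n_input, "accepted": len(accepted),
              "analyzed": len(eff_traces), "states": model.n_states}
    bundle = ResultBundle(config=config, qc_reports=reports,
                          efficiency_traces=eff_traces, state_model=model,
                          hmm_model=hmm_model, landscape=scape,
                          histogram=hist, distances=dist, counts=counts)
    if config.out_dir is not None:
        _write_bundle(bundle)
    return bundle


def _write_bundle(bundle: ResultBundle) -> None:
    out = Path(bundle.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc.qc_table(bundle.qc_reports).to_csv(out / "qc_report.tsv", sep="\t",
                                          index=False)
    for et in bundle.efficiency_traces:
        pd.DataFrame({
            "time_ms": np.arange(et.n_bins) * et.bin_width,
            "E_raw": np.round(et.raw_efficiency, 6),
            "E_denoised": np.round(et.denoised_efficiency, 6),
        }).to_csv(out / f"efficiency_{et.molecule_id}.tsv", sep="\t", index=False)
    io.write_results(bundle.state_model, bundle.landscape, out,
                     histogram=bundle.histogram,
                     distance_table=bundle.distances)
    provenance = {
        "software": f"fretscape {__version__}",
        "config": dataclasses.asdict(bundle.config),
        "config_hash": bundle.config.digest(),
        "molecule_counts": bundle.counts,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                    sort_keys=True) + "\n")


def compare_conditions(bundle_a: ResultBundle, bundle_b: ResultBundle) -> pd.DataFrame:
    """Descriptive per-state comparison of two conditions.

    States are matched greedily by nearest efficiency; the report lists
    matched efficiency and occupancy differences (b minus a) and flags
    unmatched states.  No hypothesis testing.
    """
    ea = np.asarray(bundle_a.state_model.state_efficiencies)
    eb = np.asarray(bundle_b.state_model.state_efficiencies)
    oa = np.asarray(bundle_a.state_model.occupancies)
    ob = np.asarray(bundle_b.state_model.occupancies)
    pairs = sorted(((abs(x - y), i, j) for i, x in enumerate(ea)
                    for j, y in enumerate(eb)))
    used_a, used_b, matched = set(), set(), []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    rows = []
    for i, j in sorted(matched):
        rows.append({"state_a": i, "state_b": j,
                     "E_a": ea[i], "E_b": eb[j], "dE": eb[j] - ea[i],
                     "occ_a": oa[i], "occ_b": ob[j],
                     "d_occupancy": ob[j] - oa[i], "unmatched": ""})
    for i in range(len(ea)):
        if i not in used_a:
            rows.append({"state_a": i, "state_b": -1, "E_a": ea[i],
                         "E_b": np.nan, "dE": np.nan, "occ_a": oa[i],
                         "occ_b": np.nan, "d_occupancy": np.nan,
                         "unmatched": "a"})
    for j in range(len(eb)):
        if j not in used_b:
            rows.append({"state_a": -1, "state_b": j, "E_a": np.nan,
                         "E_b": eb[j], "dE": np.nan, "occ_a": np.nan,
                         "occ_b": ob[j], "d_occupancy": np.nan,
                         "unmatched": "b"})
    return pd.DataFrame(rows, columns=["state_a", "state_b", "E_a", "E_b",
                                       "dE", "occ_a", "occ_b", "d_occupancy",
                                       "unmatched"])
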