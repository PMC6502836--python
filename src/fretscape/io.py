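"""Trace and result-table input/output.

The interchange format is deliberately plain: one tab-separated file per
molecule with columns ``time_ms, donor, acceptor[, acceptor_direct]``
(time is bin-start, 0-based, milliseconds), preceded by ``#`` metadata lines,
plus a manifest listing molecule files and their experimental condition
labels.  Result tables (state tables, transition matrices, free-energy
tables) are TSV with a deterministic column order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PhotonTrace", "ParseError", "read_trace", "read_traces",
           "write_trace", "write_traces", "write_results", "read_manifest"]


class ParseError(ValueError):
    """A trace file violated the format or an invariant."""


@dataclass
class PhotonTrace:
    """Raw two-channel binned photon counts for one molecule.

    ``donor`` and ``acceptor`` are counts per bin under donor excitation;
    ``acceptor_direct`` (optional) is the acceptor channel under direct
    acceptor excitation, used only for label verification.
    """

    molecule_id: str
    bin_width: float  # ms
    donor: np.ndarray
    acceptor: np.ndarray
    acceptor_direct: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self):
        self.donor = np.asarray(self.donor)
        self.acceptor = np.asarray(self.acceptor)
        if self.acceptor_direct is not None:
            self.acceptor_direct = np.asarray(self.acceptor_direct)
        self.validate()

    def validate(self):
        if self.bin_width <= 0:
            raise ParseError(f"{self.molecule_id}: bin_width must be > 0")
        n = len(self.donor)
        channels = [("donor", self.donor), ("acceptor", self.acceptor)]
        if self.acceptor_direct is not None:
            channels.append(("acceptor_direct", self.acceptor_direct))
        for name, ch in channels:
            if len(ch) != n:
                raise ParseError(
                    f"{self.molecule_id}: channel {name} length {len(ch)} != {n}")
            neg = np.flatnonzero(np.asarray(ch) < 0)
            if neg.size:
                raise ParseError(
                    f"{self.molecule_id}: negative count in channel {name} "
                    f"at row {int(neg[0])}")

    @property
    def n_bins(self) -> int:
        return len(self.donor)

    @property
    def time_ms(self) -> np.ndarray:
        """Bin-start times in ms (0-based)."""
        return np.arange(self.n_bins) * self.bin_width

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


def write_trace(trace: PhotonTrace, path) -> None:
    path = Path(path)
    cols = {"time_ms": trace.time_ms,
            "donor": trace.donor,
            "acceptor": trace.acceptor}
    if trace.acceptor_direct is not None:
        cols["acceptor_direct"] = trace.acceptor_direct
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# molecule_id={trace.molecule_id}\n")
        fh.write(f"# bin_width_ms={trace.bin_width:g}\n")
        if trace.provenance:
            fh.write(f"# provenance={trace.provenance}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%g")


def read_trace(path) -> PhotonTrace:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        try:
            df = pd.read_csv(fh, sep="\t")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"{path.name}: unparseable trace table: {exc}") from exc
    required = {"time_ms", "donor", "acceptor"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path.name}: missing columns "
                         f"{sorted(required - set(df.columns))}")
    mol_id = meta.get("molecule_id", path.stem)
    bin_width = float(meta.get("bin_width_ms", 0) or 0)
    if bin_width <= 0:
        t = df["time_ms"].to_numpy()
        bin_width = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return PhotonTrace(
        molecule_id=mol_id,
        bin_width=bin_width,
        donor=df["donor"].to_numpy(),
        acceptor=df["acceptor"].to_numpy(),
        acceptor_direct=(df["acceptor_direct"].to_numpy()
                         if "acceptor_direct" in df.columns else None),
        provenance=meta.get("provenance", ""),
    )


def write_traces(traces, out_dir, condition: str = "") -> Path:
    """Write one TSV per trace plus a ``manifest.tsv``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trace in traces:
        fname = f"{trace.molecule_id}.tsv"
        write_trace(trace, out_dir / fname)
        rows.append({"molecule_id": trace.molecule_id, "file": fname,
                     "condition": condition})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows, columns=["molecule_id", "file", "condition"]).to_csv(
        manifest, sep="\t", index=False)
    return manifest


def read_manifest(manifest_path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path, sep="\t")
    if "molecule_id" not in df.columns or "file" not in df.columns:
        raise ParseError(f"{manifest_path}: manifest needs molecule_id and file columns")
    return df


def read_traces(path) -> list[PhotonTrace]:
    """Read all traces below ``path``.

    ``path`` may be a manifest file, a directory containing ``manifest.tsv``,
    or a directory of ``*.tsv`` trace files.  Molecule ids must be unique.
    """
    path = Path(path)
    if path.is_dir():
        manifest = path / "manifest.tsv"
        if manifest.exists():
            df = read_manifest(manifest)
            files = [path / f for f in df["file"]]
        else:
            files = sorted(p for p in path.glob("*.tsv"))
    elif path.name.endswith("manifest.tsv") or path.suffix == ".manifest":
        df = read_manifest(path)
        files = [path.parent / f for f in df["file"]]
    else:
        files = [path]
    traces = [read_trace(f) for f in files]
    ids = [t.molecule_id for t in traces]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"duplicate molecule ids: {dup}")
    return traces


def write_results(state_model, landscape, out_dir, histogram=None,
                  distance_table=None) -> dict[str, Path]:
    """Write analysis products as TSV tables with deterministic column order.

    Parameters
    ----------
    state_model : fretscape.states.StateModel or None
    landscape : fretscape.landscape.EnergyLandscape or None
    histogram : optional (bin_center, fraction) arrays
    distance_table : optional DataFrame from fretscape.landscape.distance_table
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    def _write(name, df):
        p = out_dir / name
        df.to_csv(p, sep="\t", index=False)
        written[name] = p

    if state_model is not None:
        n = state_model.n_states
        bins_per_state = np.zeros(n, dtype=int)
        for a in state_model.assignments.values():
            bins_per_state += np.bincount(a, minlength=n)
        _write("state_table.tsv", pd.DataFrame({
            "state": np.arange(n),
            "efficiency": np.round(state_model.state_efficiencies, 6),
            "fwhm": np.round(state_model.state_halfwidths, 6),
            "occupancy": np.round(state_model.occupancies, 6),
            "n_bins": bins_per_state,
        }))
    else:
        _write("state_table.tsv", pd.DataFrame(
            columns=["state", "efficiency", "fwhm", "occupancy", "n_bins"]))

    if landscape is not None:
        k = landscape.transition_counts.shape[0]
        idx = [f"s{i}" for i in range(k)]
        for name, mat in (("transition_counts.tsv", landscape.transition_counts),
                          ("transition_probs.tsv", landscape.transition_probs),
                          ("Ea.tsv", landscape.Ea),
                          ("Ea_symmetrized.tsv", landscape.Ea_symmetrized)):
            df = pd.DataFrame(mat, columns=idx)
            df.insert(0, "from_state", idx)
            _write(name, df)
        _write("delta_G.tsv", pd.DataFrame({
            "state": np.arange(len(landscape.delta_G)),
            "delta_G_kBT": np.round(landscape.delta_G, 6),
        }))

    if histogram is not None:
        centers, frac = histogram
        _write("histogram.tsv", pd.DataFrame(
            {"efficiency": np.round(centers, 6), "fraction": frac}))
    if distance_table is not None:
        _write("distance_table.tsv", distance_table)
    return written
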