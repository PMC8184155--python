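"""Tabular input/output: spike tables (CSV + HDF5 twin), trial manifests and
per-trial result tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lif_core import SpikeRecord

__all__ = [
    "spikes_to_frame",
    "write_spikes_csv",
    "write_spikes_hdf5",
    "read_spikes_csv",
    "timelines_to_frame",
    "outcomes_to_frame",
    "trial_results_to_frame",
    "trial_manifest_to_frame",
]

_SPIKE_COLUMNS = ["trial", "population", "neuron", "time_ms"]


def spikes_to_frame(trials) -> pd.DataFrame:
    """Long-format spike table from a list of RingTrial."""
    parts = []
    for i, tr in enumerate(trials):
        for pop, rec in (("pyr", tr.spikes_pyr), ("int", tr.spikes_int)):
            parts.append(pd.DataFrame({
                "trial": i, "population": pop,
                "neuron": rec.neuron, "time_ms": rec.time_ms}))
    if not parts:
        return pd.DataFrame(columns=_SPIKE_COLUMNS)
    return pd.concat(parts, ignore_index=True)[_SPIKE_COLUMNS]


def write_spikes_csv(trials, path) -> None:
    spikes_to_frame(trials).to_csv(path, index=False)


def write_spikes_hdf5(trials, path) -> None:
    """Binary twin of the CSV spike table (one dataset per column)."""
    import h5py

    df = spikes_to_frame(trials)
    with h5py.File(path, "w") as f:
        f.create_dataset("trial", data=df["trial"].to_numpy(np.int64))
        f.create_dataset("population",
                         data=df["population"].to_numpy("S8"))
        f.create_dataset("neuron", data=df["neuron"].to_numpy(np.int64))
        f.create_dataset("time_ms", data=df["time_ms"].to_numpy(float))


def read_spikes_csv(path, population: str = "pyr", trial: int = 0,
                    n_neurons: int | None = None) -> SpikeRecord:
    """Load one trial/population back into a SpikeRecord."""
    df = pd.read_csv(path)
    sub = df[(df["population"] == population) & (df["trial"] == trial)]
    n = n_neurons if n_neurons is not None else int(df["neuron"].max()) + 1
    return SpikeRecord(sub["neuron"].to_numpy(np.int64),
                       sub["time_ms"].to_numpy(float), n)


def timelines_to_frame(timelines) -> pd.DataFrame:
    """Long-format decoded-state table: trial, t_ms, best_state and one
    similarity-index column per stimulus."""
    parts = []
    for i, tl in enumerate(timelines):
        cols = {"trial": i, "t_ms": tl.t_ms,
                "best_state": [tl.labels[s] if s >= 0 else "none"
                               for s in tl.state]}
        for j, lab in enumerate(tl.labels):
            cols[f"index_{lab}"] = tl.indices[:, j]
        parts.append(pd.DataFrame(cols))
    return pd.concat(parts, ignore_index=True)


def outcomes_to_frame(outcomes) -> pd.DataFrame:
    """Per-trial outcome-classification table."""
    return pd.DataFrame([
        {"trial": i, "outcome_class": o.outcome,
         "t_cue_onset": o.t_cue_onset, "t_collapse": o.t_collapse,
         "t_jump": o.t_jump}
        for i, o in enumerate(outcomes)])


def trial_results_to_frame(results) -> pd.DataFrame:
    """Per-trial DPX result table."""
    rows = []
    for i, r in enumerate(results):
        rows.append({
            "trial": i, "type": r.trial_type, "choice": r.choice,
            "correct": r.correct, "rt_ms": r.rt_ms,
            "probe_repr_onset_ms": r.probe_repr_onset_ms,
            "memory_outcome": r.memory_outcome.outcome,
            "perception_outcome": r.perception_outcome.outcome,
        })
    return pd.DataFrame(rows)


def trial_manifest_to_frame(trial_specs) -> pd.DataFrame:
    """Exportable manifest of a DPX trial sequence."""
    rows = []
    for i, t in enumerate(trial_specs):
        seed = t.seed
        if isinstance(seed, np.random.SeedSequence):
            seed = repr(seed.entropy)
        rows.append({"trial": i, "type": t.trial_type, "cue": t.cue,
                     "probe": t.probe,
                     "distractor_theta": t.distractor_theta, "seed": seed})
    return pd.DataFrame(rows)
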