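"""Parameter sweeps and behavioral summaries.

Reproduces the model's main computational experiments:

- regime maps: fractions of maintain / jump / collapse / epileptic outcomes
  of the cue-probe protocol over the (NMDA_g,pyr x NMDA_g,int x AMPA_g,Aff)
  grid;
- inertia thresholds: the smallest afferent conductance at which the probe
  jumps an established bump, per ring preset;
- NMDA-conductance manipulations of the DPX agent (percent changes of
  pyramidal and/or interneuron conductances, in one or both networks), with
  error-rate and reaction-time summaries per trial type;
- tuning-curve width summaries across conditions.

All sweeps derive per-condition seeds from one master seed and are exactly
reproducible; results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._rng import child_sequences
from .decoding import (classify_trial_outcome, decode_state_timeline,
                       estimate_tuning_curve)
from .decision_agent import AgentConfig, TrialResult, run_dpx_block
from .ring_network import RingConfig, StimulusSpec, run_ring_batch
from .task_protocols import (ProtocolSpec, cue_probe_protocol, dpx_protocol,
                             sample_trial_sequence)

__all__ = [
    "SweepGrid",
    "ManipulationSpec",
    "OUTCOME_CLASSES",
    "run_cue_probe_block",
    "run_regime_sweep",
    "find_inertia_threshold",
    "run_manipulation_experiment",
    "tuning_width_summary",
    "summarize_behavior",
]

OUTCOME_CLASSES = ("maintain", "jump", "collapse", "epileptic")


@dataclass(frozen=True)
class SweepGrid:
    """Cartesian sweep over NMDA conductances and afferent conductance (uS).

    Defaults cover the standard exploration range: pyramidal 0.30-0.40 and
    interneuron 0.25-0.35 in 0.01 steps, afferent 0.5-1.5 in 0.1 steps.
    """

    nmda_pyr: tuple = tuple(np.round(np.arange(0.30, 0.401, 0.01), 3))
    nmda_int: tuple = tuple(np.round(np.arange(0.25, 0.351, 0.01), 3))
    ampa_aff: tuple = tuple(np.round(np.arange(0.5, 1.51, 0.1), 2))
    trials_per_cell: int = 20


@dataclass(frozen=True)
class ManipulationSpec:
    """A percent NMDA-conductance manipulation of the DPX agent.

    target: which cell type's conductance is scaled; scope: which network(s).
    percent = -8 means a multiplier of 0.92 on the baseline conductance.
    """

    target: str   # "pyramidal" | "interneuron" | "both"
    scope: str = "both"   # "both" | "perception" | "memory"
    percent: float = 0.0

    def apply(self, agent: AgentConfig) -> AgentConfig:
        f = 1.0 + self.percent / 100.0
        pf = f if self.target in ("pyramidal", "both") else 1.0
        inf = f if self.target in ("interneuron", "both") else 1.0

        def scale(ring: RingConfig) -> RingConfig:
            return ring.scale_nmda(pyr_factor=pf, int_factor=inf)

        per = scale(agent.perception) if self.scope in ("both", "perception") \
            else agent.perception
        mem = scale(agent.memory) if self.scope in ("both", "memory") \
            else agent.memory
        return replace(agent, perception=per, memory=mem)


def run_cue_probe_block(config: RingConfig, g_aff: float, n_trials: int,
                        seed, protocol: ProtocolSpec | None = None,
                        trials=None) -> list:
    """Run seeded cue-probe trials of one condition and classify outcomes.

    The tuning curve is fitted from the last 100 ms of the cue period of
    this block's own trials.  Returns a list of TrialOutcome.
    """
    if protocol is None:
        protocol = cue_probe_protocol()
    if trials is None:
        stims = protocol.stimuli("cue", "probe", g_aff)
        trials = run_ring_batch(config, stims, protocol.duration_ms,
                                child_sequences(seed, n_trials))
    return classify_block(trials, protocol)


def classify_block(trials, protocol: ProtocolSpec) -> list:
    """Classify already-simulated cue-probe trials (shared tuning fit)."""
    recs = [t.spikes_pyr for t in trials]
    t1 = protocol.cue_window[1]
    try:
        tuning = estimate_tuning_curve(recs, t1 - 100.0, t1)
    except ValueError:
        # no cue-period activity anywhere: every trial failed to represent
        return [classify_trial_outcome(
            _silent_timeline(protocol, r), "cue", "probe",
            protocol.cue_window, protocol.probe_window) for r in recs]
    out = []
    for r in recs:
        tl = decode_state_timeline(r, tuning, protocol.labels,
                                   protocol.duration_ms)
        out.append(classify_trial_outcome(tl, "cue", "probe",
                                          protocol.cue_window,
                                          protocol.probe_window))
    return out


def _silent_timeline(protocol, record):
    from .decoding import StateTimeline
    T = int(protocol.duration_ms)
    names = list(protocol.labels)
    rates = record.binned_counts(protocol.duration_ms, 1.0).mean(axis=1) * 1000.0
    return StateTimeline(t_ms=np.arange(1, T + 1, dtype=float), labels=names,
                         indices=np.ones((T, len(names))),
                         state=np.full(T, -1), pop_rate_hz=rates)


def run_regime_sweep(grid: SweepGrid, base: RingConfig, seed,
                     protocol: ProtocolSpec | None = None,
                     progress: bool = False) -> pd.DataFrame:
    """Outcome fractions per (NMDA_g,pyr, NMDA_g,int, AMPA_g,Aff) cell.

    Per-condition seeds derive from the master seed and the condition index,
    so any sub-grid reproduces the full sweep's values.
    """
    if protocol is None:
        protocol = cue_probe_protocol()
    rows = []
    conds = [(gp, gi, ga) for gp in grid.nmda_pyr for gi in grid.nmda_int
             for ga in grid.ampa_aff]
    for ci, (gp, gi, ga) in enumerate(conds):
        cfg = base.with_nmda(g_pyr=gp, g_int=gi)
        ss = np.random.SeedSequence((seed, ci))
        outcomes = run_cue_probe_block(cfg, ga, grid.trials_per_cell, ss,
                                       protocol)
        counts = {c: sum(o.outcome == c for o in outcomes)
                  for c in OUTCOME_CLASSES}
        n = len(outcomes)
        row = {"nmda_pyr": gp, "nmda_int": gi, "ampa_aff": ga, "n_trials": n}
        row.update({f"frac_{c}": counts[c] / n for c in OUTCOME_CLASSES})
        rows.append(row)
        if progress:
            print(f"[{ci + 1}/{len(conds)}] pyr={gp} int={gi} aff={ga}: "
                  + " ".join(f"{c}={counts[c]}" for c in OUTCOME_CLASSES))
    return pd.DataFrame(rows)


def find_inertia_threshold(config: RingConfig, seed,
                           aff_grid=None, n_trials: int = 5,
                           protocol: ProtocolSpec | None = None) -> float | None:
    """Smallest afferent conductance at which jump is the majority outcome.

    Runs the cue-probe protocol at each grid conductance (default 0.5-1.5 uS
    in 0.1 steps) with `n_trials` seeded trials per point; all conditions
    are simulated in a single batch.  Returns None if no grid point reaches
    a jump majority.
    """
    if protocol is None:
        protocol = cue_probe_protocol()
    if aff_grid is None:
        aff_grid = np.round(np.arange(0.5, 1.51, 0.1), 2)
    seeds = child_sequences(seed, len(aff_grid) * n_trials)
    stim_lists, cond = [], []
    for i, ga in enumerate(aff_grid):
        stims = protocol.stimuli("cue", "probe", float(ga))
        stim_lists.extend([stims] * n_trials)
        cond.extend([i] * n_trials)
    trials = run_ring_batch(config, stim_lists, protocol.duration_ms, seeds)
    cond = np.asarray(cond)
    for i, ga in enumerate(aff_grid):
        sub = [trials[j] for j in np.nonzero(cond == i)[0]]
        outcomes = classify_block(sub, protocol)
        n_jump = sum(o.outcome == "jump" for o in outcomes)
        if n_jump > len(outcomes) / 2:
            return float(ga)
    return None


def run_manipulation_experiment(agent: AgentConfig, manip: ManipulationSpec,
                                n_trials: int, seed,
                                protocol: ProtocolSpec | None = None,
                                trial_sequence=None) -> list[TrialResult]:
    """Run a DPX block under a percent NMDA manipulation.

    With percent = 0 this reproduces the baseline agent exactly (same
    seeds).  The trial sequence (types, distractor sides, per-trial seeds)
    is derived from the master seed, so manipulated and baseline blocks see
    identical trial sequences.
    """
    if protocol is None:
        protocol = dpx_protocol()
    if trial_sequence is None:
        trial_sequence = sample_trial_sequence(n_trials, seed)
    return run_dpx_block(manip.apply(agent), trial_sequence, protocol)


def tuning_width_summary(conditions: dict, seed, n_trials: int = 5,
                         g_aff: float = 1.0,
                         cue_window: tuple = (500.0, 1000.0),
                         theta_cue: float = np.pi / 2) -> pd.DataFrame:
    """Tuning-curve shape metrics (FWHM, baseline offset) per condition.

    `conditions` maps a name to a RingConfig; each condition runs `n_trials`
    cue-only simulations and fits its own tuning curve from the last 100 ms
    of the cue.
    """
    rows = []
    dur = cue_window[1] + 50.0
    for ci, (name, cfg) in enumerate(conditions.items()):
        ss = np.random.SeedSequence((_as_int(seed), ci))
        stim = StimulusSpec(theta_cue, cue_window[0], cue_window[1], g_aff)
        trials = run_ring_batch(cfg, [stim], dur, child_sequences(ss, n_trials))
        tuning = estimate_tuning_curve([t.spikes_pyr for t in trials],
                                       cue_window[1] - 100.0, cue_window[1])
        rows.append({"condition": name, "fwhm_rad": tuning.fwhm_rad(),
                     "baseline": tuning.baseline()})
    return pd.DataFrame(rows)


def _as_int(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.entropy if np.isscalar(seed.entropy) else seed.entropy[0])
    return int(seed)


def summarize_behavior(results: list[TrialResult],
                       ci_alpha: float = 0.05) -> pd.DataFrame:
    """Error rates (with binomial confidence intervals) and RT quantiles per
    trial type.

    The returned frame's ``attrs["rt_bifurcation_ms"]`` holds the absolute
    difference between the median RT of X-probe trials and of Y-probe
    trials (the reaction-time bifurcation statistic).  Omissions (no probe
    representation, hence no response) count as errors and contribute no RT.
    """
    if not results:
        raise ValueError("no trial results to summarize")
    rows = []
    for tt in ("AX", "AY", "BX", "BY"):
        sub = [r for r in results if r.trial_type == tt]
        if not sub:
            continue
        n = len(sub)
        errors = sum(not r.correct for r in sub)
        lo, hi = _binom_ci(errors, n, ci_alpha)
        rts = np.asarray([r.rt_ms for r in sub if r.rt_ms is not None])
        rows.append({
            "trial_type": tt, "n": n, "n_errors": errors,
            "error_rate": errors / n, "err_ci_low": lo, "err_ci_high": hi,
            "rt_median_ms": float(np.median(rts)) if rts.size else np.nan,
            "rt_q25_ms": float(np.quantile(rts, 0.25)) if rts.size else np.nan,
            "rt_q75_ms": float(np.quantile(rts, 0.75)) if rts.size else np.nan,
            "n_omissions": sum(r.choice is None for r in sub),
        })
    df = pd.DataFrame(rows)
    x_rts = np.asarray([r.rt_ms for r in results
                        if r.trial_type.endswith("X") and r.rt_ms is not None])
    y_rts = np.asarray([r.rt_ms for r in results
                        if r.trial_type.endswith("Y") and r.rt_ms is not None])
    if x_rts.size and y_rts.size:
        df.attrs["rt_bifurcation_ms"] = float(
            abs(np.median(x_rts) - np.median(y_rts)))
    else:
        df.attrs["rt_bifurcation_ms"] = np.nan
    return df


def _binom_ci(k: int, n: int, alpha: float) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    from scipy.stats import norm
    z = norm.ppf(1.0 - alpha / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)
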