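"""The two-ring DPX agent and its decision process.

Architecture: stimuli drive the pyramidal cells of a low-inertia "perception"
ring (afferent AMPA conductance 1.0 uS, above its inertia); perception
pyramidal spikes project weakly (localized weights summing to 0.05) into the
afferent channel of a high-inertia "memory" ring.  Both rings are decoded
per ms into representational similarity indices; represented stimuli feed
two leaky response accumulators (first-order kinetics, 80-ms mean lifetime):

    memory-A   -> left  accumulator, weight 1.00
    perception-X -> left  accumulator, weight 0.25
    memory-B   -> right accumulator, weight 1.25
    perception-Y -> right accumulator, weight 2.00

(the non-target weights are larger because B and Y must override the
prepotent target response).  A softmax with temperature tau = 15 converts
the accumulators to P(left); once the perception ring represents the probe,
noisy collapsing decision boundaries are started, and the first boundary to
cross P(left) fixes the choice and the reaction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import child_sequences
from .decoding import (INDEX_CUTOFF, StateTimeline, TrialOutcome, TuningCurve,
                       classify_trial_outcome, decode_state_timeline,
                       estimate_tuning_curve)
from .ring_network import (FeedForwardDrive, RingConfig,
                           feed_forward_coupling, memory_preset,
                           perception_preset, run_ring_batch)
from .task_protocols import ProtocolSpec, TrialSpec, correct_action, dpx_protocol

__all__ = [
    "AgentConfig",
    "DecisionBoundary",
    "TrialResult",
    "feed_forward_coupling",
    "neurotypical_agent",
    "accumulate_evidence",
    "softmax_probability",
    "sample_boundaries",
    "decide",
    "run_dpx_trial",
    "run_dpx_block",
    "simulate_dpx_spikes",
]

DEFAULT_EVIDENCE_WEIGHTS = {
    ("memory", "A"): ("left", 1.00),
    ("perception", "X"): ("left", 0.25),
    ("memory", "B"): ("right", 1.25),
    ("perception", "Y"): ("right", 2.00),
}


@dataclass(frozen=True)
class AgentConfig:
    """Parameters of the two-ring DPX agent."""

    perception: RingConfig
    memory: RingConfig
    ff_weight_sum: float = 0.05   # summed perception->memory weight per cell
    aff_g: float = 1.0            # uS, stimulus afferent conductance
    accumulator_tau: float = 80.0  # ms, response-accumulator mean lifetime
    softmax_tau: float = 15.0
    evidence_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_EVIDENCE_WEIGHTS))
    boundary_start_mean: float = 1.15
    boundary_start_sd: float = 0.075
    collapse_ms: float = 500.0    # default time for a boundary to reach 0
    slope_mult_mean: float = 1.0
    slope_mult_sd: float = 0.45


def neurotypical_agent(**overrides) -> AgentConfig:
    """The default agent: perception ring 0.37/0.30 uS, memory ring
    0.37/0.35 uS (pyramidal/interneuron NMDA conductances)."""
    return AgentConfig(perception=perception_preset(),
                       memory=memory_preset(), **overrides)


# ---------------------------------------------------------------------------
# evidence accumulation and action probabilities

def accumulate_evidence(timelines: dict, weights: dict, tau: float = 80.0,
                        cutoff: float = INDEX_CUTOFF) -> np.ndarray:
    """Integrate per-ms representational evidence into the two accumulators.

    For each (network, stimulus) in `weights` whose similarity index is
    below the cutoff at time t, (1 - index) * weight is added to the mapped
    accumulator; both accumulators decay per ms by exp(-1/tau).

    Returns an (T, 2) array with columns (s_left, s_right).
    """
    T = min(tl.t_ms.size for tl in timelines.values())
    inflow = np.zeros((T, 2))
    col = {"left": 0, "right": 1}
    for (net, stim), (action, w) in weights.items():
        tl = timelines[net]
        if stim not in tl.labels:
            continue
        idx = tl.indices[:T, tl.labels.index(stim)]
        gated = np.where(idx < cutoff, (1.0 - idx) * w, 0.0)
        inflow[:, col[action]] += gated
    decay = math.exp(-1.0 / tau)
    acc = np.zeros((T, 2))
    prev = np.zeros(2)
    for t in range(T):
        prev = prev * decay + inflow[t]
        acc[t] = prev
    return acc


def softmax_probability(acc: np.ndarray, tau: float = 15.0) -> np.ndarray:
    """P(left) from accumulators (..., 2); probabilities sum to 1."""
    acc = np.asarray(acc, float)
    d = (acc[..., 0] - acc[..., 1]) / tau
    return 1.0 / (1.0 + np.exp(-d))


# ---------------------------------------------------------------------------
# collapsing boundaries

@dataclass(frozen=True)
class DecisionBoundary:
    """A linear collapsing threshold on the P(left) axis.

    The left boundary starts above 1 and collapses toward 0; the right
    boundary is its mirror (1 - start', rising).  `value(t)` gives the
    threshold t ms after the boundary clock starts.
    """

    side: str      # "left" | "right"
    start: float   # intercept on the P(left) axis
    slope: float   # per ms; negative for left, positive for right

    def value(self, t: float) -> float:
        return self.start + self.slope * t

    def crossed(self, t: float, p_left: float) -> bool:
        return (self.value(t) <= p_left if self.side == "left"
                else self.value(t) >= p_left)


def sample_boundaries(rng: np.random.Generator,
                      agent: AgentConfig) -> tuple[DecisionBoundary, DecisionBoundary]:
    """Draw one (left, right) boundary pair.

    Left: start ~ N(1.15, 0.075); slope reaches 0 at `collapse_ms` with a
    multiplicative N(1.0, 0.45) speed factor (resampled until positive so
    every boundary eventually terminates).  Right: an independent mirror on
    the P(left) axis, starting at 1 - start' (below 0) and rising.
    """
    def speed():
        m = rng.normal(agent.slope_mult_mean, agent.slope_mult_sd)
        while m <= 0:
            m = rng.normal(agent.slope_mult_mean, agent.slope_mult_sd)
        return m

    a_l = rng.normal(agent.boundary_start_mean, agent.boundary_start_sd)
    left = DecisionBoundary("left", a_l, -(a_l / agent.collapse_ms) * speed())
    a_r = rng.normal(agent.boundary_start_mean, agent.boundary_start_sd)
    right = DecisionBoundary("right", 1.0 - a_r,
                             (a_r / agent.collapse_ms) * speed())
    return left, right


def decide(p_left: np.ndarray, onset_ms: float, trial_end_ms: float,
           rng: np.random.Generator, agent: AgentConfig,
           max_epochs: int = 1000) -> tuple[str, float]:
    """Run the boundary process on a per-ms P(left) trajectory.

    The boundary clock starts at `onset_ms` (probe-representation onset);
    crossings are evaluated every ms with linear interpolation inside the
    crossing ms.  If no boundary crosses by trial end, boundaries are
    resampled with a restarted clock and P(left) held at its final value
    until a crossing occurs.

    Returns (choice, crossing time in ms on the trial clock).
    """
    T = p_left.size  # p_left[t-1] is the value at t ms
    left, right = sample_boundaries(rng, agent)
    clock0 = onset_ms
    t = int(math.ceil(onset_ms))
    epoch_end = trial_end_ms
    for _ in range(max_epochs):
        while t <= epoch_end:
            p_now = p_left[min(t, T) - 1]
            tb = t - clock0
            cl = left.crossed(tb, p_now)
            cr = right.crossed(tb, p_now)
            if cl or cr:
                p_prev = p_left[min(t, T) - 2] if t >= 2 else p_now
                tau_l = _crossing_fraction(left, tb, p_prev, p_now) if cl else None
                tau_r = _crossing_fraction(right, tb, p_prev, p_now) if cr else None
                if cl and cr:
                    over_l = p_now - left.value(tb)
                    over_r = right.value(tb) - p_now
                    if not math.isclose(over_l, over_r, abs_tol=1e-12):
                        side = "left" if over_l > over_r else "right"
                    else:
                        side = "left" if tau_l <= tau_r else "right"
                else:
                    side = "left" if cl else "right"
                tau = tau_l if side == "left" else tau_r
                return side, t - 1 + tau
            t += 1
        left, right = sample_boundaries(rng, agent)
        clock0 = epoch_end
        epoch_end = epoch_end + trial_end_ms  # extended clock, P held
    raise RuntimeError("decision did not terminate")


def _crossing_fraction(b: DecisionBoundary, tb: float, p_prev: float,
                       p_now: float) -> float:
    """Fraction of the crossing ms at which boundary and P(left) met."""
    g_prev = (p_prev - b.value(tb - 1.0)) * (1 if b.side == "left" else -1)
    g_now = (p_now - b.value(tb)) * (1 if b.side == "left" else -1)
    if g_prev >= 0.0:       # already crossed at the previous sample
        return 0.0
    return min(1.0, -g_prev / (g_now - g_prev))


# ---------------------------------------------------------------------------
# full trials

@dataclass
class TrialResult:
    """Outcome of one DPX trial."""

    trial_type: str
    choice: str | None      # None = omission (probe never represented)
    rt_ms: float | None     # relative to probe stimulus onset
    correct: bool
    probe_repr_onset_ms: float | None
    memory_outcome: TrialOutcome
    perception_outcome: TrialOutcome
    p_left: np.ndarray | None = None


def simulate_dpx_spikes(agent: AgentConfig, trials: list[TrialSpec],
                        protocol: ProtocolSpec):
    """Simulate both rings for a DPX block (batched across trials).

    Stimuli drive the perception ring; its pyramidal spikes feed the memory
    ring through the localized NMDA projection.  Returns (perception trials,
    memory trials) as RingTrial lists.
    """
    B = len(trials)
    dur = protocol.duration_ms
    seed_triplets = [child_sequences(tr.seed, 3) for tr in trials]
    stim_lists = [protocol.stimuli(tr.cue, tr.probe, agent.aff_g,
                                   tr.distractor_theta) for tr in trials]
    p_trials = run_ring_batch(agent.perception, stim_lists, dur,
                              [s[0] for s in seed_triplets])
    n_steps = int(round(dur / 0.05))
    ff = FeedForwardDrive([t.spikes_pyr for t in p_trials], agent.memory,
                          agent.ff_weight_sum, n_steps)
    m_trials = run_ring_batch(agent.memory, [[]] * B, dur,
                              [s[1] for s in seed_triplets],
                              external_drive=ff)
    return p_trials, m_trials


def run_dpx_block(agent: AgentConfig, trials: list[TrialSpec],
                  protocol: ProtocolSpec | None = None,
                  keep_traces: bool = False,
                  spikes=None) -> list[TrialResult]:
    """Simulate a block of DPX trials (batched across trials).

    Both rings are simulated for every trial; tuning curves for each ring
    are fitted from the last 100 ms of the cue period of this block's own
    trials; timelines, evidence, and the boundary process then produce the
    choice and reaction time.

    `spikes` may pass previously simulated (perception, memory) RingTrial
    lists from `simulate_dpx_spikes`, e.g. to re-run only the decision layer
    under different evidence weights.
    """
    if protocol is None:
        protocol = dpx_protocol()
    dur = protocol.duration_ms
    seed_triplets = [child_sequences(tr.seed, 3) for tr in trials]
    if spikes is None:
        p_trials, m_trials = simulate_dpx_spikes(agent, trials, protocol)
    else:
        p_trials, m_trials = spikes

    cue_t0, cue_t1 = protocol.cue_window[1] - 100.0, protocol.cue_window[1]
    tunings = {}
    for name, recs in (("perception", p_trials), ("memory", m_trials)):
        try:
            tunings[name] = estimate_tuning_curve(
                [t.spikes_pyr for t in recs], cue_t0, cue_t1)
        except ValueError:
            tunings[name] = None

    results = []
    probe_on = protocol.probe_window[0]
    for b, tr in enumerate(trials):
        tls = {}
        for name, rec in (("perception", p_trials[b].spikes_pyr),
                          ("memory", m_trials[b].spikes_pyr)):
            tls[name] = _timeline_or_silent(rec, tunings[name],
                                            protocol.labels, dur)
        acc = accumulate_evidence(tls, agent.evidence_weights,
                                  tau=agent.accumulator_tau)
        p_left = softmax_probability(acc, agent.softmax_tau)
        onsets = [tls["perception"].onset_time(s, after=probe_on)
                  for s in ("X", "Y")]
        onsets = [o for o in onsets if o is not None]
        probe_onset = min(onsets) if onsets else None
        dec_rng = np.random.default_rng(seed_triplets[b][2])
        if probe_onset is None:
            choice, rt = None, None
        else:
            choice, t_cross = decide(p_left, probe_onset, dur, dec_rng, agent)
            rt = t_cross - probe_on
        mem_out = classify_trial_outcome(tls["memory"], tr.cue, tr.probe,
                                         protocol.cue_window,
                                         protocol.probe_window)
        per_out = classify_trial_outcome(tls["perception"], tr.cue, tr.probe,
                                         protocol.cue_window,
                                         protocol.probe_window)
        results.append(TrialResult(
            trial_type=tr.trial_type, choice=choice, rt_ms=rt,
            correct=(choice == correct_action(tr.trial_type)),
            probe_repr_onset_ms=probe_onset,
            memory_outcome=mem_out, perception_outcome=per_out,
            p_left=p_left if keep_traces else None))
    return results


def run_dpx_trial(agent: AgentConfig, trial: TrialSpec,
                  protocol: ProtocolSpec | None = None,
                  **kwargs) -> TrialResult:
    """Simulate one DPX trial (see `run_dpx_block`).

    Note: tuning curves are fitted from this single trial's cue period, so
    multi-trial blocks give more stable decoding.
    """
    return run_dpx_block(agent, [trial], protocol, **kwargs)[0]


def _timeline_or_silent(record, tuning: TuningCurve | None, labels: dict,
                        duration_ms: float) -> StateTimeline:
    if tuning is not None:
        return decode_state_timeline(record, tuning, labels, duration_ms)
    T = int(duration_ms)
    names = list(labels)
    return StateTimeline(t_ms=np.arange(1, T + 1, dtype=float), labels=names,
                         indices=np.ones((T, len(names))),
                         state=np.full(T, -1),
                         pop_rate_hz=np.zeros(T))
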