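"""Trial protocols: the simple cue-probe experiment and the DPX task.

Cue-probe: cue at pi/2 (500-1000 ms), probe at 3pi/2 (3000-3500 ms), trial
length 4000 ms; used to map maintain/jump/collapse/epileptic regimes.

DPX (dot pattern expectancy): cue A (0.3 pi) or B (0.7 pi) at 500-1500 ms, a
4000-ms interstimulus interval with a 250-ms distractor at 3500 ms (at 0 or
pi, unrelated to task stimuli), probe X (1.3 pi) or Y (1.7 pi) at 5500-6000
ms, then 600 ms of intertrial interval.  Only the A-cue -> X-probe pair
requires the target (left) response; AY, BX and BY require the non-target
(right) response.  The network state is fully reset between trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import child_sequences
from .ring_network import StimulusSpec

__all__ = [
    "DPX_DIRECTIONS",
    "TRIAL_TYPE_PROPORTIONS",
    "ProtocolSpec",
    "TrialSpec",
    "cue_probe_protocol",
    "dpx_protocol",
    "sample_trial_sequence",
    "correct_action",
]

DPX_DIRECTIONS = {
    "A": 0.3 * math.pi,
    "B": 0.7 * math.pi,
    "X": 1.3 * math.pi,
    "Y": 1.7 * math.pi,
}
DISTRACTOR_DIRECTIONS = (0.0, math.pi)
TRIAL_TYPE_PROPORTIONS = {"AX": 0.64, "AY": 0.16, "BX": 0.16, "BY": 0.04}


@dataclass(frozen=True)
class ProtocolSpec:
    """A timed stimulus schedule plus labels and response mapping."""

    duration_ms: float
    labels: dict              # stimulus label -> ring direction (radians)
    cue_window: tuple[float, float]
    probe_window: tuple[float, float]
    distractor_window: tuple[float, float] | None = None
    correct_actions: dict = field(default_factory=dict)  # trial type -> action
    n_trials_default: int = 100

    def stimuli(self, cue_label: str, probe_label: str, g_ampa_aff: float,
                distractor_theta: float | None = None,
                Fmax: float = 1.25, sigma: float = 0.4) -> list[StimulusSpec]:
        """Build the stimulus list of one trial (windows never overlap)."""
        out = [
            StimulusSpec(self.labels[cue_label], *self.cue_window, g_ampa_aff,
                         Fmax=Fmax, sigma=sigma),
            StimulusSpec(self.labels[probe_label], *self.probe_window,
                         g_ampa_aff, Fmax=Fmax, sigma=sigma),
        ]
        if self.distractor_window is not None and distractor_theta is not None:
            out.append(StimulusSpec(distractor_theta, *self.distractor_window,
                                    g_ampa_aff, Fmax=Fmax, sigma=sigma))
        return sorted(out, key=lambda s: s.onset)


def cue_probe_protocol(n_trials: int = 100) -> ProtocolSpec:
    """The simple two-stimulus protocol: 500 ms blank, 500 ms cue (pi/2),
    2000 ms interstimulus interval, 500 ms probe (3pi/2), 500 ms intertrial
    interval."""
    return ProtocolSpec(
        duration_ms=4000.0,
        labels={"cue": math.pi / 2, "probe": 3 * math.pi / 2},
        cue_window=(500.0, 1000.0),
        probe_window=(3000.0, 3500.0),
        n_trials_default=n_trials,
    )


def dpx_protocol(include_distractor: bool = True,
                 isi_ms: float = 4000.0) -> ProtocolSpec:
    """The DPX trial schedule.

    With the default 4000-ms ISI: blank 0-500, cue 500-1500, distractor
    3500-3750 (middle of the ISI, at 0 or pi), probe 5500-6000, then 600 ms
    ITI (trial length 6600 ms).  `isi_ms` scales the delay (the 250-ms
    distractor stays centred in it); `include_distractor=False` removes the
    distractor entirely.
    """
    cue_off = 1500.0
    probe_on = cue_off + isi_ms
    distract = None
    if include_distractor:
        # onset at the ISI midpoint (3500 ms for the default 4000-ms ISI)
        mid = cue_off + isi_ms / 2.0
        distract = (mid, mid + 250.0)
    return ProtocolSpec(
        duration_ms=probe_on + 500.0 + 600.0,
        labels=dict(DPX_DIRECTIONS),
        cue_window=(500.0, cue_off),
        probe_window=(probe_on, probe_on + 500.0),
        distractor_window=distract,
        correct_actions={"AX": "left", "AY": "right",
                         "BX": "right", "BY": "right"},
    )


@dataclass(frozen=True)
class TrialSpec:
    """One DPX trial: type, stimulus directions, distractor side, RNG seed."""

    trial_type: str          # "AX" | "AY" | "BX" | "BY"
    cue: str
    probe: str
    distractor_theta: float | None
    seed: object

    @property
    def correct(self) -> str:
        return correct_action(self.trial_type)


def correct_action(trial_type: str) -> str:
    """AX -> left (target); AY, BX, BY -> right (non-target)."""
    if trial_type == "AX":
        return "left"
    if trial_type in ("AY", "BX", "BY"):
        return "right"
    raise ValueError(f"unknown trial type: {trial_type!r}")


def sample_trial_sequence(n_trials: int, seed,
                          proportions: dict | None = None,
                          include_distractor: bool = True) -> list[TrialSpec]:
    """Seeded random DPX trial sequence with the stated type proportions
    (default 64% AX, 16% AY, 16% BX, 4% BY) and per-trial distractor side
    sampled uniformly from {0, pi}."""
    props = dict(TRIAL_TYPE_PROPORTIONS if proportions is None else proportions)
    total = sum(props.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError("trial-type proportions must sum to 1")
    types = list(props)
    p = np.asarray([props[t] for t in types])
    children = child_sequences(seed, n_trials + 1)
    seq_rng = np.random.default_rng(children[0])
    trial_seeds = children[1:]
    out = []
    for i in range(n_trials):
        tt = types[int(seq_rng.choice(len(types), p=p))]
        theta_d = None
        if include_distractor:
            theta_d = DISTRACTOR_DIRECTIONS[int(seq_rng.integers(2))]
        out.append(TrialSpec(trial_type=tt, cue=tt[0], probe=tt[1],
                             distractor_theta=theta_d, seed=trial_seeds[i]))
    return out
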