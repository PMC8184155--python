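"""Decoding of ring-attractor spike rasters into represented stimuli.

The pipeline follows the population-vector / representational-similarity
approach:

1. A canonical tuning curve T is estimated from the last part of the cue
   period across trials: per-window firing-rate vectors are aligned to their
   population-vector direction, averaged, boxcar-smoothed (11 neurons,
   circular) and normalized to a maximum of 1.
2. The instantaneous activity bump A(x, t) is the tuning-curve-smoothed,
   max-normalized firing-rate profile over ring directions (trailing 25-ms
   windows evaluated every 1 ms).
3. The expected bump for a stimulus is the same construction applied to the
   tuning curve itself, shifted to the stimulus direction.
4. A similarity index per stimulus divides the sum-of-squares distance of the
   current bump from that stimulus' expected bump by the mean distance to the
   other stimuli; a stimulus is "represented" when its index < 0.75 and the
   representation onset requires 50 ms of continuous best description.

Decoding is a pure function of the spike record: the same raster always
yields the same timeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lif_core import SpikeRecord

__all__ = [
    "WINDOW_MS",
    "INDEX_CUTOFF",
    "ONSET_MS",
    "TuningCurve",
    "StateTimeline",
    "TrialOutcome",
    "population_vector",
    "estimate_tuning_curve",
    "expected_bump",
    "similarity_index",
    "decode_state_timeline",
    "classify_trial_outcome",
]

WINDOW_MS = 25.0      # sliding rate window
INDEX_CUTOFF = 0.75   # similarity index below which a stimulus is represented
ONSET_MS = 50         # continuous best-description required for onset
BOXCAR_WIDTH = 11     # tuning-curve smoothing (neurons)

EPILEPTIC_RATE_HZ = 30.0   # population-mean pyramidal rate threshold
EPILEPTIC_SPAN_MS = 500.0  # sustained duration with no represented stimulus


def population_vector(counts, directions) -> float:
    """Direction of the rate-weighted circular mean of spiking activity.

    Parameters
    ----------
    counts : per-neuron spike counts (or rates) in one window.
    directions : per-neuron radial directions (radians).

    Raises
    ------
    ValueError if the window contains no spikes (undefined direction).
    """
    counts = np.asarray(counts, float)
    if counts.sum() <= 0:
        raise ValueError("population vector undefined for an empty window")
    y = float(np.sum(counts * np.sin(directions)))
    x = float(np.sum(counts * np.cos(directions)))
    return float(np.arctan2(y, x) % (2.0 * np.pi))


def _circular_boxcar(values: np.ndarray, width: int = BOXCAR_WIDTH) -> np.ndarray:
    kern = np.zeros(values.size)
    half = width // 2
    kern[:width] = 1.0 / width
    kern = np.roll(kern, -half)
    return np.fft.irfft(np.fft.rfft(values) * np.fft.rfft(kern), n=values.size)


@dataclass(frozen=True)
class TuningCurve:
    """Canonical per-neuron activity profile aligned to the population-vector
    direction (index 0), normalized to max 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if not np.isclose(v.max(), 1.0):
            raise ValueError("tuning curve must be normalized to max 1")

    @property
    def n(self) -> int:
        return self.values.size

    def fwhm_rad(self) -> float:
        """Full width at half maximum, where "half" is midway between the
        curve's baseline (minimum) and its peak."""
        v = self.values
        n = v.size
        half = 0.5 * (1.0 + v.min())
        peak = int(np.argmax(v))
        c = np.roll(v, -peak)  # peak at index 0
        above = c >= half
        # walk right then left from the peak with linear interpolation
        right = 0
        while right < n - 1 and above[right + 1]:
            right += 1
        left = 0
        while left < n - 1 and above[-1 - left]:
            left += 1
        def interp(i_in, i_out, sign):
            if i_out >= n:
                return float(i_in)
            v_in, v_out = c[sign * i_in % n], c[sign * i_out % n]
            if v_in == v_out:
                return float(i_in)
            return i_in + (v_in - half) / (v_in - v_out)
        w = interp(right, right + 1, 1) + interp(left, left + 1, -1)
        return 2.0 * np.pi * w / n

    def baseline(self) -> float:
        return float(self.values.min())


def sliding_rates(record: SpikeRecord, duration_ms: float,
                  window_ms: float = WINDOW_MS) -> np.ndarray:
    """(T, n) firing rates (Hz) in trailing windows [t - window, t) for
    integer t = 1..duration."""
    binned = record.binned_counts(duration_ms, 1.0)
    T = binned.shape[0]
    cum = np.vstack([np.zeros((1, record.n_neurons), int), np.cumsum(binned, 0)])
    w = int(window_ms)
    lo = np.maximum(np.arange(1, T + 1) - w, 0)
    rates = (cum[1:T + 1] - cum[lo]) * (1000.0 / window_ms)
    return rates


def estimate_tuning_curve(records, t0: float, t1: float,
                          window_ms: float = WINDOW_MS,
                          smooth_width: int = BOXCAR_WIDTH) -> TuningCurve:
    """Fit the canonical tuning curve from cue-period spiking across trials.

    Sliding windows (1-ms steps) over [t0, t1) of each record are aligned to
    their population-vector direction and averaged; windows without spikes
    are skipped.

    Raises
    ------
    ValueError if no window in any record contains a spike.
    """
    if isinstance(records, SpikeRecord):
        records = [records]
    n = records[0].n_neurons
    directions = 2.0 * np.pi * np.arange(n) / n
    acc = np.zeros(n)
    n_windows = 0
    w = int(window_ms)
    for rec in records:
        binned = rec.binned_counts(t1, 1.0)[int(t0):]
        if binned.shape[0] < w:
            continue
        cum = np.vstack([np.zeros((1, n), int), np.cumsum(binned, 0)])
        for stop in range(w, binned.shape[0] + 1):
            c = cum[stop] - cum[stop - w]
            tot = c.sum()
            if tot == 0:
                continue
            phi = population_vector(c, directions)
            shift = int(round(phi * n / (2.0 * np.pi))) % n
            acc += np.roll(c, -shift)
            n_windows += 1
    if n_windows == 0:
        raise ValueError("no spikes in any tuning-curve window")
    curve = _circular_boxcar(acc / n_windows, smooth_width)
    curve = np.clip(curve, 0.0, None)
    return TuningCurve(curve / curve.max())


def _bump_from_profile(tuning: TuningCurve, profile: np.ndarray) -> np.ndarray:
    """A(x) = sum_k T(x - theta_k) p_k / sum_k T, for max-normalized p."""
    T_hat = np.fft.rfft(tuning.values)
    return np.fft.irfft(T_hat * np.fft.rfft(profile), n=tuning.n) / tuning.values.sum()


def expected_bump(tuning: TuningCurve, theta_stim: float) -> np.ndarray:
    """Template activity bump for a stimulus at direction `theta_stim`."""
    n = tuning.n
    shifted = np.roll(tuning.values[::-1], int(round(theta_stim * n / (2 * np.pi))) + 1)
    return _bump_from_profile(tuning, shifted)


def similarity_index(bump: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Per-stimulus similarity index of one activity bump.

    index_s = SSD(bump, template_s) / mean_{s' != s} SSD(bump, template_s');
    lower is better; < 0.75 counts as represented.  Requires >= 2 templates.
    """
    templates = np.atleast_2d(templates)
    S = templates.shape[0]
    if S < 2:
        raise ValueError("need at least two stimulus templates")
    ssd = ((bump[None, :] - templates) ** 2).sum(axis=1)
    other = (ssd.sum() - ssd) / (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(other > 0, ssd / np.where(other == 0, 1, other), 1.0)
    if np.all(ssd == 0):
        idx = np.ones(S)
    return idx


@dataclass
class StateTimeline:
    """Per-ms decoded representation of one trial.

    `indices` is (T, S); `state` holds the best-described stimulus index per
    ms (-1 when nothing is represented); `pop_rate_hz` is the population-mean
    firing rate in the same trailing windows.
    """

    t_ms: np.ndarray
    labels: list
    indices: np.ndarray
    state: np.ndarray
    pop_rate_hz: np.ndarray

    def represented(self, label) -> np.ndarray:
        """Boolean mask of ms bins where `label` is the represented state."""
        return self.state == self.labels.index(label)

    def onset_time(self, label, after: float = 0.0,
                   min_run_ms: int = ONSET_MS) -> float | None:
        """Start of the first >= min_run continuous run of `label` starting
        at/after `after` (ms); None if never."""
        mask = self.represented(label) & (self.t_ms >= after)
        run = _first_run(mask, min_run_ms)
        return float(self.t_ms[run]) if run is not None else None

    def loss_time(self, label, after: float,
                  min_run_ms: int = ONSET_MS) -> float | None:
        """Start of the first >= min_run continuous absence of `label` after
        time `after`; None if the label is held to the end."""
        mask = (~self.represented(label)) & (self.t_ms >= after)
        run = _first_run(mask, min_run_ms)
        return float(self.t_ms[run]) if run is not None else None


def _first_run(mask: np.ndarray, min_len: int) -> int | None:
    """Index of the first run of >= min_len consecutive True; None if absent."""
    if mask.size < min_len:
        return None
    x = mask.astype(np.int32)
    run = np.convolve(x, np.ones(min_len, dtype=np.int32), mode="valid")
    hits = np.nonzero(run == min_len)[0]
    return int(hits[0]) if hits.size else None


def decode_state_timeline(record: SpikeRecord, tuning: TuningCurve,
                          stim_directions: dict, duration_ms: float,
                          cutoff: float = INDEX_CUTOFF) -> StateTimeline:
    """Decode a spike record against a set of stimulus templates.

    `stim_directions` maps stimulus labels to ring directions (radians).
    """
    labels = list(stim_directions)
    templates = np.stack([expected_bump(tuning, stim_directions[lab])
                          for lab in labels])
    rates = sliding_rates(record, duration_ms)
    mx = rates.max(axis=1, keepdims=True)
    profile = np.where(mx > 0, rates / np.where(mx == 0, 1, mx), 0.0)
    bumps = np.fft.irfft(np.fft.rfft(profile, axis=1)
                         * np.fft.rfft(tuning.values), n=tuning.n,
                         axis=1) / tuning.values.sum()
    # SSD via the expansion |a-b|^2 = |a|^2 + |b|^2 - 2 a.b
    ssd = ((bumps ** 2).sum(1, keepdims=True)
           + (templates ** 2).sum(1)[None, :]
           - 2.0 * bumps @ templates.T)
    np.clip(ssd, 0.0, None, out=ssd)
    S = len(labels)
    other = (ssd.sum(1, keepdims=True) - ssd) / (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(other > 0, ssd / np.where(other == 0, 1, other), 1.0)
    idx[np.all(ssd == 0, axis=1)] = 1.0
    best = np.argmin(idx, axis=1)
    t = np.arange(1, rates.shape[0] + 1, dtype=float)
    state = np.where(idx[np.arange(t.size), best] < cutoff, best, -1)
    pop_rate = rates.mean(axis=1)
    return StateTimeline(t_ms=t, labels=labels, indices=idx, state=state,
                         pop_rate_hz=pop_rate)


@dataclass(frozen=True)
class TrialOutcome:
    """Outcome class of one cue-probe style trial.

    outcome is one of "maintain", "jump", "collapse", "epileptic";
    `t_collapse`/`t_jump` give the relevant transition times (ms) when the
    class involves one.
    """

    outcome: str
    t_cue_onset: float | None = None
    t_collapse: float | None = None
    t_jump: float | None = None


def classify_trial_outcome(timeline: StateTimeline, cue_label, probe_label,
                           cue_window: tuple[float, float],
                           probe_window: tuple[float, float],
                           epileptic_rate_hz: float = EPILEPTIC_RATE_HZ,
                           epileptic_span_ms: float = EPILEPTIC_SPAN_MS
                           ) -> TrialOutcome:
    """Classify one trial as maintain / jump / collapse / epileptic.

    Precedence: epileptic (sustained extreme population firing with no
    represented stimulus) dominates; a cue representation that never
    initiates before probe onset, or is lost before probe onset, is a
    collapse; a probe representation acquired during/after the probe is a
    jump; a cue representation held through the end of the probe window is a
    maintain; anything else counts as collapse.
    """
    probe_on, probe_off = probe_window
    # epileptic: population rate above threshold with nothing represented
    ep_mask = (timeline.pop_rate_hz > epileptic_rate_hz) & (timeline.state == -1)
    if _first_run(ep_mask, int(epileptic_span_ms)) is not None:
        return TrialOutcome("epileptic")

    cue_on = timeline.onset_time(cue_label, after=cue_window[0])
    if cue_on is None or cue_on >= probe_on:
        return TrialOutcome("collapse", t_collapse=cue_window[0])
    lost = timeline.loss_time(cue_label, after=cue_on)
    if lost is not None and lost < probe_on:
        return TrialOutcome("collapse", t_cue_onset=cue_on, t_collapse=lost)
    jump = timeline.onset_time(probe_label, after=probe_on)
    if jump is not None:
        return TrialOutcome("jump", t_cue_onset=cue_on, t_jump=jump)
    if lost is None or lost >= probe_off:
        return TrialOutcome("maintain", t_cue_onset=cue_on)
    return TrialOutcome("collapse", t_cue_onset=cue_on, t_collapse=lost)
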