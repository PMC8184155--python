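"""Decoder tests: population vectors, tuning-curve estimation, similarity
indices (with an independent sum-of-squares oracle) and outcome
classification on constructed timelines."""

import numpy as np
import pytest

from ringdpx.decoding import (INDEX_CUTOFF, StateTimeline, TrialOutcome,
                              TuningCurve, classify_trial_outcome,
                              decode_state_timeline, estimate_tuning_curve,
                              expected_bump, population_vector,
                              similarity_index)
from ringdpx.lif_core import SpikeRecord
from ringdpx.ring_network import ring_directions
from ringdpx.synthetic import (bump_rate_profile, sample_bump_raster,
                               sample_poisson_raster)


def _naive_similarity(bump, templates):
    """Independent oracle: literal sum-of-squares similarity indices."""
    S = len(templates)
    ssd = []
    for t in templates:
        acc = 0.0
        for a, b in zip(bump, t):
            acc += (a - b) ** 2
        ssd.append(acc)
    out = []
    for s in range(S):
        others = [ssd[j] for j in range(S) if j != s]
        mean_other = sum(others) / len(others)
        out.append(ssd[s] / mean_other if mean_other > 0 else 1.0)
    return np.asarray(out)


class TestPopulationVector:
    def test_single_active_neuron(self):
        n = 8
        counts = np.zeros(n)
        counts[2] = 5  # direction pi/2
        assert population_vector(counts, ring_directions(n)) == pytest.approx(
            np.pi / 2)

    def test_symmetric_pair_averages_to_zero(self):
        dirs = np.array([0.5, -0.5])
        assert population_vector([3.0, 3.0], dirs) == pytest.approx(0.0)

    def test_three_neuron_vector_sum(self):
        dirs = np.array([0.0, np.pi / 2, np.pi])
        # rates 1, 2, 1: x components cancel, only the pi/2 component remains
        assert population_vector([1.0, 2.0, 1.0], dirs) == pytest.approx(
            np.pi / 2)

    def test_empty_window_is_an_error(self):
        with pytest.raises(ValueError):
            population_vector(np.zeros(4), ring_directions(4))


class TestTuningCurve:
    def test_single_neuron_raster_gives_boxcar_plateau(self):
        n = 64
        # one neuron fires regularly: after alignment the raw profile is a
        # delta, and 11-point smoothing spreads it into a plateau of 11 bins
        rec = SpikeRecord(np.zeros(40, int), np.linspace(0.5, 99.5, 40), n)
        curve = estimate_tuning_curve(rec, 0.0, 100.0)
        assert curve.values.max() == pytest.approx(1.0)
        assert np.sum(curve.values > 0.5) == 11

    def test_normalized_to_unit_maximum(self, mini_trials):
        curve = estimate_tuning_curve([t.spikes_pyr for t in mini_trials],
                                      300.0, 400.0)
        assert curve.values.max() == pytest.approx(1.0)

    def test_recovers_generating_profile(self):
        n, n_trials = 128, 100
        rng_seeds = range(n_trials)
        center = np.pi  # any direction; alignment removes it
        rasters = [sample_bump_raster(n, center, 125.0, s, peak_hz=120.0,
                                      sigma=0.4, baseline_hz=0.0)
                   for s in rng_seeds]
        curve = estimate_tuning_curve(rasters, 0.0, 125.0)
        truth = bump_rate_profile(n, 0.0, 1.0, sigma=0.4)
        truth /= truth.max()
        rms = np.sqrt(np.mean((curve.values - truth) ** 2))
        assert rms < 0.05

    def test_no_spikes_is_an_error(self):
        rec = SpikeRecord([], [], 32)
        with pytest.raises(ValueError):
            estimate_tuning_curve(rec, 0.0, 100.0)

    def test_fwhm_of_analytic_profile(self):
        n = 512
        prof = bump_rate_profile(n, 0.0, 1.0, sigma=0.4)
        curve = TuningCurve(prof / prof.max())
        # half level (baseline ~ 0): cos width from exp(2pi(cos d - 1)/sigma) = 1/2
        half = 0.5 * (1.0 + prof.min())
        d_half = np.arccos(1.0 + 0.4 * np.log(half) / (2 * np.pi))
        assert curve.fwhm_rad() == pytest.approx(2 * d_half, rel=0.02)

    def test_fwhm_invariant_to_peak_position(self):
        n = 256
        prof = bump_rate_profile(n, 0.0, 1.0, sigma=0.4)
        a = TuningCurve(prof / prof.max()).fwhm_rad()
        rolled = np.roll(prof, 100)
        b = TuningCurve(rolled / rolled.max()).fwhm_rad()
        assert a == pytest.approx(b, rel=1e-6)


class TestExpectedBump:
    def _curve(self, n=64):
        prof = bump_rate_profile(n, 0.0, 1.0, sigma=0.4)
        return TuningCurve(prof / prof.max())

    def test_templates_are_circular_shifts(self):
        curve = self._curve()
        n = curve.n
        a = expected_bump(curve, np.pi / 2)
        b = expected_bump(curve, 3 * np.pi / 2)
        shift = int(round((np.pi) * n / (2 * np.pi)))
        assert np.allclose(a, np.roll(b, -shift), atol=1e-12)

    def test_flat_tuning_gives_flat_template(self):
        curve = TuningCurve(np.ones(32))
        t = expected_bump(curve, 1.0)
        assert np.allclose(t, t[0])

    def test_peak_at_stimulus_direction(self):
        curve = self._curve(128)
        for theta in (0.3 * np.pi, 1.3 * np.pi):
            t = expected_bump(curve, theta)
            peak = 2 * np.pi * np.argmax(t) / 128
            assert abs(np.angle(np.exp(1j * (peak - theta)))) < 0.1


class TestSimilarityIndex:
    def _templates(self, n=64):
        curve = TuningCurve(
            bump_rate_profile(n, 0.0, 1.0, 0.4)
            / bump_rate_profile(n, 0.0, 1.0, 0.4).max())
        thetas = [0.3 * np.pi, 0.7 * np.pi, 1.3 * np.pi, 1.7 * np.pi]
        return np.stack([expected_bump(curve, t) for t in thetas])

    def test_exact_match_is_represented(self):
        temps = self._templates()
        idx = similarity_index(temps[0], temps)
        assert idx[0] == pytest.approx(0.0, abs=1e-12)
        assert idx[0] < INDEX_CUTOFF
        assert np.all(idx[1:] > INDEX_CUTOFF)

    def test_equidistant_bump_represents_nothing(self):
        temps = np.stack([np.eye(8)[0], np.eye(8)[1]])
        bump = np.zeros(8)
        bump[4] = 1.0  # same SSD to both templates
        idx = similarity_index(bump, temps)
        assert np.allclose(idx, 1.0)

    def test_matches_naive_reimplementation_bitwise(self):
        temps = self._templates()
        bump = 0.9 * temps[0] + 0.1 * temps[1]
        idx = similarity_index(bump, temps)
        oracle = _naive_similarity(bump, list(temps))
        assert int(np.argmin(idx)) == 0
        assert np.allclose(idx, oracle, rtol=1e-12, atol=0.0)

    def test_requires_two_templates(self):
        with pytest.raises(ValueError):
            similarity_index(np.ones(4), np.ones((1, 4)))


class TestDecodeTimeline:
    def _tuning(self, n=128):
        prof = bump_rate_profile(n, 0.0, 1.0, sigma=0.4)
        return TuningCurve(prof / prof.max())

    def test_stable_bump_decoded_quickly(self):
        n = 128
        raster = sample_bump_raster(n, 0.3 * np.pi, 500.0, seed=1,
                                    peak_hz=60.0, baseline_hz=0.5)
        tl = decode_state_timeline(raster, self._tuning(n),
                                   {"A": 0.3 * np.pi, "B": 0.7 * np.pi,
                                    "X": 1.3 * np.pi, "Y": 1.7 * np.pi},
                                   500.0)
        onset = tl.onset_time("A")
        assert onset is not None and onset <= 75.0
        # state A from onset (plus the 50-ms qualifying run) onward
        frm = int(onset) + 50
        assert np.all(tl.state[frm:] == tl.labels.index("A"))

    def test_silent_raster_decodes_to_none(self):
        rec = SpikeRecord([], [], 128)
        tl = decode_state_timeline(rec, self._tuning(), {"A": 0.0, "B": np.pi},
                                   300.0)
        assert np.all(tl.state == -1)

    def test_bump_switch_detected_within_window(self):
        n = 128
        a = sample_bump_raster(n, 0.3 * np.pi, 400.0, seed=2, peak_hz=60.0)
        b = sample_bump_raster(n, 1.3 * np.pi, 400.0, seed=3, peak_hz=60.0)
        neurons = np.concatenate([a.neuron, b.neuron])
        times = np.concatenate([a.time_ms, b.time_ms + 400.0])
        rec = SpikeRecord(neurons, times, n)
        tl = decode_state_timeline(rec, self._tuning(n),
                                   {"A": 0.3 * np.pi, "X": 1.3 * np.pi},
                                   800.0)
        onset_x = tl.onset_time("X", after=400.0)
        assert onset_x is not None
        assert onset_x <= 400.0 + 50.0 + 25.0

    def test_decoding_is_deterministic(self):
        raster = sample_bump_raster(64, np.pi, 300.0, seed=9)
        tun = self._tuning(64)
        t1 = decode_state_timeline(raster, tun, {"A": np.pi, "B": 0.0}, 300.0)
        t2 = decode_state_timeline(raster, tun, {"A": np.pi, "B": 0.0}, 300.0)
        assert np.array_equal(t1.indices, t2.indices)
        assert np.array_equal(t1.state, t2.state)

    def test_indices_invariant_to_rate_rescaling(self):
        n = 64
        rates = bump_rate_profile(n, np.pi, 80.0, baseline_hz=1.0)
        r1 = sample_poisson_raster(rates, 400.0, seed=4)
        # identical raster, every spike duplicated (rates scaled by 2)
        r2 = SpikeRecord(np.concatenate([r1.neuron, r1.neuron]),
                         np.concatenate([r1.time_ms, r1.time_ms]), n)
        tun = self._tuning(n)
        t1 = decode_state_timeline(r1, tun, {"A": np.pi, "B": 0.0}, 400.0)
        t2 = decode_state_timeline(r2, tun, {"A": np.pi, "B": 0.0}, 400.0)
        assert np.allclose(t1.indices, t2.indices, atol=1e-12)

    def test_correct_stimulus_decoded_above_95_percent(self):
        n = 128
        thetas = {"A": 0.3 * np.pi, "B": 0.7 * np.pi,
                  "X": 1.3 * np.pi, "Y": 1.7 * np.pi}
        tun = self._tuning(n)
        correct = 0
        total = 0
        for i, (lab, th) in enumerate(list(thetas.items()) * 10):
            raster = sample_bump_raster(n, th, 300.0, seed=100 + i,
                                        peak_hz=40.0, baseline_hz=0.5)
            tl = decode_state_timeline(raster, tun, thetas, 300.0)
            states = tl.state[50:]
            decoded = states[states >= 0]
            total += 1
            if decoded.size and np.bincount(decoded).argmax() == \
                    tl.labels.index(lab):
                correct += 1
        assert correct / total > 0.95


def _mk_timeline(states, labels=("cue", "probe"), rate=5.0):
    T = len(states)
    idx = np.ones((T, len(labels)))
    st = np.full(T, -1)
    for t, s in enumerate(states):
        if s is not None:
            j = labels.index(s) if isinstance(s, str) else s
            st[t] = j
            idx[t, j] = 0.1
    return StateTimeline(t_ms=np.arange(1, T + 1, dtype=float),
                         labels=list(labels), indices=idx, state=st,
                         pop_rate_hz=np.full(T, rate))


class TestClassifyOutcome:
    CUE_W = (100.0, 300.0)
    PROBE_W = (600.0, 800.0)

    def classify(self, tl):
        return classify_trial_outcome(tl, "cue", "probe", self.CUE_W,
                                      self.PROBE_W)

    def test_maintain(self):
        states = [None] * 150 + ["cue"] * 850
        assert self.classify(_mk_timeline(states)).outcome == "maintain"

    def test_jump(self):
        states = [None] * 150 + ["cue"] * 500 + ["probe"] * 350
        out = self.classify(_mk_timeline(states))
        assert out.outcome == "jump"
        assert out.t_jump == pytest.approx(651.0)

    def test_collapse_during_delay(self):
        states = [None] * 150 + ["cue"] * 250 + [None] * 600
        out = self.classify(_mk_timeline(states))
        assert out.outcome == "collapse"
        assert out.t_collapse == pytest.approx(401.0)

    def test_never_initiated_counts_as_collapse(self):
        assert self.classify(_mk_timeline([None] * 1000)).outcome == "collapse"

    def test_epileptic_dominates(self):
        # high population rate with nothing represented for > 500 ms
        tl = _mk_timeline([None] * 1000, rate=45.0)
        assert self.classify(tl).outcome == "epileptic"

    def test_high_rate_with_representation_is_not_epileptic(self):
        states = [None] * 150 + ["cue"] * 850
        tl = _mk_timeline(states, rate=45.0)
        assert self.classify(tl).outcome == "maintain"

    def test_brief_gap_shorter_than_rule_is_tolerated(self):
        states = ([None] * 150 + ["cue"] * 400 + [None] * 30
                  + ["cue"] * 420)
        assert self.classify(_mk_timeline(states)).outcome == "maintain"
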