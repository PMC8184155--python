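"""Ring-attractor construction and forward simulation.

A ring module pairs a pyramidal population (neurons assigned evenly spaced
radial directions on [0, 2pi)) with an interneuron population.  Pyramidal ->
pyramidal connections are localized (stronger between similar directions);
pyramidal -> interneuron, interneuron -> pyramidal and interneuron ->
interneuron connections are uniform.  Incoming weights from any source
population to a neuron sum to 1.

The simulator integrates many independent trials side by side (a batch axis)
with one RNG stream pair (background noise, afferent signal) per trial, so a
trial's spike record is bit-identical whether it is run alone or inside any
batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from ._rng import child_sequences
from .lif_core import DT_DEFAULT, SpikeRecord
from .params import (CellParams, ReceptorParams, default_interneuron_cell,
                     default_interneuron_receptors, default_pyramidal_cell,
                     default_pyramidal_receptors)

__all__ = [
    "RingConfig",
    "StimulusSpec",
    "Connectivity",
    "RingTrial",
    "FeedForwardDrive",
    "localized_weight_profile",
    "build_connectivity",
    "afferent_rate_profile",
    "ring_directions",
    "perception_preset",
    "memory_preset",
    "run_ring",
    "run_ring_batch",
]

_NOISE_CHUNK = 256  # steps of background-noise events drawn per RNG call


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class RingConfig:
    """Full parameterization of one ring attractor.

    The two NMDA conductances (on pyramidal cells and on interneurons) set
    the module's excitation-inhibition balance and hence whether it behaves
    as a "perception" (low-inertia) or "memory" (high-inertia) network.
    """

    n_pyr: int = 1024
    n_int: int = 256
    P: float = 0.7            # localized proportion of the pyr->pyr weight
    sigma_w: float = 0.05     # width of the localized weight profile
    pyr_cell: CellParams = field(default_factory=default_pyramidal_cell)
    int_cell: CellParams = field(default_factory=default_interneuron_cell)
    pyr_receptors: ReceptorParams = field(default_factory=default_pyramidal_receptors)
    int_receptors: ReceptorParams = field(default_factory=default_interneuron_receptors)
    noise_rate: float = 1.80  # kHz per neuron, background Poisson EPSPs
    noise_weight: float = 0.001
    noise_to_interneurons: bool = True
    aff_sigma: float = 0.4    # width of the afferent rate profile
    aff_Fmax: float = 1.25    # kHz, peak afferent rate
    aff_weight: float = 0.001

    def __post_init__(self) -> None:
        if self.n_pyr <= 0 or self.n_int <= 0:
            raise ValueError("population sizes must be positive")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("P must lie in [0, 1]")
        if self.sigma_w <= 0 or self.aff_sigma <= 0:
            raise ValueError("profile widths must be positive")

    def with_nmda(self, g_pyr: float | None = None,
                  g_int: float | None = None) -> "RingConfig":
        """Copy with replaced NMDA conductances (uS)."""
        pr = self.pyr_receptors if g_pyr is None else replace(self.pyr_receptors, g_NMDA=g_pyr)
        ir = self.int_receptors if g_int is None else replace(self.int_receptors, g_NMDA=g_int)
        return replace(self, pyr_receptors=pr, int_receptors=ir)

    def scale_nmda(self, pyr_factor: float = 1.0,
                   int_factor: float = 1.0) -> "RingConfig":
        """Copy with NMDA conductances multiplied (percent manipulations)."""
        return self.with_nmda(self.pyr_receptors.g_NMDA * pyr_factor,
                              self.int_receptors.g_NMDA * int_factor)


def perception_preset(**overrides) -> RingConfig:
    """Low-inertia ring (NMDA_g,pyr = 0.37 uS, NMDA_g,int = 0.30 uS): tracks
    new stimuli, suited to a perceptual role."""
    cfg = RingConfig(pyr_receptors=default_pyramidal_receptors(0.37),
                     int_receptors=default_interneuron_receptors(0.30))
    return replace(cfg, **overrides) if overrides else cfg


def memory_preset(**overrides) -> RingConfig:
    """High-inertia ring (NMDA_g,pyr = 0.37 uS, NMDA_g,int = 0.35 uS): holds
    an established bump against probe stimulation, suited to working memory."""
    cfg = RingConfig(pyr_receptors=default_pyramidal_receptors(0.37),
                     int_receptors=default_interneuron_receptors(0.35))
    return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class StimulusSpec:
    """One timed, spatially profiled afferent stimulus.

    Afferent Poisson rates follow F(theta - theta_aff) =
    Fmax * exp(2 pi (cos(theta - theta_aff) - 1) / sigma), targeting the
    pyramidal population only, with per-connection weight given by the ring
    config.
    """

    theta_aff: float   # radians in [0, 2pi)
    onset: float       # ms
    offset: float      # ms
    g_ampa_aff: float  # uS, AMPA conductance of the afferent channel
    Fmax: float = 1.25  # kHz
    sigma: float = 0.4

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")
        if not 0.0 <= self.theta_aff < 2 * math.pi:
            raise ValueError("theta_aff must lie in [0, 2pi)")


# ---------------------------------------------------------------------------
# connectivity

def ring_directions(n: int) -> np.ndarray:
    """Radial directions theta_i = 2 pi i / n assigned to pyramidal cells."""
    return 2.0 * np.pi * np.arange(n) / n


def localized_weight_profile(delta_theta, P, sigma):
    """Unnormalized pyr->pyr weight, W(d) = P exp(2 pi (cos d - 1)/sigma) + (1-P).

    Even in delta_theta; equals 1 at delta_theta = 0.
    """
    d = np.asarray(delta_theta, float)
    return P * np.exp(2.0 * np.pi * (np.cos(d) - 1.0) / sigma) + (1.0 - P)


@dataclass(frozen=True)
class Connectivity:
    """Dense weight matrices W[src, dst]; incoming weights (columns) sum to 1."""

    W_pp: np.ndarray
    W_pi: np.ndarray
    W_ip: np.ndarray
    W_ii: np.ndarray

    def validate(self, atol: float = 1e-9) -> None:
        for name in ("W_pp", "W_pi", "W_ip", "W_ii"):
            W = getattr(self, name)
            sums = W.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=atol, rtol=0.0):
                raise ValueError(f"{name} incoming weights do not sum to 1")


def build_connectivity(config: RingConfig) -> Connectivity:
    """Construct the four weight matrices of one ring module.

    W_pp is circulant (built from the localized profile of direction
    differences and normalized so each column sums to 1); the other three
    are uniform.  Self-connections are included; normalization absorbs them.
    """
    theta = ring_directions(config.n_pyr)
    prof = localized_weight_profile(theta[:, None] - theta[None, :],
                                    config.P, config.sigma_w)
    W_pp = prof / prof.sum(axis=0, keepdims=True)
    W_pi = np.full((config.n_pyr, config.n_int), 1.0 / config.n_pyr)
    W_ip = np.full((config.n_int, config.n_pyr), 1.0 / config.n_int)
    W_ii = np.full((config.n_int, config.n_int), 1.0 / config.n_int)
    conn = Connectivity(W_pp=W_pp, W_pi=W_pi, W_ip=W_ip, W_ii=W_ii)
    conn.validate()
    return conn


def _pp_kernel(config: RingConfig) -> np.ndarray:
    """First column of the circulant W_pp (incoming weights to neuron 0)."""
    theta = ring_directions(config.n_pyr)
    k = localized_weight_profile(theta, config.P, config.sigma_w)
    return k / k.sum()


def _circulant_table(kernel: np.ndarray) -> np.ndarray:
    """(n, n) table whose row r is the incoming-weight pattern produced by a
    presynaptic spike at neuron r (circulant from the kernel)."""
    nk = kernel.size
    idx = (np.arange(nk)[None, :] - np.arange(nk)[:, None]) % nk
    return kernel[idx]


def afferent_rate_profile(theta, stim: StimulusSpec) -> np.ndarray:
    """Per-neuron afferent Poisson rate (kHz) while the stimulus is active."""
    d = np.asarray(theta, float) - stim.theta_aff
    return stim.Fmax * np.exp(2.0 * np.pi * (np.cos(d) - 1.0) / stim.sigma)


# ---------------------------------------------------------------------------
# feed-forward coupling (used by the two-ring agent)

class FeedForwardDrive:
    """Spike-train drive from an upstream pyramidal population into the
    recurrent NMDA channel of a downstream ring.

    Weights follow the same localized profile as the recurrent pyr->pyr
    connections but are normalized so incoming weights sum to `weight_sum`
    (0.05 for the DPX agent, 20x weaker than the recurrent normalization to
    1): each upstream spike increments the downstream NMDA x gating by
    alpha_x times the connection weight, exactly like a recurrent spike.
    """

    def __init__(self, spike_records: Sequence[SpikeRecord],
                 config: RingConfig, weight_sum: float,
                 n_steps: int, dt: float = DT_DEFAULT):
        n = config.n_pyr
        self._table = _circulant_table(_pp_kernel(config) * weight_sum
                                       * config.pyr_receptors.alpha_x)
        self.n_steps = n_steps
        steps, bs, ns = [], [], []
        for b, rec in enumerate(spike_records):
            st = np.minimum((rec.time_ms / dt).astype(np.int64), n_steps - 1)
            steps.append(st)
            bs.append(np.full(st.size, b, dtype=np.int64))
            ns.append(rec.neuron)
        steps = np.concatenate(steps) if steps else np.empty(0, np.int64)
        order = np.argsort(steps, kind="stable")
        self._steps = steps[order]
        self._b = np.concatenate(bs)[order] if bs else np.empty(0, np.int64)
        self._n = np.concatenate(ns)[order] if ns else np.empty(0, np.int64)
        self._indptr = np.searchsorted(self._steps, np.arange(n_steps + 1))

    def total_incoming_weight(self) -> float:
        return float(self._table.sum(axis=0)[0])

    def add_increments(self, step: int, out: np.ndarray) -> None:
        """Add this step's weighted events into `out` (shape (B, n_pyr))."""
        i0, i1 = self._indptr[step], self._indptr[step + 1]
        if i1 > i0:
            np.add.at(out, self._b[i0:i1], self._table[self._n[i0:i1]])


def feed_forward_coupling(spike_records, config: RingConfig, n_steps: int,
                          weight_sum: float = 0.05,
                          dt: float = DT_DEFAULT) -> FeedForwardDrive:
    """Build the perception->memory drive from perception spike records."""
    return FeedForwardDrive(spike_records, config, weight_sum, n_steps, dt)


# ---------------------------------------------------------------------------
# simulation

@dataclass
class RingTrial:
    """Spike output (and optional membrane traces) of one simulated trial."""

    spikes_pyr: SpikeRecord
    spikes_int: SpikeRecord
    duration_ms: float
    seed: object
    vm_pyr: np.ndarray | None = None  # (n_samples, n_pyr), if recorded
    vm_int: np.ndarray | None = None
    vm_stride_ms: float | None = None
    traces: dict | None = None  # optional gating traces (same stride)


def _trial_streams(seed) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent (noise, afferent) generators for one trial."""
    noise_ss, aff_ss = child_sequences(seed, 2)
    return np.random.default_rng(noise_ss), np.random.default_rng(aff_ss)


def run_ring_batch(config: RingConfig,
                   stimuli: Sequence[StimulusSpec] | Sequence[Sequence[StimulusSpec]],
                   duration_ms: float,
                   seeds: Sequence,
                   dt: float = DT_DEFAULT,
                   external_drive: FeedForwardDrive | None = None,
                   record_vm_stride_ms: float | None = None) -> list[RingTrial]:
    """Simulate a batch of independent trials of one ring configuration.

    Parameters
    ----------
    stimuli : either one stimulus list shared by all trials, or one list per
        trial (e.g. per-trial afferent conductances or distractor sides).
    seeds : one RNG seed (int or SeedSequence) per trial; each trial owns
        independent noise and afferent streams, so results do not depend on
        batch composition or execution order.
    external_drive : optional spike-train drive into the pyramidal afferent
        channel (the agent's perception->memory coupling).  Mutually
        exclusive with `stimuli`.

    Returns one RingTrial per seed.
    """
    B = len(seeds)
    n, m = config.n_pyr, config.n_int
    n_steps = int(round(duration_ms / dt))
    per_trial = bool(stimuli) and isinstance(stimuli[0], (list, tuple))
    stim_lists = list(stimuli) if per_trial else [list(stimuli)] * B
    if per_trial and len(stim_lists) != B:
        raise ValueError("need one stimulus list per seed")
    if external_drive is not None and any(stim_lists):
        raise ValueError("external_drive and stimuli are mutually exclusive")
    if external_drive is not None and external_drive.n_steps < n_steps:
        raise ValueError("external drive is shorter than the simulation")

    theta = ring_directions(n)
    k_table = _circulant_table(_pp_kernel(config))
    pr, ir = config.pyr_receptors, config.int_receptors
    pc, ic = config.pyr_cell, config.int_cell

    # per-trial stimulus schedule -> per-step active-stimulus index (-1 = none)
    stim_lams: list[np.ndarray] = []   # flattened per (trial, stimulus)
    stim_g: list[float] = []
    active = np.full((B, n_steps), -1, dtype=np.int32)
    for b, stims in enumerate(stim_lists):
        for s in stims:
            k0 = int(round(s.onset / dt))
            k1 = min(int(round(s.offset / dt)), n_steps)
            if k0 < n_steps and np.any(active[b, k0:k1] >= 0):
                raise ValueError("overlapping stimulus windows")
            active[b, k0:k1] = len(stim_lams)
            stim_lams.append(afferent_rate_profile(theta, s) * dt)
            stim_g.append(s.g_ampa_aff)
    stim_g_arr = np.asarray(stim_g + [0.0])
    step_has_stim = (active >= 0).any(axis=0)
    # event-based afferent sampling: total rate + inverse-CDF positions
    stim_tot = [float(lam.sum()) for lam in stim_lams]
    stim_cdf = [np.cumsum(lam) / lam.sum() if lam.sum() > 0 else None
                for lam in stim_lams]

    noise_rngs, aff_rngs = zip(*(_trial_streams(s) for s in seeds))
    lam_noise = config.noise_rate * dt
    n_noise_cols = n + (m if config.noise_to_interneurons else 0)
    lam_noise_tot = n_noise_cols * lam_noise

    decay_gaba = math.exp(-dt / pr.tau_s_gaba)
    decay_ampa = math.exp(-dt / pr.tau_s_ampa)
    w_noise = config.noise_weight
    w_aff = config.aff_weight

    # dynamic state (batch-major)
    vm_p = np.full((B, n), pc.V_rest)
    vm_i = np.full((B, m), ic.V_rest)
    ref_p = np.full((B, n), -np.inf)
    ref_i = np.full((B, m), -np.inf)
    # NMDA gating per postsynaptic neuron, x incremented by connection weight
    # per presynaptic spike (uniform pyr->int weights make the interneuron
    # gating identical across targets: kept as one column per trial)
    x_p = np.zeros((B, n))
    s_p = np.zeros((B, n))
    x_i = np.zeros((B, 1))
    s_i = np.zeros((B, 1))
    sg_p = np.zeros((B, 1))   # uniform GABA gating (identical across targets)
    sg_i = np.zeros((B, 1))
    sn_p = np.zeros((B, n))
    sn_i = np.zeros((B, m))
    sa_p = np.zeros((B, n))
    g_aff_now = np.zeros(B)

    s_p_next = np.zeros((B, n))   # double buffer for the NMDA gating
    s_i_next = np.zeros((B, 1))
    sa_none = np.zeros((B, 1))    # interneurons receive no afferent channel
    g_aff_none = np.zeros(B)
    prev_spk_pb = np.empty(0, np.int64)
    prev_spk_pn = np.empty(0, np.int64)
    prev_spk_ib = np.empty(0, np.int64)

    all_pb, all_pn, all_pt = [], [], []   # pyramidal spikes across the run
    all_ib, all_in, all_it = [], [], []
    out_b = np.empty(B * n, np.int64)
    out_n = np.empty(B * n, np.int64)
    out_t = np.empty(B * n, float)
    oib = np.empty(B * m, np.int64)
    oin = np.empty(B * m, np.int64)
    oit = np.empty(B * m, float)

    record = record_vm_stride_ms is not None
    if record:
        rec_every = max(1, int(round(record_vm_stride_ms / dt)))
        vm_p_trace, vm_i_trace = [], []
        gating_trace: dict[str, list] = {k: [] for k in
                                         ("s_nmda", "s_gaba",
                                          "s_noise", "s_aff")}

    ev_b = ev_po = chunk_indptr = None
    for k in range(n_steps):
        t = k * dt
        kk = k % _NOISE_CHUNK
        if kk == 0:
            # draw this chunk's background events (total count per step,
            # then uniform target positions: exact for equal per-neuron rates)
            K = min(_NOISE_CHUNK, n_steps - k)
            bs, sts, pos = [], [], []
            for b in range(B):
                totals = noise_rngs[b].poisson(lam_noise_tot, K)
                tot = int(totals.sum())
                pos.append(noise_rngs[b].integers(0, n_noise_cols, tot))
                sts.append(np.repeat(np.arange(K), totals))
                bs.append(np.full(tot, b, np.int64))
            ev_b = np.concatenate(bs)
            ev_step = np.concatenate(sts)
            ev_po = np.concatenate(pos)
            order = np.argsort(ev_step, kind="stable")
            ev_b, ev_step, ev_po = ev_b[order], ev_step[order], ev_po[order]
            chunk_indptr = np.searchsorted(ev_step, np.arange(K + 1))

        # --- decay of first-order gating + start-of-step increments --------
        i0, i1 = chunk_indptr[kk], chunk_indptr[kk + 1]
        _kernels.begin_step(
            sn_p, sn_i, sa_p, sg_p, sg_i, decay_ampa, decay_gaba,
            ev_b[i0:i1], ev_po[i0:i1], n, w_noise,
            config.noise_to_interneurons,
            x_p, k_table, prev_spk_pb, prev_spk_pn, pr.alpha_x,
            x_i, ir.alpha_x / n, prev_spk_ib, 1.0 / m)

        if external_drive is not None:
            # upstream spikes enter the NMDA x gating; the feed-forward
            # table already carries alpha_x times the connection weights
            external_drive.add_increments(k, x_p)
        elif step_has_stim[k]:
            act_k = active[:, k]
            for b in np.nonzero(act_k >= 0)[0]:
                si = act_k[b]
                n_ev = int(aff_rngs[b].poisson(stim_tot[si]))
                if n_ev:
                    tgt = np.searchsorted(stim_cdf[si], aff_rngs[b].random(n_ev))
                    np.add.at(sa_p[b], tgt, w_aff)
            g_aff_now = stim_g_arr[act_k]

        # --- NMDA gating to the end of the step -----------------------------
        _kernels.nmda_rk2(x_p, s_p, s_p_next, dt, pr.tau_x, pr.alpha_s,
                          pr.tau_s_nmda)
        _kernels.nmda_rk2(x_i, s_i, s_i_next, dt, ir.tau_x, ir.alpha_s,
                          ir.tau_s_nmda)

        # --- membranes (start-of-step gating + exact decay factors) ---------
        cnt_p = _kernels.membrane_step(
            vm_p, ref_p, t, dt, pc.V_rest, pc.V_th, pc.V_L, pc.gL, pc.Cm,
            pc.tau_ref, pr.V_I, pr.Mg, pr.g_NMDA, pr.g_AMPA_noise,
            g_aff_now, sn_p, sa_p, sg_p[:, 0], pr.g_GABA,
            decay_ampa, decay_gaba, s_p, s_p_next, out_b, out_n, out_t)
        cnt_i = _kernels.membrane_step(
            vm_i, ref_i, t, dt, ic.V_rest, ic.V_th, ic.V_L, ic.gL, ic.Cm,
            ic.tau_ref, ir.V_I, ir.Mg, ir.g_NMDA, ir.g_AMPA_noise,
            g_aff_none, sn_i, sa_none, sg_i[:, 0], ir.g_GABA,
            decay_ampa, decay_gaba, s_i, s_i_next, oib, oin, oit)

        # --- swap NMDA buffers, collect spikes ------------------------------
        s_p, s_p_next = s_p_next, s_p
        s_i, s_i_next = s_i_next, s_i
        prev_spk_pb = out_b[:cnt_p].copy()
        prev_spk_pn = out_n[:cnt_p].copy()
        prev_spk_ib = oib[:cnt_i].copy()
        if cnt_p:
            all_pb.append(prev_spk_pb)
            all_pn.append(prev_spk_pn)
            all_pt.append(out_t[:cnt_p].copy())
        if cnt_i:
            all_ib.append(prev_spk_ib)
            all_in.append(oin[:cnt_i].copy())
            all_it.append(oit[:cnt_i].copy())
        if k % 400 == 0 and not np.isfinite(vm_p).all():
            raise FloatingPointError(
                f"membrane integration blew up near t={t:.1f} ms")
        if record and k % rec_every == 0:
            vm_p_trace.append(vm_p.copy())
            vm_i_trace.append(vm_i.copy())
            gating_trace["s_nmda"].append(s_p.copy())
            gating_trace["s_gaba"].append(sg_p.copy())
            gating_trace["s_noise"].append(sn_p.mean(-1, keepdims=True).copy())
            gating_trace["s_aff"].append(sa_p.copy())

    if not np.isfinite(vm_p).all() or not np.isfinite(vm_i).all():
        raise FloatingPointError("membrane integration blew up")

    def gather(all_b, all_n, all_t, n_neurons):
        if all_b:
            eb = np.concatenate(all_b)
            en = np.concatenate(all_n)
            et = np.concatenate(all_t)
        else:
            eb = np.empty(0, np.int64)
            en = np.empty(0, np.int64)
            et = np.empty(0)
        return [SpikeRecord(en[eb == b], et[eb == b], n_neurons)
                for b in range(B)]

    recs_p = gather(all_pb, all_pn, all_pt, n)
    recs_i = gather(all_ib, all_in, all_it, m)
    trials = []
    for b in range(B):
        trials.append(RingTrial(
            spikes_pyr=recs_p[b], spikes_int=recs_i[b],
            duration_ms=duration_ms, seed=seeds[b],
            vm_pyr=np.stack([v[b] for v in vm_p_trace]) if record else None,
            vm_int=np.stack([v[b] for v in vm_i_trace]) if record else None,
            vm_stride_ms=(rec_every * dt) if record else None,
            traces={key: np.stack([v[b] for v in vals])
                    for key, vals in gating_trace.items()} if record else None))
    return trials


def run_ring(config: RingConfig, stimuli: Sequence[StimulusSpec],
             duration_ms: float, seed, dt: float = DT_DEFAULT,
             **kwargs) -> RingTrial:
    """Simulate a single trial (see `run_ring_batch`)."""
    return run_ring_batch(config, [list(stimuli)], duration_ms, [seed],
                          dt=dt, **kwargs)[0]
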