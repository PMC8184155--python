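"""Conductance-based leaky integrate-and-fire primitives.

All operations are vectorized over arbitrary leading axes, so a "population"
may be shaped ``(n_neurons,)`` or ``(n_batch, n_neurons)`` (independent
simulations stacked along the first axis).

Model summary
-------------
Membrane:   Cm dVm/dt = -I_NMDA - I_GABA - I_Leak - I_Noise - I_Aff
with I_Leak = gL (Vm - V_L).  A neuron crossing V_th emits a spike whose time
is linearly interpolated within the step, then is clamped at V_rest for an
absolute refractory period tau_ref.  Integration is second-order Runge-Kutta
(Heun) at dt = 0.05 ms by default.

Synapses:   I = g * s * (Vm - V_rev), with an additional voltage-dependent
Mg2+ block for NMDA.  NMDA gating is second order (x jumps by alpha_x per
presynaptic spike and drives s through ds/dt = alpha_s x (1-s) - s/tau_s);
GABA/AMPA gating is first order (jumps by the connection weight per spike,
exponential decay).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import CellParams, ReceptorParams

__all__ = [
    "DT_DEFAULT",
    "PopulationState",
    "SpikeRecord",
    "mg_block_factor",
    "nmda_current",
    "gaba_current",
    "ampa_current",
    "synaptic_currents",
    "update_first_order_kinetics",
    "update_nmda_kinetics",
    "step_population",
    "poisson_drive",
]

DT_DEFAULT = 0.05  # ms


# ---------------------------------------------------------------------------
# currents

def mg_block_factor(Vm, Mg):
    """Voltage-dependent Mg2+ attenuation of the NMDA conductance.

    Returns 1 / (1 + [Mg] exp(-0.062 Vm) / 3.57); strictly increasing in Vm,
    equal to 1 when [Mg] = 0.
    """
    return 1.0 / (1.0 + Mg * np.exp(-0.062 * np.asarray(Vm, float)) / 3.57)


def nmda_current(Vm, s_drive, g_NMDA, V_E=0.0, Mg=1.0):
    """I_NMDA = g s (Vm - V_E) * mg_block; `s_drive` is the weighted sum of
    presynaptic open fractions for each postsynaptic neuron."""
    return g_NMDA * s_drive * (Vm - V_E) * mg_block_factor(Vm, Mg)


def gaba_current(Vm, s, g_GABA, V_I=-70.0):
    return g_GABA * s * (Vm - V_I)


def ampa_current(Vm, s, g_AMPA, V_E=0.0):
    return g_AMPA * s * (Vm - V_E)


def synaptic_currents(state: "PopulationState", params: ReceptorParams,
                      W_nmda: np.ndarray | None = None,
                      g_AMPA_aff: float | np.ndarray | None = None):
    """Per-neuron synaptic currents (nA) with the membrane sign convention
    (positive values are subtracted from dVm/dt).

    Parameters
    ----------
    W_nmda : (n_src, n_post) weight matrix for the recurrent NMDA drive, or
        None if the postsynaptic NMDA drive is already stored in the state
        (``state.s_nmda`` is then interpreted as per-postsynaptic drive).
    g_AMPA_aff : afferent conductance override (the experimentally varied
        AMPA_g,Aff); defaults to ``params.g_AMPA_aff``.

    Returns
    -------
    (I_NMDA, I_GABA, I_Noise, I_Aff)
    """
    Vm = state.Vm
    if W_nmda is not None:
        if state.s_nmda.shape[-1] != W_nmda.shape[0]:
            raise ValueError("s_nmda length does not match weight matrix rows")
        drive = state.s_nmda @ W_nmda
    else:
        drive = state.s_nmda
    g_aff = params.g_AMPA_aff if g_AMPA_aff is None else g_AMPA_aff
    I_nmda = nmda_current(Vm, drive, params.g_NMDA, params.V_E, params.Mg)
    I_gaba = gaba_current(Vm, state.s_gaba, params.g_GABA, params.V_I)
    I_noise = ampa_current(Vm, state.s_ampa_noise, params.g_AMPA_noise, params.V_E)
    I_aff = ampa_current(Vm, state.s_ampa_aff, g_aff, params.V_E)
    return I_nmda, I_gaba, I_noise, I_aff


# ---------------------------------------------------------------------------
# gating kinetics

def update_first_order_kinetics(s, weighted_spike_input, dt, tau):
    """Advance first-order (GABA/AMPA) gating by one step.

    The weighted spike input (sum of connection weights of this step's
    presynaptic spikes) is added at the start of the step, then the gating
    decays exactly: s <- (s + input) * exp(-dt/tau).
    """
    return (s + weighted_spike_input) * np.exp(-dt / tau)


def update_nmda_kinetics(x, s, spike_counts, dt,
                         alpha_x=1.0, tau_x=2.0, alpha_s=1.0, tau_s=80.0):
    """Advance second-order NMDA gating by one Heun (RK2) step.

    `x` jumps by alpha_x per presynaptic spike at the start of the step; both
    ODEs  dx/dt = -x/tau_x,  ds/dt = alpha_s x (1 - s) - s/tau_s  are then
    advanced by RK2.  `s` is clipped to [0, 1] (the continuous dynamics keep
    it there; clipping removes O(dt^3) overshoot).
    """
    x0 = x + alpha_x * spike_counts
    k1x = -x0 / tau_x
    k1s = alpha_s * x0 * (1.0 - s) - s / tau_s
    x1 = x0 + dt * k1x
    s1 = s + dt * k1s
    k2x = -x1 / tau_x
    k2s = alpha_s * x1 * (1.0 - s1) - s1 / tau_s
    x_new = x0 + 0.5 * dt * (k1x + k2x)
    s_new = s + 0.5 * dt * (k1s + k2s)
    np.clip(s_new, 0.0, 1.0, out=s_new)
    return x_new, s_new


# ---------------------------------------------------------------------------
# membrane integration

def step_population(Vm, refrac_until, t, dt, cell: CellParams,
                    current_fn: Callable[[np.ndarray, int], np.ndarray]):
    """Advance membrane potentials by one RK2 step and detect spikes.

    Parameters
    ----------
    Vm : array of membrane potentials (mV), modified copy returned.
    refrac_until : array of absolute times (ms) until which each neuron is
        refractory (clamped at V_rest).
    t : step start time (ms).
    current_fn : callable ``(Vm, stage) -> I`` returning the summed synaptic
        current (nA, subtracted from the membrane equation) evaluated with
        start-of-step gating (stage 0) or end-of-step gating (stage 1).
        Injected depolarizing test currents enter with a negative sign.

    Neurons whose refractory period ends inside the step resume integration
    from V_rest over the remaining fraction of the step.  Spike times are
    linearly interpolated between the step endpoints.

    Returns
    -------
    (Vm_new, refrac_until, spiked, t_spike) where `spiked` is a boolean array
    and `t_spike` holds interpolated spike times where `spiked` is True.
    """
    Vm = np.asarray(Vm, float)
    start_gap = refrac_until - t
    dt_eff = np.clip(dt - start_gap, 0.0, dt)
    active = dt_eff > 0.0
    vm0 = np.where(start_gap > 0.0, cell.V_rest, Vm)

    inv_Cm = 1.0 / cell.Cm
    k1 = -(cell.gL * (vm0 - cell.V_L) + current_fn(vm0, 0)) * inv_Cm
    vm_e = vm0 + dt_eff * k1
    k2 = -(cell.gL * (vm_e - cell.V_L) + current_fn(vm_e, 1)) * inv_Cm
    vm_new = vm0 + 0.5 * dt_eff * (k1 + k2)
    if not np.all(np.isfinite(vm_new[active] if vm_new.ndim else vm_new)):
        raise FloatingPointError(
            f"membrane integration produced non-finite Vm at t={t:.3f} ms")

    spiked = active & (vm_new >= cell.V_th)
    dv = vm_new - vm0
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(dv != 0.0, (cell.V_th - vm0) / dv, 1.0)
    frac = np.clip(frac, 0.0, 1.0)
    t_spike = t + (dt - dt_eff) + dt_eff * frac

    vm_new = np.where(active, vm_new, cell.V_rest)
    vm_new = np.where(spiked, cell.V_rest, vm_new)
    refrac_until = np.where(spiked, t_spike + cell.tau_ref, refrac_until)
    return vm_new, refrac_until, spiked, t_spike


def poisson_drive(rates_khz, dt, rng: np.random.Generator):
    """Independent Poisson event counts per neuron for one step.

    `rates_khz` is events/ms per neuron; the expected count per step is
    rate * dt.  Exact Poisson sampling (not a Bernoulli approximation), so
    high rates remain correct at any dt.
    """
    lam = np.asarray(rates_khz, float) * dt
    if np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# containers

@dataclass
class PopulationState:
    """Dynamic state of one population (arrays share a leading batch shape).

    NMDA gating (`x_nmda`, `s_nmda`) is kept per presynaptic source (one pair
    per excitatory neuron, driven by that neuron's own spikes); postsynaptic
    NMDA drive is the weight-matrix-weighted sum of `s_nmda`.  GABA and AMPA
    gating are kept per postsynaptic neuron and incremented by connection
    weight per presynaptic event.
    """

    Vm: np.ndarray
    refrac_until: np.ndarray
    x_nmda: np.ndarray
    s_nmda: np.ndarray
    s_gaba: np.ndarray
    s_ampa_noise: np.ndarray
    s_ampa_aff: np.ndarray

    @classmethod
    def zeros(cls, shape, V_init: float) -> "PopulationState":
        full = np.full(shape, float(V_init))
        z = lambda: np.zeros(shape)
        return cls(Vm=full, refrac_until=np.full(shape, -np.inf),
                   x_nmda=z(), s_nmda=z(), s_gaba=z(),
                   s_ampa_noise=z(), s_ampa_aff=z())


class SpikeRecord:
    """Spike events (neuron index, interpolated time) of one population.

    Events are stored sorted by time.  Per-neuron times are non-decreasing
    and consecutive spikes of one neuron are separated by >= tau_ref by
    construction of the integrator.
    """

    def __init__(self, neuron, time_ms, n_neurons: int):
        neuron = np.asarray(neuron, dtype=np.int64)
        time_ms = np.asarray(time_ms, dtype=float)
        if neuron.shape != time_ms.shape:
            raise ValueError("neuron and time arrays must match")
        order = np.argsort(time_ms, kind="stable")
        self.neuron = neuron[order]
        self.time_ms = time_ms[order]
        self.n_neurons = int(n_neurons)

    def __len__(self) -> int:
        return self.neuron.size

    def window(self, t0: float, t1: float) -> "SpikeRecord":
        """Events with t0 <= t < t1."""
        i0, i1 = np.searchsorted(self.time_ms, [t0, t1])
        return SpikeRecord(self.neuron[i0:i1], self.time_ms[i0:i1],
                           self.n_neurons)

    def counts(self, t0: float, t1: float) -> np.ndarray:
        """Per-neuron spike counts in [t0, t1)."""
        w = self.window(t0, t1)
        return np.bincount(w.neuron, minlength=self.n_neurons)

    def binned_counts(self, duration_ms: float, bin_ms: float = 1.0) -> np.ndarray:
        """(n_bins, n_neurons) spike-count matrix."""
        n_bins = int(np.ceil(duration_ms / bin_ms))
        b = np.minimum((self.time_ms / bin_ms).astype(np.int64), n_bins - 1)
        out = np.zeros((n_bins, self.n_neurons), dtype=np.int32)
        np.add.at(out, (b, self.neuron), 1)
        return out

    def mean_rate_hz(self, t0: float, t1: float) -> float:
        """Population-mean firing rate (Hz) in [t0, t1)."""
        w = self.window(t0, t1)
        return 1000.0 * len(w) / (self.n_neurons * (t1 - t0))
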