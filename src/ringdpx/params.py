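"""Cellular and synaptic parameter containers.

Internal unit system: ms, mV, nF, uS, nA (so uS*mV = nA and nA/nF = mV/ms).
Published tables for this model family mix nS and uS; values are converted
to uS when a config file is loaded (leak conductances are the only entries
usually printed in nS).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

__all__ = [
    "CellParams",
    "ReceptorParams",
    "default_pyramidal_cell",
    "default_interneuron_cell",
    "default_pyramidal_receptors",
    "default_interneuron_receptors",
    "load_parameter_file",
    "default_parameters",
]


@dataclass(frozen=True)
class CellParams:
    """Passive membrane and spiking parameters of one LIF population.

    Attributes
    ----------
    Cm : float
        Membrane capacitance (nF).
    gL : float
        Leak conductance (uS).
    V_L : float
        Leak reversal potential (mV).
    V_th : float
        Spike threshold (mV).
    V_rest : float
        Post-spike reset / resting potential (mV).
    tau_ref : float
        Absolute refractory period (ms).
    """

    Cm: float
    gL: float
    V_L: float
    V_th: float
    V_rest: float
    tau_ref: float

    def __post_init__(self) -> None:
        if self.Cm <= 0:
            raise ValueError("Cm must be positive")
        if self.gL <= 0:
            raise ValueError("gL must be positive")
        if self.V_th <= self.V_rest:
            raise ValueError("V_th must exceed V_rest")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant Cm/gL (ms)."""
        return self.Cm / self.gL


@dataclass(frozen=True)
class ReceptorParams:
    """Synaptic receptor parameters of one postsynaptic population.

    Conductances are the *open-channel* conductances g in I = g s (Vm - V_rev);
    `s` is the dimensionless gating (open fraction) driven by presynaptic
    spikes.  NMDA uses second-order kinetics (x -> s) plus a voltage-dependent
    Mg2+ block; GABA and AMPA use first-order (jump-and-decay) kinetics.
    """

    g_NMDA: float          # uS, recurrent NMDA conductance
    g_GABA: float          # uS, recurrent GABA conductance
    g_AMPA_noise: float    # uS, background-noise AMPA conductance
    g_AMPA_aff: float      # uS, afferent-signal AMPA conductance
    V_E: float = 0.0       # mV, excitatory reversal
    V_I: float = -70.0     # mV, inhibitory reversal
    Mg: float = 1.0        # mM, extracellular Mg2+
    alpha_x: float = 1.0   # 1/ms, per-spike increment of the NMDA x kinetic
    tau_x: float = 2.0     # ms, closed->open lifetime
    alpha_s: float = 1.0   # dimensionless saturation factor
    tau_s_nmda: float = 80.0  # ms, open->closed lifetime
    tau_s_gaba: float = 10.0  # ms, GABA gating decay
    tau_s_ampa: float = 2.0   # ms, AMPA gating decay

    def __post_init__(self) -> None:
        for name in ("g_NMDA", "g_GABA", "g_AMPA_noise", "g_AMPA_aff", "Mg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("tau_x", "tau_s_nmda", "tau_s_gaba", "tau_s_ampa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _build(cls, mapping: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_parameter_file(path_or_stream) -> dict[str, Any]:
    """Load a structured parameter YAML into typed containers.

    The file holds two top-level groups, ``pyramidal`` and ``interneuron``,
    each with ``cell`` and ``receptors`` sub-maps, plus a ``drive`` group with
    noise/afferent settings and a ``connectivity`` group.  Leak conductance
    may be given as ``gL_nS`` and is converted to uS.
    """
    if hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            raw = yaml.safe_load(fh)
    out: dict[str, Any] = {"version": raw.get("version", "unversioned")}
    for pop in ("pyramidal", "interneuron"):
        grp = raw[pop]
        cell = dict(grp["cell"])
        if "gL_nS" in cell:
            cell["gL"] = cell.pop("gL_nS") * 1e-3
        out[pop] = {
            "cell": _build(CellParams, cell),
            "receptors": _build(ReceptorParams, dict(grp["receptors"])),
        }
    out["drive"] = dict(raw.get("drive", {}))
    out["connectivity"] = dict(raw.get("connectivity", {}))
    return out


def default_parameters() -> dict[str, Any]:
    """The bundled default parameter set (versioned YAML shipped in-package)."""
    ref = resources.files("ringdpx").joinpath("data/default_parameters.yaml")
    with ref.open("r") as fh:
        return load_parameter_file(fh)


def default_pyramidal_cell() -> CellParams:
    return CellParams(Cm=0.5, gL=0.025, V_L=-70.0, V_th=-50.0,
                      V_rest=-60.0, tau_ref=2.0)


def default_interneuron_cell() -> CellParams:
    return CellParams(Cm=0.2, gL=0.020, V_L=-70.0, V_th=-50.0,
                      V_rest=-60.0, tau_ref=2.0)


def default_pyramidal_receptors(g_NMDA: float = 0.37) -> ReceptorParams:
    return ReceptorParams(g_NMDA=g_NMDA, g_GABA=1.25,
                          g_AMPA_noise=3.10, g_AMPA_aff=1.0)


def default_interneuron_receptors(g_NMDA: float = 0.30) -> ReceptorParams:
    # Interneurons receive no stimulus afferent; g_AMPA_aff kept at 0.
    return ReceptorParams(g_NMDA=g_NMDA, g_GABA=1.0,
                          g_AMPA_noise=2.38, g_AMPA_aff=0.0)
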