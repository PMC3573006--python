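"""Single-neuron dynamics for the slow-wave network model.

This module holds the scalar reference implementation of the model neuron:
Izhikevich's two-variable spiking model, first-order synaptic conductance
kinetics (AMPA / NMDA / GABA_A / GABA_B), and the slow activity-dependent
excitability feedback that terminates UP states and lets the network recover
during DOWN states.

The vectorized network engine (:mod:`swostim._kernel`) re-implements these
update rules for speed; the functions here are the ground truth that the
engine is tested against.

Units
-----
Membrane potential ``v`` and recovery variable ``u`` are in mV / mV-scale as
in Izhikevich's original formulation, which integrates in milliseconds.
Public time arguments follow the field convention of the surrounding code:
``izhikevich_step`` and ``excitability_update`` take seconds,
``decay_conductances`` takes milliseconds (synaptic time constants are
quoted in ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "NeuronParams",
    "NeuronState",
    "SynapseKinetics",
    "nmda_gating",
    "izhikevich_step",
    "synaptic_current",
    "decay_conductances",
    "excitability_update",
    "NumericalBlowupError",
]

#: Spike detection / reset threshold of the Izhikevich model (mV).
SPIKE_THRESHOLD_MV = 30.0


class NumericalBlowupError(RuntimeError):
    """Raised when a membrane variable becomes non-finite during integration."""

    def __init__(self, neuron: int | str, t: float):
        super().__init__(
            f"non-finite membrane state for neuron {neuron!r} at t={t:.6f} s; "
            "reduce dt or check input currents"
        )
        self.neuron = neuron
        self.t = t


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich constants plus the excitability-feedback parameters.

    ``a, b, c, d`` are the standard recovery/reset constants (regular-spiking
    cortical pyramidal defaults).  ``e_ss`` is the steady-state excitability
    bias added to the voltage equation's drive; ``k_e`` the feedback gain and
    ``tau_r`` the time constant (s) of the leaky firing-rate estimate that
    drives the feedback.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    is_excitatory: bool = True
    e_ss: float = 2.9
    k_e: float = 6.0
    tau_r: float = 0.9

    def __post_init__(self) -> None:
        if not (self.tau_r > 0):
            raise ValueError("tau_r must be positive")
        if self.k_e < 0:
            raise ValueError("k_e must be nonnegative")
        for name in ("a", "b", "c", "d"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")


@dataclass
class NeuronState:
    """Dynamical state of one model neuron."""

    v: float = -70.0
    u: float = -14.0
    r: float = 0.0  # leaky firing-rate estimate (Hz)
    e: float = 0.0  # current excitability bias
    g_ampa: float = 0.0
    g_nmda: float = 0.0
    g_gabaa: float = 0.0
    g_gabab: float = 0.0
    last_spike_time: float = field(default=-math.inf)
    last_isi: float = field(default=math.inf)

    @classmethod
    def at_rest(cls, params: NeuronParams) -> "NeuronState":
        """State at the resting fixed point of the deterministic equations.

        Solves ``0.04 v^2 + 5 v + 140 - b v + e_ss = 0`` (with ``u = b v``)
        for the stable (more hyperpolarized) root.
        """
        a_, b_, c_ = 0.04, 5.0 - params.b, 140.0 + params.e_ss
        disc = b_ * b_ - 4.0 * a_ * c_
        if disc < 0:
            raise ValueError(
                "no resting fixed point: e_ss exceeds rheobase for these parameters"
            )
        v_rest = (-b_ - math.sqrt(disc)) / (2.0 * a_)
        return cls(v=v_rest, u=params.b * v_rest, e=params.e_ss)


@dataclass(frozen=True)
class SynapseKinetics:
    """Synaptic decay constants (ms), reversal potentials (mV) and mean
    per-spike conductance increments.

    A presynaptic excitatory spike increments the fast (AMPA) conductance by
    the edge weight w and the slow (NMDA) conductance by ``nmda_frac * w``;
    inhibitory spikes likewise increment GABA_A by w and GABA_B by
    ``gabab_frac * w``.  The slow-channel fractions keep the 150-ms
    conductances from dominating the balance at realistic firing rates.
    """

    tau_ampa: float = 5.0
    tau_nmda: float = 150.0
    tau_gabaa: float = 6.0
    tau_gabab: float = 150.0
    E_exc: float = 0.0
    E_gabaa: float = -70.0
    E_gabab: float = -90.0
    w_exc_mean: float = 0.032
    w_inh_mean: float = 0.2
    nmda_frac: float = 1.0
    gabab_frac: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_ampa", "tau_nmda", "tau_gabaa", "tau_gabab"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")


def nmda_gating(v: float) -> float:
    """Voltage dependence of the NMDA conductance, B(v) = x^2/(1+x^2) with
    x = (v+80)/60 (magnesium-block sigmoid of the companion cortical model)."""
    x = (v + 80.0) / 60.0
    return x * x / (1.0 + x * x)


def synaptic_current(state: NeuronState, kin: SynapseKinetics, w_hom: float = 1.0) -> float:
    """Total synaptic current onto a neuron at its present voltage.

    The homeostatic factor ``w_hom`` multiplies the excitatory (AMPA + NMDA)
    terms only; inhibitory conductances are untouched.
    """
    if w_hom < 0:
        raise ValueError("w_hom must be nonnegative")
    v = state.v
    i_exc = (state.g_ampa + state.g_nmda * nmda_gating(v)) * (kin.E_exc - v)
    i_inh = state.g_gabaa * (kin.E_gabaa - v) + state.g_gabab * (kin.E_gabab - v)
    return w_hom * i_exc + i_inh


def decay_conductances(state: NeuronState, kin: SynapseKinetics, dt_ms: float) -> NeuronState:
    """Exact exponential decay of all four conductances over ``dt_ms``."""
    if not (dt_ms > 0):
        raise ValueError("dt_ms must be positive")
    return replace(
        state,
        g_ampa=state.g_ampa * math.exp(-dt_ms / kin.tau_ampa),
        g_nmda=state.g_nmda * math.exp(-dt_ms / kin.tau_nmda),
        g_gabaa=state.g_gabaa * math.exp(-dt_ms / kin.tau_gabaa),
        g_gabab=state.g_gabab * math.exp(-dt_ms / kin.tau_gabab),
    )


def izhikevich_step(
    state: NeuronState,
    params: NeuronParams,
    I_total: float,
    dt: float,
    *,
    t: float = 0.0,
    neuron: int | str = 0,
    n_substeps: int = 2,
) -> tuple[NeuronState, bool]:
    """Advance ``v, u`` by one step of duration ``dt`` seconds.

    ``I_total`` is the full drive *excluding* the excitability bias ``e``,
    which is added here from the state (so quiescent neurons sit at the rest
    point shifted by ``e``).  The voltage equation is integrated with
    ``n_substeps`` forward-Euler half-steps (default two 0.25 ms halves at
    dt = 0.5 ms); ``u`` is advanced once per step.  On crossing +30 mV the
    neuron spikes: ``v -> c``, ``u -> u + d``, and the spike-time/ISI
    bookkeeping updates.
    """
    if not (0.0 < dt <= 1e-3):
        raise ValueError("dt must be in (0, 1 ms]")
    if not math.isfinite(I_total):
        raise NumericalBlowupError(neuron, t)

    dt_ms = dt * 1e3
    v, u = state.v, state.u
    drive = I_total + state.e
    h = dt_ms / n_substeps
    spiked = False
    for _ in range(n_substeps):
        v = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u + drive)
        if v >= SPIKE_THRESHOLD_MV:
            # clamp the spike-time voltage so the u-update stays bounded
            # regardless of how far Euler overshot the threshold
            v = SPIKE_THRESHOLD_MV
            spiked = True
            break
        if v < -120.0:  # numerical guard against Euler undershoot
            v = -120.0
    u = u + dt_ms * params.a * (params.b * v - u)
    if spiked:
        v = params.c
        u = u + params.d

    if not (math.isfinite(v) and math.isfinite(u)):
        raise NumericalBlowupError(neuron, t)

    new = replace(state, v=v, u=u)
    if spiked:
        t_spike = t + dt
        if math.isfinite(state.last_spike_time):
            new.last_isi = t_spike - state.last_spike_time
        new.last_spike_time = t_spike
    return new, spiked


def excitability_update(
    state: NeuronState, params: NeuronParams, dt: float, spiked: bool
) -> NeuronState:
    """Advance the leaky rate estimate ``r`` and recompute the bias ``e``.

    ``r`` is a leaky integrator of the spike train with time constant
    ``tau_r``: it decays as exp(-dt/tau_r) and each spike adds ``1/tau_r``,
    so its stationary mean for a rate-f train is f (Hz).  The bias is the
    algebraic negative feedback ``e = e_ss - k_e * r``: sustained firing
    lowers excitability, quiescence restores it toward ``e_ss`` at the
    rate-estimator's time scale.
    """
    if not (dt > 0):
        raise ValueError("dt must be positive")
    r = state.r * math.exp(-dt / params.tau_r)
    if spiked:
        r += 1.0 / params.tau_r
    return replace(state, r=r, e=params.e_ss - params.k_e * r)
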