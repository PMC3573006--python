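"""Firing-rate homeostatic scaling of excitatory synapses.

Each neuron carries a multiplicative factor ``w_hom`` on its excitatory
(AMPA + NMDA) input currents.  The factor integrates the normalized rate
error toward a target rate r0:

    tau_h * dw_hom/dt = (r0 - r_inst) / r0

where ``r_inst`` is the instantaneous rate, the inverse of the latest
inter-spike interval.  Neurons firing above target are weakened, neurons
below target strengthened; ``w_hom`` is clipped at zero.  A silent neuron's
``r_inst`` goes stale: after ``stale_after`` seconds without a spike it is
reset to zero so that silence registers as below-target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HomeostasisState", "isi_rate_update", "homeostatic_step"]


@dataclass
class HomeostasisState:
    """Per-neuron homeostatic factors and instantaneous-rate bookkeeping."""

    n_neurons: int
    r0: float = 2.0  # target firing rate (Hz)
    tau_h: float = 60.0  # time constant of the scaling process (s)
    stale_after: float = 5.0  # r_inst horizon without spikes (s)
    enabled: bool = True
    relative_error: bool = True  # drive (r0-r)/r0; False -> absolute (r0-r)
    w_hom: np.ndarray = field(default=None)
    r_inst: np.ndarray = field(default=None)
    last_spike_time: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.tau_h <= 0 or self.r0 <= 0:
            raise ValueError("tau_h and r0 must be positive")
        if self.w_hom is None:
            self.w_hom = np.ones(self.n_neurons)
        if self.r_inst is None:
            self.r_inst = np.zeros(self.n_neurons)
        if self.last_spike_time is None:
            self.last_spike_time = np.full(self.n_neurons, -np.inf)


def isi_rate_update(
    h: HomeostasisState, neuron: int, spike_time: float, last_spike_time: float
) -> HomeostasisState:
    """Update a neuron's instantaneous rate from a new spike.

    ``r_inst = 1 / ISI``; a first-ever spike (no prior spike time) leaves
    ``r_inst`` unchanged since the ISI is undefined.
    """
    if np.isfinite(last_spike_time):
        if spike_time <= last_spike_time:
            raise ValueError("spike_time must exceed last_spike_time")
        h.r_inst[neuron] = 1.0 / (spike_time - last_spike_time)
    h.last_spike_time[neuron] = spike_time
    return h


def homeostatic_step(h: HomeostasisState, dt: float, t: float | None = None) -> HomeostasisState:
    """Advance every neuron's ``w_hom`` by one step of the scaling ODE.

    If ``t`` is given, neurons silent for longer than ``stale_after`` first
    have ``r_inst`` reset to zero.  The update sign strictly follows
    ``sign(r0 - r_inst)``; values are clipped at zero.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not h.enabled:
        return h
    if t is not None:
        stale = (t - h.last_spike_time) > h.stale_after
        h.r_inst[stale] = 0.0
    err = h.r0 - h.r_inst
    if h.relative_error:
        err = err / h.r0
    h.w_hom += (dt / h.tau_h) * err
    np.maximum(h.w_hom, 0.0, out=h.w_hom)
    return h
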