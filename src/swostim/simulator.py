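"""Time-stepping engine, LFP computation and UP/DOWN detection.

A simulation advances the whole lattice with the compiled kernel
(:mod:`swostim._kernel`): Izhikevich voltage/recovery updates, exponential
conductance decay, the slow excitability feedback that generates UP/DOWN
transitions, optional field injection and homeostatic scaling.  The model
LFP is the average post-synaptic current across neurons, zero-phase
low-pass filtered at 2.5 Hz; four 11x11 subregion LFPs play the role of
separate EEG electrodes.

Default excitability and coupling values were fixed by a calibration sweep
so that the unstimulated 900-neuron lattice oscillates in the slow-wave
band (0.5-1 Hz), fires at ~5 Hz in UP states, and loses cycle coherence
after ~3 cycles, matching human slow-wave EEG statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

from . import _kernel
from .dynamics import NeuronParams, SynapseKinetics
from .network import LatticeNetwork, build_lattice, sample_parameters, subregion_indices
from .plasticity import HomeostasisState
from .stimulation import (
    CouplingCalibration,
    FieldProfile,
    StimulusWaveform,
    calibrate_coupling,
    waveform_envelope,
)

__all__ = [
    "PlasticityConfig",
    "SimConfig",
    "SimResult",
    "run_simulation",
    "default_network",
    "compute_lfp",
    "population_rate",
    "detect_updown",
    "mean_up_rate",
]

# calibrated defaults (see docs/methods.md, "Calibration of the stated world")
DEFAULT_E_SS_EXC = 2.9
DEFAULT_E_SS_INH = 2.0
DEFAULT_NOISE_STD = 1.0


@dataclass(frozen=True)
class PlasticityConfig:
    """Homeostatic-scaling switches for a run (see :mod:`swostim.plasticity`).

    ``r0 = None`` means "calibrate": experiment drivers measure the
    network's own baseline mean instantaneous (ISI-based) rate and set the
    target to ``target_fraction`` of it, so every realization starts above
    target and downscales, as during early sleep.
    """

    enabled: bool = False
    r0: float | None = None
    tau_h: float = 3600.0
    stale_after: float = 5.0
    relative_error: bool = True
    target_fraction: float = 0.8


@dataclass
class SimConfig:
    """Everything needed to reproduce one simulation run."""

    net: LatticeNetwork
    duration_s: float = 60.0
    dt_ms: float = 0.5
    seed: int = 0
    e_ss_exc: float = DEFAULT_E_SS_EXC
    e_ss_inh: float = DEFAULT_E_SS_INH
    k_e: float = 6.0
    tau_r: float = 0.9
    noise_std: float = DEFAULT_NOISE_STD
    waveform: StimulusWaveform = field(default_factory=lambda: StimulusWaveform("sham"))
    profile: FieldProfile | None = None
    coupling: CouplingCalibration | None = None
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    lfp_cutoff: float = 2.5
    time_compression: float = 60.0  # simulated seconds -> night-equivalent: 1 min ~ 1 h
    record_stride: int = 100  # w_hom / rate series stride (steps)
    max_mean_rate: float = 40.0  # spike-buffer sizing cap (Hz per neuron)
    subregions: bool = True
    w_hom_init: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.dt_ms <= 0:
            raise ValueError("duration and dt must be positive")
        if self.lfp_cutoff <= 0:
            raise ValueError("lfp_cutoff must be positive")


@dataclass
class SimResult:
    """Raw and derived outputs of one run."""

    fs: float  # sample rate of the raw LFP series (Hz)
    duration_s: float
    seed: int
    spike_neurons: np.ndarray
    spike_times: np.ndarray
    lfp_raw: np.ndarray  # mean post-synaptic current, unfiltered
    lfp: np.ndarray  # low-pass filtered at lfp_cutoff
    lfp_subregions: np.ndarray  # (4, n_steps), filtered
    w_hom_mean: np.ndarray
    r_inst_mean: np.ndarray
    record_times: np.ndarray
    time_compression: float
    final_w_hom: np.ndarray
    n_neurons: int
    is_excitatory: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.lfp_raw.size) / self.fs


def default_network(seed: int = 0, **kwargs) -> LatticeNetwork:
    """30x30 lattice with jittered parameters — the baseline stated world."""
    net = build_lattice(seed=seed, **kwargs)
    return sample_parameters(net, cv=0.05, seed=seed + 1)


def run_simulation(cfg: SimConfig) -> SimResult:
    """Integrate the network and return LFPs, spikes and plasticity series."""
    net = cfg.net
    n = net.n_neurons
    kin = net.kinetics
    dt_ms = cfg.dt_ms
    n_steps = int(round(cfg.duration_s / (dt_ms * 1e-3)))
    fs = 1e3 / dt_ms

    e_ss = np.where(net.is_excitatory, cfg.e_ss_exc, cfg.e_ss_inh).astype(float)

    # field drive per neuron at unit envelope
    field_drive = np.zeros(n)
    if cfg.profile is not None and cfg.waveform.kind != "sham":
        cal = cfg.coupling
        if cal is None:
            cal = calibrate_coupling(NeuronParams())
        pcf = cfg.profile.per_column_field
        if pcf.size != net.n_cols:
            raise ValueError(
                f"field profile has {pcf.size} columns, lattice has {net.n_cols}"
            )
        cols = net.column_of()
        field_drive = np.where(
            net.is_excitatory,
            cfg.waveform.amplitude * pcf[cols] * cal.current_per_Vm,
            0.0,
        )

    envelope = waveform_envelope(cfg.waveform, np.arange(n_steps) * dt_ms * 1e-3)

    exc_indptr, exc_targets, exc_w = _kernel.out_csr(net.exc_edges, net.w_exc, n)
    inh_indptr, inh_targets, inh_w = _kernel.out_csr(net.inh_edges, net.w_inh, n)

    region_id = np.full(n, -1, dtype=np.int64)
    n_regions = 0
    if cfg.subregions and net.n_rows >= 22 and net.n_cols >= 22:
        blocks = subregion_indices(net, k=4, size=11)
        for q, idx in enumerate(blocks):
            region_id[idx] = q
        n_regions = len(blocks)

    # initial state: resting values; excitability starts at e_ss (fresh DOWN)
    b = net.abcd[:, 1]
    v0 = np.full(n, -70.0)
    u0 = b * v0
    r0_leaky = np.zeros(n)
    w_hom0 = (
        np.ones(n) if cfg.w_hom_init is None else np.asarray(cfg.w_hom_init, float)
    )

    max_spikes = int(n * cfg.duration_s * cfg.max_mean_rate)
    pl = cfg.plasticity
    if pl.enabled and pl.r0 is None:
        raise ValueError(
            "plasticity.r0 is None (auto); resolve it first, e.g. via "
            "experiments.calibrate_target_rate or night_run"
        )

    (
        lfp_raw,
        region_lfp,
        spike_neuron,
        spike_step,
        overflow,
        w_hom_mean,
        r_inst_mean,
        _v,
        _u,
        _r,
        w_hom_final,
    ) = _kernel.run_network(
        n_steps,
        dt_ms,
        np.ascontiguousarray(net.abcd[:, 0]),
        np.ascontiguousarray(net.abcd[:, 1]),
        np.ascontiguousarray(net.abcd[:, 2]),
        np.ascontiguousarray(net.abcd[:, 3]),
        e_ss,
        cfg.k_e,
        cfg.tau_r,
        net.is_excitatory,
        np.exp(-dt_ms / kin.tau_ampa),
        np.exp(-dt_ms / kin.tau_nmda),
        np.exp(-dt_ms / kin.tau_gabaa),
        np.exp(-dt_ms / kin.tau_gabab),
        kin.E_exc,
        kin.E_gabaa,
        kin.E_gabab,
        exc_indptr,
        exc_targets,
        exc_w,
        inh_indptr,
        inh_targets,
        inh_w,
        kin.nmda_frac,
        kin.gabab_frac,
        field_drive,
        envelope,
        cfg.noise_std,
        cfg.seed % (2**31),
        pl.enabled,
        0.0 if pl.r0 is None else pl.r0,
        pl.tau_h,
        pl.stale_after,
        pl.relative_error,
        w_hom0,
        region_id,
        n_regions,
        cfg.record_stride,
        max_spikes,
        v0,
        u0,
        r0_leaky,
    )
    if overflow:
        raise RuntimeError(
            "spike buffer overflow: mean rate exceeded max_mean_rate "
            f"({cfg.max_mean_rate} Hz); likely runaway excitation"
        )
    if not np.isfinite(lfp_raw).all():
        bad = int(np.flatnonzero(~np.isfinite(lfp_raw))[0])
        raise RuntimeError(f"numerical blowup at t={bad / fs:.3f} s")

    lfp = compute_lfp(lfp_raw, fs, cfg.lfp_cutoff)
    sub = (
        np.vstack([compute_lfp(x, fs, cfg.lfp_cutoff) for x in region_lfp])
        if n_regions
        else np.empty((0, n_steps))
    )

    return SimResult(
        fs=fs,
        duration_s=cfg.duration_s,
        seed=cfg.seed,
        spike_neurons=spike_neuron,
        spike_times=(spike_step + 1) * dt_ms * 1e-3,
        lfp_raw=lfp_raw,
        lfp=lfp,
        lfp_subregions=sub,
        w_hom_mean=w_hom_mean,
        r_inst_mean=r_inst_mean,
        record_times=np.arange(w_hom_mean.size) * cfg.record_stride * dt_ms * 1e-3,
        time_compression=cfg.time_compression,
        final_w_hom=w_hom_final,
        n_neurons=n,
        is_excitatory=net.is_excitatory,
    )


def compute_lfp(mean_current: np.ndarray, fs: float, cutoff: float = 2.5) -> np.ndarray:
    """Zero-phase low-pass filter of the mean post-synaptic current."""
    if np.allclose(mean_current, mean_current[0] if mean_current.size else 0.0):
        return np.asarray(mean_current, dtype=float).copy()
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, mean_current)


def population_rate(
    result: SimResult,
    bin_s: float = 0.005,
    smooth_s: float = 0.05,
    exc_only: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed population firing rate (Hz per neuron) from the spike raster."""
    n_bins = int(np.ceil(result.duration_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    if exc_only:
        mask = result.is_excitatory[result.spike_neurons]
        times = result.spike_times[mask]
        n_cells = int(result.is_excitatory.sum())
    else:
        times = result.spike_times
        n_cells = result.n_neurons
    counts, _ = np.histogram(times, bins=edges)
    rate = counts / (n_cells * bin_s)
    win = max(1, int(round(smooth_s / bin_s)))
    kernel = np.ones(win) / win
    return edges[:-1] + bin_s / 2, np.convolve(rate, kernel, mode="same")


def detect_updown(
    rate: np.ndarray,
    times: np.ndarray,
    hi_frac: float = 0.3,
    lo_frac: float = 0.1,
) -> list[tuple[str, float, float]]:
    """Hysteresis segmentation of the population rate into UP/DOWN intervals.

    UP onset when the smoothed rate exceeds ``hi_frac`` of its 90th
    percentile, offset when it drops below ``lo_frac`` of the same reference.
    Returns alternating ("up"/"down", start, end) intervals covering the
    series; an empty list if the rate never crosses threshold.
    """
    ref = np.percentile(rate, 90)
    if ref <= 0:
        return []
    hi, lo = hi_frac * ref, lo_frac * ref
    intervals: list[tuple[str, float, float]] = []
    state = "up" if rate[0] > hi else "down"
    start = times[0]
    for i in range(1, rate.size):
        if state == "down" and rate[i] > hi:
            intervals.append(("down", start, times[i]))
            state, start = "up", times[i]
        elif state == "up" and rate[i] < lo:
            intervals.append(("up", start, times[i]))
            state, start = "down", times[i]
    intervals.append((state, start, times[-1]))
    if all(s == intervals[0][0] for s, _, _ in intervals):
        return intervals if intervals[0][0] == "up" else []
    return intervals


def mean_up_rate(
    result: SimResult,
    discard_s: float = 5.0,
    **detect_kwargs,
) -> float:
    """Mean excitatory firing rate (Hz) inside detected UP states.

    The initial ``discard_s`` transient is excluded.  Detection runs on the
    all-neuron smoothed population rate; the average counts excitatory
    spikes per excitatory neuron per second of UP time.
    """
    times, rate = population_rate(result)
    keep = times >= discard_s
    intervals = detect_updown(rate[keep], times[keep], **detect_kwargs)
    ups = [(s, e) for lab, s, e in intervals if lab == "up"]
    total_up = sum(e - s for s, e in ups)
    if total_up <= 0:
        return 0.0
    mask = result.is_excitatory[result.spike_neurons]
    st = result.spike_times[mask]
    n_spk = sum(int(((st >= s) & (st < e)).sum()) for s, e in ups)
    n_exc = int(result.is_excitatory.sum())
    return n_spk / (n_exc * total_up)
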