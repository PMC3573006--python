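"""Flat YAML configuration for simulations.

Keys are grouped into sections (``neuron``, ``synapse``, ``network``,
``integrator``, ``stimulation``, ``plasticity``, ``simulation``); anything
omitted falls back to the calibrated defaults.  ``default_config()`` returns
the full defaults dict, which the CLI's ``show-config`` prints.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .dynamics import SynapseKinetics
from .network import build_lattice, sample_parameters
from .simulator import (
    DEFAULT_E_SS_EXC,
    DEFAULT_E_SS_INH,
    DEFAULT_NOISE_STD,
    PlasticityConfig,
    SimConfig,
)
from .stimulation import StimulusWaveform

__all__ = ["default_config", "load_config", "build_sim_config"]


def default_config() -> dict:
    kin = SynapseKinetics()
    return {
        "neuron": {
            "a_exc": 0.02, "b_exc": 0.2, "c_exc": -65.0, "d_exc": 8.0,
            "a_inh": 0.1, "b_inh": 0.2, "c_inh": -65.0, "d_inh": 2.0,
            "e_ss_exc": DEFAULT_E_SS_EXC,
            "e_ss_inh": DEFAULT_E_SS_INH,
            "k_e": 6.0,
            "tau_r": 0.9,
        },
        "synapse": {
            "tau_ampa": kin.tau_ampa, "tau_nmda": kin.tau_nmda,
            "tau_gabaa": kin.tau_gabaa, "tau_gabab": kin.tau_gabab,
            "E_exc": kin.E_exc, "E_gabaa": kin.E_gabaa, "E_gabab": kin.E_gabab,
            "w_exc_mean": kin.w_exc_mean, "w_inh_mean": kin.w_inh_mean,
            "nmda_frac": kin.nmda_frac, "gabab_frac": kin.gabab_frac,
        },
        "network": {
            "n_rows": 30, "n_cols": 30, "frac_inhibitory": 0.2,
            "param_cv": 0.05, "seed": 0,
        },
        "integrator": {"dt_ms": 0.5},
        "stimulation": {
            "kind": "sham", "frequency": 0.75, "amplitude": 0.31,
            "ramp_fraction": 0.1,
        },
        "plasticity": {
            "enabled": False, "r0": None, "tau_h": 3600.0, "stale_after": 5.0,
            "relative_error": True, "target_fraction": 0.8,
        },
        "simulation": {
            "duration_s": 60.0, "seed": 0, "noise_std": DEFAULT_NOISE_STD,
            "lfp_cutoff": 2.5, "time_compression": 60.0,
        },
    }


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML file (may be partial) over the defaults."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, vals in user.items():
            if section not in cfg:
                raise KeyError(f"unknown config section {section!r}")
            for k, v in vals.items():
                if k not in cfg[section]:
                    raise KeyError(f"unknown config key {section}.{k}")
                cfg[section][k] = v
    return cfg


def build_sim_config(cfg: dict) -> SimConfig:
    """Materialize a :class:`SimConfig` (network included) from a config dict."""
    syn = cfg["synapse"]
    kin = SynapseKinetics(**syn)
    netc = cfg["network"]
    net = build_lattice(
        netc["n_rows"], netc["n_cols"], netc["frac_inhibitory"], netc["seed"],
        kinetics=kin,
    )
    net = sample_parameters(net, netc["param_cv"], netc["seed"] + 1)
    stim = cfg["stimulation"]
    wf = StimulusWaveform(
        stim["kind"], stim["frequency"], stim["amplitude"], stim["ramp_fraction"]
    )
    pl = PlasticityConfig(**cfg["plasticity"])
    simc = cfg["simulation"]
    neuron = cfg["neuron"]
    return SimConfig(
        net=net,
        duration_s=simc["duration_s"],
        dt_ms=cfg["integrator"]["dt_ms"],
        seed=simc["seed"],
        e_ss_exc=neuron["e_ss_exc"],
        e_ss_inh=neuron["e_ss_inh"],
        k_e=neuron["k_e"],
        tau_r=neuron["tau_r"],
        noise_std=simc["noise_std"],
        waveform=wf,
        plasticity=pl,
        lfp_cutoff=simc["lfp_cutoff"],
        time_compression=simc["time_compression"],
    )
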