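"""Synthetic multi-channel sleep-EEG generator with programmed decay rates.

The human overnight recordings this package's analysis targets are not
publicly deposited, so the analysis pipeline is exercised on surrogate
signals whose ground truth is known by construction: every channel mixes a
*shared* narrowband slow-wave source with a per-channel *independent* one,

    x_k(t) = env(t) * [ sqrt(rho(t) P(t)) s(t) + sqrt((1-rho(t)) P(t)) n_k(t) ]
             + noise_floor,

where the sources are unit-variance band-limited (0.5-1 Hz) noise.  The
total band power P(t) follows the programmed exponential decay
(``power_decay`` dB/hour) and the shared band-power fraction rho(t) is
scheduled so that the pairwise magnitude-squared coherence rho(t)^2 decays
at ``coherence_decay`` dB/hour.  A multiplicative envelope with ~90-minute
period emulates non-REM/REM cycling; it averages out of the robust decay
fits.  All randomness is seed-deterministic, and the programmed slopes are
emitted alongside the signals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = ["SynthEEGConfig", "generate_eeg", "generate_condition_pair", "save_eeg_text", "load_eeg_text"]


@dataclass(frozen=True)
class SynthEEGConfig:
    """Stated world of one synthetic overnight recording."""

    n_channels: int = 11
    fs: float = 20.0
    duration_h: float = 7.0
    power_decay: float = -1.22  # dB/hour, SWO band
    coherence_decay: float = -0.70  # dB/hour of the squared coherence
    swo_band: tuple[float, float] = (0.5, 1.0)
    rho0: float = 0.8  # initial shared band-power fraction
    p0: float = 1.0  # initial per-channel band power (signal units^2)
    cycle_period_min: float = 84.0  # non-REM/REM cycle; 5 cycles in 7 h
    cycle_depth_db: float = 6.0  # peak-to-trough band-power swing (dB)
    noise_floor: float = 0.1  # broadband noise amplitude relative to sqrt(p0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 4 * self.swo_band[1] / 2:
            raise ValueError("fs must exceed twice the band upper edge comfortably")
        if not (0 < self.rho0 <= 1):
            raise ValueError("rho0 must be in (0, 1]")


def _narrowband(n: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / y.std()


def generate_eeg(cfg: SynthEEGConfig) -> tuple[np.ndarray, dict]:
    """Generate channels (n_channels, n_samples) plus the ground-truth record.

    Raises if the programmed decay combination is infeasible (the shared
    fraction would have to exceed 1 at any time).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_h * 3600 * cfg.fs))
    t_h = np.arange(n) / cfg.fs / 3600.0

    p_t = cfg.p0 * 10.0 ** (cfg.power_decay * t_h / 10.0)
    # squared coherence rho^2 decays at coherence_decay dB/h
    rho_t = cfg.rho0 * 10.0 ** (cfg.coherence_decay * t_h / 20.0)
    if np.any(rho_t > 1.0):
        raise ValueError("infeasible decay combination: shared fraction exceeds 1")

    # non-REM/REM cycling as a cosine in log-power, peaking at sleep onset:
    # over whole cycles a cosine is orthogonal to the linear time trend (a
    # sine is not), so the fitted decay slope stays unbiased; the shift to
    # (cos - 1) makes env(0) = 1 so the initial band power equals p0, at
    # the cost of a constant (slope-neutral) dB offset
    env = 10.0 ** (
        (cfg.cycle_depth_db / 2.0)
        * (np.cos(2 * np.pi * t_h * 60.0 / cfg.cycle_period_min) - 1.0)
        / 20.0
    )

    shared = _narrowband(n, cfg.fs, cfg.swo_band, rng)
    chans = np.empty((cfg.n_channels, n))
    for k in range(cfg.n_channels):
        own = _narrowband(n, cfg.fs, cfg.swo_band, rng)
        sig = np.sqrt(rho_t * p_t) * shared + np.sqrt((1.0 - rho_t) * p_t) * own
        chans[k] = env * sig + cfg.noise_floor * np.sqrt(cfg.p0) * rng.standard_normal(n)

    truth = {
        "power_decay_db_per_h": cfg.power_decay,
        "coherence_decay_db_per_h": cfg.coherence_decay,
        "rho0": cfg.rho0,
        "p0": cfg.p0,
        "seed": cfg.seed,
        "fs": cfg.fs,
        "duration_h": cfg.duration_h,
    }
    return chans, truth


def generate_condition_pair(
    cfg: SynthEEGConfig,
    sham_slope: float,
    stim_slope: float,
    n_subjects: int = 10,
    subject_sd: float = 0.3,
    seed: int = 0,
):
    """Paired synthetic "study": per-subject sham/stim recordings.

    Each subject's two recordings share a subject-level random offset on the
    programmed power slope (SD ``subject_sd`` dB/h) plus the condition
    difference, enabling end-to-end rehearsal of the paired shuffle test.
    Returns a list of dicts with keys ``sham``/``stim`` (channel arrays) and
    ``truth`` (programmed slopes).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_subjects):
        offset = subject_sd * rng.standard_normal()
        rec = {}
        for cond, slope in (("sham", sham_slope), ("stim", stim_slope)):
            c = SynthEEGConfig(
                n_channels=cfg.n_channels,
                fs=cfg.fs,
                duration_h=cfg.duration_h,
                power_decay=slope + offset,
                coherence_decay=cfg.coherence_decay,
                rho0=cfg.rho0,
                p0=cfg.p0,
                cycle_period_min=cfg.cycle_period_min,
                cycle_depth_db=cfg.cycle_depth_db,
                noise_floor=cfg.noise_floor,
                seed=int(rng.integers(2**31)),
            )
            rec[cond], rec[f"{cond}_truth"] = generate_eeg(c)
        rec["truth"] = {"sham_slope": sham_slope + offset, "stim_slope": stim_slope + offset}
        out.append(rec)
    return out


def save_eeg_text(path: str | Path, chans: np.ndarray, fs: float, truth: dict | None = None) -> None:
    """Write channels as delimited text with a sample-rate header line; the
    ground truth goes into a JSON sidecar ``<path>.json``."""
    path = Path(path)
    header = f"fs_hz={fs}\t" + "\t".join(f"ch{k}" for k in range(chans.shape[0]))
    np.savetxt(path, chans.T, delimiter="\t", header=header, comments="# ")
    if truth is not None:
        Path(str(path) + ".json").write_text(json.dumps(truth, indent=1))


def load_eeg_text(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a delimited-text EEG file written by :func:`save_eeg_text`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    fs = float(header.split("fs_hz=")[1].split()[0])
    data = np.loadtxt(path)
    return data.T, fs
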