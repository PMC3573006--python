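"""EEG/LFP analysis: windowed band power, spatial coherence, robust decay
fits, paired shuffle statistics, FDR and entrainment measures.

The same pipeline applies to simulated subregion LFPs and to (synthetic)
multi-channel sleep EEG: band power is measured per 40-s window as the sum
of periodogram power over the slow-wave band (SWO 0.5-1 Hz by default);
spatial coherence is the band-averaged, power-normalized similarity of
channel pairs; overnight decay is the slope of these series in dB against
time in hours, from a robust (IRLS, Tukey bisquare) line fit; condition
differences use a paired label-shuffle test with Benjamini-Hochberg FDR
across electrodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import statsmodels.api as sm
from scipy import signal as sps

__all__ = [
    "SpectralSeries",
    "DecayFit",
    "band_power_series",
    "spatial_coherence_series",
    "decay_rate",
    "paired_shuffle_test",
    "fdr_bh",
    "phase_locking",
    "rayleigh_p",
    "dominant_frequency",
    "coherence_time",
    "to_db",
]

SWO_BAND = (0.5, 1.0)
SWA_BAND = (0.5, 4.0)


def to_db(linear: np.ndarray) -> np.ndarray:
    """10*log10 of nonnegative band values; zeros become NaN (masked)."""
    linear = np.asarray(linear, dtype=float)
    out = np.full_like(linear, np.nan)
    pos = linear > 0
    out[pos] = 10.0 * np.log10(linear[pos])
    return out


@dataclass
class SpectralSeries:
    """Per-window band power or coherence for one channel."""

    times: np.ndarray  # window centers (s)
    values: np.ndarray  # linear scale, >= 0
    band: tuple[float, float]
    window_len: float
    channel: str = "ch0"

    @property
    def db(self) -> np.ndarray:
        return to_db(self.values)


@dataclass(frozen=True)
class DecayFit:
    """Robust line fit of a dB series against time in hours."""

    slope: float  # dB/hour
    intercept: float  # dB
    fit_window: tuple[float, float]  # hours
    method: str
    n_windows: int
    residual_scale: float


def _band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return (freqs >= lo) & (freqs <= hi)


def band_power_series(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = SWO_BAND,
    window_len: float = 40.0,
    channel: str = "ch0",
) -> SpectralSeries:
    """Band power per non-overlapping window (plain rectangular periodogram).

    Power is summed over the periodogram bins inside ``band`` with a
    one-sided amplitude normalization, so a pure in-band sinusoid of
    amplitude A contributes A^2/2 and white noise contributes its variance
    times the band fraction (Parseval).
    """
    x = np.asarray(x, dtype=float)
    if band[1] >= fs / 2:
        raise ValueError("band upper edge must be below Nyquist")
    nper = int(round(window_len * fs))
    if x.size < nper:
        raise ValueError("signal shorter than one window")
    n_win = x.size // nper
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    mask = _band_bins(freqs, band)
    times = (np.arange(n_win) + 0.5) * window_len
    vals = np.empty(n_win)
    for w in range(n_win):
        seg = x[w * nper : (w + 1) * nper]
        seg = seg - seg.mean()
        spec = np.abs(np.fft.rfft(seg)) ** 2 * (2.0 / nper**2)
        spec[0] /= 2.0
        if nper % 2 == 0:
            spec[-1] /= 2.0
        vals[w] = spec[mask].sum()
    return SpectralSeries(times, vals, band, window_len, channel)


def spatial_coherence_series(
    signals: np.ndarray,
    fs: float,
    band: tuple[float, float] = SWO_BAND,
    window_len: float = 40.0,
    seg_len: float = 8.0,
    channels: list[str] | None = None,
    debias: bool = True,
) -> list[SpectralSeries]:
    """Per-channel spatial coherence over sliding 40-s windows.

    Within each window, every channel pair's magnitude-squared coherence
    (Welch sub-segments of ``seg_len`` seconds, 50% overlap) is averaged
    over the band bins; each channel's value is the mean over all pairs
    involving it.  Being power-normalized, the measure is invariant to
    per-channel amplitude rescaling and bounded in [0, 1].  ``debias``
    applies the standard small-sample correction (L*C - 1)/(L - 1) for L
    averaged segments, which removes the upward bias of the null.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n_samp = signals.shape
    if n_ch < 2:
        raise ValueError("need at least 2 channels for spatial coherence")
    nper = int(round(window_len * fs))
    nseg = int(round(seg_len * fs))
    nover = nseg // 2
    n_win = n_samp // nper
    if n_win < 1:
        raise ValueError("signal shorter than one window")
    n_avg = max(1, (nper - nover) // (nseg - nover))

    times = (np.arange(n_win) + 0.5) * window_len
    pair_vals = {}
    freqs = None
    for i, j in combinations(range(n_ch), 2):
        vals = np.empty(n_win)
        for w in range(n_win):
            sl = slice(w * nper, (w + 1) * nper)
            freqs, cxy = sps.coherence(
                signals[i, sl], signals[j, sl], fs=fs, nperseg=nseg, noverlap=nover
            )
            c = cxy[_band_bins(freqs, band)].mean()
            if debias and n_avg > 1:
                c = (n_avg * c - 1.0) / (n_avg - 1.0)
            vals[w] = min(max(c, 0.0), 1.0)
        pair_vals[(i, j)] = vals

    if channels is None:
        channels = [f"ch{k}" for k in range(n_ch)]
    out = []
    for k in range(n_ch):
        mine = [v for (i, j), v in pair_vals.items() if k in (i, j)]
        out.append(
            SpectralSeries(times, np.mean(mine, axis=0), band, window_len, channels[k])
        )
    return out


def decay_rate(
    db_values: np.ndarray,
    times_hours: np.ndarray,
    fit_window: tuple[float, float] | None = None,
    min_windows: int = 10,
) -> DecayFit:
    """Robust slope (dB/hour) of a dB series against time in hours.

    IRLS with Tukey bisquare weights (c = 4.685) via statsmodels RLM; an
    exact line (zero residuals) falls back to ordinary least squares.  NaN
    values (masked zero-power windows) are dropped.
    """
    y = np.asarray(db_values, dtype=float)
    t = np.asarray(times_hours, dtype=float)
    keep = np.isfinite(y) & np.isfinite(t)
    if fit_window is not None:
        keep &= (t >= fit_window[0]) & (t <= fit_window[1])
    y, t = y[keep], t[keep]
    if y.size < min_windows:
        raise ValueError(
            f"only {y.size} finite windows inside fit window; need >= {min_windows}"
        )
    X = sm.add_constant(t)
    ols = sm.OLS(y, X).fit()
    if np.allclose(ols.resid, 0.0, atol=1e-10):
        return DecayFit(
            slope=float(ols.params[1]),
            intercept=float(ols.params[0]),
            fit_window=(float(t.min()), float(t.max())),
            method="ols-exact",
            n_windows=int(y.size),
            residual_scale=0.0,
        )
    rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit()
    return DecayFit(
        slope=float(rlm.params[1]),
        intercept=float(rlm.params[0]),
        fit_window=(float(t.min()), float(t.max())),
        method="rlm-bisquare-4.685",
        n_windows=int(y.size),
        residual_scale=float(rlm.scale),
    )


def paired_shuffle_test(
    sham: np.ndarray,
    stim: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Two-sided paired permutation test on the mean condition difference.

    Within-pair label swaps flip the sign of each subject's difference.  All
    2^n sign patterns are enumerated when feasible (2^n <= n_perm); otherwise
    ``n_perm`` random patterns are sampled with the add-one correction
    p = (b + 1)/(n_perm + 1).
    """
    sham = np.asarray(sham, dtype=float)
    stim = np.asarray(stim, dtype=float)
    if sham.shape != stim.shape or sham.size < 2:
        raise ValueError("need equal-length paired vectors of size >= 2")
    d = stim - sham
    n = d.size
    obs = abs(d.mean())
    tol = 1e-12 * (1.0 + obs)
    if 2**n <= n_perm:
        signs = np.array(
            [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2**n)],
            dtype=float,
        )
        means = np.abs(signs @ d) / n
        return float(np.mean(means >= obs - tol))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = np.abs(signs @ d) / n
    b = int(np.sum(means >= obs - tol))
    return (b + 1) / (n_perm + 1)


def fdr_bh(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up: (reject mask, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = sm.stats.multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def rayleigh_p(phases: np.ndarray) -> float:
    """Rayleigh test of circular uniformity (standard approximation)."""
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    R = abs(np.exp(1j * phases).mean()) * n
    z = R * R / n
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - R * R)) - (1.0 + 2.0 * n))
    return min(1.0, p)


def phase_locking(
    lfp: np.ndarray,
    fs: float,
    onset_times: np.ndarray,
    band: tuple[float, float] = SWO_BAND,
) -> tuple[float, float, float]:
    """Phase locking of the LFP to a periodic stimulus landmark.

    The LFP is band-filtered, its instantaneous phase taken from the
    analytic signal, and sampled at each stimulus ON onset.  Returns
    ``(plv, mean_phase_rad, rayleigh_p)`` where PLV is the mean vector
    strength (1 = perfect locking).
    """
    onset_times = np.asarray(onset_times, dtype=float)
    if onset_times.size < 10:
        raise ValueError("need at least 10 stimulus cycles")
    sos = sps.butter(3, band, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, np.asarray(lfp, dtype=float))
    phase = np.angle(sps.hilbert(filt))
    idx = np.clip(np.round(onset_times * fs).astype(int), 0, phase.size - 1)
    ph = phase[idx]
    vec = np.exp(1j * ph).mean()
    return abs(vec), float(np.angle(vec)), rayleigh_p(ph)


def dominant_frequency(
    x: np.ndarray,
    fs: float,
    fmin: float = 0.1,
    fmax: float = 4.0,
    nperseg_s: float = 40.0,
) -> float:
    """Frequency of the Welch spectral peak within [fmin, fmax] Hz."""
    x = np.asarray(x, dtype=float)
    nper = min(x.size, int(round(nperseg_s * fs)))
    freqs, psd = sps.welch(x, fs=fs, nperseg=nper, detrend="linear")
    mask = (freqs >= fmin) & (freqs <= fmax)
    if not mask.any():
        raise ValueError("no spectral bins inside the requested range")
    return float(freqs[mask][np.argmax(psd[mask])])


def coherence_time(
    x: np.ndarray,
    fs: float,
    f0: float | None = None,
    max_cycles: int = 12,
    min_peak: float = 0.15,
) -> float:
    """Oscillation coherence time in cycles, from the autocorrelation envelope.

    The normalized autocorrelation of the (slow-wave) signal shows peaks at
    multiples of the oscillation period whose heights decay roughly
    exponentially; an exponential fit to those peak heights gives a decay
    constant tau, reported as tau * f0 cycles.  Drift slower than a third of
    the oscillation frequency is removed first so the envelope reflects
    cycle-to-cycle phase coherence rather than baseline wander.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if f0 is None:
        f0 = dominant_frequency(x, fs)
    # remove drift below the oscillatory band so baseline wander does not
    # masquerade as long-range coherence
    sos = sps.butter(2, f0 / 3.0, btype="high", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    n = x.size
    ac = sps.fftconvolve(x, x[::-1], mode="full")[n - 1 :]
    ac /= ac[0]
    period = int(round(fs / f0))
    max_lag = min(ac.size - 1, max_cycles * period)
    peaks, _ = sps.find_peaks(
        ac[: max_lag + 1], distance=int(0.6 * period), height=min_peak
    )
    # the sample autocorrelation flattens onto a pedestal at long lags
    # (finite-record noise plus slow rate fluctuations that are not cycle
    # coherence); estimate it from the tail and fit only peaks clearly
    # above it, stopping once the decay stalls
    tail = np.abs(ac[min(10 * period, ac.size // 2) : min(20 * period, ac.size)])
    pedestal = float(np.median(tail)) if tail.size else 0.0
    floor = max(min_peak, 1.3 * pedestal)
    lags, heights = [], []
    for p in peaks:
        h = float(ac[p])
        if h < floor or (heights and h >= 0.95 * heights[-1]):
            break
        lags.append(p / fs)
        heights.append(h)
    if len(lags) < 2:
        return 1.0 if len(lags) == 1 else 0.5
    slope = np.polyfit(lags, np.log(heights), 1)[0]
    if slope >= 0:
        return float("inf")
    tau = -1.0 / slope
    return tau * f0
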