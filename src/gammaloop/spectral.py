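"""Multitaper spectral estimation, band power, and circular phase statistics.

Power spectra and coherence follow the classic sliding-window multitaper
recipe: the signal is cut into 3 s windows with 50% overlap, each window is
demeaned and tapered with the discrete prolate spheroidal sequences (DPSS),
and per-taper periodograms are averaged over tapers and windows.  Defaults
(time-bandwidth 3, 5 tapers) follow the common convention of multitaper
toolboxes in systems neuroscience.  Coherence is reported as magnitude (not
squared) with the cross-spectral phase.

Band power time courses are computed as zero-phase band-pass filtering
followed by per-window RMS; inter-regional phase lags come from the
analytic-signal instantaneous phase difference, summarized with circular
statistics over high-amplitude epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "SpectralEstimate",
    "BandPowerSeries",
    "multitaper_psd",
    "multitaper_coherence",
    "band_rms_series",
    "power_change",
    "phase_lag",
    "circular_mean_resultant",
]

GAMMA_BAND_HZ = (30.0, 80.0)


@dataclass
class SpectralEstimate:
    """Frequency grid with power density or coherence, plus windowing provenance.

    ``values`` is a one-sided power density (units^2/Hz) for kind="psd", or a
    coherence magnitude in [0, 1] for kind="coherence" (``phase_rad`` then
    carries the cross-spectral phase in (-pi, pi]).
    """

    freqs_hz: np.ndarray
    values: np.ndarray
    kind: str  # "psd" | "coherence"
    window_s: float
    overlap_frac: float
    time_bandwidth: float
    n_tapers: int
    n_windows: int
    phase_rad: np.ndarray | None = None

    def band_mean(self, band_hz: tuple[float, float]) -> float:
        lo, hi = band_hz
        mask = (self.freqs_hz >= lo) & (self.freqs_hz <= hi)
        return float(np.mean(self.values[mask]))

    def total_power(self) -> float:
        """Integral of the density over frequency (trapezoid-free Riemann sum)."""
        df = self.freqs_hz[1] - self.freqs_hz[0]
        return float(np.sum(self.values) * df)


@dataclass
class BandPowerSeries:
    """Windowed band-limited RMS power versus time (window centers)."""

    times_s: np.ndarray
    rms: np.ndarray
    band_hz: tuple[float, float] = GAMMA_BAND_HZ
    window_s: float = 0.05
    step_s: float = 0.05

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.rms = np.asarray(self.rms, dtype=float)
        if self.times_s.shape != self.rms.shape:
            raise ValueError("times_s and rms must have equal length")
        if np.any(self.rms < 0):
            raise ValueError("rms power must be non-negative")
        if self.times_s.size > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.rms)


def _sliding_windows(n: int, win: int, step: int) -> range:
    if n < win:
        raise ValueError(f"signal length {n} shorter than one window ({win} samples)")
    return range(0, n - win + 1, step)


def _multitaper_spectra(
    x: np.ndarray,
    sampling_rate_hz: float,
    window_s: float,
    overlap_frac: float,
    time_bandwidth: float,
    n_tapers: int,
):
    """Per-window, per-taper one-sided spectra of ``x``.

    Returns (freqs, X) with X of shape (n_windows, n_tapers, n_freqs); each
    row is the rFFT of a demeaned, unit-energy-tapered window, scaled so that
    |X|^2 summed over the one-sided grid times df equals the window variance.
    """
    x = np.asarray(x, dtype=float)
    if n_tapers > 2 * time_bandwidth - 1:
        raise ValueError(
            f"n_tapers={n_tapers} exceeds 2*time_bandwidth-1={2 * time_bandwidth - 1:g}"
        )
    win = int(round(window_s * sampling_rate_hz))
    step = max(1, int(round(win * (1.0 - overlap_frac))))
    starts = _sliding_windows(x.size, win, step)

    tapers = signal.windows.dpss(win, time_bandwidth, Kmax=n_tapers)  # unit energy
    freqs = np.fft.rfftfreq(win, d=1.0 / sampling_rate_hz)

    segs = np.stack([x[s : s + win] for s in starts])
    segs = segs - segs.mean(axis=1, keepdims=True)
    # (n_windows, n_tapers, win) -> rFFT along time
    tapered = segs[:, None, :] * tapers[None, :, :]
    X = np.fft.rfft(tapered, axis=-1)
    # one-sided scaling: double everything except DC (and Nyquist when win even)
    scale = np.full(freqs.size, 2.0 / sampling_rate_hz)
    scale[0] = 1.0 / sampling_rate_hz
    if win % 2 == 0:
        scale[-1] = 1.0 / sampling_rate_hz
    X = X * np.sqrt(scale)
    return freqs, X


def multitaper_psd(
    x: np.ndarray,
    sampling_rate_hz: float,
    window_s: float = 3.0,
    overlap_frac: float = 0.5,
    time_bandwidth: float = 3.0,
    n_tapers: int = 5,
) -> SpectralEstimate:
    """Multitaper power spectral density averaged over sliding windows.

    The density is normalized so that its integral over frequency
    approximates the signal variance (Parseval).
    """
    freqs, X = _multitaper_spectra(
        x, sampling_rate_hz, window_s, overlap_frac, time_bandwidth, n_tapers
    )
    psd = np.mean(np.abs(X) ** 2, axis=(0, 1))
    return SpectralEstimate(
        freqs_hz=freqs,
        values=psd,
        kind="psd",
        window_s=window_s,
        overlap_frac=overlap_frac,
        time_bandwidth=time_bandwidth,
        n_tapers=n_tapers,
        n_windows=X.shape[0],
    )


def multitaper_coherence(
    x: np.ndarray,
    y: np.ndarray,
    sampling_rate_hz: float,
    window_s: float = 3.0,
    overlap_frac: float = 0.5,
    time_bandwidth: float = 3.0,
    n_tapers: int = 5,
) -> SpectralEstimate:
    """Magnitude coherence and cross-spectral phase between two signals.

    Cross- and auto-spectra are averaged over all window x taper products
    before normalization.  The phase convention is arg<X Y*>: positive phase
    means ``y`` lags ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    freqs, X = _multitaper_spectra(
        x, sampling_rate_hz, window_s, overlap_frac, time_bandwidth, n_tapers
    )
    _, Y = _multitaper_spectra(
        y, sampling_rate_hz, window_s, overlap_frac, time_bandwidth, n_tapers
    )
    if X.shape[0] * X.shape[1] < 2:
        raise ValueError(
            "coherence undefined from a single window-taper product; "
            "use more windows or tapers"
        )
    Sxy = np.mean(X * np.conj(Y), axis=(0, 1))
    Sxx = np.mean(np.abs(X) ** 2, axis=(0, 1))
    Syy = np.mean(np.abs(Y) ** 2, axis=(0, 1))
    denom = np.sqrt(Sxx * Syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(Sxy) / denom
    coh = np.nan_to_num(np.clip(coh, 0.0, 1.0))
    return SpectralEstimate(
        freqs_hz=freqs,
        values=coh,
        kind="coherence",
        window_s=window_s,
        overlap_frac=overlap_frac,
        time_bandwidth=time_bandwidth,
        n_tapers=n_tapers,
        n_windows=X.shape[0],
        phase_rad=np.angle(Sxy),
    )


def band_rms_series(
    x: np.ndarray,
    sampling_rate_hz: float,
    band_hz: tuple[float, float] = GAMMA_BAND_HZ,
    window_s: float = 0.05,
    step_s: float = 0.05,
    filter_order: int = 8,
) -> BandPowerSeries:
    """Zero-phase band-pass then per-window RMS (gamma power time course)."""
    from .gamma_events import band_filter_zero_phase, sliding_rms

    filtered = band_filter_zero_phase(x, sampling_rate_hz, band_hz, order=filter_order)
    series = sliding_rms(filtered, sampling_rate_hz, window_s=window_s, step_s=step_s)
    series.band_hz = band_hz
    return series


def power_change(pre_power: float, post_power: float) -> float:
    """Relative power change (post - pre) / pre, dimensionless and signed.

    This is the quantity used to relate a gamma-suppressing intervention to
    behaviour: averaged band power after the intervention versus before.
    """
    if pre_power < 0 or post_power < 0:
        raise ValueError("powers must be non-negative")
    if pre_power == 0:
        raise ZeroDivisionError("pre_power is zero; power change undefined")
    return (post_power - pre_power) / pre_power


def circular_mean_resultant(angles_rad: np.ndarray) -> tuple[float, float]:
    """Circular mean in (-pi, pi] and resultant length in [0, 1]."""
    angles_rad = np.asarray(angles_rad, dtype=float)
    if angles_rad.size == 0:
        raise ValueError("no angles supplied")
    z = np.mean(np.exp(1j * angles_rad))
    return float(np.angle(z)), float(np.abs(z))


def phase_lag(
    x: np.ndarray,
    y: np.ndarray,
    sampling_rate_hz: float,
    band_hz: tuple[float, float] = GAMMA_BAND_HZ,
    filter_order: int = 8,
) -> tuple[float, float]:
    """Band-limited instantaneous phase lag of ``y`` behind ``x``.

    Both signals are zero-phase band-passed; the per-sample difference of
    analytic-signal phases (phase_x - phase_y, so a delayed y gives a
    positive lag) is summarized by its circular mean and resultant length.
    Only high-amplitude epochs contribute: samples where the joint envelope
    (geometric mean of the two Hilbert envelopes) exceeds its median.
    """
    from .gamma_events import band_filter_zero_phase

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    min_len = int(np.ceil(10 * sampling_rate_hz / band_hz[0]))
    if x.size < min_len:
        raise ValueError(f"need at least 10 cycles of the band ({min_len} samples)")
    if not (np.any(x) and np.any(y)):
        raise ValueError("all-zero input: instantaneous phase undefined")

    xf = band_filter_zero_phase(x, sampling_rate_hz, band_hz, order=filter_order)
    yf = band_filter_zero_phase(y, sampling_rate_hz, band_hz, order=filter_order)
    ax = signal.hilbert(xf)
    ay = signal.hilbert(yf)
    dphi = np.angle(ax * np.conj(ay))
    env = np.sqrt(np.abs(ax) * np.abs(ay))
    mask = env > np.median(env)
    return circular_mean_resultant(dphi[mask])
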