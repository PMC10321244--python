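"""Synthetic multichannel LFP with labeled ground truth.

Emulates the statistical structure an implanted four-site rodent montage
(olfactory bulb, left/right piriform cortex, and a lateral-entorhinal /
ventral-hippocampal reference) presents to the analysis chain:

* per-channel 1/f^beta background noise (spectrally shaped white noise,
  exact slope control, RMS-normalized);
* transient gamma bursts (Poisson arrivals, hann envelopes, frequencies
  drawn inside the 30-80 Hz band) injected on the OB channel and reproduced
  on both PirC channels with a fixed conduction lag, mimicking coherent
  OB-to-PirC gamma transmission;
* broadband common-mode artifacts (EMG-like noise transients) added
  identically to every channel, the disturbance reference subtraction is
  meant to cancel.

Construction is strictly additive (background + bursts + artifacts) and
fully deterministic given the seed; every injected burst and artifact is
returned as ground truth so detector performance can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gamma_events import band_filter_zero_phase
from .lfp_io import ChannelMeta, Recording, RegionRole

__all__ = [
    "BurstSpec",
    "SynthConfig",
    "GroundTruth",
    "MONTAGE",
    "generate_background",
    "generate_recording",
    "write_ground_truth",
    "read_ground_truth",
]

# Implanted montage emulated throughout: gamma source, bilateral target, reference.
MONTAGE = (
    ChannelMeta("OB", RegionRole.OB),
    ChannelMeta("PIRC_LEFT", RegionRole.PIRC_LEFT),
    ChannelMeta("PIRC_RIGHT", RegionRole.PIRC_RIGHT),
    ChannelMeta("REF_LEC_VHIP", RegionRole.REF_LEC_VHIP),
)


@dataclass(frozen=True)
class BurstSpec:
    """One injected gamma burst.

    ``amplitude`` is the peak sinusoid amplitude in the same units as the
    background; ``lag_s`` is the delay applied where the burst is reproduced
    on non-source (PirC) channels; ``target_channels`` lists every channel
    that receives the burst (the first entry is the undelayed source).
    """

    onset_s: float
    duration_s: float
    freq_hz: float
    amplitude: float
    envelope: str = "hann"
    target_channels: tuple[str, ...] = ("OB", "PIRC_LEFT", "PIRC_RIGHT")
    lag_s: float = 0.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.onset_s < 0 or self.duration_s <= 0 or self.amplitude <= 0:
            raise ValueError("onset_s >= 0, duration_s > 0, amplitude > 0 required")
        if not 30.0 <= self.freq_hz <= 80.0:
            raise ValueError(f"freq_hz {self.freq_hz} outside the 30-80 Hz gamma band")
        if self.envelope not in ("hann", "flat"):
            raise ValueError("envelope must be 'hann' or 'flat'")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic recording.

    ``burst_amplitude_snr`` is the peak burst amplitude divided by the RMS
    of the background inside the 30-80 Hz band, i.e. the amplitude SNR the
    detector faces.  ``background_exponent`` is the slope beta of the
    1/f^beta background power spectrum (1 = pink noise).  Amplitudes are in
    arbitrary units; only ratios matter to every consumer.
    """

    duration_s: float = 60.0
    sampling_rate_hz: float = 1250.0
    background_exponent: float = 1.0
    background_rms: float = 1.0
    burst_rate_hz: float = 0.2
    burst_duration_dist: tuple[float, float] = (0.3, 0.5)
    burst_amplitude_snr: float = 5.0
    burst_freq_dist: tuple[float, float] = (35.0, 75.0)
    artifact_rate_hz: float = 0.05
    artifact_amplitude: float = 20.0
    artifact_duration_s: float = 0.1
    ob_to_pirc_lag_s: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.sampling_rate_hz < 220.0:
            raise ValueError("sampling_rate_hz must be >= 220 Hz (2 x 110 Hz)")
        if self.burst_rate_hz < 0 or self.artifact_rate_hz < 0:
            raise ValueError("rates must be >= 0")
        if self.background_rms < 0:
            raise ValueError("background_rms must be >= 0")
        lo, hi = self.burst_duration_dist
        if not 0 < lo <= hi:
            raise ValueError("burst_duration_dist must satisfy 0 < min <= max")


@dataclass
class GroundTruth:
    """Everything injected into a synthetic recording."""

    bursts: list[BurstSpec]
    artifacts: list[tuple[float, float]]  # (onset_s, duration_s)
    config: SynthConfig

    def burst_intervals(self) -> np.ndarray:
        if not self.bursts:
            return np.empty((0, 2))
        return np.array([[b.onset_s, b.offset_s] for b in self.bursts])


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, beta: float) -> np.ndarray:
    """Unit-RMS noise with PSD proportional to 1/f^beta above 1 Hz.

    White Gaussian noise is shaped in the frequency domain; below 1 Hz the
    shaping is held flat at its 1 Hz value to keep the variance finite, and
    DC is removed.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f_eff = np.maximum(f, 1.0)
    spec *= f_eff ** (-beta / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_background(config: SynthConfig, n_channels: int = 4) -> Recording:
    """Independent 1/f^beta background noise per channel, RMS-normalized.

    Deterministic given ``config.seed``; each channel draws from its own
    seeded sub-stream, so adding channels never perturbs existing ones.
    """
    n = int(round(config.duration_s * config.sampling_rate_hz))
    children = np.random.SeedSequence([config.seed, 0]).spawn(n_channels)
    samples = np.empty((n_channels, n))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if config.background_rms == 0:
            samples[i] = 0.0
        else:
            samples[i] = config.background_rms * _shaped_noise(
                rng, n, config.sampling_rate_hz, config.background_exponent
            )
    if n_channels == len(MONTAGE):
        channels = list(MONTAGE)
    else:
        channels = [ChannelMeta(f"ch{i}") for i in range(n_channels)]
    return Recording(
        samples=samples,
        sampling_rate_hz=config.sampling_rate_hz,
        channels=channels,
        gain_volts_per_count=1.0,
    )


def _burst_waveform(spec: BurstSpec, fs: float) -> np.ndarray:
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    carrier = np.sin(2 * np.pi * spec.freq_hz * t + spec.phase_rad)
    if spec.envelope == "hann":
        env = 0.5 * (1.0 - np.cos(2 * np.pi * t / spec.duration_s))
    else:
        env = np.ones(n)
    return spec.amplitude * env * carrier


def _add_at(target: np.ndarray, waveform: np.ndarray, onset_s: float, fs: float) -> None:
    start = int(round(onset_s * fs))
    stop = min(start + waveform.size, target.size)
    if start < target.size:
        target[start:stop] += waveform[: stop - start]


def _band_rms(x: np.ndarray, fs: float, band=(30.0, 80.0)) -> float:
    return float(np.sqrt(np.mean(band_filter_zero_phase(x, fs, band) ** 2)))


def _draw_bursts(config: SynthConfig, rng: np.random.Generator, amplitude: float) -> list[BurstSpec]:
    n_bursts = rng.poisson(config.burst_rate_hz * config.duration_s)
    lag = config.ob_to_pirc_lag_s
    bursts = []
    for _ in range(n_bursts):
        dur = rng.uniform(*config.burst_duration_dist)
        latest = config.duration_s - dur - max(lag, 0.0)
        if latest <= 0:
            continue
        bursts.append(
            BurstSpec(
                onset_s=float(rng.uniform(0.0, latest)),
                duration_s=float(dur),
                freq_hz=float(rng.uniform(*config.burst_freq_dist)),
                amplitude=amplitude,
                envelope="hann",
                lag_s=lag,
                phase_rad=float(rng.uniform(0.0, 2 * np.pi)),
            )
        )
    return sorted(bursts, key=lambda b: b.onset_s)


def _draw_artifacts(config: SynthConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    n_art = rng.poisson(config.artifact_rate_hz * config.duration_s)
    arts = []
    for _ in range(n_art):
        latest = config.duration_s - config.artifact_duration_s
        if latest <= 0:
            continue
        arts.append((float(rng.uniform(0.0, latest)), config.artifact_duration_s))
    return sorted(arts)


def generate_recording(
    config: SynthConfig,
    bursts: list[BurstSpec] | None = None,
    artifacts: list[tuple[float, float]] | None = None,
) -> tuple[Recording, GroundTruth]:
    """Background + gamma bursts + common-mode artifacts, with ground truth.

    Bursts arrive as a Poisson process at ``burst_rate_hz``; each burst is
    added to the OB channel and reproduced on both PirC channels delayed by
    ``ob_to_pirc_lag_s``.  Artifacts are hann-windowed white-noise
    transients added identically to all channels.  Pass explicit ``bursts``
    or ``artifacts`` to script the injection instead of drawing it.
    """
    rec = generate_background(config, n_channels=len(MONTAGE))
    fs = config.sampling_rate_hz
    sigma_band = _band_rms(rec.channel("OB"), fs)
    amplitude = config.burst_amplitude_snr * sigma_band if sigma_band > 0 else config.burst_amplitude_snr

    if bursts is None:
        rng_b = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        bursts = _draw_bursts(config, rng_b, amplitude)
    for spec in bursts:
        if spec.offset_s > config.duration_s + 1e-9:
            raise ValueError(f"burst ending at {spec.offset_s} s exceeds recording duration")
        waveform = _burst_waveform(spec, fs)
        source, *delayed = spec.target_channels
        _add_at(rec.channel(source), waveform, spec.onset_s, fs)
        for label in delayed:
            _add_at(rec.channel(label), waveform, spec.onset_s + spec.lag_s, fs)

    rng_a = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if artifacts is None:
        artifacts = _draw_artifacts(config, rng_a)
    for onset, dur in artifacts:
        n = int(round(dur * fs))
        env = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(n) / n))
        wave = config.artifact_amplitude * env * rng_a.standard_normal(n)
        for row in rec.samples:
            _add_at(row, wave, onset, fs)

    return rec, GroundTruth(bursts=list(bursts), artifacts=list(artifacts), config=config)


# ---------------------------------------------------------------------------
# Ground-truth tables (CSV, for the CLI round trip)


def write_ground_truth(truth: GroundTruth, bursts_path, artifacts_path=None) -> None:
    pd.DataFrame(
        [
            {
                "onset_s": b.onset_s,
                "duration_s": b.duration_s,
                "freq_hz": b.freq_hz,
                "amplitude": b.amplitude,
                "envelope": b.envelope,
                "lag_s": b.lag_s,
                "phase_rad": b.phase_rad,
            }
            for b in truth.bursts
        ],
        columns=["onset_s", "duration_s", "freq_hz", "amplitude", "envelope", "lag_s", "phase_rad"],
    ).to_csv(bursts_path, index=False, float_format="%.9g")
    if artifacts_path is not None:
        pd.DataFrame(truth.artifacts, columns=["onset_s", "duration_s"]).to_csv(
            artifacts_path, index=False, float_format="%.9g"
        )


def read_ground_truth(bursts_path, config: SynthConfig | None = None) -> GroundTruth:
    df = pd.read_csv(bursts_path)
    bursts = [
        BurstSpec(
            onset_s=float(r.onset_s),
            duration_s=float(r.duration_s),
            freq_hz=float(r.freq_hz),
            amplitude=float(r.amplitude),
            envelope=str(r.envelope),
            lag_s=float(r.lag_s),
            phase_rad=float(r.phase_rad),
        )
        for r in df.itertuples(index=False)
    ]
    return GroundTruth(bursts=bursts, artifacts=[], config=config or SynthConfig())
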