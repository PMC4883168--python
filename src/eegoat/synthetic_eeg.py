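"""Benchmark-shaped synthetic EEG generation.

Generates five class-sets shaped like the Bonn corpus (A–E, 100 channels ×
4097 samples, 23.6 s) with class-dependent amplitude, variance and
rhythmicity so the whole sampling → features → detection pipeline can be
exercised and tested without the external download.

Each channel is an AR(2) noise process plus an optional sinusoid and
Poisson-timed spike bursts, scaled to a class-specific amplitude.  The
three class profiles mimic the qualitative structure of the benchmark:
moderate 10 Hz (alpha-band) activity for healthy recordings, irregular
background with sparse interictal spikes for the seizure-free class, and
large-amplitude 3 Hz rhythmic discharges for the seizure class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .eeg_io import SET_CLASS, Signal, SignalSet
from .exceptions import ValidationError

BONN_N_CHANNELS = 100
BONN_N_POINTS = 4097
BONN_DURATION_S = 23.6


@dataclass(frozen=True)
class ClassProfile:
    """Generative parameters for one EEG class.

    ar_coefficients
        (a1, a2) of the AR(2) background ``x_t = a1 x_{t-1} + a2 x_{t-2} + e_t``;
        must lie inside the stationarity triangle.
    noise_sd
        Innovation standard deviation of the AR process (µV, pre-scale).
    oscillation_frequency / oscillation_amplitude
        Dominant rhythm (Hz) and its amplitude (µV, pre-scale); random
        phase per channel.
    burst_rate / burst_amplitude
        Poisson rate (events/s) and amplitude (µV, pre-scale) of transient
        spike bursts (Gaussian bumps of ~40 ms width, random sign).
    amplitude_scale
        Overall output scale (µV); the seizure class is several-fold larger.
    gain_jitter_sd
        Log-normal sd of the per-channel gain, giving between-channel
        amplitude variability within a set.
    """

    class_label: str
    ar_coefficients: tuple[float, float] = (0.5, -0.2)
    noise_sd: float = 1.0
    oscillation_frequency: float = 0.0
    oscillation_amplitude: float = 0.0
    burst_rate: float = 0.0
    burst_amplitude: float = 0.0
    amplitude_scale: float = 1.0
    gain_jitter_sd: float = 0.15

    def __post_init__(self) -> None:
        a1, a2 = self.ar_coefficients
        # AR(2) stationarity triangle: |a2|<1, a2±a1<1
        if not (abs(a2) < 1 and a1 + a2 < 1 and a2 - a1 < 1):
            raise ValidationError(
                f"AR coefficients {self.ar_coefficients} outside the stationarity region"
            )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        for name in (
            "oscillation_amplitude",
            "burst_rate",
            "burst_amplitude",
            "amplitude_scale",
            "gain_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


#: Frozen default profiles for the three classes (pre-scale units arbitrary,
#: amplitude_scale sets the µV magnitude).  The seizure class is 5–10× the
#: healthy amplitude, mirroring the benchmark's qualitative contrast.
DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "healthy": ClassProfile(
        class_label="healthy",
        ar_coefficients=(0.5, -0.2),
        noise_sd=1.0,
        oscillation_frequency=10.0,
        oscillation_amplitude=1.5,
        amplitude_scale=40.0,
    ),
    "seizure-free": ClassProfile(
        class_label="seizure-free",
        ar_coefficients=(0.6, -0.25),
        noise_sd=1.2,
        burst_rate=0.5,
        burst_amplitude=5.0,
        amplitude_scale=80.0,
    ),
    "seizure": ClassProfile(
        class_label="seizure",
        ar_coefficients=(0.5, -0.2),
        noise_sd=1.5,
        oscillation_frequency=3.0,
        oscillation_amplitude=6.0,
        burst_rate=1.0,
        burst_amplitude=8.0,
        amplitude_scale=280.0,
    ),
}

#: Set → profile assignment matching the benchmark's class structure.
SET_PROFILES: dict[str, str] = dict(SET_CLASS)

_BURST_WIDTH_S = 0.04  # Gaussian bump sd in seconds


def ar2_stationary_variance(a1: float, a2: float, noise_sd: float) -> float:
    """Closed-form stationary variance of an AR(2) process."""
    return (
        noise_sd**2
        * (1 - a2)
        / ((1 + a2) * ((1 - a2) ** 2 - a1**2))
    )


def generate_channel(
    profile: ClassProfile,
    n_points: int,
    sampling_rate: float,
    seed: int | np.random.Generator,
    channel_id: str = "synthetic",
) -> Signal:
    """Simulate one channel: AR(2) noise + sinusoid + spike bursts, scaled.

    Deterministic given (profile, n_points, seed).  A 500-sample burn-in
    brings the AR process close to stationarity before the recording window.
    """
    if n_points <= 0:
        raise ValidationError("n_points must be positive")
    rng = np.random.default_rng(seed)
    a1, a2 = profile.ar_coefficients
    burn_in = 500
    innovations = rng.normal(0.0, profile.noise_sd, size=n_points + burn_in)
    ar = lfilter([1.0], [1.0, -a1, -a2], innovations)[burn_in:]

    t = np.arange(n_points) / sampling_rate
    osc = np.zeros(n_points)
    if profile.oscillation_amplitude > 0 and profile.oscillation_frequency > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        osc = profile.oscillation_amplitude * np.sin(
            2.0 * np.pi * profile.oscillation_frequency * t + phase
        )

    bursts = np.zeros(n_points)
    if profile.burst_rate > 0 and profile.burst_amplitude > 0:
        duration = n_points / sampling_rate
        n_events = rng.poisson(profile.burst_rate * duration)
        for _ in range(n_events):
            t0 = rng.uniform(0.0, duration)
            sign = rng.choice([-1.0, 1.0])
            bursts += (
                sign
                * profile.burst_amplitude
                * np.exp(-0.5 * ((t - t0) / _BURST_WIDTH_S) ** 2)
            )

    gain = np.exp(rng.normal(0.0, profile.gain_jitter_sd))
    samples = profile.amplitude_scale * gain * (ar + osc + bursts)
    return Signal(
        channel_id=channel_id, samples=samples, sampling_rate=sampling_rate
    )


def generate_signal_set(
    set_id: str,
    profile: ClassProfile,
    seed: int,
    n_channels: int = BONN_N_CHANNELS,
    n_points: int = BONN_N_POINTS,
    duration_seconds: float = BONN_DURATION_S,
) -> SignalSet:
    """Generate one class-set; channel RNG streams are independent.

    Each channel uses a SeedSequence spawned from (seed, set index, channel
    index) so single channels are reproducible in isolation.
    """
    set_index = "ABCDE".find(set_id)
    if set_index < 0:
        set_index = abs(hash(set_id)) % 2**16
    sampling_rate = n_points / duration_seconds
    channels = []
    for j in range(n_channels):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(set_index, j))
        channels.append(
            generate_channel(
                profile,
                n_points,
                sampling_rate,
                np.random.default_rng(ss),
                channel_id=f"{set_id}{j:03d}",
            )
        )
    return SignalSet(
        set_id=set_id,
        class_label=profile.class_label,
        channels=channels,
        duration_seconds=duration_seconds,
    )


def generate_benchmark_like_dataset(
    seed: int,
    n_channels: int = BONN_N_CHANNELS,
    n_points: int = BONN_N_POINTS,
    duration_seconds: float = BONN_DURATION_S,
    profiles: dict[str, ClassProfile] | None = None,
) -> dict[str, SignalSet]:
    """Generate the five benchmark-shaped sets A–E.

    A,B share the healthy profile, C,D the seizure-free profile and E the
    seizure profile.  Pure function of (parameters, seed).
    """
    profiles = profiles or DEFAULT_PROFILES
    out: dict[str, SignalSet] = {}
    for set_id in "ABCDE":
        profile = profiles[SET_PROFILES[set_id]]
        out[set_id] = generate_signal_set(
            set_id,
            profile,
            seed,
            n_channels=n_channels,
            n_points=n_points,
            duration_seconds=duration_seconds,
        )
    return out


def save_signal_set(ss: SignalSet, directory: str | Path) -> None:
    """Persist a set in the Bonn-style layout readable by eeg_io."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ch in ss.channels:
        lines = "\n".join(f"{v:.6f}" for v in ch.samples)
        (directory / f"{ch.channel_id}.txt").write_text(lines + "\n")


def scaled_profile(label: str, factor: float) -> ClassProfile:
    """Convenience: a default profile with amplitude_scale multiplied."""
    base = DEFAULT_PROFILES[label]
    return replace(base, amplitude_scale=base.amplitude_scale * factor)
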