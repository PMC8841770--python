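"""Synthetic EIT boundary-voltage signals and motion-artifact injectors.

The simulated clean channel is a two-sinusoid model of the thoracic
impedance waveform — a respiratory component (0.25 Hz, amplitude 0.9) and a
cardiac component (1 Hz, amplitude 0.2) — with additive Gaussian noise:

    x[n] = (1/2) * sum_i mu_i * sin(2 pi f_i n / fs) + lambda * g[n]

sampled at 20 Hz for 5,000 samples by default. Three artifact families are
injected additively on top of it:

* ``drift``  — slow baseline wander (linear ramp or a sub-respiratory
  sinusoid, e.g. a 0.02 Hz pulsating-mattress cycle);
* ``step``   — an abrupt, persistent baseline shift (postural change);
* ``spike``  — short triangular excursions that return to baseline.

All generators are deterministic given their seeds, and the contaminated
signal is exactly truth + sum(artifact vectors): nothing is renormalized,
so ground-truth evaluation can recover each injected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import N_CHANNELS, FrameSeries

__all__ = [
    "BreathingSimConfig",
    "ArtifactSpec",
    "simulate_breathing",
    "artifact_vector",
    "inject_artifact",
    "simulate_contaminated_dataset",
    "simulate_frame_series",
]

#: respiratory (0.25 Hz, mu = 0.9) and cardiac (1 Hz, mu = 0.2) components
DEFAULT_COMPONENTS: tuple[tuple[float, float], ...] = ((0.25, 0.9), (1.0, 0.2))

#: Gaussian noise amplitude; small enough that the oscillatory structure
#: dominates (SNR ~ 26 dB)
DEFAULT_NOISE = 0.02


@dataclass
class BreathingSimConfig:
    """Parameters of the two-sinusoid breathing + cardiac simulation."""

    components: tuple[tuple[float, float], ...] = DEFAULT_COMPONENTS
    noise_amplitude: float = DEFAULT_NOISE
    fs: float = 20.0
    n_samples: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be nonnegative")
        for f, _mu in self.components:
            if f >= self.fs / 2:
                raise ValueError(
                    f"component frequency {f} Hz violates Nyquist for fs={self.fs}"
                )

    def to_dict(self) -> dict:
        return {
            "components": [list(c) for c in self.components],
            "noise_amplitude": self.noise_amplitude,
            "fs": self.fs,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }


@dataclass
class ArtifactSpec:
    """Parametric description of one injected artifact (ground truth).

    ``kind`` is ``drift``, ``step`` or ``spike``. ``onset`` is a 0-based
    sample index. Drift parameters: ``shape`` in {linear, sinusoidal} and
    ``drift_freq`` (Hz, sinusoidal only). Spike parameters: ``width``
    (samples, full base width of the triangular pulse), ``count`` and
    ``seed`` for the pulse locations; an ``onset`` > 0 pins the first pulse
    center there, the remaining pulses are placed at seeded-random samples.
    """

    kind: str
    amplitude: float = 1.0
    onset: int = 0
    shape: str = "sinusoidal"
    drift_freq: float = 0.02
    width: int = 3
    count: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("drift", "step", "spike"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("onset must be nonnegative")
        if self.kind == "spike" and self.width < 1:
            raise ValueError("spike width must be >= 1")
        if self.kind == "drift" and self.shape not in ("linear", "sinusoidal"):
            raise ValueError(f"unknown drift shape {self.shape!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "amplitude": self.amplitude,
            "onset": self.onset,
            "shape": self.shape,
            "drift_freq": self.drift_freq,
            "width": self.width,
            "count": self.count,
            "seed": self.seed,
        }


def simulate_breathing(config: BreathingSimConfig | None = None) -> np.ndarray:
    """Simulated clean EIT channel (breathing + cardiac + Gaussian noise)."""
    cfg = config or BreathingSimConfig()
    t = np.arange(cfg.n_samples) / cfg.fs
    x = np.zeros(cfg.n_samples)
    for f, mu in cfg.components:
        x += 0.5 * mu * np.sin(2 * np.pi * f * t)
    if cfg.noise_amplitude > 0:
        rng = np.random.default_rng(cfg.seed)
        x = x + cfg.noise_amplitude * rng.standard_normal(cfg.n_samples)
    return x


def artifact_vector(spec: ArtifactSpec, n_samples: int, fs: float) -> np.ndarray:
    """The pure additive artifact component described by ``spec``."""
    if spec.onset >= n_samples:
        raise ValueError(
            f"onset {spec.onset} outside signal of length {n_samples}"
        )
    out = np.zeros(n_samples)
    n = np.arange(n_samples)
    if spec.kind == "step":
        out[spec.onset:] = spec.amplitude
    elif spec.kind == "drift":
        rel = n[spec.onset:] - spec.onset
        if spec.shape == "linear":
            span = max(n_samples - 1 - spec.onset, 1)
            out[spec.onset:] = spec.amplitude * rel / span
        else:
            out[spec.onset:] = spec.amplitude * np.sin(
                2 * np.pi * spec.drift_freq * rel / fs
            )
    else:  # spike
        half = spec.width // 2
        rng = np.random.default_rng(spec.seed)
        lo = half
        hi = n_samples - half - 1
        if hi <= lo:
            raise ValueError("signal too short for the requested spikes")
        # onset > 0 pins the first pulse center; the rest are seeded-random
        centers: list[int] = []
        if spec.onset > 0:
            if not lo <= spec.onset <= hi:
                raise ValueError("spike onset too close to the record edge")
            centers.append(spec.onset)
        for _ in range(1000):
            if len(centers) == spec.count:
                break
            c = int(rng.integers(lo, hi + 1))
            if all(abs(c - prev) > 2 * spec.width for prev in centers):
                centers.append(c)
        if len(centers) < spec.count:
            raise ValueError("could not place the requested number of spikes")
        for c in sorted(centers):
            for k in range(-half, half + 1):
                out[c + k] += spec.amplitude * (1 - abs(k) / (half + 1))
    return out


def inject_artifact(signal: np.ndarray, spec: ArtifactSpec, fs: float = 20.0) -> np.ndarray:
    """Additively superimpose one artifact; output - input is the artifact."""
    x = np.asarray(signal, dtype=float)
    return x + artifact_vector(spec, len(x), fs)


def simulate_contaminated_dataset(
    config: BreathingSimConfig | None = None,
    specs: list[ArtifactSpec] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Return (truth, contaminated, artifact vectors) for one channel."""
    cfg = config or BreathingSimConfig()
    truth = simulate_breathing(cfg)
    artifacts = [artifact_vector(s, cfg.n_samples, cfg.fs) for s in (specs or [])]
    if artifacts:
        contaminated = truth + np.sum(artifacts, axis=0)
    else:
        contaminated = truth.copy()
    return truth, contaminated, artifacts


def simulate_frame_series(
    config: BreathingSimConfig | None = None,
    specs: list[ArtifactSpec] | None = None,
    channel_gains: np.ndarray | None = None,
    artifact_gains: np.ndarray | None = None,
) -> tuple[FrameSeries, FrameSeries]:
    """Extend the 1-D simulation to a 208-channel frame series.

    Channel ``c`` carries ``gain_c`` times the shared noiseless waveform plus
    independent Gaussian noise of amplitude ``noise_amplitude``; artifacts are
    added scaled by ``artifact_gains`` (default: equally on every channel).
    Returns (truth, contaminated) series.
    """
    cfg = config or BreathingSimConfig()
    gains = np.ones(N_CHANNELS) if channel_gains is None else np.asarray(
        channel_gains, dtype=float
    )
    if gains.shape != (N_CHANNELS,):
        raise ValueError(f"expected {N_CHANNELS} channel gains, got {gains.shape}")
    again = np.ones(N_CHANNELS) if artifact_gains is None else np.asarray(
        artifact_gains, dtype=float
    )
    if again.shape != (N_CHANNELS,):
        raise ValueError(f"expected {N_CHANNELS} artifact gains, got {again.shape}")

    clean_cfg = BreathingSimConfig(
        components=cfg.components,
        noise_amplitude=0.0,
        fs=cfg.fs,
        n_samples=cfg.n_samples,
        seed=cfg.seed,
    )
    shared = simulate_breathing(clean_cfg)
    rng = np.random.default_rng(cfg.seed)
    noise = cfg.noise_amplitude * rng.standard_normal((cfg.n_samples, N_CHANNELS))
    truth = shared[:, None] * gains[None, :] + noise

    total_artifact = np.zeros(cfg.n_samples)
    for s in specs or []:
        total_artifact += artifact_vector(s, cfg.n_samples, cfg.fs)
    contaminated = truth + total_artifact[:, None] * again[None, :]
    return FrameSeries(truth, fs=cfg.fs), FrameSeries(contaminated, fs=cfg.fs)
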