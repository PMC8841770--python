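"""Detection and removal of the three motion-artifact classes.

Each artifact class lives in a characteristic part of the wavelet domain of
a 20 Hz impedance channel decomposed with db8:

* baseline drift is a slow-varying signal captured by the deep approximation
  ``a_6`` (below ~0.156 Hz); excluding ``a_6`` from the rebuild removes it
  while keeping the 0.25 Hz respiratory band;
* step-like shifts produce isolated large finest-detail (``d_1``)
  coefficients, which localize the change point; the persistent offset is
  then estimated by harmonic-background regression and subtracted;
* spike-like transients concentrate in ``d_1 .. d_4``; outlier coefficients
  in those bands are hard-suppressed (or, optionally, the bands are zeroed
  wholesale) before the rebuild.

Thresholds are robust: tau = k * MAD / 0.6745 (MAD about the median), i.e.
``k`` Gaussian-equivalent standard deviations, with ``k = 5`` by default.
Every procedure operates on one channel; :func:`clean_frames` applies them
independently to each of the 208 channels of a frame series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import FrameSeries
from .wavelet import (
    DEFAULT_MODE,
    DEFAULT_WAVELET,
    CoefficientMask,
    dwt_decompose,
    dwt_rebuild,
    max_decomposition_level,
)

__all__ = [
    "CleaningConfig",
    "DetectedEvent",
    "drift_level_for_cutoff",
    "remove_baseline_drift",
    "detect_steps",
    "correct_steps",
    "remove_spikes",
    "clean_channel",
    "clean_frames",
    "DEFAULT_STAGES",
]

#: default stage order: steps are corrected on the raw signal first, because
#: high-passing first (drift removal) turns a persistent step into a decaying
#: transient and biases the offset estimate
DEFAULT_STAGES = ("step", "drift", "spike")

#: MAD -> Gaussian sigma conversion constant
MAD_TO_SIGMA = 0.6745


@dataclass
class CleaningConfig:
    """Tunable parameters of the three cleaning procedures.

    Defaults reflect a 20 Hz recording: drift removal excludes the level-6
    approximation (high-pass at ~0.156 Hz), steps are localized in the
    level-1 detail, spikes are suppressed in detail levels 1-4, and the
    step offset is fit over three ``step_offset_window`` (2 s) spans on
    each side of the change point.
    """

    drift_level: int = 6
    step_detection_level: int = 1
    spike_levels: tuple[int, int] = (1, 4)
    threshold_k: float = 5.0
    step_offset_window: int = 40
    min_event_separation: int = 40
    spike_mode: str = "threshold_local"
    wavelet_name: str = DEFAULT_WAVELET
    extension_mode: str = DEFAULT_MODE

    def __post_init__(self) -> None:
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")
        if self.step_offset_window < 1 or self.min_event_separation < 1:
            raise ValueError("windows must be >= 1 sample")
        lo, hi = self.spike_levels
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid spike level range {self.spike_levels}")
        if self.drift_level < 1 or self.step_detection_level < 1:
            raise ValueError("decomposition levels must be >= 1")
        if self.spike_mode not in ("threshold_local", "zero_global"):
            raise ValueError(f"unknown spike_mode {self.spike_mode!r}")

    def to_dict(self) -> dict:
        return {
            "drift_level": self.drift_level,
            "step_detection_level": self.step_detection_level,
            "spike_levels": list(self.spike_levels),
            "threshold_k": self.threshold_k,
            "step_offset_window": self.step_offset_window,
            "min_event_separation": self.min_event_separation,
            "spike_mode": self.spike_mode,
            "wavelet_name": self.wavelet_name,
            "extension_mode": self.extension_mode,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "CleaningConfig":
        kwargs = dict(obj)
        if "spike_levels" in kwargs:
            kwargs["spike_levels"] = tuple(kwargs["spike_levels"])
        return cls(**kwargs)


@dataclass
class DetectedEvent:
    """One detected abrupt change: a persistent step or a transient spike."""

    kind: str  # "step" | "spike"
    location: int  # sample index of the change point
    support: tuple[int, int]  # half-open sample interval containing it
    offset_estimate: float = 0.0  # signed baseline shift (steps)

    def __post_init__(self) -> None:
        lo, hi = self.support
        if not lo <= self.location < hi:
            raise ValueError("support must contain the event location")


def drift_level_for_cutoff(fs: float, f_cut: float) -> int:
    """Decomposition depth whose approximation band ends near ``f_cut`` Hz."""
    if f_cut <= 0 or f_cut >= fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    return max(1, int(np.floor(np.log2(fs / (2 * f_cut)))))


def _robust_sigma(values: np.ndarray) -> float:
    med = np.median(values)
    return float(np.median(np.abs(values - med)) / MAD_TO_SIGMA)


def _validate_signal(signal) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    return x


# ---------------------------------------------------------------------------
# baseline drift
# ---------------------------------------------------------------------------

def remove_baseline_drift(
    signal, fs: float = 20.0, config: CleaningConfig | None = None
) -> np.ndarray:
    """High-pass the channel by excluding ``a_L`` from the wavelet rebuild.

    With the default L = 6 at 20 Hz this removes content below ~0.156 Hz —
    mattress-type drift — while the 0.25 Hz respiratory band survives.
    """
    cfg = config or CleaningConfig()
    x = _validate_signal(signal)
    max_l = max_decomposition_level(len(x), cfg.wavelet_name)
    if cfg.drift_level > max_l:
        raise ValueError(
            f"drift_level {cfg.drift_level} exceeds maximum admissible "
            f"level {max_l} for {len(x)} samples"
        )
    dec = dwt_decompose(x, cfg.drift_level, cfg.wavelet_name, cfg.extension_mode)
    return dwt_rebuild(dec, CoefficientMask(zero_approx=True))


# ---------------------------------------------------------------------------
# step-like artifacts
# ---------------------------------------------------------------------------

def _candidate_regions(flags: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Merge flagged indices closer than ``gap`` into half-open runs."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    regions = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > gap:
            regions.append((start, prev + 1))
            start = i
        prev = i
    regions.append((start, prev + 1))
    return regions


def _diff_jump_estimate(x: np.ndarray, loc: int, half: int = 10) -> float:
    """Baseline jump at ``loc``: the change-point difference minus the
    local background slope (median of neighboring first differences)."""
    d = np.diff(x)
    j = loc - 1  # d[j] = x[loc] - x[loc - 1], the jump across the change
    lo = max(0, j - half)
    hi = min(len(d), j + half + 1)
    neighbors = np.delete(d[lo:hi], j - lo)
    slope = float(np.median(neighbors)) if neighbors.size else 0.0
    return float(d[j] - slope)


#: half-width (samples) of the harmonic-regression fit window; 6 s at 20 Hz,
#: i.e. ~1.5 respiratory periods, which separates the step regressor from
#: the oscillatory background
JUMP_FIT_HALF = 120

#: half-width (samples) of the window used to estimate the dominant
#: oscillation frequencies around a change point
FREQ_WINDOW_HALF = 512


def _local_jump_estimate(x: np.ndarray, loc: int, half: int = JUMP_FIT_HALF) -> float:
    """Step amplitude at ``loc`` by harmonic-background regression.

    The physiological background around a change point is quasi-periodic
    (respiratory plus cardiac oscillation); a plain median level difference
    is biased by its phase, and a purely local difference is noisy. Here the
    two dominant oscillation frequencies are estimated from the periodogram
    around the change point (after removing a rough jump estimate), and the
    jump is re-estimated by least squares with a linear trend, sinusoids at
    those frequencies, and a unit step as regressors.
    """
    jump0 = _diff_jump_estimate(x, loc)
    if loc < 20 or len(x) - loc < 20:
        return jump0  # too close to the record edge for a stable fit
    lo = max(0, loc - half)
    hi = min(len(x), loc + half)
    n = (np.arange(lo, hi) - loc).astype(float)
    step_reg = (n >= 0).astype(float)
    seg = x[lo:hi]

    wlo = max(0, loc - FREQ_WINDOW_HALF)
    whi = min(len(x), loc + FREQ_WINDOW_HALF)
    z = np.concatenate([x[wlo:loc], x[loc:whi] - jump0])
    z = z - z.mean()
    freqs: list[float] = []
    if z.size >= 64:
        spectrum = np.abs(np.fft.rfft(z * np.hanning(z.size)))
        grid = np.fft.rfftfreq(z.size)  # cycles/sample
        for i in np.argsort(spectrum)[::-1]:
            if grid[i] < 0.002:
                continue
            if all(abs(grid[i] - f) > 0.01 for f in freqs):
                freqs.append(float(grid[i]))
            if len(freqs) == 2:
                break
    cols = [np.ones_like(n), n, step_reg]
    for f in freqs:
        cols.append(np.sin(2 * np.pi * f * n))
        cols.append(np.cos(2 * np.pi * f * n))
    coef, *_ = np.linalg.lstsq(np.column_stack(cols), seg, rcond=None)
    return float(coef[2])


def detect_steps(signal, config: CleaningConfig | None = None) -> list[DetectedEvent]:
    """Locate abrupt changes from suprathreshold finest-detail coefficients.

    Candidate change points are level-1 detail coefficients with
    ``|d_1| > tau``, ``tau = k * MAD(d_1)/0.6745``. Candidates are mapped
    back to sample indices (coefficient c covers samples near 2c), merged
    within ``min_event_separation``, refined to the largest local first
    difference, and classified: if the median over ``step_offset_window``
    samples after the change minus the median before persists above the
    threshold, the event is a step, otherwise a spike. Steps carry a
    trend-corrected least-squares jump amplitude as ``offset_estimate``.
    """
    cfg = config or CleaningConfig()
    x = _validate_signal(signal)
    if len(x) < 2 * cfg.step_offset_window:
        raise ValueError(
            f"signal of length {len(x)} shorter than twice the offset "
            f"window ({cfg.step_offset_window})"
        )
    dec = dwt_decompose(
        x, cfg.step_detection_level, cfg.wavelet_name, cfg.extension_mode
    )
    d1 = dec.detail(cfg.step_detection_level)
    sigma = _robust_sigma(d1)
    if sigma == 0.0:
        return []  # constant or noiseless-smooth signal: nothing abrupt
    tau = cfg.threshold_k * sigma
    stride = 2**cfg.step_detection_level
    flags = np.abs(d1) > tau
    gap = max(1, cfg.min_event_separation // stride)
    events: list[DetectedEvent] = []
    half_filter = 8  # db8 half-support at level 1
    for c_lo, c_hi in _candidate_regions(flags, gap):
        lo = max(0, c_lo * stride - half_filter)
        hi = min(len(x), c_hi * stride + half_filter)
        if hi - lo < 2:
            continue
        # refine change point: largest jump between consecutive samples
        seg = np.diff(x[lo:hi])
        j1 = int(np.argmax(np.abs(seg)))
        loc = lo + j1 + 1  # first sample after the jump
        # step vs spike: a transient excursion returns to baseline, so its
        # leading jump has a matching opposite-sign jump nearby; a
        # persistent baseline shift does not
        opposite = seg[np.sign(seg) == -np.sign(seg[j1])]
        returning = opposite.size > 0 and np.max(np.abs(opposite)) > 0.5 * abs(seg[j1])
        kind = "spike" if returning else "step"
        events.append(
            DetectedEvent(
                kind=kind,
                location=loc,
                support=(lo, hi),
                offset_estimate=(
                    _local_jump_estimate(x, loc, 3 * cfg.step_offset_window)
                    if kind == "step"
                    else 0.0
                ),
            )
        )
    events.sort(key=lambda e: e.location)
    return events


def correct_steps(signal, events: list[DetectedEvent]) -> np.ndarray:
    """Subtract each step's estimated offset from all samples at/after it."""
    x = _validate_signal(signal).copy()
    for ev in sorted(events, key=lambda e: e.location):
        if not 0 <= ev.location < len(x):
            raise ValueError(
                f"event location {ev.location} outside signal of length {len(x)}"
            )
        if ev.kind != "step":
            continue
        x[ev.location:] -= ev.offset_estimate
    return x


# ---------------------------------------------------------------------------
# spike-like artifacts
# ---------------------------------------------------------------------------

def remove_spikes(signal, config: CleaningConfig | None = None) -> np.ndarray:
    """Suppress spike-band coefficients and rebuild the channel.

    In ``threshold_local`` mode (default) only coefficients in detail levels
    ``spike_levels`` whose magnitude exceeds that level's robust threshold
    are zeroed, so sub-threshold physiology (notably the ~1 Hz cardiac
    component living in ``d_4`` at 20 Hz) passes through. ``zero_global``
    zeroes those bands wholesale.
    """
    cfg = config or CleaningConfig()
    x = _validate_signal(signal)
    lo, hi = cfg.spike_levels
    max_l = max_decomposition_level(len(x), cfg.wavelet_name)
    if hi > max_l:
        raise ValueError(
            f"spike level {hi} exceeds maximum admissible level {max_l}"
        )
    dec = dwt_decompose(x, hi, cfg.wavelet_name, cfg.extension_mode)
    if cfg.spike_mode == "zero_global":
        mask = CoefficientMask(zeroed_detail_levels=frozenset(range(lo, hi + 1)))
    else:
        thresholds = {}
        for lv in range(lo, hi + 1):
            sigma = _robust_sigma(dec.detail(lv))
            thresholds[lv] = cfg.threshold_k * sigma if sigma > 0 else np.inf
        thresholds = {lv: t for lv, t in thresholds.items() if np.isfinite(t)}
        mask = CoefficientMask(per_level_thresholds=thresholds)
    return dwt_rebuild(dec, mask)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def clean_channel(
    signal,
    fs: float = 20.0,
    config: CleaningConfig | None = None,
    stages: tuple[str, ...] = DEFAULT_STAGES,
) -> tuple[np.ndarray, list[DetectedEvent]]:
    """Apply the requested cleaning stages in order to one channel.

    ``stages`` is an ordered subset of {"drift", "step", "spike"}; the
    default runs all three, steps first (a step must be corrected before
    the drift high-pass smears it out). Returns the cleaned channel and every event
    detected along the way.
    """
    cfg = config or CleaningConfig()
    if not stages:
        raise ValueError("stages must be a nonempty ordered subset")
    unknown = [s for s in stages if s not in ("drift", "step", "spike")]
    if unknown:
        raise ValueError(f"unknown stages {unknown}")
    x = _validate_signal(signal)
    events: list[DetectedEvent] = []
    for stage in stages:
        if stage == "drift":
            x = remove_baseline_drift(x, fs, cfg)
        elif stage == "step":
            found = detect_steps(x, cfg)
            events.extend(found)
            x = correct_steps(x, found)
        else:  # spike
            x = remove_spikes(x, cfg)
    return x, events


def clean_frames(
    frames: FrameSeries,
    config: CleaningConfig | None = None,
    stages: tuple[str, ...] = DEFAULT_STAGES,
) -> tuple[FrameSeries, dict[int, list[DetectedEvent]]]:
    """Apply :func:`clean_channel` independently to every channel."""
    cfg = config or CleaningConfig()
    cleaned = np.empty_like(frames.data)
    per_channel: dict[int, list[DetectedEvent]] = {}
    for c in range(frames.data.shape[1]):
        cleaned[:, c], events = clean_channel(frames.data[:, c], frames.fs, cfg, stages)
        if events:
            per_channel[c] = events
    return FrameSeries(cleaned, fs=frames.fs), per_channel
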