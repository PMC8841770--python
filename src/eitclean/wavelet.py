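"""Multilevel 1-D discrete wavelet decomposition and rebuild.

The decompose / rebuild pair is the core primitive of the motion-artifact
removal pipeline: a boundary-voltage channel is split into one deep
approximation band ``a_L`` and detail bands ``d_1 .. d_L`` (``d_1`` finest),
selected coefficients are suppressed, and the channel is resynthesised.

Level indexing follows the usual multiresolution convention: at sampling
rate ``fs`` the detail band ``d_i`` covers roughly ``(fs/2**(i+1), fs/2**i]``
and the approximation ``a_L`` covers ``[0, fs/2**(L+1)]``.

Filtering is delegated to PyWavelets; equivalence with an explicit
boundary-extension + convolution + dyadic-downsampling reference is asserted
in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "WaveletDecomposition",
    "CoefficientMask",
    "dwt_decompose",
    "dwt_rebuild",
    "max_decomposition_level",
    "detail_band",
    "approx_band",
]

DEFAULT_WAVELET = "db8"  # Daubechies, 8 vanishing moments, 16-tap filters
DEFAULT_MODE = "symmetric"  # half-sample symmetric boundary extension


def _filter_length(wavelet_name: str) -> int:
    return pywt.Wavelet(wavelet_name).dec_len


def max_decomposition_level(n_samples: int, wavelet_name: str = DEFAULT_WAVELET) -> int:
    """Largest level L such that the dyadic downsampling rule stays valid.

    Uses the standard rule ``floor(log2(n / (filter_length - 1)))``; e.g.
    5,000 samples with db8 (16 taps) admit 8 levels.
    """
    flen = _filter_length(wavelet_name)
    if n_samples < flen:
        raise ValueError(
            f"signal of length {n_samples} is shorter than the {wavelet_name} "
            f"filter length {flen}"
        )
    return int(np.floor(np.log2(n_samples / (flen - 1))))


def detail_band(level: int, fs: float) -> tuple[float, float]:
    """Approximate frequency band (Hz) of detail coefficients at ``level``."""
    return fs / 2 ** (level + 1), fs / 2**level


def approx_band(level_count: int, fs: float) -> tuple[float, float]:
    """Approximate frequency band (Hz) of the deepest approximation."""
    return 0.0, fs / 2 ** (level_count + 1)


@dataclass
class WaveletDecomposition:
    """Coefficients of a multilevel DWT of a single channel.

    ``details[0]`` is the finest band ``d_1``; ``approx`` is ``a_L``.
    """

    approx: np.ndarray
    details: list[np.ndarray]  # d_1 (finest) .. d_L (coarsest)
    wavelet_name: str = DEFAULT_WAVELET
    extension_mode: str = DEFAULT_MODE
    level_count: int = 0
    original_length: int = 0

    def __post_init__(self) -> None:
        self.approx = np.asarray(self.approx, dtype=float)
        self.details = [np.asarray(d, dtype=float) for d in self.details]
        if self.level_count == 0:
            self.level_count = len(self.details)
        if len(self.details) != self.level_count:
            raise ValueError(
                f"level_count {self.level_count} does not match "
                f"{len(self.details)} detail vectors"
            )

    def detail(self, level: int) -> np.ndarray:
        """Detail coefficients ``d_level`` (1-based, 1 = finest)."""
        if not 1 <= level <= self.level_count:
            raise ValueError(f"level {level} outside 1..{self.level_count}")
        return self.details[level - 1]

    def coefficient_energy(self) -> float:
        return float(
            np.sum(self.approx**2) + sum(np.sum(d**2) for d in self.details)
        )

    def to_json(self) -> str:
        """Serialize to a JSON container for debugging / provenance."""
        return json.dumps(
            {
                "wavelet": self.wavelet_name,
                "mode": self.extension_mode,
                "L": self.level_count,
                "N": self.original_length,
                "approx": self.approx.tolist(),
                "details": [d.tolist() for d in self.details],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "WaveletDecomposition":
        obj = json.loads(text)
        return cls(
            approx=np.array(obj["approx"], dtype=float),
            details=[np.array(d, dtype=float) for d in obj["details"]],
            wavelet_name=obj["wavelet"],
            extension_mode=obj["mode"],
            level_count=obj["L"],
            original_length=obj["N"],
        )


@dataclass
class CoefficientMask:
    """Which coefficients to suppress before the synthesis (rebuild) half.

    ``zeroed_detail_levels`` removes whole bands; ``per_level_thresholds``
    hard-suppresses coefficients whose magnitude exceeds the level threshold,
    restricted to ``localized_supports`` (coefficient-index intervals,
    half-open) when given for that level.
    """

    zero_approx: bool = False
    zeroed_detail_levels: frozenset[int] = field(default_factory=frozenset)
    per_level_thresholds: dict[int, float] | None = None
    localized_supports: dict[int, list[tuple[int, int]]] | None = None

    def validate(self, level_count: int) -> None:
        levels = set(self.zeroed_detail_levels)
        if self.per_level_thresholds:
            if any(t < 0 for t in self.per_level_thresholds.values()):
                raise ValueError("thresholds must be nonnegative")
            levels |= set(self.per_level_thresholds)
        if self.localized_supports:
            levels |= set(self.localized_supports)
        bad = [lv for lv in levels if not 1 <= lv <= level_count]
        if bad:
            raise ValueError(
                f"mask references levels {sorted(bad)} outside 1..{level_count}"
            )

    def apply(self, dec: WaveletDecomposition) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return (approx, details) with the mask applied (inputs untouched)."""
        self.validate(dec.level_count)
        approx = np.zeros_like(dec.approx) if self.zero_approx else dec.approx.copy()
        details = [d.copy() for d in dec.details]
        for lv in self.zeroed_detail_levels:
            details[lv - 1][:] = 0.0
        if self.per_level_thresholds:
            for lv, thr in self.per_level_thresholds.items():
                d = details[lv - 1]
                if self.localized_supports and lv in self.localized_supports:
                    for lo, hi in self.localized_supports[lv]:
                        seg = d[lo:hi]
                        seg[np.abs(seg) > thr] = 0.0
                else:
                    d[np.abs(d) > thr] = 0.0
        return approx, details


def dwt_decompose(
    signal: np.ndarray,
    level_count: int,
    wavelet_name: str = DEFAULT_WAVELET,
    extension_mode: str = DEFAULT_MODE,
) -> WaveletDecomposition:
    """Decompose ``signal`` into ``a_L`` and ``d_1 .. d_L``."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    max_level = max_decomposition_level(len(x), wavelet_name)
    if level_count < 1:
        raise ValueError("level_count must be >= 1")
    if level_count > max_level:
        raise ValueError(
            f"level_count {level_count} exceeds maximum admissible level "
            f"{max_level} for {len(x)} samples with {wavelet_name}"
        )
    coeffs = pywt.wavedec(x, wavelet_name, mode=extension_mode, level=level_count)
    # pywt returns [a_L, d_L, ..., d_1]; store d_1 first
    return WaveletDecomposition(
        approx=coeffs[0],
        details=list(reversed(coeffs[1:])),
        wavelet_name=wavelet_name,
        extension_mode=extension_mode,
        level_count=level_count,
        original_length=len(x),
    )


def dwt_rebuild(
    dec: WaveletDecomposition, mask: CoefficientMask | None = None
) -> np.ndarray:
    """Resynthesise the signal, optionally suppressing masked coefficients.

    With an empty mask this inverts :func:`dwt_decompose` to floating-point
    tolerance (perfect reconstruction of the orthogonal filter bank).
    """
    if mask is None:
        mask = CoefficientMask()
    approx, details = mask.apply(dec)
    coeffs = [approx] + list(reversed(details))
    out = pywt.waverec(coeffs, dec.wavelet_name, mode=dec.extension_mode)
    return np.asarray(out[: dec.original_length], dtype=float)
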