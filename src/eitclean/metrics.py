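"""Signal- and image-level agreement metrics for before/after comparisons.

Two signal metrics and two image metrics are provided, plus the
relative-improvement percentage used to summarise them:

* ``prd`` — percent root difference, the ratio of the residual sum of
  squares to the reference sum of squares, on a x100 scale. Implemented as
  the plain ratio of sums of squares (no square root); the classical
  square-root variant is available via ``root=True``.
* ``r_squared`` — the variance ratio sum((y - xbar)^2) / sum((x - xbar)^2)
  with ``xbar = mean(x)``. This is a similarity measure, not the regression
  coefficient of determination: it equals 1 for perfect agreement and CAN
  exceed 1 when the candidate is more variable than the reference (an
  artifact-contaminated signal typically is).
* ``image_error`` — sum|A - B| / sum|R| over in-mask pixels, with R the
  artifact-free reference image.
* ``image_corr`` — Pearson correlation of in-mask pixel values.

Images may be passed as plain arrays (NaN marks off-mask pixels) or as
:class:`eitclean.imaging.EITImage` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "prd",
    "r_squared",
    "image_error",
    "image_corr",
    "improvement_pct",
    "MetricsReport",
]


def _as_signal(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty signal")
    return arr


def prd(reference, candidate, *, root: bool = False) -> float:
    """Percent root difference between a reference and a candidate signal.

    ``100 * sum((x - y)^2) / sum(x^2)``; with ``root=True`` the classical
    square-root form ``100 * sqrt(.)`` is returned instead.
    """
    x = _as_signal(reference)
    y = _as_signal(candidate)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    denom = float(np.sum(x**2))
    if denom == 0.0:
        raise ValueError("reference signal has zero energy")
    ratio = float(np.sum((x - y) ** 2)) / denom
    return 100.0 * (np.sqrt(ratio) if root else ratio)


def r_squared(reference, candidate) -> float:
    """Variance ratio sum((y - xbar)^2) / sum((x - xbar)^2), xbar = mean(x)."""
    x = _as_signal(reference)
    y = _as_signal(candidate)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    xbar = float(np.mean(x))
    denom = float(np.sum((x - xbar) ** 2))
    if denom == 0.0:
        raise ValueError("reference signal is constant")
    return float(np.sum((y - xbar) ** 2)) / denom


def _image_values(img) -> np.ndarray:
    pixels = getattr(img, "pixels", img)
    arr = np.asarray(pixels, dtype=float)
    return arr


def _common_mask(*imgs: np.ndarray) -> np.ndarray:
    shape = imgs[0].shape
    for im in imgs[1:]:
        if im.shape != shape:
            raise ValueError("image shape mismatch")
    mask = np.ones(shape, dtype=bool)
    for im in imgs:
        mask &= np.isfinite(im)
    return mask


def image_error(a, b, reference) -> float:
    """sum|A_i - B_i| / sum|R_i| over the common in-mask pixels."""
    A, B, R = _image_values(a), _image_values(b), _image_values(reference)
    m = _common_mask(A, B, R)
    denom = float(np.sum(np.abs(R[m])))
    if denom == 0.0:
        raise ValueError("reference image has zero absolute sum over the mask")
    return float(np.sum(np.abs(A[m] - B[m]))) / denom


def image_corr(a, b) -> float:
    """Pearson correlation of in-mask pixel values; in [-1, 1]."""
    A, B = _image_values(a), _image_values(b)
    m = _common_mask(A, B)
    av, bv = A[m], B[m]
    if av.size < 2 or np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("images must be non-constant over the mask")
    ac = av - av.mean()
    bc = bv - bv.mean()
    return float(np.sum(ac * bc) / np.sqrt(np.sum(ac**2) * np.sum(bc**2)))


def improvement_pct(before: float, after: float) -> float:
    """Relative improvement ``(before - after) / before * 100`` (percent)."""
    if before == 0:
        raise ValueError("before-value must be nonzero")
    return (before - after) / before * 100.0


@dataclass
class MetricsReport:
    """Bundle of agreement metrics for one before/after comparison."""

    prd: float | None = None
    r2: float | None = None
    image_error: float | None = None
    image_corr: float | None = None
    improvement_pct: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {}
        for key in ("prd", "r2", "image_error", "image_corr"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        if self.improvement_pct:
            out["improvement_pct"] = dict(self.improvement_pct)
        return out
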