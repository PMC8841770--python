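"""Linear difference-EIT imaging on a 2-D 16-electrode disk phantom.

Reconstruction follows the dynamic (time-difference) formulation
``y = B (x_c - x_ref)``: each frame ``x`` holds the 208 boundary voltages of
one adjacent-drive cycle, and ``B`` is a regularized (one-step Tikhonov)
inverse of the linearized sensitivity matrix, composed with an
element-to-pixel rasterization onto a 32 x 32 grid with a circular mask.

The forward model is a piecewise-linear finite-element solution of the 2-D
conductivity equation on the unit disk with 16 equally spaced point
electrodes and unit background conductivity. Current is injected between
adjacent electrode pairs; voltages are measured between adjacent pairs not
involving the injecting electrodes, giving 16 x 13 = 208 channels per frame.

Channel ordering: channels are enumerated drive pair by drive pair. Drive
pair ``p`` (0-based) injects +1 at electrode ``p`` and -1 at electrode
``(p+1) % 16``; for each ``p`` the 13 usable measurement pairs ``q`` (again
``(q, q+1)``) are listed in increasing ``q``, skipping ``q`` in
``{p-1, p, p+1}`` (mod 16).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

__all__ = [
    "N_ELECTRODES",
    "N_CHANNELS",
    "FrameSeries",
    "EITImage",
    "SensitivityModel",
    "channel_table",
    "build_sensitivity",
    "forward_frame",
    "homogeneous_frame",
    "reconstruct",
    "reconstruct_series",
    "circular_inclusion",
]

N_ELECTRODES = 16
N_CHANNELS = 16 * 13  # adjacent drive, adjacent measurement -> 208
PIXEL_GRID = 32


# ---------------------------------------------------------------------------
# frame container
# ---------------------------------------------------------------------------

@dataclass
class FrameSeries:
    """Boundary-voltage frames over time: (n_frames, 208) matrix at ``fs`` Hz."""

    data: np.ndarray
    fs: float = 20.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != N_CHANNELS:
            raise ValueError(
                f"expected {N_CHANNELS} channels, got {self.data.shape[1]}"
            )
        if self.data.shape[0] == 0:
            raise ValueError("FrameSeries must contain at least one frame")
        if not np.all(np.isfinite(self.data)):
            frame, chan = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite voltage at frame {frame}, channel {chan}"
            )
        self.fs = float(self.fs)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, c: int) -> np.ndarray:
        return self.data[:, c]

    def global_waveform(self) -> np.ndarray:
        """Mean over channels (the global impedance waveform)."""
        return self.data.mean(axis=1)

    def to_csv(self, path) -> None:
        cols = [f"ch{c + 1:03d}" for c in range(N_CHANNELS)]
        pd.DataFrame(self.data, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float = 20.0) -> "FrameSeries":
        df = pd.read_csv(path)
        if "t" in df.columns:
            df = df.drop(columns=["t"])
        return cls(df.to_numpy(dtype=float), fs=fs)


def channel_table() -> list[tuple[int, int]]:
    """(drive pair, measurement pair) for each of the 208 channels, in order."""
    chans = []
    for p in range(N_ELECTRODES):
        skip = {(p - 1) % N_ELECTRODES, p, (p + 1) % N_ELECTRODES}
        for q in range(N_ELECTRODES):
            if q not in skip:
                chans.append((p, q))
    assert len(chans) == N_CHANNELS
    return chans


# ---------------------------------------------------------------------------
# mesh and finite-element machinery
# ---------------------------------------------------------------------------

def _disk_mesh(n_rings: int):
    """Structured triangulation of the unit disk.

    Ring ``k`` (k = 1..n_rings) has 16k nodes at radius k/n_rings, so the
    16 electrodes land exactly on boundary nodes every ``n_rings``-th node.
    Returns (nodes (n,2), triangles (m,3), electrode node indices (16,)).
    """
    pts = [(0.0, 0.0)]
    for k in range(1, n_rings + 1):
        r = k / n_rings
        m = 16 * k
        theta = 2 * np.pi * np.arange(m) / m
        pts.extend(zip(r * np.cos(theta), r * np.sin(theta)))
    nodes = np.array(pts)
    from scipy.spatial import Delaunay

    tri = Delaunay(nodes)
    simplices = tri.simplices
    # drop degenerate slivers (collinear boundary triples), if any
    p = nodes[simplices]
    areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    simplices = simplices[areas > 1e-12]
    first_boundary = 1 + 16 * (n_rings - 1) * n_rings // 2  # start of outer ring
    electrodes = first_boundary + n_rings * np.arange(16)
    return nodes, simplices, electrodes


def _element_geometry(nodes: np.ndarray, tris: np.ndarray):
    """Per-element areas and P1 shape-function gradient operators (2x3)."""
    p = nodes[tris]  # (m, 3, 2)
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    areas = 0.5 * np.abs(det)
    # gradient of barycentric coordinate i is the rotated opposite edge / 2A
    grads = np.empty((len(tris), 2, 3))
    for i in range(3):
        a = p[:, (i + 1) % 3]
        b = p[:, (i + 2) % 3]
        edge = b - a
        grads[:, 0, i] = -edge[:, 1]
        grads[:, 1, i] = edge[:, 0]
    grads /= det[:, None, None]
    return areas, grads


def _assemble_stiffness(nodes, tris, areas, grads, sigma=None) -> csc_matrix:
    m = len(tris)
    sig = np.ones(m) if sigma is None else np.asarray(sigma, dtype=float)
    # local stiffness K_e = sigma_e * A_e * G^T G  (3x3)
    gtg = np.einsum("eki,ekj->eij", grads, grads)  # (m,3,3)
    local = gtg * (sig * areas)[:, None, None]
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    K = coo_matrix((local.ravel(), (rows, cols)), shape=(len(nodes), len(nodes)))
    return K.tocsc()


@dataclass
class SensitivityModel:
    """Linearized forward/inverse operators for the disk phantom."""

    nodes: np.ndarray
    triangles: np.ndarray
    electrode_nodes: np.ndarray
    jacobian: np.ndarray          # (208, n_elements) dV/d(sigma)
    inverse_elements: np.ndarray  # (n_elements, 208) Tikhonov inverse
    alpha: float
    pixel_element: np.ndarray     # (32*32,) element index per pixel, -1 off-mask
    channels: list[tuple[int, int]] = field(default_factory=channel_table)
    reference_frame: np.ndarray | None = None  # homogeneous-background frame

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def mask(self) -> np.ndarray:
        return (self.pixel_element >= 0).reshape(PIXEL_GRID, PIXEL_GRID)

    def rasterize(self, element_values: np.ndarray) -> np.ndarray:
        """Map per-element values onto the 32x32 grid (NaN off-mask)."""
        vals = np.asarray(element_values, dtype=float)
        if vals.shape != (self.n_elements,):
            raise ValueError("element vector length mismatch")
        img = np.full(PIXEL_GRID * PIXEL_GRID, np.nan)
        inmask = self.pixel_element >= 0
        img[inmask] = vals[self.pixel_element[inmask]]
        return img.reshape(PIXEL_GRID, PIXEL_GRID)

    def inverse_norm(self) -> float:
        """Spectral norm of the element-space inverse (noise amplification)."""
        return float(np.linalg.norm(self.inverse_elements, 2))


@dataclass
class EITImage:
    """32x32 impedance-change image; NaN marks off-mask pixels."""

    pixels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (PIXEL_GRID, PIXEL_GRID):
            raise ValueError("expected a 32x32 pixel matrix")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.pixels)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.pixels).to_csv(path, index=False, header=False)


def build_sensitivity(
    mesh_resolution: int = 800, alpha: float | None = None
) -> SensitivityModel:
    """Build mesh, sensitivity matrix and regularized inverse.

    Parameters
    ----------
    mesh_resolution:
        Target element count (>= 200); the structured mesh uses the smallest
        ring count whose element count reaches it.
    alpha:
        Tikhonov parameter. Default ``1e-3 * trace(J^T J) / n_elements``.
    """
    if mesh_resolution < 200:
        raise ValueError("mesh_resolution must be >= 200 elements")
    n_rings = max(4, int(round(np.sqrt(mesh_resolution / 16))))
    nodes, tris, electrodes = _disk_mesh(n_rings)
    areas, grads = _element_geometry(nodes, tris)
    K = _assemble_stiffness(nodes, tris, areas, grads)

    # ground the center node to remove the Neumann nullspace
    K = K.tolil()
    K[0, :] = 0.0
    K[:, 0] = 0.0
    K[0, 0] = 1.0
    K = K.tocsc()
    try:
        lu = splu(K)
    except RuntimeError as exc:  # pragma: no cover - degenerate mesh
        raise ValueError(f"singular FEM system: {exc}") from exc

    # one potential field per adjacent injection pair
    n_nodes = len(nodes)
    rhs = np.zeros((n_nodes, N_ELECTRODES))
    for p in range(N_ELECTRODES):
        rhs[electrodes[p], p] += 1.0
        rhs[electrodes[(p + 1) % N_ELECTRODES], p] -= 1.0
    rhs[0, :] = 0.0  # grounded node
    U = lu.solve(rhs)  # (n_nodes, 16)

    # sensitivity by the adjoint-field formula:
    # dV(drive p, meas q)/d sigma_e = -A_e * grad(u_p) . grad(u_q)
    chans = channel_table()
    n_el = len(tris)
    J = np.empty((N_CHANNELS, n_el))
    Ue = U[tris]                       # (m, 3, 16)
    Ge = np.einsum("ekn,enp->ekp", grads, Ue)  # (m, 2, 16) element gradients
    P = -np.einsum("ekp,ekq,e->pqe", Ge, Ge, areas)  # (16, 16, m)
    for row, (p, q) in enumerate(chans):
        J[row] = P[p, q]

    jtj = J.T @ J
    if alpha is None:
        alpha = 1e-3 * float(np.trace(jtj)) / n_el
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    B = np.linalg.solve(jtj + alpha * np.eye(n_el), J.T)  # (n_el, 208)

    # pixel raster: nearest element centroid for in-disk pixel centers
    coords = (np.arange(PIXEL_GRID) + 0.5) / PIXEL_GRID * 2 - 1
    gx, gy = np.meshgrid(coords, coords)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    inmask = np.hypot(centers[:, 0], centers[:, 1]) <= 1.0
    centroids = nodes[tris].mean(axis=1)
    tree = cKDTree(centroids)
    pixel_element = np.full(PIXEL_GRID * PIXEL_GRID, -1, dtype=int)
    _, idx = tree.query(centers[inmask])
    pixel_element[inmask] = idx

    model = SensitivityModel(
        nodes=nodes,
        triangles=tris,
        electrode_nodes=electrodes,
        jacobian=J,
        inverse_elements=B,
        alpha=float(alpha),
        pixel_element=pixel_element,
    )

    # homogeneous-background measurement frame (useful as x_ref)
    frame = np.empty(N_CHANNELS)
    for row, (p, q) in enumerate(chans):
        e_a = electrodes[q]
        e_b = electrodes[(q + 1) % N_ELECTRODES]
        frame[row] = U[e_a, p] - U[e_b, p]
    model.reference_frame = frame
    return model


def forward_frame(model: SensitivityModel, conductivity_perturbation) -> np.ndarray:
    """Linearized boundary-voltage change ``J @ d_sigma`` for one frame."""
    d = np.asarray(conductivity_perturbation, dtype=float)
    if d.shape != (model.n_elements,):
        raise ValueError(
            f"expected perturbation of length {model.n_elements}, got {d.shape}"
        )
    return model.jacobian @ d


def homogeneous_frame(model: SensitivityModel) -> np.ndarray:
    """Measured frame of the homogeneous (unit-conductivity) background."""
    assert model.reference_frame is not None
    return model.reference_frame.copy()


def reconstruct(model: SensitivityModel, frame, reference) -> EITImage:
    """One-step Tikhonov difference image ``y = B (x_c - x_ref)``."""
    xc = np.asarray(frame, dtype=float).ravel()
    xr = np.asarray(reference, dtype=float).ravel()
    if xc.shape != (N_CHANNELS,) or xr.shape != (N_CHANNELS,):
        raise ValueError(f"frames must have {N_CHANNELS} channels")
    if not (np.all(np.isfinite(xc)) and np.all(np.isfinite(xr))):
        raise ValueError("non-finite voltages in frame or reference")
    elem = model.inverse_elements @ (xc - xr)
    return EITImage(model.rasterize(elem))


def reconstruct_series(
    model: SensitivityModel,
    frames: FrameSeries,
    reference_policy: str = "first_frame",
    reference_index: int = 0,
    mean_window: tuple[int, int] = (0, 1),
) -> list[EITImage]:
    """Reconstruct every frame against a reference chosen by policy.

    Policies: ``first_frame``, ``fixed_index`` (uses ``reference_index``),
    ``mean_window`` (mean frame over ``mean_window`` = half-open index range).
    """
    if reference_policy == "first_frame":
        ref = frames.data[0]
    elif reference_policy == "fixed_index":
        ref = frames.data[reference_index]
    elif reference_policy == "mean_window":
        lo, hi = mean_window
        if not 0 <= lo < hi <= frames.n_frames:
            raise ValueError("invalid mean_window")
        ref = frames.data[lo:hi].mean(axis=0)
    else:
        raise ValueError(f"unknown reference policy {reference_policy!r}")
    meta = {"reference_policy": reference_policy}
    images = []
    for i in range(frames.n_frames):
        img = reconstruct(model, frames.data[i], ref)
        img.metadata = dict(meta, frame=i)
        images.append(img)
    return images


def circular_inclusion(
    model: SensitivityModel, center: tuple[float, float], radius: float, value: float
) -> np.ndarray:
    """Per-element conductivity perturbation: ``value`` inside a disk."""
    centroids = model.nodes[model.triangles].mean(axis=1)
    d = np.hypot(centroids[:, 0] - center[0], centroids[:, 1] - center[1])
    out = np.zeros(model.n_elements)
    out[d <= radius] = value
    return out
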