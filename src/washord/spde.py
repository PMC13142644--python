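"""Finite-element SPDE representation of Matérn Gaussian random fields.

A Gaussian random field u(s) with Matérn covariance (smoothness ν = 1 in two
dimensions) is the stationary solution of the stochastic partial differential
equation (κ² − Δ) u(s) = W(s) scaled white noise.  Discretising u on a
triangulated mesh with piecewise-linear basis functions turns the field into
a Gaussian vector of node weights w whose precision matrix

    Q = τ² (κ⁴ C + 2 κ² G + G C⁻¹ G)

is sparse: C is the (lumped, diagonal) mass matrix, G the stiffness matrix,
κ = √8 / range links κ to the *practical range* (the distance at which the
Matérn ν=1 correlation drops to ≈ 0.14), and τ = 1 / (√(4π) κ σ_u) fixes the
marginal variance of the field at σ_u².

Coordinates are treated as planar Euclidean (longitude/latitude degrees used
directly); at the sub-continental extents this package targets the induced
metric distortion is a documented approximation, not corrected for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import Delaunay

__all__ = [
    "Mesh",
    "SpatialHyperparams",
    "build_mesh",
    "fem_matrices",
    "range_to_kappa",
    "kappa_to_range",
    "precision_matrix",
    "projection_matrix",
    "matern_correlation",
]

_SQRT8 = np.sqrt(8.0)


@dataclass
class Mesh:
    """Triangulated support of the SPDE field.

    Attributes
    ----------
    nodes : (n_m, 2) float array of node coordinates.
    triangles : (m, 3) int array of node-index triples.
    C : diagonal sparse mass matrix (mass-lumped).
    G : sparse symmetric stiffness matrix; G @ 1 = 0.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    C: sparse.dia_matrix = field(repr=False)
    G: sparse.csr_matrix = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def area(self) -> float:
        """Total meshed area = trace of the lumped mass matrix."""
        return float(self.C.diagonal().sum())

    def save(self, path) -> None:
        """Write nodes/triangles as a plain-text .npz-style container."""
        np.savez(path, nodes=self.nodes, triangles=self.triangles)

    @classmethod
    def load(cls, path) -> "Mesh":
        with np.load(path) as z:
            nodes, triangles = z["nodes"], z["triangles"]
        C, G = fem_matrices(nodes, triangles)
        return cls(nodes=nodes, triangles=triangles, C=C, G=G)


@dataclass
class SpatialHyperparams:
    """Log practical range and log marginal SD of the Matérn field."""

    log_range: float
    log_sigma_u: float

    def __post_init__(self):
        if not (np.isfinite(self.log_range) and np.isfinite(self.log_sigma_u)):
            raise ValueError("spatial hyperparameters must be finite")

    @property
    def range(self) -> float:
        return float(np.exp(self.log_range))

    @property
    def sigma_u(self) -> float:
        return float(np.exp(self.log_sigma_u))


def range_to_kappa(practical_range: float) -> float:
    """κ = √8 / range for a Matérn field with ν = 1 in two dimensions."""
    if practical_range <= 0:
        raise ValueError(f"practical range must be positive, got {practical_range}")
    return _SQRT8 / practical_range


def kappa_to_range(kappa: float) -> float:
    """Inverse of :func:`range_to_kappa`."""
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    return _SQRT8 / kappa


def matern_correlation(h, practical_range: float):
    """Closed-form Matérn ν=1 correlation (κh)·K₁(κh) at distance h.

    Equals 1 at h = 0 and ≈ 0.139 at h = practical range.
    """
    from scipy.special import k1

    kappa = range_to_kappa(practical_range)
    h = np.asarray(h, dtype=float)
    x = kappa * h
    with np.errstate(invalid="ignore"):
        rho = np.where(x > 0, x * k1(np.maximum(x, 1e-300)), 1.0)
    return rho


def build_mesh(points: np.ndarray, buffer_fraction: float = 0.2,
               max_edge: float | None = None) -> Mesh:
    """Delaunay-triangulate observation points plus an outer buffer ring.

    The ring of boundary nodes extends the convex hull outward by
    ``buffer_fraction`` of the point-cloud diameter, mitigating the variance
    inflation the SPDE approximation suffers near the mesh boundary.  If
    ``max_edge`` is given, a regular grid of filler nodes at that spacing is
    added over the buffered bounding box so triangles stay quasi-uniform even
    where observation points are sparse.

    All input points are mesh nodes (the first ``len(points)`` nodes, in
    order).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise ValueError("need at least 3 points of shape (n, 2)")
    # uniqueness check for degeneracy only; duplicates collapse triangles
    span = points.max(axis=0) - points.min(axis=0)
    diameter = float(np.hypot(*span))
    if diameter == 0.0:
        raise ValueError("all points coincide; cannot build a mesh")

    extra = []
    if buffer_fraction > 0:
        buf = buffer_fraction * diameter
        center = 0.5 * (points.max(axis=0) + points.min(axis=0))
        half = 0.5 * span + buf
        lo, hi = center - half, center + half
        # nodes along the buffered bounding-box perimeter, spaced ~ buf/1.5
        # (or max_edge when finer), corners included exactly once
        spacing = buf / 1.5 if max_edge is None else min(buf / 1.5, max_edge)
        nx = max(2, int(np.ceil((hi[0] - lo[0]) / spacing)) + 1)
        ny = max(2, int(np.ceil((hi[1] - lo[1]) / spacing)) + 1)
        xs = np.linspace(lo[0], hi[0], nx)
        ys = np.linspace(lo[1], hi[1], ny)
        ring = np.vstack([
            np.column_stack([xs, np.full(nx, lo[1])]),
            np.column_stack([xs, np.full(nx, hi[1])]),
            np.column_stack([np.full(ny - 2, lo[0]), ys[1:-1]]),
            np.column_stack([np.full(ny - 2, hi[0]), ys[1:-1]]),
        ])
        extra.append(ring)
    else:
        lo = points.min(axis=0)
        hi = points.max(axis=0)
    if max_edge is not None:
        if max_edge <= 0:
            raise ValueError("max_edge must be positive")
        gx = np.arange(lo[0], hi[0] + 0.5 * max_edge, max_edge)
        gy = np.arange(lo[1], hi[1] + 0.5 * max_edge, max_edge)
        gxx, gyy = np.meshgrid(gx, gy)
        grid = np.column_stack([gxx.ravel(), gyy.ravel()])
        # drop filler nodes that sit (almost) on top of an existing node
        from scipy.spatial import cKDTree

        tree = cKDTree(np.vstack([points] + extra))
        d, _ = tree.query(grid)
        extra.append(grid[d > 0.3 * max_edge])

    all_nodes = np.vstack([points] + extra) if extra else points
    # deduplicate non-observation nodes against observation nodes
    try:
        tri = Delaunay(all_nodes)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate point configuration: {exc}") from exc
    if tri.coplanar.size:
        # coplanar points were dropped by qhull; only acceptable for fillers
        dropped = set(tri.coplanar[:, 0])
        if any(i < len(points) for i in dropped):
            raise ValueError("input points degenerate under triangulation")
    nodes = tri.points
    triangles = tri.simplices
    # drop zero-area slivers that qhull can emit on cocircular boundary nodes
    areas = _triangle_areas(nodes, triangles)
    keep = areas > 1e-12 * max(areas.max(), 1.0)
    triangles = triangles[keep]
    # prune auxiliary nodes left unreferenced (qhull-merged near-duplicates);
    # observation nodes must all survive
    used = np.zeros(nodes.shape[0], dtype=bool)
    used[triangles.ravel()] = True
    if not used[: len(points)].all():
        raise ValueError("an input point was lost during triangulation "
                         "(duplicate or degenerate coordinates?)")
    if not used.all():
        remap = -np.ones(nodes.shape[0], dtype=np.int64)
        remap[used] = np.arange(used.sum())
        nodes = nodes[used]
        triangles = remap[triangles]
    C, G = fem_matrices(nodes, triangles)
    return Mesh(nodes=nodes, triangles=triangles, C=C, G=G)


def _triangle_areas(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p0 = nodes[triangles[:, 0]]
    e1 = nodes[triangles[:, 1]] - p0
    e2 = nodes[triangles[:, 2]] - p0
    return 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])


def fem_matrices(nodes: np.ndarray, triangles: np.ndarray):
    """Assemble P1 finite-element mass (lumped) and stiffness matrices.

    C is diagonal with C_ii = one third of the total area of triangles
    incident to node i; G is the standard piecewise-linear stiffness matrix
    assembled from per-triangle basis-function gradients.
    """
    nodes = np.asarray(nodes, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    n = nodes.shape[0]
    if triangles.min() < 0 or triangles.max() >= n:
        raise ValueError("triangle node indices out of range")
    areas = _triangle_areas(nodes, triangles)
    bad = np.nonzero(areas <= 0)[0]
    if bad.size:
        raise ValueError(f"zero-area triangle(s) at indices {bad.tolist()}")

    c_diag = np.zeros(n)
    np.add.at(c_diag, triangles.ravel(),
              np.repeat(areas / 3.0, 3))

    # per-triangle gradients of the three barycentric basis functions
    p0, p1, p2 = (nodes[triangles[:, k]] for k in range(3))
    # edge vectors opposite each vertex
    e0 = p2 - p1
    e1 = p0 - p2
    e2 = p1 - p0
    # grad φ_k = rot90(e_k) / (2 A); stiffness entries = A * gradφ_i · gradφ_j
    rows, cols, vals = [], [], []
    edges = (e0, e1, e2)
    for i in range(3):
        gi = np.column_stack([-edges[i][:, 1], edges[i][:, 0]]) / (2 * areas)[:, None]
        for j in range(3):
            gj = np.column_stack([-edges[j][:, 1], edges[j][:, 0]]) / (2 * areas)[:, None]
            vals.append(areas * np.einsum("ij,ij->i", gi, gj))
            rows.append(triangles[:, i])
            cols.append(triangles[:, j])
    G = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    G.sum_duplicates()
    C = sparse.diags(c_diag)
    return C, G.tocsr()


def precision_matrix(mesh: Mesh, hyper: SpatialHyperparams) -> sparse.csc_matrix:
    """Sparse precision of the mesh-node weights of the Matérn ν=1 field.

    Q = τ² (κ⁴ C + 2 κ² G + G C⁻¹ G) with τ chosen so that the stationary
    marginal variance is σ_u² (σ² = 1/(4π κ² τ²) for ν = 1, d = 2).
    """
    sigma_u = hyper.sigma_u
    if sigma_u <= 0:
        raise ValueError("sigma_u must be positive; drop the field instead of "
                         "passing a degenerate scale")
    kappa = range_to_kappa(hyper.range)
    tau = 1.0 / (np.sqrt(4 * np.pi) * kappa * sigma_u)
    C = mesh.C.tocsc()
    G = mesh.G.tocsc()
    c_inv = sparse.diags(1.0 / mesh.C.diagonal())
    Q = tau**2 * (kappa**4 * C + 2 * kappa**2 * G + G @ c_inv @ G)
    Q = 0.5 * (Q + Q.T)  # kill round-off asymmetry
    return Q.tocsc()


def projection_matrix(mesh: Mesh, locations: np.ndarray,
                      warn_outside: bool = True) -> sparse.csr_matrix:
    """Barycentric interpolation matrix A mapping node weights to locations.

    Row i holds the (≤ 3, nonnegative, unit-sum) barycentric coordinates of
    location i within its containing triangle.  Locations outside the mesh
    get an all-zero row (no spatial contribution) and trigger a warning.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    tri = Delaunay(mesh.nodes)  # qhull point order == node order
    simplex = tri.find_simplex(locations)
    inside = simplex >= 0
    n_out = int((~inside).sum())
    if n_out and warn_outside:
        warnings.warn(f"{n_out} location(s) outside the mesh get zero spatial "
                      "contribution", stacklevel=2)
    rows, cols, vals = [], [], []
    if inside.any():
        idx = np.nonzero(inside)[0]
        s = simplex[idx]
        T = tri.transform[s]
        bary2 = np.einsum("ijk,ik->ij", T[:, :2, :], locations[idx] - T[:, 2, :])
        bary = np.column_stack([bary2, 1.0 - bary2.sum(axis=1)])
        bary = np.clip(bary, 0.0, 1.0)
        bary /= bary.sum(axis=1, keepdims=True)
        verts = tri.simplices[s]
        rows.append(np.repeat(idx, 3))
        cols.append(verts.ravel())
        vals.append(bary.ravel())
    A = sparse.coo_matrix(
        (np.concatenate(vals) if vals else [],
         (np.concatenate(rows) if rows else [],
          np.concatenate(cols) if cols else [])),
        shape=(locations.shape[0], mesh.n_nodes),
    )
    return A.tocsr()
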