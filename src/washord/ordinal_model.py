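"""Cumulative-logit ordinal regression with cluster and spatial random effects.

The observed ordinal category y ∈ {0, …, K−1} arises from a latent variable

    z_i = x_i'β + u(s_i) + b_c(i),

where u is a Matérn Gaussian random field (SPDE representation, see
:mod:`washord.spde`) evaluated at the household's cluster coordinates and
b_c is an iid Gaussian cluster random effect.  Category membership follows
the cumulative logit link P(y ≤ k) = logit⁻¹(θ_k − z) with monotone
thresholds θ_1 < … < θ_{K−1}.  There is no fixed intercept: the thresholds
absorb location, the standard cumulative-logit identifiability convention.

Estimation maximises the Laplace-approximated marginal likelihood: the joint
negative log-likelihood (ordinal data term + Gaussian penalties for b and
the field weights w) is minimised over (b, w) by sparse Newton iterations,
and the marginal criterion JNLL(mode) + ½ log det H − (n_re/2) log 2π is
minimised over the fixed parameters by a quasi-Newton outer loop with
central finite-difference gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.special import expit

from . import spde as spde_mod
from .spde import Mesh, SpatialHyperparams

__all__ = [
    "ModelParams",
    "RandomEffects",
    "FittedModel",
    "MeshConfig",
    "FitConfig",
    "thresholds_from_raw",
    "class_probabilities",
    "ordinal_nll",
    "joint_nll",
    "inner_mode",
    "laplace_marginal_nll",
    "fit",
]

_D_FLOOR = 1e-10  # floor on latent second derivatives, keeps H positive definite


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ModelParams:
    """Unconstrained fixed-parameter vector of the ordinal spatial model.

    Thresholds are parameterised as θ_1 = theta1, θ_k = θ_{k−1} +
    exp(log_deltas[k−2]) so any real vector maps to a strictly increasing
    threshold set.  Hyperparameters are stored on the log scale; a ``None``
    entry means the corresponding random-effect block is absent from the
    model (e.g. no spatial field).
    """

    beta: np.ndarray
    theta1: float
    log_deltas: np.ndarray
    log_sigma_b: float | None = None
    log_range: float | None = None
    log_sigma_u: float | None = None

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.log_deltas = np.asarray(self.log_deltas, dtype=float).reshape(-1)
        vals = [self.beta, [self.theta1], self.log_deltas]
        for v in (self.log_sigma_b, self.log_range, self.log_sigma_u):
            if v is not None:
                vals.append([v])
        if not all(np.all(np.isfinite(v)) for v in vals):
            raise ValueError("ModelParams entries must be finite")

    @property
    def thresholds(self) -> np.ndarray:
        return thresholds_from_raw(self.theta1, self.log_deltas)

    @property
    def K(self) -> int:
        return len(self.log_deltas) + 2

    @property
    def sigma_b(self) -> float | None:
        return None if self.log_sigma_b is None else float(np.exp(self.log_sigma_b))

    @property
    def spatial(self) -> SpatialHyperparams | None:
        if self.log_range is None or self.log_sigma_u is None:
            return None
        return SpatialHyperparams(self.log_range, self.log_sigma_u)


@dataclass
class RandomEffects:
    """Cluster effects b (one per cluster) and mesh-node field weights w."""

    b: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float).reshape(-1)
        self.w = np.asarray(self.w, dtype=float).reshape(-1)
        if not (np.all(np.isfinite(self.b)) and np.all(np.isfinite(self.w))):
            raise ValueError("random effects must be finite")

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate([self.b, self.w])


# ---------------------------------------------------------------------------
# likelihood primitives


def thresholds_from_raw(theta1: float, log_deltas) -> np.ndarray:
    """Map (θ_1, log increments) to strictly increasing thresholds."""
    log_deltas = np.asarray(log_deltas, dtype=float).reshape(-1)
    return np.concatenate([[theta1], theta1 + np.cumsum(np.exp(log_deltas))])


def _check_thresholds(thresholds) -> np.ndarray:
    thresholds = np.asarray(thresholds, dtype=float).reshape(-1)
    if thresholds.size == 0 or np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be non-empty and strictly increasing")
    return thresholds


def class_probabilities(z, thresholds) -> np.ndarray:
    """Category probabilities p_k = σ(θ_k − z) − σ(θ_{k−1} − z), k = 0..K−1.

    ``z`` may be a scalar or an array; the result has one trailing axis of
    length K = len(thresholds) + 1 and rows summing to 1.
    """
    thresholds = _check_thresholds(thresholds)
    z = np.asarray(z, dtype=float)
    cum = expit(thresholds - z[..., None])  # P(y <= k), k = 0..K-2
    ones = np.ones(z.shape + (1,))
    zeros = np.zeros(z.shape + (1,))
    upper = np.concatenate([cum, ones], axis=-1)
    lower = np.concatenate([zeros, cum], axis=-1)
    return upper - lower


def _log_sigmoid(x):
    return -np.logaddexp(0.0, -x)


def _bracket_thresholds(y, thresholds, K):
    """Per-observation (lower, upper) thresholds with ±inf sentinels."""
    th_up = np.concatenate([thresholds, [np.inf]])[y]
    th_lo = np.concatenate([[-np.inf], thresholds])[y]
    return th_lo, th_up


def ordinal_nll(y, z, thresholds):
    """Per-observation −log p_y(z), numerically stable for |θ−z| ≲ 700.

    Uses the identity σ(a) − σ(b) = σ(a)σ(−b)(1 − e^{b−a}) so wide bins and
    extreme latent values never suffer catastrophic cancellation.
    """
    thresholds = _check_thresholds(thresholds)
    K = len(thresholds) + 1
    y = np.asarray(y)
    if np.any((y < 0) | (y >= K)):
        raise ValueError(f"categories must lie in 0..{K - 1}")
    z = np.asarray(z, dtype=float)
    y, z = np.broadcast_arrays(y, z)
    th_lo, th_up = _bracket_thresholds(y, thresholds, K)
    a = th_up - z
    b = th_lo - z
    logp = np.empty(z.shape)
    top = ~np.isfinite(a)      # y = K-1: p = σ(−b)
    bot = ~np.isfinite(b)      # y = 0:   p = σ(a)
    mid = ~(top | bot)
    logp[bot] = _log_sigmoid(a[bot])
    logp[top] = _log_sigmoid(-b[top])
    if mid.any():
        am, bm = a[mid], b[mid]
        logp[mid] = (_log_sigmoid(am) + _log_sigmoid(-bm)
                     + np.log1p(-np.exp(bm - am)))
    return -logp


def _ordinal_derivs(y, z, thresholds):
    """(nll, d nll/dz, d² nll/dz²) per observation; second derivative floored.

    The cumulative-logit NLL is convex in z, so the floored curvature keeps
    the inner Newton Hessian positive definite even in flat tails.
    """
    nll = ordinal_nll(y, z, thresholds)
    p = np.exp(-nll)
    th_lo, th_up = _bracket_thresholds(np.asarray(y), np.asarray(thresholds, float),
                                       len(thresholds) + 1)
    a = th_up - z
    b = th_lo - z
    sa = expit(np.where(np.isfinite(a), a, 0.0))
    sb = expit(np.where(np.isfinite(b), b, 0.0))
    fa = np.where(np.isfinite(a), sa * (1 - sa), 0.0)
    fb = np.where(np.isfinite(b), sb * (1 - sb), 0.0)
    fpa = np.where(np.isfinite(a), fa * (1 - 2 * sa), 0.0)
    fpb = np.where(np.isfinite(b), fb * (1 - 2 * sb), 0.0)
    lp1 = (fb - fa) / p               # d log p / dz
    lp2 = (fpa - fpb) / p - lp1**2    # d² log p / dz²
    d1 = -lp1
    d2 = np.maximum(-lp2, _D_FLOOR)
    return nll, d1, d2


def _sparse_logdet(M: sparse.spmatrix) -> float:
    """log det of a symmetric positive-definite sparse matrix via sparse LU."""
    lu = splu(sparse.csc_matrix(M))
    diag = lu.U.diagonal()
    if np.any(diag == 0):
        raise np.linalg.LinAlgError("singular matrix in log-determinant")
    return float(np.sum(np.log(np.abs(diag))))


# ---------------------------------------------------------------------------
# model workspace: precomputed design pieces shared by all likelihood calls


class _Workspace:
    """Assembled design for one dataset/mesh pair.

    Holds X, y, the cluster incidence matrix Z, the household projection
    matrix A_h (observation rows of the mesh projection), the stacked
    random-effect Jacobian J = [Z, A_h], and the FEM matrices needed to
    rebuild the field precision Q for any hyperparameter value.  Caches the
    latest inner mode for warm-started Laplace evaluations.
    """

    def __init__(self, data, mesh: Mesh | None, A: sparse.spmatrix | None,
                 use_cluster: bool = True):
        self.X = data.X
        self.y = np.asarray(data.households["y"].to_numpy(), dtype=np.int64)
        codes, uniques = pd.factorize(data.households["cluster_id"], sort=True)
        self.cluster_idx = codes
        self.cluster_ids = uniques
        self.n = len(self.y)
        self.n_clusters = len(uniques)
        self.K = data.K
        self.use_cluster = use_cluster
        self.mesh = mesh
        if mesh is not None:
            if A is None:
                raise ValueError("mesh given without projection matrix")
            A = sparse.csr_matrix(A)
            if A.shape[0] == self.n_clusters:   # cluster-level projection
                A = A[self.cluster_idx]
            elif A.shape[0] != self.n:
                raise ValueError("projection matrix rows match neither "
                                 "clusters nor households")
            self.A_h = A
            self.GCG = (mesh.G @ sparse.diags(1.0 / mesh.C.diagonal())
                        @ mesh.G).tocsc()
            self.n_mesh = mesh.n_nodes
        else:
            self.A_h = None
            self.n_mesh = 0
        blocks = []
        if use_cluster:
            Z = sparse.csr_matrix(
                (np.ones(self.n), (np.arange(self.n), self.cluster_idx)),
                shape=(self.n, self.n_clusters))
            blocks.append(Z)
        if self.A_h is not None:
            blocks.append(self.A_h)
        if not blocks:
            raise ValueError("model needs at least one random-effect block")
        self.J = sparse.hstack(blocks).tocsr()
        self.n_re = self.J.shape[1]
        self._warm = np.zeros(self.n_re)

    # -- pieces -----------------------------------------------------------

    def split(self, v: np.ndarray) -> RandomEffects:
        nb = self.n_clusters if self.use_cluster else 0
        return RandomEffects(b=v[:nb], w=v[nb:])

    def precision_Q(self, params: ModelParams) -> sparse.csc_matrix | None:
        hyper = params.spatial
        if self.mesh is None or hyper is None:
            return None
        kappa = spde_mod.range_to_kappa(hyper.range)
        tau = 1.0 / (np.sqrt(4 * np.pi) * kappa * hyper.sigma_u)
        Q = tau**2 * (kappa**4 * self.mesh.C.tocsc()
                      + 2 * kappa**2 * self.mesh.G.tocsc() + self.GCG)
        return sparse.csc_matrix(0.5 * (Q + Q.T))

    def prior_block(self, params: ModelParams):
        """(sparse prior precision P, prior nll constant+logdet part)."""
        parts = []
        const = 0.0
        if self.use_cluster:
            if params.log_sigma_b is None:
                raise ValueError("cluster block active but log_sigma_b is None")
            sb2 = np.exp(2 * min(params.log_sigma_b, 150.0))
            parts.append(sparse.identity(self.n_clusters) / sb2)
            const += 0.5 * self.n_clusters * np.log(2 * np.pi) \
                + self.n_clusters * params.log_sigma_b
        if self.A_h is not None:
            Q = self.precision_Q(params)
            parts.append(Q)
            const += 0.5 * self.n_mesh * np.log(2 * np.pi) \
                - 0.5 * _sparse_logdet(Q)
        P = sparse.block_diag(parts, format="csc")
        return P, const

    def latent(self, params: ModelParams, v: np.ndarray) -> np.ndarray:
        return self.X @ params.beta + self.J @ v

    def joint_nll(self, params: ModelParams, v: np.ndarray,
                  P=None, prior_const=None) -> float:
        if P is None:
            P, prior_const = self.prior_block(params)
        z = self.latent(params, v)
        data_term = float(ordinal_nll(self.y, z, params.thresholds).sum())
        quad = 0.5 * float(v @ (P @ v))
        total = data_term + prior_const + quad
        if not np.isfinite(total):
            raise FloatingPointError(
                "non-finite joint NLL "
                f"(data={data_term}, prior_quad={quad}, const={prior_const})")
        return total

    def newton_mode(self, params: ModelParams, tol: float = 1e-8,
                    max_iter: int = 100, start: np.ndarray | None = None):
        """Inner Newton optimisation of the joint NLL over (b, w).

        Monotone: full Newton steps are halved until the joint NLL does not
        increase.  Returns (mode v, sparse Hessian H at mode, jnll at mode,
        trajectory of jnll values).
        """
        P, prior_const = self.prior_block(params)
        v = np.array(self._warm if start is None else start, dtype=float)
        if v.shape != (self.n_re,):
            v = np.zeros(self.n_re)
        thresholds = params.thresholds
        eta = self.X @ params.beta
        f = self.joint_nll(params, v, P, prior_const)
        traj = [f]
        H = None
        converged = False
        for _ in range(max_iter):
            z = eta + self.J @ v
            _, d1, d2 = _ordinal_derivs(self.y, z, thresholds)
            grad = self.J.T @ d1 + P @ v
            gnorm = float(np.max(np.abs(grad)))
            H = (self.J.T @ sparse.diags(d2) @ self.J + P).tocsc()
            if gnorm < tol:
                converged = True
                break
            step = splu(H).solve(grad)
            # Newton decrement: scale-free optimality measure, robust when H
            # is too ill-conditioned for the gradient norm to keep shrinking
            if 0.5 * abs(float(grad @ step)) < 1e-13 * (1.0 + abs(f)):
                converged = True
                break
            t = 1.0
            for _ in range(40):
                f_new = self.joint_nll(params, v - t * step, P, prior_const)
                # relative accept tolerance: near the optimum real
                # improvements sit below the absolute float resolution of f
                if f_new <= f + 1e-11 * (1.0 + abs(f)):
                    break
                t *= 0.5
            else:
                converged = True  # no descent possible: numerical optimum
                break
            v = v - t * step
            f = f_new
            traj.append(f)
        if not converged:
            raise RuntimeError(
                f"inner Newton did not converge in {max_iter} iterations; "
                f"joint NLL trajectory: {traj}")
        self._warm = v.copy()
        return v, H, f, traj

    def marginal_nll(self, params: ModelParams, inner_tol: float = 1e-8,
                     max_inner: int = 100) -> float:
        v, H, f, _ = self.newton_mode(params, tol=inner_tol,
                                      max_iter=max_inner)
        return f + 0.5 * _sparse_logdet(H) - 0.5 * self.n_re * np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# public functional API (thin wrappers over the workspace)


def joint_nll(params: ModelParams, re: RandomEffects, data,
              mesh: Mesh | None = None, A: sparse.spmatrix | None = None,
              use_cluster: bool = True) -> float:
    """Joint negative log-likelihood: ordinal data term + Gaussian penalties.

    Sums (i) per-household −log p_y(z) with z = x'β + (Aw) + b_c, (ii) the
    N(0, σ_b²I) negative log-density of b, (iii) the N(0, Q⁻¹) negative
    log-density of the field weights w, all with normalising constants.
    """
    ws = _Workspace(data, mesh, A, use_cluster=use_cluster)
    return ws.joint_nll(params, re.stacked)


def inner_mode(params: ModelParams, data, mesh=None, A=None,
               tol: float = 1e-8, max_iter: int = 100,
               use_cluster: bool = True):
    """Newton mode of the random effects and the sparse Hessian there."""
    ws = _Workspace(data, mesh, A, use_cluster=use_cluster)
    v, H, _, _ = ws.newton_mode(params, tol=tol, max_iter=max_iter)
    return ws.split(v), H


def laplace_marginal_nll(params: ModelParams, data, mesh=None, A=None,
                         use_cluster: bool = True,
                         inner_tol: float = 1e-8) -> float:
    """Laplace-approximated marginal NLL of the fixed parameters."""
    ws = _Workspace(data, mesh, A, use_cluster=use_cluster)
    return ws.marginal_nll(params, inner_tol=inner_tol)


# ---------------------------------------------------------------------------
# outer fit


@dataclass
class MeshConfig:
    buffer_fraction: float = 0.25
    max_edge: float | None = None


@dataclass
class FitConfig:
    use_spatial: bool = True
    use_cluster: bool = True
    outer_tol: float = 1e-5
    inner_tol: float = 1e-8
    max_outer: int = 300
    max_inner: int = 100
    compute_cov: bool = True
    hessian_step: float = 1e-4
    start: ModelParams | None = None


@dataclass
class FittedModel:
    """Everything needed to predict and diagnose from a fitted model."""

    params: ModelParams
    re_mode: RandomEffects
    param_cov: np.ndarray
    param_names: list
    conditional_precision: sparse.csc_matrix
    mesh: Mesh | None
    standardization: dict
    design_columns: list
    K: int
    convergence: dict
    use_cluster: bool = True
    cluster_ids: np.ndarray | None = None

    @property
    def beta_cov(self) -> np.ndarray:
        p = len(self.params.beta)
        return self.param_cov[:p, :p]

    @property
    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov))

    def save(self, path) -> None:
        """Serialise to <path>.npz (arrays) + <path>.yaml (metadata)."""
        path = Path(path)
        H = sparse.coo_matrix(self.conditional_precision)
        arrays = dict(
            beta=self.params.beta, log_deltas=self.params.log_deltas,
            b=self.re_mode.b, w=self.re_mode.w,
            param_cov=self.param_cov,
            H_row=H.row, H_col=H.col, H_data=H.data,
            H_shape=np.array(H.shape),
        )
        if self.mesh is not None:
            arrays.update(mesh_nodes=self.mesh.nodes,
                          mesh_triangles=self.mesh.triangles)
        if self.cluster_ids is not None:
            arrays.update(cluster_ids=np.asarray(self.cluster_ids))
        np.savez(path.with_suffix(".npz"), **arrays)
        scalars = {k: (None if v is None else float(v)) for k, v in
                   dict(theta1=self.params.theta1,
                        log_sigma_b=self.params.log_sigma_b,
                        log_range=self.params.log_range,
                        log_sigma_u=self.params.log_sigma_u).items()}
        meta = dict(
            K=int(self.K), params=scalars,
            param_names=[str(s) for s in self.param_names],
            design_columns=[str(s) for s in self.design_columns],
            standardization={k: [float(m), float(s)] for k, (m, s)
                             in self.standardization.items()},
            convergence={k: (float(v) if np.isscalar(v) else v)
                         for k, v in self.convergence.items()},
            use_cluster=bool(self.use_cluster),
        )
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path) -> "FittedModel":
        path = Path(path)
        meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
        with np.load(path.with_suffix(".npz"), allow_pickle=False) as z:
            arrays = {k: z[k] for k in z.files}
        s = meta["params"]
        params = ModelParams(beta=arrays["beta"], theta1=s["theta1"],
                             log_deltas=arrays["log_deltas"],
                             log_sigma_b=s["log_sigma_b"],
                             log_range=s["log_range"],
                             log_sigma_u=s["log_sigma_u"])
        H = sparse.coo_matrix(
            (arrays["H_data"], (arrays["H_row"], arrays["H_col"])),
            shape=tuple(arrays["H_shape"])).tocsc()
        mesh = None
        if "mesh_nodes" in arrays:
            C, G = spde_mod.fem_matrices(arrays["mesh_nodes"],
                                         arrays["mesh_triangles"])
            mesh = Mesh(nodes=arrays["mesh_nodes"],
                        triangles=arrays["mesh_triangles"], C=C, G=G)
        return cls(params=params,
                   re_mode=RandomEffects(arrays["b"], arrays["w"]),
                   param_cov=arrays["param_cov"],
                   param_names=meta["param_names"],
                   conditional_precision=H, mesh=mesh,
                   standardization={k: tuple(v) for k, v in
                                    meta["standardization"].items()},
                   design_columns=meta["design_columns"], K=meta["K"],
                   convergence=meta["convergence"],
                   use_cluster=meta["use_cluster"],
                   cluster_ids=arrays.get("cluster_ids"))


def _pack(params: ModelParams, cfg: FitConfig) -> tuple[np.ndarray, list]:
    vec = list(params.beta) + [params.theta1] + list(params.log_deltas)
    names = [f"beta[{i}]" for i in range(len(params.beta))] + ["theta1"] \
        + [f"log_delta[{i}]" for i in range(len(params.log_deltas))]
    if cfg.use_cluster:
        vec.append(params.log_sigma_b)
        names.append("log_sigma_b")
    if cfg.use_spatial:
        vec += [params.log_range, params.log_sigma_u]
        names += ["log_range", "log_sigma_u"]
    return np.asarray(vec, dtype=float), names


def _unpack(vec: np.ndarray, p: int, K: int, cfg: FitConfig) -> ModelParams:
    i = 0
    beta = vec[i:i + p]; i += p
    theta1 = float(vec[i]); i += 1
    log_deltas = vec[i:i + K - 2]; i += K - 2
    log_sigma_b = log_range = log_sigma_u = None
    if cfg.use_cluster:
        log_sigma_b = float(vec[i]); i += 1
    if cfg.use_spatial:
        log_range = float(vec[i]); log_sigma_u = float(vec[i + 1]); i += 2
    return ModelParams(beta=beta, theta1=theta1, log_deltas=log_deltas,
                       log_sigma_b=log_sigma_b, log_range=log_range,
                       log_sigma_u=log_sigma_u)


def _fd_gradient(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference gradient of a scalar function."""
    d = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    g = np.empty(d)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        g[i] = (fun(x + ei) - fun(x - ei)) / (2 * h[i])
    return g


def _fd_hessian(fun, x: np.ndarray, step: float) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    d = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    f0 = fun(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _start_values(ws: _Workspace, data, cfg: FitConfig) -> ModelParams:
    """Scale-aware defaults: β = 0, thresholds from empirical cumulative
    frequencies, σ_b = 0.5, range = ¼ domain diameter, σ_u = 0.5."""
    K = ws.K
    freqs = np.bincount(ws.y, minlength=K) / ws.n
    cum = np.cumsum(freqs)[:-1]
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    theta = np.log(cum / (1 - cum))
    theta1 = float(theta[0])
    diffs = np.maximum(np.diff(theta), 1e-3)
    log_deltas = np.log(diffs)
    log_sigma_b = np.log(0.5) if cfg.use_cluster else None
    log_range = log_sigma_u = None
    if cfg.use_spatial:
        coords = data.clusters[["lon", "lat"]].to_numpy()
        span = coords.max(axis=0) - coords.min(axis=0)
        diam = float(np.hypot(*span))
        log_range = float(np.log(max(diam / 4.0, 1e-3)))
        log_sigma_u = float(np.log(0.5))
    return ModelParams(beta=np.zeros(ws.X.shape[1]), theta1=theta1,
                       log_deltas=log_deltas, log_sigma_b=log_sigma_b,
                       log_range=log_range, log_sigma_u=log_sigma_u)


def fit(data, mesh_config: MeshConfig | None = None,
        fit_config: FitConfig | None = None) -> FittedModel:
    """Fit the spatial ordinal model by Laplace-approximated maximum likelihood.

    Deterministic given the data and configuration: starting values are
    fixed functions of the data and no randomness enters the optimisation.

    Raises
    ------
    ValueError
        If fewer than 2 clusters are present or some category in 0..K−1 is
        unobserved (merge sparse categories before fitting).
    """
    mesh_config = mesh_config or MeshConfig()
    cfg = fit_config or FitConfig()

    y = data.households["y"].to_numpy()
    K = data.K
    observed = np.unique(y)
    if len(observed) < 2 or len(np.unique(data.households["cluster_id"])) < 2:
        raise ValueError("need at least 2 clusters and 2 observed categories")
    missing = sorted(set(range(K)) - set(int(c) for c in observed))
    if missing:
        raise ValueError(
            f"categories {missing} unobserved; merge categories before "
            "fitting (separation would make their thresholds unidentifiable)")

    mesh = A = None
    if cfg.use_spatial:
        coords = data.clusters[["lon", "lat"]].to_numpy()
        mesh = spde_mod.build_mesh(coords,
                                   buffer_fraction=mesh_config.buffer_fraction,
                                   max_edge=mesh_config.max_edge)
        A = spde_mod.projection_matrix(mesh, coords)
    ws = _Workspace(data, mesh, A, use_cluster=cfg.use_cluster)

    start = cfg.start if cfg.start is not None else _start_values(ws, data, cfg)
    x0, names = _pack(start, cfg)
    p = ws.X.shape[1]

    def objective(vec):
        try:
            params = _unpack(vec, p, K, cfg)
            return ws.marginal_nll(params, inner_tol=cfg.inner_tol,
                                   max_inner=cfg.max_inner)
        except (FloatingPointError, np.linalg.LinAlgError, RuntimeError):
            return 1e12

    res = optimize.minimize(objective, x0, method="L-BFGS-B", jac="3-point",
                            options=dict(maxiter=cfg.max_outer,
                                         gtol=cfg.outer_tol,
                                         ftol=1e-13))
    x, fx = res.x, float(res.fun)
    n_iter = int(res.nit)

    # Newton polish: the quasi-Newton loop can stop on function-value
    # stagnation with the gradient still above tolerance; a couple of exact
    # Newton steps on the finite-difference Hessian finish the job and the
    # final Hessian doubles as the parameter covariance.
    gnorm = np.inf
    Hout = None
    last_step_size = np.inf
    for _ in range(3):
        g = _fd_gradient(objective, x)
        gnorm = float(np.max(np.abs(g)))
        if gnorm < cfg.outer_tol:
            break
        Hout = _fd_hessian(objective, x, cfg.hessian_step)
        try:
            step = np.linalg.solve(0.5 * (Hout + Hout.T), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(0.5 * (Hout + Hout.T), g, rcond=None)[0]
        t, improved = 1.0, False
        for _ in range(12):
            f_new = objective(x - t * step)
            if f_new < fx:
                x, fx, improved = x - t * step, f_new, True
                last_step_size = float(np.max(np.abs(t * step)))
                break
            t *= 0.5
        n_iter += 1
        if not improved:
            break

    params = _unpack(x, p, K, cfg)
    v, H, _, _ = ws.newton_mode(params, tol=cfg.inner_tol,
                                max_iter=cfg.max_inner)

    d = len(x)
    if cfg.compute_cov:
        # the polish Hessian is reusable when the final step barely moved x
        if Hout is None or last_step_size > 1e-3:
            Hout = _fd_hessian(objective, x, cfg.hessian_step)
        eigvals = np.linalg.eigvalsh(0.5 * (Hout + Hout.T))
        if np.min(eigvals) <= 0:
            warnings.warn("outer Hessian not positive definite; using "
                          "pseudo-inverse for the parameter covariance")
            param_cov = np.linalg.pinv(0.5 * (Hout + Hout.T))
        else:
            param_cov = np.linalg.inv(0.5 * (Hout + Hout.T))
    else:
        param_cov = np.full((d, d), np.nan)

    convergence = dict(outer_iterations=n_iter,
                       final_gradient_norm=gnorm,
                       marginal_nll=fx,
                       success=bool(gnorm < 10 * cfg.outer_tol
                                    or res.success))
    return FittedModel(params=params, re_mode=ws.split(v),
                       param_cov=param_cov, param_names=names,
                       conditional_precision=sparse.csc_matrix(H),
                       mesh=mesh, standardization=dict(data.standardization),
                       design_columns=list(data.design_columns), K=K,
                       convergence=convergence, use_cluster=cfg.use_cluster,
                       cluster_ids=np.asarray(ws.cluster_ids))
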