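"""Synthetic cluster-sampled ordinal household surveys.

Emulates the statistical structure of DHS/MICS-style surveys: clusters
(primary sampling units) scattered over a lon/lat domain, ~25–30 households
sampled per cluster, cluster-level covariates (standardized continuous
surfaces, categorical factors, and a log-time term counting days since
2005-01-01), and an ordinal outcome with up to five categories generated
from the package's own latent-variable model

    z = x'β + u(s) + b_c,    P(y ≤ k) = logit⁻¹(θ_k − z),

with b_c iid Gaussian cluster effects and u a Matérn ν=1 Gaussian random
field.  Because the generator *is* the model, every downstream stage
(estimation, prediction, diagnostics) can be validated for self-consistency
without access to the restricted real surveys.

All randomness flows through one seeded generator in a fixed stream order:
cluster coordinates, household counts, covariates (in spec order), cluster
effects b, spatial field u, outcomes y.
"""

from __future__ import annotations

import datetime as _dt
import warnings
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import pdist, squareform

from . import spde as spde_mod
from .ordinal_model import class_probabilities

__all__ = [
    "SurveyConfig",
    "SurveyDataset",
    "time_covariate",
    "sample_grf",
    "simulate_survey",
    "make_prediction_grid",
    "default_covariate_spec",
]

EPOCH = _dt.date(2005, 1, 1)


# ---------------------------------------------------------------------------
# configuration


def default_covariate_spec() -> list[dict]:
    """Two standardized continuous surfaces, one binary factor, one log-time
    term — a desk-scale stand-in for a full environmental covariate suite."""
    return [
        {"name": "hdi", "kind": "continuous", "trend_sd": 1.0, "noise_sd": 0.3},
        {"name": "nightlight", "kind": "continuous", "trend_sd": 1.0,
         "noise_sd": 0.3},
        {"name": "urbanicity", "kind": "categorical",
         "levels": ["rural", "urban"], "probs": [0.6, 0.4]},
        {"name": "time", "kind": "time", "start": "2006-01-01",
         "end": "2023-12-31"},
    ]


@dataclass
class SurveyConfig:
    """Generative settings for one synthetic survey."""

    n_clusters: int = 150
    households_per_cluster: tuple[int, int] = (25, 30)
    K: int = 4
    beta: np.ndarray = dc_field(
        default_factory=lambda: np.array([0.8, -0.5, 0.6, 0.3]))
    thresholds: np.ndarray = dc_field(
        default_factory=lambda: np.array([-1.2, 0.0, 1.2]))
    sigma_b: float = 0.5
    spatial_range: float = 3.0
    sigma_u: float = 0.8
    domain: tuple[float, float, float, float] = (0.0, 10.0, 0.0, 10.0)
    covariate_spec: list = dc_field(default_factory=default_covariate_spec)
    seed: int = 0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).reshape(-1)
        self.thresholds = np.asarray(self.thresholds, dtype=float).reshape(-1)
        if not (2 <= self.K <= 5):
            raise ValueError("K must be between 2 and 5 (up to five ordered "
                             "service-level categories)")
        if len(self.thresholds) != self.K - 1:
            raise ValueError("need K-1 thresholds")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        lo, hi = self.households_per_cluster
        if not (1 <= lo <= hi <= 1000):
            raise ValueError("households_per_cluster bounds must satisfy "
                             "1 <= low <= high <= 1000")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        if self.sigma_b < 0 or self.sigma_u < 0:
            raise ValueError("sigma_b and sigma_u must be nonnegative")
        if self.spatial_range <= 0:
            raise ValueError("spatial_range must be positive")
        x0, x1, y0, y1 = self.domain
        if not (x0 < x1 and y0 < y1):
            raise ValueError("domain must be a nonempty bounding box")

    def to_yaml(self, path) -> None:
        d = dict(n_clusters=self.n_clusters,
                 households_per_cluster=list(self.households_per_cluster),
                 K=self.K, beta=self.beta.tolist(),
                 thresholds=self.thresholds.tolist(),
                 sigma_b=self.sigma_b, spatial_range=self.spatial_range,
                 sigma_u=self.sigma_u, domain=list(self.domain),
                 covariate_spec=self.covariate_spec, seed=self.seed)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "SurveyConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["households_per_cluster"] = tuple(d["households_per_cluster"])
        d["domain"] = tuple(d["domain"])
        d["beta"] = np.asarray(d["beta"], dtype=float)
        d["thresholds"] = np.asarray(d["thresholds"], dtype=float)
        return cls(**d)


@dataclass
class SurveyDataset:
    """Household-level survey table plus the cluster table.

    ``households`` has columns household_id, cluster_id, lon, lat, y and one
    column per design-matrix entry (standardized continuous / one-hot
    categorical); ``standardization`` maps continuous column names to the
    training (mean, sd) used to standardize them.  ``truth`` (simulation
    only) retains the latent pieces b, u, z.
    """

    households: pd.DataFrame
    clusters: pd.DataFrame
    K: int
    design_columns: list
    standardization: dict
    covariate_spec: list
    truth: dict | None = None

    @property
    def X(self) -> np.ndarray:
        return self.households[self.design_columns].to_numpy(dtype=float)

    @property
    def n_households(self) -> int:
        return len(self.households)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def save(self, basename) -> None:
        """Write <basename>_households.csv, <basename>_clusters.csv and a
        <basename>.yaml sidecar (K, design columns, standardization)."""
        base = Path(basename)
        self.households.to_csv(base.parent / f"{base.name}_households.csv",
                               index=False)
        self.clusters.to_csv(base.parent / f"{base.name}_clusters.csv",
                             index=False)
        meta = dict(K=int(self.K),
                    design_columns=[str(c) for c in self.design_columns],
                    standardization={k: [float(m), float(s)] for k, (m, s)
                                     in self.standardization.items()},
                    covariate_spec=self.covariate_spec)
        (base.parent / f"{base.name}.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, basename) -> "SurveyDataset":
        base = Path(basename)
        households = pd.read_csv(base.parent / f"{base.name}_households.csv")
        clusters = pd.read_csv(base.parent / f"{base.name}_clusters.csv")
        meta = yaml.safe_load((base.parent / f"{base.name}.yaml").read_text())
        return cls(households=households, clusters=clusters, K=meta["K"],
                   design_columns=meta["design_columns"],
                   standardization={k: tuple(v) for k, v in
                                    meta["standardization"].items()},
                   covariate_spec=meta["covariate_spec"])


# ---------------------------------------------------------------------------
# covariate machinery


def time_covariate(date) -> float:
    """Natural log of the number of whole days since 2005-01-01.

    Raises for dates on or before the epoch (log of a nonpositive count).
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    if isinstance(date, _dt.datetime):
        date = date.date()
    days = (date - EPOCH).days
    if days <= 0:
        raise ValueError(f"date must be strictly after {EPOCH}, got {date}")
    return float(np.log(days))


def _covariate_rng(seed: int, name: str) -> np.random.Generator:
    """Per-covariate generator, stable across runs and call sites."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _surface(lon, lat, domain, seed: int, name: str, trend_sd: float):
    """Smooth low-order polynomial trend surface, deterministic in (seed, name).

    Coordinates are affinely mapped to [-1, 1]² before evaluating a quadratic
    with seeded coefficients, so survey points and prediction grids see the
    same surface.
    """
    x0, x1, y0, y1 = domain
    xn = 2 * (np.asarray(lon) - x0) / (x1 - x0) - 1
    yn = 2 * (np.asarray(lat) - y0) / (y1 - y0) - 1
    c = _covariate_rng(seed, name).normal(size=6)
    raw = (c[0] * xn + c[1] * yn + c[2] * xn * yn
           + c[3] * (xn**2 - 1 / 3) + c[4] * (yn**2 - 1 / 3)
           + c[5] * np.sin(np.pi * xn) * np.sin(np.pi * yn))
    norm = np.sqrt((c[:5] ** 2).sum() / 3 + c[5] ** 2 / 4) or 1.0
    return trend_sd * raw / norm


def _categorical_cutpoints(spec, domain, seed):
    """Quantile cutpoints of the latent surface giving the requested marginal
    level probabilities, computed on a dense reference lattice."""
    gx = np.linspace(domain[0], domain[1], 101)
    gy = np.linspace(domain[2], domain[3], 101)
    gxx, gyy = np.meshgrid(gx, gy)
    latent = _surface(gxx, gyy, domain, seed, spec["name"], 1.0)
    probs = np.asarray(spec.get("probs",
                                [1 / len(spec["levels"])] * len(spec["levels"])))
    cum = np.cumsum(probs)[:-1]
    return np.quantile(latent, cum)


def _raw_covariates(lon, lat, covariate_spec, domain, seed,
                    rng: np.random.Generator | None = None,
                    dates=None, pred_date=None) -> pd.DataFrame:
    """Raw (unstandardized, un-encoded) covariate values at locations.

    ``rng`` adds sampling noise to continuous covariates (survey mode);
    grids pass ``rng=None`` for the noise-free surfaces.  Time covariates use
    per-location ``dates`` (survey) or a single ``pred_date`` (grid).
    """
    out = {}
    for spec in covariate_spec:
        name, kind = spec["name"], spec["kind"]
        if kind == "continuous":
            vals = _surface(lon, lat, domain, seed, name,
                            spec.get("trend_sd", 1.0))
            if rng is not None:
                vals = vals + rng.normal(0.0, spec.get("noise_sd", 0.3),
                                         size=np.shape(lon))
            out[name] = vals
        elif kind == "categorical":
            latent = _surface(lon, lat, domain, seed, name, 1.0)
            cuts = _categorical_cutpoints(spec, domain, seed)
            idx = np.digitize(latent, cuts)
            out[name] = np.asarray(spec["levels"])[idx]
        elif kind == "time":
            if dates is not None:
                out[name] = np.array([time_covariate(d) for d in dates])
            elif pred_date is not None:
                out[name] = np.full(np.shape(lon), time_covariate(pred_date))
            else:
                raise ValueError(f"time covariate '{name}' needs dates or a "
                                 "prediction date")
        else:
            raise ValueError(f"unknown covariate kind '{kind}'")
    return pd.DataFrame(out)


def design_columns_for(covariate_spec) -> list[str]:
    """Design-matrix column names implied by a covariate spec: one per
    continuous/time covariate, levels[1:] one-hot columns per categorical."""
    cols = []
    for spec in covariate_spec:
        if spec["kind"] == "categorical":
            cols += [f"{spec['name']}={lvl}" for lvl in spec["levels"][1:]]
        else:
            cols.append(spec["name"])
    return cols


def encode_design(raw: pd.DataFrame, covariate_spec,
                  standardization: dict | None = None):
    """Standardize continuous columns, one-hot encode categorical ones.

    With ``standardization=None`` the (mean, sd) pairs are computed from
    ``raw`` (training mode) and returned; otherwise the supplied training
    statistics are applied unchanged (prediction mode).
    """
    train = standardization is None
    stats = {} if train else dict(standardization)
    out = {}
    for spec in covariate_spec:
        name, kind = spec["name"], spec["kind"]
        if kind == "categorical":
            for lvl in spec["levels"][1:]:
                out[f"{name}={lvl}"] = (raw[name].to_numpy() == lvl).astype(float)
        else:
            vals = raw[name].to_numpy(dtype=float)
            if train:
                m, s = float(vals.mean()), float(vals.std())
                if s == 0.0:
                    s = 1.0
                stats[name] = (m, s)
            m, s = stats[name]
            out[name] = (vals - m) / s
    return pd.DataFrame(out)[design_columns_for(covariate_spec)], stats


def destandardize(values, name: str, standardization: dict):
    """Inverse of the standardization affine map for one covariate."""
    m, s = standardization[name]
    return np.asarray(values) * s + m


# ---------------------------------------------------------------------------
# Gaussian random field sampling


def sample_grf(locations, spatial_range: float, sigma_u: float, seed,
               dense_cap: int = 2500) -> np.ndarray:
    """One realization of a zero-mean Matérn ν=1 field at given locations.

    For n ≤ ``dense_cap`` the exact dense covariance σ_u²(κh)K₁(κh) is
    Cholesky-factorised (duplicate locations get 10⁻⁸ diagonal jitter with a
    warning).  Larger problems fall back to the sparse SPDE representation:
    a quasi-uniform mesh over the bounding box, a draw of the node weights
    from the precision matrix, and barycentric projection to the locations.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    n = locations.shape[0]
    if n < 1:
        raise ValueError("need at least one location")
    if spatial_range <= 0:
        raise ValueError("spatial_range must be positive")
    if sigma_u < 0:
        raise ValueError("sigma_u must be nonnegative")
    if sigma_u == 0.0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    if n <= dense_cap:
        cov = sigma_u**2 * np.asarray(
            spde_mod.matern_correlation(
                squareform(pdist(locations)) if n > 1 else np.zeros((1, 1)),
                spatial_range))
        if n > 1 and np.min(pdist(locations)) == 0.0:
            warnings.warn("duplicate locations; adding 1e-8 diagonal jitter",
                          stacklevel=2)
            cov = cov + 1e-8 * np.eye(n)
        jitter = 0.0
        for _ in range(4):
            try:
                L = np.linalg.cholesky(cov + jitter * np.eye(n))
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 100, 1e-10 * sigma_u**2)
        else:
            raise np.linalg.LinAlgError("covariance not positive definite")
        return L @ rng.standard_normal(n)
    # SPDE path: mesh resolution a fraction of the range, node count capped
    span = locations.max(axis=0) - locations.min(axis=0)
    diam = float(np.hypot(*span))
    max_edge = max(spatial_range / 3.0, diam / 60.0)
    corners = np.array([[locations[:, 0].min(), locations[:, 1].min()],
                        [locations[:, 0].max(), locations[:, 1].min()],
                        [locations[:, 0].min(), locations[:, 1].max()],
                        [locations[:, 0].max(), locations[:, 1].max()]])
    mesh = spde_mod.build_mesh(corners, buffer_fraction=0.25, max_edge=max_edge)
    Q = spde_mod.precision_matrix(
        mesh, spde_mod.SpatialHyperparams(np.log(spatial_range),
                                          np.log(sigma_u)))
    Lq = np.linalg.cholesky(Q.toarray())
    w = np.linalg.solve(Lq.T, rng.standard_normal(mesh.n_nodes))
    A = spde_mod.projection_matrix(mesh, locations, warn_outside=False)
    return np.asarray(A @ w)


# ---------------------------------------------------------------------------
# survey simulation


def simulate_survey(config: SurveyConfig) -> SurveyDataset:
    """Draw one survey dataset from the generative latent-variable model.

    Fully reproducible given ``config.seed``; the retained ``truth`` block
    holds the cluster effects b, the per-household field values u and latent
    values z, enabling self-consistency checks downstream.
    """
    rng = np.random.default_rng(config.seed)
    x0, x1, y0, y1 = config.domain
    nc = config.n_clusters

    # stream order: coords, counts, covariates, b, u, y
    lon = rng.uniform(x0, x1, nc)
    lat = rng.uniform(y0, y1, nc)
    lo, hi = config.households_per_cluster
    counts = rng.integers(lo, hi + 1, nc)

    dates = None
    if any(s["kind"] == "time" for s in config.covariate_spec):
        tspec = next(s for s in config.covariate_spec if s["kind"] == "time")
        d0 = _dt.date.fromisoformat(tspec.get("start", "2006-01-01"))
        d1 = _dt.date.fromisoformat(tspec.get("end", "2023-12-31"))
        offs = rng.integers(0, (d1 - d0).days + 1, nc)
        dates = [d0 + _dt.timedelta(days=int(o)) for o in offs]

    raw_c = _raw_covariates(lon, lat, config.covariate_spec, config.domain,
                            config.seed, rng=rng, dates=dates)

    b = rng.normal(0.0, config.sigma_b, nc) if config.sigma_b > 0 \
        else np.zeros(nc)
    u_cluster = sample_grf(np.column_stack([lon, lat]), config.spatial_range,
                           config.sigma_u,
                           seed=rng.integers(0, 2**31 - 1)) \
        if config.sigma_u > 0 else np.zeros(nc)

    cluster_idx = np.repeat(np.arange(nc), counts)
    n = len(cluster_idx)
    raw_h = raw_c.iloc[cluster_idx].reset_index(drop=True)
    design, stats = encode_design(raw_h, config.covariate_spec)
    X = design.to_numpy(dtype=float)
    if X.shape[1] != len(config.beta):
        raise ValueError(f"beta has length {len(config.beta)} but the "
                         f"covariate spec implies {X.shape[1]} design columns")

    z = X @ config.beta + u_cluster[cluster_idx] + b[cluster_idx]
    probs = class_probabilities(z, config.thresholds)
    y = (rng.uniform(size=n)[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)

    households = pd.DataFrame({
        "household_id": np.arange(n),
        "cluster_id": cluster_idx,
        "lon": lon[cluster_idx],
        "lat": lat[cluster_idx],
        "y": y.astype(np.int64),
    })
    households = pd.concat([households, design], axis=1)
    clusters = pd.DataFrame({"cluster_id": np.arange(nc),
                             "lon": lon, "lat": lat})
    truth = dict(b=b, u=u_cluster[cluster_idx], z=z,
                 beta=config.beta.copy(), thresholds=config.thresholds.copy(),
                 sigma_b=config.sigma_b, spatial_range=config.spatial_range,
                 sigma_u=config.sigma_u, probs=probs)
    return SurveyDataset(households=households, clusters=clusters,
                         K=config.K,
                         design_columns=list(design.columns),
                         standardization=stats,
                         covariate_spec=config.covariate_spec, truth=truth)


def make_prediction_grid(domain, resolution: float, covariate_spec,
                         standardization: dict, seed: int):
    """Regular lon/lat grid of cell centers with standardized covariate layers.

    Continuous layers are the noise-free trend surfaces standardized with the
    *training* means/sds (never the grid's own); categorical layers are the
    training one-hot encoding.  Time covariates are not materialised here —
    prediction supplies them from the prediction date.
    """
    from .prediction import PredictionGrid

    if resolution <= 0:
        raise ValueError("resolution must be positive")
    x0, x1, y0, y1 = domain
    lon_axis = np.arange(x0 + resolution / 2, x1, resolution)
    lat_axis = np.arange(y0 + resolution / 2, y1, resolution)
    if lon_axis.size == 0 or lat_axis.size == 0:
        raise ValueError("empty prediction grid")
    gx, gy = np.meshgrid(lon_axis, lat_axis)
    spatial_spec = [s for s in covariate_spec if s["kind"] != "time"]
    raw = _raw_covariates(gx.ravel(), gy.ravel(), spatial_spec, domain, seed,
                          rng=None)
    design, _ = encode_design(raw, spatial_spec, standardization)
    layers = {c: design[c].to_numpy().reshape(gx.shape)
              for c in design.columns}
    return PredictionGrid(lon_axis=lon_axis, lat_axis=lat_axis, layers=layers)
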