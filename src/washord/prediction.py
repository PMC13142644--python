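"""Gridded prediction surfaces with delta-method uncertainty.

Evaluates a fitted spatial ordinal model on a regular lon/lat grid: the
fixed-effect linear predictor from the covariate layers (time supplied as a
prediction date), the spatial field projected from its estimated mesh-node
weights, and the cluster effect at its zero mean (clusters are survey-design
artifacts, not map features).  Per-class probability and standard-error
surfaces are written as GeoTIFF rasters in WGS84 (EPSG:4326) following the
naming convention ``{component}_prob_{class}.tif`` / ``{component}_se_{class}.tif``.

Standard errors come from the delta method on the linear predictor:
Var(z*) = x*'Cov(β̂)x* + a*'Cov(w | data)a* (fixed-effect and conditional
spatial-field terms, each separately toggleable; the β–w cross term and
threshold uncertainty are omitted — plug-in thresholds), and
SE(p_k) = |∂p_k/∂z|·SD(z*).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import sparse
from scipy.sparse.linalg import splu

from . import spde as spde_mod
from .ordinal_model import FittedModel, class_probabilities

__all__ = [
    "PredictionGrid",
    "RasterLayer",
    "predict_probabilities",
    "predict_se",
    "write_rasters",
    "read_raster",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113


@dataclass
class PredictionGrid:
    """Regular lon/lat grid of cell centers with named covariate layers.

    ``lon_axis``/``lat_axis`` are ascending cell-center coordinates at
    uniform spacing; each layer is a (n_lat, n_lon) array already on the
    model's design scale (standardized / one-hot).
    """

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    layers: dict
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        for ax in (self.lon_axis, self.lat_axis):
            if ax.size < 1:
                raise ValueError("empty grid axis")
            if ax.size > 1:
                d = np.diff(ax)
                if np.any(d <= 0) or np.max(np.abs(d - d[0])) > 1e-9:
                    raise ValueError("grid axes must be ascending with "
                                     "uniform spacing")
        shape = (self.lat_axis.size, self.lon_axis.size)
        for name, layer in self.layers.items():
            if np.shape(layer) != shape:
                raise ValueError(f"layer '{name}' has shape "
                                 f"{np.shape(layer)}, expected {shape}")
        if self.mask is None:
            self.mask = np.all(
                [np.isfinite(v) for v in self.layers.values()] or
                [np.ones(shape, dtype=bool)], axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_axis.size, self.lon_axis.size)

    @property
    def resolution(self) -> float:
        ax = self.lon_axis if self.lon_axis.size > 1 else self.lat_axis
        return float(ax[1] - ax[0]) if ax.size > 1 else 1.0

    def cell_coords(self) -> np.ndarray:
        gx, gy = np.meshgrid(self.lon_axis, self.lat_axis)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class RasterLayer:
    """Georeferenced 2-D surface (row 0 = northernmost row, NaN = nodata)."""

    values: np.ndarray
    origin: tuple[float, float]       # (lon, lat) of the outer top-left corner
    pixel_size: tuple[float, float]   # (dlon, dlat); dlat negative (north-up)
    name: str
    crs: str = "EPSG:4326"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def geotransform(self):
        return (self.origin[0], self.pixel_size[0], 0.0,
                self.origin[1], 0.0, self.pixel_size[1])


def _grid_to_raster(grid: PredictionGrid, values2d: np.ndarray,
                    name: str) -> RasterLayer:
    res = grid.resolution
    origin = (float(grid.lon_axis[0] - res / 2),
              float(grid.lat_axis[-1] + res / 2))
    return RasterLayer(values=values2d[::-1], origin=origin,
                       pixel_size=(res, -res), name=name)


def _design_matrix(model: FittedModel, grid: PredictionGrid, date,
                   time_column: str | None = "time") -> np.ndarray:
    cols = []
    for name in model.design_columns:
        if name in grid.layers:
            cols.append(np.asarray(grid.layers[name], dtype=float).ravel())
        elif name == time_column:
            if date is None:
                raise ValueError(f"design column '{name}' needs a prediction "
                                 "date")
            from .synthetic_data import time_covariate

            m, s = model.standardization[name]
            val = (time_covariate(date) - m) / s
            cols.append(np.full(grid.shape[0] * grid.shape[1], val))
        else:
            raise ValueError(f"grid is missing covariate layer '{name}'")
    return np.column_stack(cols)


def _latent_surface(model: FittedModel, grid: PredictionGrid, date,
                    time_column: str | None = "time"):
    """(z*, A*, validity mask) on the flattened grid."""
    X = _design_matrix(model, grid, date, time_column)
    eta = X @ model.params.beta
    coords = grid.cell_coords()
    mask = grid.mask.ravel().copy()
    if model.mesh is not None:
        A = spde_mod.projection_matrix(model.mesh, coords, warn_outside=False)
        inside = np.asarray((A != 0).sum(axis=1)).ravel() > 0
        mask &= inside
        u = np.asarray(A @ model.re_mode.w)
    else:
        A = sparse.csr_matrix((coords.shape[0],
                               max(len(model.re_mode.w), 1)))
        u = np.zeros(coords.shape[0])
    return X, eta + u, A, mask


def predict_probabilities(model: FittedModel, grid: PredictionGrid, date,
                          time_column: str | None = "time",
                          component: str = "wash",
                          class_names=None) -> list[RasterLayer]:
    """Per-class probability rasters at z* = x*'β̂ + A*ŵ (cluster effect 0).

    Returns K north-up :class:`RasterLayer` objects; cells outside the mesh
    or with non-finite covariates are NaN.
    """
    _, z, _, mask = _latent_surface(model, grid, date, time_column)
    probs = class_probabilities(z, model.params.thresholds)
    probs[~mask] = np.nan
    names = class_names or [f"class{k}" for k in range(model.K)]
    if len(names) != model.K:
        raise ValueError(f"need {model.K} class names, got {len(names)}")
    return [_grid_to_raster(grid, probs[:, k].reshape(grid.shape),
                            f"{component}_prob_{names[k]}")
            for k in range(model.K)]


def latent_variance(model: FittedModel, grid: PredictionGrid, date,
                    time_column: str | None = "time",
                    include_fixed: bool = True,
                    include_spatial: bool = True) -> np.ndarray:
    """Delta-method variance of the linear predictor per grid cell.

    Fixed-effect term x*'Cov(β̂)x* plus the conditional spatial-field term
    a*'Cov(w | data)a* obtained by sparse solves against the conditional
    precision; the β–w cross-covariance is omitted.
    """
    X, _, A, mask = _latent_surface(model, grid, date, time_column)
    var = np.zeros(X.shape[0])
    if include_fixed:
        bc = model.beta_cov
        if np.any(np.linalg.eigvalsh(0.5 * (bc + bc.T)) < -1e-8):
            raise ValueError("fixed-effect covariance is not positive "
                             "semidefinite")
        var += np.einsum("ij,jk,ik->i", X, bc, X)
    if include_spatial and model.mesh is not None:
        H = model.conditional_precision
        n_re = H.shape[0]
        n_m = model.mesh.n_nodes
        nb = n_re - n_m
        lu = splu(sparse.csc_matrix(H))
        rhs = np.zeros((n_re, A.shape[0]))
        rhs[nb:, :] = A.T.toarray()
        sol = lu.solve(rhs)
        var += np.asarray(A.multiply(sol[nb:, :].T).sum(axis=1)).ravel()
    var[~mask] = np.nan
    return var


def predict_se(model: FittedModel, grid: PredictionGrid, date,
               time_column: str | None = "time",
               component: str = "wash", class_names=None,
               include_fixed: bool = True,
               include_spatial: bool = True) -> list[RasterLayer]:
    """Delta-method SE rasters: SE(p_k) = |∂p_k/∂z|·SD(z*) per cell."""
    _, z, _, mask = _latent_surface(model, grid, date, time_column)
    sd = np.sqrt(latent_variance(model, grid, date, time_column,
                                 include_fixed=include_fixed,
                                 include_spatial=include_spatial))
    th = model.params.thresholds
    from scipy.stats import logistic

    dens = logistic.pdf(th - z[:, None])          # σ'(θ_k − z), k=0..K-2
    zeros = np.zeros((z.size, 1))
    d_upper = np.concatenate([dens, zeros], axis=1)
    d_lower = np.concatenate([zeros, dens], axis=1)
    dp_dz = -(d_upper - d_lower)                  # ∂p_k/∂z
    se = np.abs(dp_dz) * sd[:, None]
    se[~mask] = np.nan
    names = class_names or [f"class{k}" for k in range(model.K)]
    return [_grid_to_raster(grid, se[:, k].reshape(grid.shape),
                            f"{component}_se_{names[k]}")
            for k in range(model.K)]


# ---------------------------------------------------------------------------
# GeoTIFF I/O (tifffile with standard GeoTIFF georeferencing tags)


def _geotiff_extratags(layer: RasterLayer):
    # GTModelType=2 (geographic lat/lon), GTRasterType=1 (PixelIsArea),
    # GeographicType=4326 (WGS84)
    geokeys = (1, 1, 0, 3,
               1024, 0, 1, 2,
               1025, 0, 1, 1,
               2048, 0, 1, 4326)
    return [
        (_TAG_PIXEL_SCALE, "d", 3,
         (abs(layer.pixel_size[0]), abs(layer.pixel_size[1]), 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, layer.origin[0], layer.origin[1], 0.0)),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]


def write_raster(layer: RasterLayer, path, overwrite: bool = False) -> Path:
    """Write one float32 GeoTIFF (EPSG:4326, NaN nodata)."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, layer.values.astype(np.float32),
                     extratags=_geotiff_extratags(layer))
    return path


def read_raster(path) -> RasterLayer:
    """Read a GeoTIFF written by :func:`write_raster` (bit-exact round trip)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        scale = page.tags[_TAG_PIXEL_SCALE].value
        tie = page.tags[_TAG_TIEPOINT].value
    return RasterLayer(values=values, origin=(float(tie[3]), float(tie[4])),
                       pixel_size=(float(scale[0]), -float(scale[1])),
                       name=path.stem)


def write_rasters(prob_layers, se_layers, component: str, class_names,
                  out_dir, overwrite: bool = False) -> list[Path]:
    """Write probability and SE rasters with the standard file naming.

    Files are ``{component}_prob_{class}.tif`` and ``{component}_se_{class}.tif``
    (e.g. ``water_prob_ImpW_Pipe.tif``), one pair per ordinal class.
    """
    if len(class_names) != len(prob_layers):
        raise ValueError("class_names length must match the number of classes")
    if se_layers is not None and len(se_layers) != len(prob_layers):
        raise ValueError("probability and SE layer counts differ")
    out_dir = Path(out_dir)
    paths = []
    for k, cls in enumerate(class_names):
        paths.append(write_raster(prob_layers[k],
                                  out_dir / f"{component}_prob_{cls}.tif",
                                  overwrite=overwrite))
        if se_layers is not None:
            paths.append(write_raster(se_layers[k],
                                      out_dir / f"{component}_se_{cls}.tif",
                                      overwrite=overwrite))
    return paths
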