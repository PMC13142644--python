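"""End-to-end orchestration: simulate → fit → predict → diagnose.

A :class:`RunConfig` (YAML on disk) describes one full run; `run_pipeline`
executes the stages in order, logs machine-parsable ``key=value`` lines with
per-stage timing and convergence information, and returns a manifest of
every artifact written with its SHA-256 checksum (reruns with the same
configuration and seed reproduce identical checksums).
"""

from __future__ import annotations

import hashlib
import logging
import sys
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import diagnostics as diag_mod
from . import ordinal_model as om
from . import prediction as pred_mod
from . import synthetic_data as syn

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("washord")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    out_dir: Path
    survey: syn.SurveyConfig
    mesh: om.MeshConfig = dc_field(default_factory=om.MeshConfig)
    fit: om.FitConfig = dc_field(default_factory=om.FitConfig)
    resolution: float = 0.5
    date: str = "2024-01-01"
    component: str = "wash"
    class_names: list = dc_field(default_factory=list)
    n_bins: int = 10
    n_rep: int = 100
    diagnostics_seed: int = 0

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if not self.class_names:
            self.class_names = [f"class{k}" for k in range(self.survey.K)]
        if len(self.class_names) != self.survey.K:
            raise ValueError(f"class_names must have length K={self.survey.K}")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        syn.time_covariate(self.date)  # validates the prediction date

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        survey = dict(raw.get("survey", {}))
        for key in ("beta", "thresholds"):
            if key in survey:
                survey[key] = np.asarray(survey[key], dtype=float)
        for key in ("households_per_cluster", "domain"):
            if key in survey:
                survey[key] = tuple(survey[key])
        predict = raw.get("predict", {})
        diagnostics = raw.get("diagnostics", {})
        return cls(
            out_dir=raw.get("out_dir", "washord_run"),
            survey=syn.SurveyConfig(**survey),
            mesh=om.MeshConfig(**raw.get("mesh", {})),
            fit=om.FitConfig(**raw.get("fit", {})),
            resolution=predict.get("resolution", 0.5),
            date=str(predict.get("date", "2024-01-01")),
            component=predict.get("component", "wash"),
            class_names=list(predict.get("class_names", [])),
            n_bins=diagnostics.get("n_bins", 10),
            n_rep=diagnostics.get("n_rep", 100),
            diagnostics_seed=diagnostics.get("seed", 0),
        )

    def to_yaml(self, path) -> None:
        s = self.survey
        d = dict(
            out_dir=str(self.out_dir),
            survey=dict(n_clusters=s.n_clusters,
                        households_per_cluster=list(s.households_per_cluster),
                        K=s.K, beta=s.beta.tolist(),
                        thresholds=s.thresholds.tolist(), sigma_b=s.sigma_b,
                        spatial_range=s.spatial_range, sigma_u=s.sigma_u,
                        domain=list(s.domain),
                        covariate_spec=s.covariate_spec, seed=s.seed),
            mesh=dict(buffer_fraction=self.mesh.buffer_fraction,
                      max_edge=self.mesh.max_edge),
            fit=dict(use_spatial=self.fit.use_spatial,
                     use_cluster=self.fit.use_cluster,
                     outer_tol=self.fit.outer_tol,
                     inner_tol=self.fit.inner_tol,
                     max_outer=self.fit.max_outer,
                     max_inner=self.fit.max_inner,
                     compute_cov=self.fit.compute_cov,
                     hessian_step=self.fit.hessian_step),
            predict=dict(resolution=self.resolution, date=self.date,
                         component=self.component,
                         class_names=list(self.class_names)),
            diagnostics=dict(n_bins=self.n_bins, n_rep=self.n_rep,
                             seed=self.diagnostics_seed),
        )
        Path(path).write_text(yaml.safe_dump(d))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _setup_logging(out_dir: Path, verbose: bool) -> None:
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s stage=%(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
    fh = logging.FileHandler(out_dir / "pipeline.log")
    fh.setFormatter(fmt)
    log.addHandler(fh)


def run_pipeline(config: RunConfig, overwrite: bool = False,
                 verbose: bool = False) -> dict:
    """Execute simulate → fit → predict → diagnose; return the manifest.

    The manifest maps every written file (relative to ``out_dir``) to its
    SHA-256 checksum.  Any stage failure raises with the stage name attached;
    files written before the failure remain on disk.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, verbose)
    manifest: dict[str, str] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        data = syn.simulate_survey(config.survey)
        data.save(out / "survey")
        for f in ("survey_households.csv", "survey_clusters.csv",
                  "survey.yaml"):
            manifest[f] = _sha256(out / f)
        log.info("simulate n_households=%d n_clusters=%d elapsed=%.2fs",
                 data.n_households, data.n_clusters, time.perf_counter() - t0)

        stage = "fit"
        t0 = time.perf_counter()
        model = om.fit(data, mesh_config=config.mesh, fit_config=config.fit)
        model.save(out / "model")
        for f in ("model.npz", "model.yaml"):
            manifest[f] = _sha256(out / f)
        log.info("fit marginal_nll=%.4f gradient_norm=%.2e iters=%d "
                 "elapsed=%.2fs", model.convergence["marginal_nll"],
                 model.convergence["final_gradient_norm"],
                 model.convergence["outer_iterations"],
                 time.perf_counter() - t0)

        stage = "predict"
        t0 = time.perf_counter()
        grid = syn.make_prediction_grid(
            config.survey.domain, config.resolution,
            config.survey.covariate_spec, model.standardization,
            seed=config.survey.seed)
        probs = pred_mod.predict_probabilities(
            model, grid, config.date, component=config.component,
            class_names=config.class_names)
        ses = pred_mod.predict_se(
            model, grid, config.date, component=config.component,
            class_names=config.class_names)
        raster_dir = out / "rasters"
        paths = pred_mod.write_rasters(probs, ses, config.component,
                                       config.class_names, raster_dir,
                                       overwrite=overwrite)
        for p in paths:
            manifest[str(p.relative_to(out))] = _sha256(p)
        log.info("predict cells=%d rasters=%d elapsed=%.2fs",
                 grid.shape[0] * grid.shape[1], len(paths),
                 time.perf_counter() - t0)

        stage = "diagnose"
        t0 = time.perf_counter()
        report = diag_mod.diagnose(model, data, n_bins=config.n_bins,
                                   n_rep=config.n_rep,
                                   seed=config.diagnostics_seed)
        for p in report.save(out / "diagnostics"):
            manifest[str(p.relative_to(out))] = _sha256(p)
        log.info("diagnose residual_mean=%.4f residual_sd=%.4f "
                 "ppc_max_diff=%.4f elapsed=%.2fs",
                 report.residual_summary["mean"],
                 report.residual_summary["sd"],
                 report.ppc.attrs["max_abs_diff"], time.perf_counter() - t0)
    except Exception as exc:
        log.error("%s FAILED error=%r", stage, exc)
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    manifest["manifest.yaml"] = "-"
    return manifest
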