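"""Model validation suite for fitted spatial ordinal models.

Covers the standard battery for ordinal geostatistical fits: probability
calibration curves, Dunn–Smyth randomized quantile residuals (standard
normal under a correctly specified model), posterior predictive checks of
the category frequencies, per-class one-vs-rest classification metrics
(AUC, precision, recall, F1, accuracy), and exact Shapley attributions of
the fixed-effect linear predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .ordinal_model import FittedModel, class_probabilities, _Workspace

__all__ = [
    "DiagnosticsReport",
    "dunn_smyth_residuals",
    "calibration_curve",
    "posterior_predictive_check",
    "classification_metrics",
    "shap_linear",
    "in_sample_probabilities",
    "diagnose",
]

_U_CLIP = 1e-12


def _check_prob_rows(probs) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2:
        raise ValueError("probs must be an (n, K) matrix")
    if np.any(probs < -1e-9) or np.any(np.abs(probs.sum(axis=1) - 1) > 1e-6):
        raise ValueError("probability rows must be nonnegative and sum to 1")
    return probs


def dunn_smyth_residuals(probs, y, seed) -> np.ndarray:
    """Randomized quantile residuals r_i = Φ⁻¹(u_i), u_i ~ U(F(y_i−1), F(y_i)).

    F is the per-observation cumulative category probability with F(−1) ≡ 0.
    Standard normal when the probabilities are the true generative ones.
    Deterministic given ``seed``; u clipped away from {0, 1}.
    """
    probs = _check_prob_rows(probs)
    y = np.asarray(y, dtype=np.int64)
    n, K = probs.shape
    if np.any((y < 0) | (y >= K)):
        raise ValueError("categories out of range")
    rng = np.random.default_rng(seed)
    cum = np.concatenate([np.zeros((n, 1)), np.cumsum(probs, axis=1)], axis=1)
    lo = cum[np.arange(n), y]
    hi = cum[np.arange(n), y + 1]
    u = rng.uniform(lo, hi)
    return stats.norm.ppf(np.clip(u, _U_CLIP, 1 - _U_CLIP))


def calibration_curve(probs, y, n_bins: int = 10) -> pd.DataFrame:
    """Per-class reliability table on equal-width probability bins.

    One row per (class, bin): bin midpoint, mean predicted probability,
    observed frequency of y = k, and bin count.  Empty bins are kept with
    NaN summaries and flagged by count 0 rather than silently dropped.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    probs = _check_prob_rows(probs)
    y = np.asarray(y, dtype=np.int64)
    n, K = probs.shape
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for k in range(K):
        p = probs[:, k]
        hit = (y == k).astype(float)
        idx = np.clip(np.digitize(p, edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = idx == b
            cnt = int(sel.sum())
            rows.append(dict(
                class_index=k, bin=b,
                bin_midpoint=0.5 * (edges[b] + edges[b + 1]),
                mean_predicted=float(p[sel].mean()) if cnt else np.nan,
                observed_frequency=float(hit[sel].mean()) if cnt else np.nan,
                count=cnt))
    return pd.DataFrame(rows)


def in_sample_probabilities(model: FittedModel, data) -> np.ndarray:
    """Fitted per-household class probabilities at the random-effect modes."""
    ws = _model_workspace(model, data)
    z = ws.latent(model.params, model.re_mode.stacked)
    return class_probabilities(z, model.params.thresholds)


def _model_workspace(model: FittedModel, data) -> _Workspace:
    from . import spde as spde_mod

    A = None
    if model.mesh is not None:
        coords = data.clusters[["lon", "lat"]].to_numpy()
        A = spde_mod.projection_matrix(model.mesh, coords, warn_outside=False)
    return _Workspace(data, model.mesh, A, use_cluster=model.use_cluster)


def posterior_predictive_check(model: FittedModel, data, n_rep: int = 100,
                               seed: int = 0,
                               sample_random_effects: bool = True
                               ) -> pd.DataFrame:
    """Compare observed category frequencies with replicate datasets.

    Replicates draw the random effects from the Laplace Gaussian
    approximation N(mode, H⁻¹) (or hold them at the mode when
    ``sample_random_effects=False``) and then outcomes from the cumulative
    logit probabilities.  Returns per-category observed frequency, mean
    replicate frequency, and their absolute difference; the table carries
    the overall max difference in ``attrs['max_abs_diff']``.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    ws = _model_workspace(model, data)
    rng = np.random.default_rng(seed)
    K = model.K
    eta = ws.X @ model.params.beta
    mode = model.re_mode.stacked
    if sample_random_effects:
        # lower-triangular factor of H => samples mode + L^{-T} z ~ N(mode, H^{-1})
        L = np.linalg.cholesky(model.conditional_precision.toarray())
    freq_rep = np.zeros((n_rep, K))
    thresholds = model.params.thresholds
    for r in range(n_rep):
        v = mode
        if sample_random_effects:
            v = mode + np.linalg.solve(
                L.T, rng.standard_normal(len(mode)))
        z = eta + ws.J @ v
        probs = class_probabilities(z, thresholds)
        ysim = (rng.uniform(size=len(z))[:, None]
                > np.cumsum(probs, axis=1)).sum(axis=1)
        freq_rep[r] = np.bincount(ysim, minlength=K) / len(z)
    obs = np.bincount(ws.y, minlength=K) / ws.n
    rep_mean = freq_rep.mean(axis=0)
    out = pd.DataFrame(dict(
        class_index=np.arange(K), observed_frequency=obs,
        replicate_mean_frequency=rep_mean,
        abs_difference=np.abs(obs - rep_mean)))
    out.attrs["max_abs_diff"] = float(np.max(np.abs(obs - rep_mean)))
    return out


def classification_metrics(probs, y) -> pd.DataFrame:
    """One-vs-rest AUC, precision, recall, F1, accuracy and support per class.

    The predicted class is the argmax of the probability rows (ties broken
    toward the lowest category); AUC uses the rank (Mann–Whitney) statistic
    with midrank tie handling on the per-class probability.  Classes with no
    positives or no negatives get NaN metrics and ``defined=False``.
    """
    probs = _check_prob_rows(probs)
    y = np.asarray(y, dtype=np.int64)
    n, K = probs.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    yhat = probs.argmax(axis=1)
    rows = []
    for k in range(K):
        pos = y == k
        support = int(pos.sum())
        defined = 0 < support < n
        if defined:
            auc = float(roc_auc_score(pos, probs[:, k]))
            tp = int(np.sum(pos & (yhat == k)))
            fp = int(np.sum(~pos & (yhat == k)))
            fn = int(np.sum(pos & (yhat != k)))
            tn = n - tp - fp - fn
            precision = tp / (tp + fp) if tp + fp else np.nan
            recall = tp / (tp + fn)
            f1 = (2 * precision * recall / (precision + recall)
                  if (precision + recall) else np.nan)
            accuracy = (tp + tn) / n
        else:
            auc = precision = recall = f1 = accuracy = np.nan
        rows.append(dict(class_index=k, auc=auc, precision=precision,
                         recall=recall, f1=f1, accuracy=accuracy,
                         support=support, defined=defined))
    return pd.DataFrame(rows)


def shap_linear(model_or_beta, X, background_means) -> np.ndarray:
    """Exact Shapley attribution of the linear predictor η = x'β.

    Under feature independence the Shapley value of feature j for a linear
    model is φ_ij = β_j (x_ij − x̄_j); rows sum to η_i − η̄ where x̄ are the
    background (training) means.  Spatial and cluster random effects do not
    enter η and are not attributed.
    """
    beta = (model_or_beta.params.beta
            if isinstance(model_or_beta, FittedModel)
            else np.asarray(model_or_beta, dtype=float))
    X = np.asarray(X, dtype=float)
    background_means = np.asarray(background_means, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(beta) \
            or len(background_means) != len(beta):
        raise ValueError("dimension mismatch between X, beta and background "
                         "means")
    return (X - background_means) * beta


@dataclass
class DiagnosticsReport:
    """Bundle of validation outputs with CSV + JSON export."""

    calibration: pd.DataFrame
    residuals: np.ndarray
    residual_summary: dict
    ppc: pd.DataFrame
    metrics: pd.DataFrame
    shap: np.ndarray
    shap_ranking: pd.DataFrame

    def save(self, out_dir) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, df in [("calibration", self.calibration),
                         ("ppc", self.ppc), ("metrics", self.metrics),
                         ("shap_ranking", self.shap_ranking)]:
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths.append(p)
        p = out_dir / "residuals.csv"
        pd.DataFrame({"residual": self.residuals}).to_csv(p, index=False)
        paths.append(p)
        summary = dict(residuals=self.residual_summary,
                       ppc_max_abs_diff=self.ppc.attrs.get("max_abs_diff"))
        p = out_dir / "summary.json"
        p.write_text(json.dumps(summary, indent=2))
        paths.append(p)
        return paths


def diagnose(model: FittedModel, data, n_bins: int = 10, n_rep: int = 100,
             seed: int = 0) -> DiagnosticsReport:
    """Run the full validation suite on a fitted model and its data."""
    probs = in_sample_probabilities(model, data)
    y = data.households["y"].to_numpy()
    resid = dunn_smyth_residuals(probs, y, seed=seed)
    summary = dict(
        mean=float(resid.mean()), sd=float(resid.std(ddof=1)),
        skewness=float(stats.skew(resid)),
        ks_statistic=float(stats.kstest(resid, "norm").statistic))
    X = data.X
    shap = shap_linear(model, X, X.mean(axis=0))
    ranking = pd.DataFrame({
        "feature": data.design_columns,
        "mean_abs_shap": np.abs(shap).mean(axis=0),
    }).sort_values("mean_abs_shap", ascending=False).reset_index(drop=True)
    return DiagnosticsReport(
        calibration=calibration_curve(probs, y, n_bins=n_bins),
        residuals=resid, residual_summary=summary,
        ppc=posterior_predictive_check(model, data, n_rep=n_rep, seed=seed),
        metrics=classification_metrics(probs, y),
        shap=shap, shap_ranking=ranking)
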