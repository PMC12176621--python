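"""Smooth benthic-minimum threshold model and benthic/pelagic classification.

The horizon envelopes supply one (seabed depth, benthic minimum) pair per
horizon.  A penalized B-spline regression — cubic B-splines on uniform
knots with a second-order difference penalty, Gaussian errors, identity
link, smoothing parameter chosen by generalized cross-validation — maps any
seabed depth to the benthic-minimum threshold: the shallowest record depth
still classed as benthic at that location.  The difference penalty shrinks
toward straight lines, so exactly linear training data are reproduced at
any smoothing level.

Predictions are evaluated with constant extension beyond the training range
(flagged as extrapolated) and clamped into ``[30 m, seabed depth]`` so the
threshold always lies between the global depth cut-off and the seafloor.
A record is benthic iff its depth is at or below the seabed by less than
the threshold allows, i.e. ``record_depth_m >= threshold``; records deeper
than the local seabed value (bathymetry-resolution artefacts) are benthic
by this rule but receive a QC flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from benthicsplit.clustering import HorizonEnvelope

__all__ = [
    "BenthicCloudModel",
    "classify",
    "fit_benthic_minima_model",
    "load_model",
    "predict_benthic_min",
    "save_model",
]

#: log10 range and resolution of the GCV smoothing-parameter grid
_ALPHA_GRID = 10.0 ** np.linspace(-6.0, 6.0, 49)

#: degrees-of-freedom inflation in the GCV denominator; plain GCV (gamma=1)
#: is known to undersmooth at small sample sizes, and ~1.4 is the standard
#: remedy recommended for penalized regression smoothers
GCV_GAMMA = 1.4

#: global shallow limit of the analysis, metres
MIN_DEPTH_M = 30.0

#: QC flag threshold: record depth exceeding seabed by this factor
QC_SEABED_EXCESS = 1.1


class ModelError(ValueError):
    pass


@dataclass
class BenthicCloudModel:
    """Fitted penalized-spline map: seabed depth -> benthic-minimum threshold."""

    seabed_depths_m: np.ndarray      # training x, one per horizon
    benthic_minima_m: np.ndarray     # training y
    knots: np.ndarray                # full uniform knot vector
    degree: int
    coef: np.ndarray
    alpha: float                     # GCV-selected smoothing parameter
    edf: float                       # effective degrees of freedom
    deviance_explained: float
    scale: float                     # residual variance estimate
    ci_lower_m: np.ndarray           # pointwise 95% CI at training depths
    ci_upper_m: np.ndarray
    min_depth_m: float = MIN_DEPTH_M
    horizon_labels: list[str] = field(default_factory=list)

    @property
    def training_range(self) -> tuple[float, float]:
        return float(self.seabed_depths_m.min()), float(self.seabed_depths_m.max())

    def diagnostics_table(self) -> pd.DataFrame:
        """Per-horizon fitted values with pointwise 95% confidence intervals."""
        fitted, _ = predict_benthic_min(self, self.seabed_depths_m, clamp=False)
        return pd.DataFrame(
            {
                "horizon": self.horizon_labels or [f"{x:g}m" for x in self.seabed_depths_m],
                "seabed_depth_m": self.seabed_depths_m,
                "benthic_min_m": self.benthic_minima_m,
                "fitted_m": fitted,
                "ci_lower_m": self.ci_lower_m,
                "ci_upper_m": self.ci_upper_m,
            }
        )


def _uniform_knots(lo: float, hi: float, basis_dim: int, degree: int) -> np.ndarray:
    """Uniform unclamped knot vector giving ``basis_dim`` B-spline functions."""
    nseg = basis_dim - degree
    h = (hi - lo) / nseg
    return lo + h * np.arange(-degree, nseg + degree + 1)


def _design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    lo, hi = knots[degree], knots[-degree - 1]
    x = np.clip(np.asarray(x, dtype=float), lo, hi)  # constant extension outside
    return BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()


def fit_benthic_minima_model(
    envelopes: list[HorizonEnvelope],
    basis_dim: int = 10,
    degree: int = 3,
    min_pairs: int = 6,
    gcv_gamma: float = GCV_GAMMA,
) -> BenthicCloudModel:
    """Fit the benthic-minimum smooth to one (seabed, benthic min) pair per horizon.

    ``basis_dim`` is capped at ``n - 1`` training pairs; the smoothing
    parameter minimises the GCV score ``n RSS / (n - gamma edf)^2`` over a
    fixed log-spaced grid (ties resolve to the smoothest fit).  Pointwise 95%
    confidence intervals use the Bayesian posterior covariance
    ``scale * (B'B + alpha P)^{-1}`` customary for penalized smooths.
    """
    if len(envelopes) < min_pairs:
        raise ModelError(
            f"need >= {min_pairs} horizon envelopes to fit the smooth, got {len(envelopes)}"
        )
    x = np.array([e.horizon.target_depth_m for e in envelopes], dtype=float)
    y = np.array([e.benthic_min_m for e in envelopes], dtype=float)
    labels = [e.horizon.label for e in envelopes]
    order = np.argsort(x)
    x, y = x[order], y[order]
    labels = [labels[i] for i in order]
    dup = np.flatnonzero(np.diff(x) == 0)
    if dup.size:
        names = sorted({labels[i] for i in np.r_[dup, dup + 1]})
        raise ModelError(f"duplicate seabed depths among horizons: {', '.join(names)}")

    n = x.size
    basis_dim = min(basis_dim, n - 1)
    if basis_dim < degree + 1:
        raise ModelError(f"basis_dim {basis_dim} too small for degree {degree}")
    knots = _uniform_knots(x.min(), x.max(), basis_dim, degree)
    B = _design(x, knots, degree)
    p = B.shape[1]
    D2 = np.diff(np.eye(p), 2, axis=0)
    P = D2.T @ D2
    BtB, Bty = B.T @ B, B.T @ y

    def _solve(alpha: float) -> tuple[np.ndarray, float, float]:
        A = BtB + alpha * P
        beta = np.linalg.solve(A, Bty)
        edf = float(np.trace(np.linalg.solve(A, BtB)))
        rss = float(np.sum((y - B @ beta) ** 2))
        return beta, edf, rss

    best_alpha, best_gcv = None, np.inf
    for alpha in _ALPHA_GRID:
        _, edf, rss = _solve(alpha)
        denom = max(n - gcv_gamma * edf, 1e-8)
        gcv = n * rss / denom**2
        if gcv <= best_gcv - 1e-12 * max(best_gcv, 1.0) or best_alpha is None:
            best_alpha, best_gcv = float(alpha), gcv
        elif abs(gcv - best_gcv) <= 1e-12 * max(best_gcv, 1.0):
            best_alpha = float(alpha)  # tie -> smoother fit
    assert best_alpha is not None

    beta, edf, rss = _solve(best_alpha)
    tss = float(np.sum((y - y.mean()) ** 2))
    dev_expl = 1.0 - rss / tss if tss > 0 else 1.0
    scale = rss / max(n - edf, 1e-8)
    cov = scale * np.linalg.inv(BtB + best_alpha * P)
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, cov, B), 0.0))
    fitted = B @ beta
    return BenthicCloudModel(
        seabed_depths_m=x,
        benthic_minima_m=y,
        knots=knots,
        degree=degree,
        coef=beta,
        alpha=best_alpha,
        edf=edf,
        deviance_explained=dev_expl,
        scale=scale,
        ci_lower_m=fitted - 1.96 * se,
        ci_upper_m=fitted + 1.96 * se,
        horizon_labels=labels,
    )


def predict_benthic_min(
    model: BenthicCloudModel,
    seabed_depth_m: float | np.ndarray,
    clamp: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Benthic-minimum threshold at each seabed depth.

    Returns ``(threshold_m, extrapolated)``.  The raw smooth is evaluated
    with constant extension beyond the training range; with ``clamp`` the
    threshold is forced into ``[min_depth_m, seabed_depth_m]`` so that
    classification is total and never reaches above the global depth cut-off
    or below the seafloor.
    """
    z = np.atleast_1d(np.asarray(seabed_depth_m, dtype=float))
    if np.any(z <= 0):
        raise ModelError("seabed depth must be positive")
    raw = _design(z, model.knots, model.degree) @ model.coef
    lo, hi = model.training_range
    extrapolated = (z < lo) | (z > hi)
    if clamp:
        raw = np.clip(raw, model.min_depth_m, z)
    if np.isscalar(seabed_depth_m):
        return raw[0], bool(extrapolated[0])
    return raw, extrapolated


def classify(
    records: pd.DataFrame, model: BenthicCloudModel
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every record benthic or pelagic against the threshold model.

    A record is benthic iff ``record_depth_m >= threshold`` at its seabed
    depth (inclusive boundary).  Records deeper than the seabed by more than
    10% get ``qc_flag = True`` but keep their benthic label.  Returns the
    labelled table (with ``label``, ``threshold_used_m``, ``extrapolated``,
    ``qc_flag`` columns) and summary counts.
    """
    if "seabed_depth_m" not in records.columns or records["seabed_depth_m"].isna().any():
        raise ModelError(
            "records must carry seabed_depth_m for every row; "
            "remove land/off-grid records at ingest"
        )
    out = records.copy()
    thr, extrap = predict_benthic_min(model, out["seabed_depth_m"].to_numpy())
    benthic = out["record_depth_m"].to_numpy() >= thr
    out["label"] = np.where(benthic, "benthic", "pelagic")
    out["threshold_used_m"] = thr
    out["extrapolated"] = extrap
    out["qc_flag"] = out["record_depth_m"].to_numpy() > QC_SEABED_EXCESS * out[
        "seabed_depth_m"
    ].to_numpy()
    counts = {
        "n_input": len(out),
        "n_benthic": int(benthic.sum()),
        "n_pelagic": int((~benthic).sum()),
        "n_qc_flagged": int(out["qc_flag"].sum()),
        "n_extrapolated": int(out["extrapolated"].sum()),
    }
    return out, counts


def save_model(model: BenthicCloudModel, path: str | Path) -> None:
    """Serialise the fitted model (training pairs + spline) as JSON."""
    payload = {
        "format": "benthicsplit-cloud-model-v1",
        "seabed_depths_m": model.seabed_depths_m.tolist(),
        "benthic_minima_m": model.benthic_minima_m.tolist(),
        "knots": model.knots.tolist(),
        "degree": model.degree,
        "coef": model.coef.tolist(),
        "alpha": model.alpha,
        "edf": model.edf,
        "deviance_explained": model.deviance_explained,
        "scale": model.scale,
        "ci_lower_m": model.ci_lower_m.tolist(),
        "ci_upper_m": model.ci_upper_m.tolist(),
        "min_depth_m": model.min_depth_m,
        "horizon_labels": model.horizon_labels,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_model(path: str | Path) -> BenthicCloudModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "benthicsplit-cloud-model-v1":
        raise ModelError(f"unrecognised model file {path}")
    return BenthicCloudModel(
        seabed_depths_m=np.asarray(payload["seabed_depths_m"], dtype=float),
        benthic_minima_m=np.asarray(payload["benthic_minima_m"], dtype=float),
        knots=np.asarray(payload["knots"], dtype=float),
        degree=int(payload["degree"]),
        coef=np.asarray(payload["coef"], dtype=float),
        alpha=float(payload["alpha"]),
        edf=float(payload["edf"]),
        deviance_explained=float(payload["deviance_explained"]),
        scale=float(payload["scale"]),
        ci_lower_m=np.asarray(payload["ci_lower_m"], dtype=float),
        ci_upper_m=np.asarray(payload["ci_upper_m"], dtype=float),
        min_depth_m=float(payload["min_depth_m"]),
        horizon_labels=list(payload["horizon_labels"]),
    )
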