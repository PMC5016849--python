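"""Gaussian-mixture class models and negative-log-likelihood scoring.

One mixture model is fit per diagnostic class (PH / non-PH) on the pooled
MFCC frames of that class's training subjects, by Expectation-Maximization
with seeded k-means-style initialization and restarts.  A test subject is
scored by the per-frame negative log-likelihood averaged over all of the
subject's frames, once under each class model; the subject is assigned to
the model with the lower average NLL.  The ratio
``nll_ph / nll_nonph`` is the continuous test statistic (PH subjects score
below 1) used for the ROC sweep.

All mixture arithmetic is done in log space (log-sum-exp); covariances are
kept positive-definite by an eigenvalue floor applied only when a
component's covariance degenerates, so that in the generic case EM is the
exact maximum-likelihood recursion and the training log-likelihood is
non-decreasing.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .mfcc import MfccMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GmmSettings",
    "GmmParams",
    "SubjectScore",
    "fit_gmm",
    "log_mixture_density",
    "average_nll",
    "classify_subject",
    "save_model",
    "load_model",
]

PH_LABEL = "PH"
NON_PH_LABEL = "non-PH"

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GmmSettings:
    """Fitting hyper-parameters; 8 components is the working default."""

    n_components: int = 8
    covariance_mode: str = "full"    # "full" | "diagonal"
    max_iter: int = 200
    tol: float = 1e-6                # relative log-likelihood change
    n_restarts: int = 3
    cov_floor: float = 1e-6


@dataclass
class GmmParams:
    """Fitted mixture: weights, means, covariances, training trace."""

    weights: np.ndarray              # (K,)
    means: np.ndarray                # (K, D)
    covariances: np.ndarray          # (K, D, D) full | (K, D) diagonal
    covariance_mode: str = "full"
    training_log: np.ndarray = field(default_factory=lambda: np.array([]))
    feature_fingerprint: str | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.training_log = np.asarray(self.training_log, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("mixture weights must be non-negative")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class SubjectScore:
    """Average NLL of one subject under both class models."""

    subject_id: str
    nll_ph: float
    nll_nonph: float
    nll_ratio: float
    predicted: str


def _as_array(features) -> tuple[np.ndarray, str | None]:
    if isinstance(features, MfccMatrix):
        return features.values, features.fingerprint
    return np.atleast_2d(np.asarray(features, dtype=float)), None


def _log_gaussians(X: np.ndarray, params: GmmParams) -> np.ndarray:
    """(N, K) log N(x_n; mu_k, Sigma_k)."""
    n, d = X.shape
    k = params.n_components
    out = np.empty((n, k))
    if params.covariance_mode == "diagonal":
        for j in range(k):
            var = params.covariances[j]
            dev = X - params.means[j]
            out[:, j] = -0.5 * (
                d * _LOG2PI + np.log(var).sum() + ((dev * dev) / var).sum(axis=1)
            )
    else:
        for j in range(k):
            chol = np.linalg.cholesky(params.covariances[j])
            dev = solve_triangular(chol, (X - params.means[j]).T, lower=True)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            out[:, j] = -0.5 * (d * _LOG2PI + logdet + (dev * dev).sum(axis=0))
    return out


def log_mixture_density(features, params: GmmParams) -> np.ndarray:
    """Per-frame log density log sum_k w_k N(x; mu_k, Sigma_k)."""
    X, _ = _as_array(features)
    if X.shape[1] != params.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"dimension {params.n_features}"
        )
    with np.errstate(divide="ignore"):
        log_w = np.log(params.weights)
    return logsumexp(_log_gaussians(X, params) + log_w[None, :], axis=1)


def _floor_covariances(cov: np.ndarray, mode: str, floor: float) -> np.ndarray:
    """Raise degenerate covariances to the floor (only when needed)."""
    if mode == "diagonal":
        return np.maximum(cov, floor)
    out = cov.copy()
    for j in range(len(out)):
        out[j] = 0.5 * (out[j] + out[j].T)
        min_eig = np.linalg.eigvalsh(out[j])[0]
        if min_eig < floor:
            out[j] += (floor - min_eig + floor) * np.eye(out[j].shape[0])
    return out


def _initial_params(
    X: np.ndarray, k: int, mode: str, floor: float, rng: np.random.Generator
) -> GmmParams:
    global_cov = np.atleast_2d(np.cov(X.T, bias=True))
    if k == 1:
        centers = X.mean(axis=0, keepdims=True)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # kmeans2 warns on empty clusters
            centers, _ = kmeans2(X, k, minit="++", seed=rng)
    if mode == "diagonal":
        cov = np.tile(np.diag(global_cov), (k, 1))
    else:
        cov = np.tile(global_cov, (k, 1, 1))
    return GmmParams(
        weights=np.full(k, 1.0 / k),
        means=centers,
        covariances=_floor_covariances(cov, mode, floor),
        covariance_mode=mode,
    )


def _em_run(
    X: np.ndarray,
    k: int,
    mode: str,
    max_iter: int,
    tol: float,
    cov_floor: float,
    rng: np.random.Generator,
) -> GmmParams:
    n, d = X.shape
    params = _initial_params(X, k, mode, cov_floor, rng)
    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_joint = _log_gaussians(X, params) + np.log(params.weights)[None, :]
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll

        resp = np.exp(log_joint - log_norm[:, None])
        nk = resp.sum(axis=0)
        for j in np.flatnonzero(nk < max(1.0, 1e-6 * n)):
            # collapsed component: re-seed on a random frame
            logger.warning("re-seeding collapsed mixture component %d", j)
            resp[:, j] = 0.0
            resp[rng.integers(n), j] = 1.0
            nk = resp.sum(axis=0)
        weights = nk / nk.sum()
        means = (resp.T @ X) / nk[:, None]
        if mode == "diagonal":
            cov = np.empty((k, d))
            for j in range(k):
                dev = X - means[j]
                cov[j] = (resp[:, j][:, None] * dev * dev).sum(axis=0) / nk[j]
        else:
            cov = np.empty((k, d, d))
            for j in range(k):
                dev = X - means[j]
                cov[j] = (resp[:, j][:, None] * dev).T @ dev / nk[j]
        params = GmmParams(
            weights=weights,
            means=means,
            covariances=_floor_covariances(cov, mode, cov_floor),
            covariance_mode=mode,
        )
    params.training_log = np.asarray(trace)
    return params


def fit_gmm(
    features,
    n_components: int = 8,
    covariance_mode: str = "full",
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_restarts: int = 3,
    cov_floor: float = 1e-6,
) -> GmmParams:
    """Fit a K-component mixture by EM; keep the best of seeded restarts.

    Deterministic given ``seed``.  Requires N >= K (D + 1) frames as an
    identifiability guard.
    """
    if covariance_mode not in ("full", "diagonal"):
        raise ValueError(f"unknown covariance_mode {covariance_mode!r}")
    X, fingerprint = _as_array(features)
    n, d = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n < n_components * (d + 1):
        raise ValueError(
            f"only {n} frames for {n_components} components in {d} dimensions; "
            f"need at least {n_components * (d + 1)} - use fewer components"
        )
    best: GmmParams | None = None
    for r in range(max(1, n_restarts)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        params = _em_run(X, n_components, covariance_mode, max_iter, tol, cov_floor, rng)
        if best is None or params.training_log[-1] > best.training_log[-1]:
            best = params
    assert best is not None
    best.feature_fingerprint = fingerprint
    return best


def average_nll(features, model: GmmParams) -> float:
    """Average per-frame negative log-likelihood of a subject's features.

    The per-frame log mixture densities are averaged and negated; this
    single number summarizes the whole recording under one class model.
    """
    X, fingerprint = _as_array(features)
    if (
        fingerprint is not None
        and model.feature_fingerprint is not None
        and fingerprint != model.feature_fingerprint
    ):
        raise ValueError(
            f"feature fingerprint {fingerprint} does not match model "
            f"fingerprint {model.feature_fingerprint}"
        )
    return float(-np.mean(log_mixture_density(X, model)))


def classify_subject(
    features, model_ph: GmmParams, model_nonph: GmmParams, subject_id: str | None = None
) -> SubjectScore:
    """Score a subject under both class models; lowest average NLL wins.

    An exact tie predicts non-PH (a screening tool favors fewer false
    positives) and is logged.
    """
    if model_ph.n_features != model_nonph.n_features:
        raise ValueError("class models have different feature dimensions")
    if subject_id is None:
        sid = ""
        if isinstance(features, MfccMatrix) and len(features.subject_ids):
            sid = str(features.subject_ids[0])
    else:
        sid = subject_id
    nll_ph = average_nll(features, model_ph)
    nll_nonph = average_nll(features, model_nonph)
    if nll_ph == nll_nonph:
        logger.info("subject %s: exact NLL tie, predicting %s", sid, NON_PH_LABEL)
        predicted = NON_PH_LABEL
    else:
        predicted = PH_LABEL if nll_ph < nll_nonph else NON_PH_LABEL
    return SubjectScore(
        subject_id=sid,
        nll_ph=nll_ph,
        nll_nonph=nll_nonph,
        nll_ratio=nll_ph / nll_nonph,
        predicted=predicted,
    )


_MODEL_FORMAT_VERSION = 1


def save_model(params: GmmParams, path) -> None:
    """Serialize a fitted model to versioned JSON."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "covariance_mode": params.covariance_mode,
        "weights": params.weights.tolist(),
        "means": params.means.tolist(),
        "covariances": params.covariances.tolist(),
        "training_log": params.training_log.tolist(),
        "feature_fingerprint": params.feature_fingerprint,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> GmmParams:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format version {version}")
    return GmmParams(
        weights=np.asarray(payload["weights"]),
        means=np.asarray(payload["means"]),
        covariances=np.asarray(payload["covariances"]),
        covariance_mode=payload["covariance_mode"],
        training_log=np.asarray(payload["training_log"]),
        feature_fingerprint=payload["feature_fingerprint"],
    )
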