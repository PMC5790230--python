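"""Niche models behind a single fit/score contract.

Each model is a scikit-learn style estimator: ``fit(X, y=None)`` takes an
environmental matrix (rows = locations, columns = variables) and, for
presence-absence methods, binary labels (1 = presence, 0 = pseudo-absence);
``score_samples(X)`` returns one suitability score per row, higher = more
suitable. Presence-only methods use only the presence rows.

Scores are comparable only within a model: the ensemble protocol thresholds
each model's scores on its own ROC curve, so any strictly monotone transform
of a model's scores yields identical downstream binary predictions.

Built in here are a representative subset of the classical method families —
the BIOCLIM envelope, three distance models (Euclidean and Mahalanobis to the
presence centroid, Gower to the nearest presence) and a logistic GLM with
optional quadratic terms. Heavier machine-learning methods are not built in;
any estimator honouring the same contract can be registered by name and used
by the ensemble protocol unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "BioclimEnvelope",
    "DistanceNicheModel",
    "LogisticNicheModel",
    "MODEL_REGISTRY",
    "register_model",
    "make_model",
]


def _presence_rows(X, y):
    X = check_array(X, dtype=float)
    if y is None:
        return X
    y = np.asarray(y)
    return X[y == 1]


class BioclimEnvelope(BaseEstimator):
    """Classic climate-envelope (BIOCLIM) scoring.

    For each variable the presence sample defines a two-tailed percentile
    score ``t_j = min(1, 2 * min(#{p <= x_j}, #{p >= x_j}) / n)`` — 1 at the
    presence median, decreasing toward the envelope edges and exactly 0
    outside the presence min–max; the model score is ``min_j t_j``. A
    degenerate variable whose presence values are all equal scores 1 at that
    value and 0 elsewhere (the same formula, no special case).

    Parameters
    ----------
    trim : float in [0, 0.5)
        Optional percentile trim applied to each variable's presence sample
        before the envelope is formed (0 = classic min–max envelope).
    """

    def __init__(self, trim: float = 0.0):
        self.trim = trim

    def fit(self, X, y=None):
        if not (0 <= self.trim < 0.5):
            raise ValueError("trim must lie in [0, 0.5)")
        P = _presence_rows(X, y)
        if P.shape[0] < 2:
            raise ValueError("BIOCLIM needs at least 2 presence records")
        if self.trim > 0:
            lo = np.quantile(P, self.trim, axis=0)
            hi = np.quantile(P, 1 - self.trim, axis=0)
            P = np.clip(P, lo, hi)
        self.presence_sorted_ = np.sort(P, axis=0)
        self.n_features_in_ = P.shape[1]
        return self

    def score_samples(self, X):
        check_is_fitted(self, "presence_sorted_")
        X = check_array(X, dtype=float)
        scores = np.ones(X.shape[0])
        for j in range(self.n_features_in_):
            s = self.presence_sorted_[:, j]
            n = len(s)
            n_le = np.searchsorted(s, X[:, j], side="right")  # presences <= x
            n_ge = n - np.searchsorted(s, X[:, j], side="left")  # presences >= x
            t = np.minimum(1.0, 2.0 * np.minimum(n_le, n_ge) / n)
            scores = np.minimum(scores, t)
        return scores


class DistanceNicheModel(BaseEstimator):
    """Environmental-distance suitability: score = 1 / (1 + d).

    ``metric="euclidean"`` — distance from the presence centroid in
    per-variable standardized space; ``metric="mahalanobis"`` — Mahalanobis
    distance to the centroid under the presence covariance (ridge-regularized
    if singular); ``metric="gower"`` — range-scaled mean absolute difference
    to the *nearest* presence (Domain-style), probing a different niche
    geometry than the centroid models.
    """

    def __init__(self, metric: str = "euclidean", ridge: float = 1e-8, ranges=None):
        self.metric = metric
        self.ridge = ridge
        self.ranges = ranges  # gower only: fixed per-variable ranges

    def fit(self, X, y=None):
        if self.metric not in ("euclidean", "gower", "mahalanobis"):
            raise ValueError(f"unknown metric {self.metric!r}")
        P = _presence_rows(X, y)
        n, p = P.shape
        self.n_features_in_ = p
        self.centroid_ = P.mean(axis=0)
        if self.metric == "euclidean":
            if n < 2:
                raise ValueError("euclidean model needs >= 2 presences to standardize")
            sd = P.std(axis=0, ddof=1)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        elif self.metric == "mahalanobis":
            if n < p + 1:
                raise ValueError(f"mahalanobis needs >= {p + 1} presences for {p} variables")
            cov = np.cov(P, rowvar=False)
            cov = np.atleast_2d(cov)
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                warnings.warn("singular presence covariance; adding ridge to diagonal")
                cov = cov + self.ridge * np.trace(cov) / p * np.eye(p)
            self.covariance_ = cov
            self.precision_ = np.linalg.inv(cov)
        else:  # gower
            if n < 1:
                raise ValueError("gower model needs >= 1 presence")
            if self.ranges is not None:
                rng = np.asarray(self.ranges, dtype=float)
            else:
                rng = P.max(axis=0) - P.min(axis=0)
            if np.any(rng < 0):
                raise ValueError("gower ranges must be positive")
            self.range_ = np.where(rng > 0, rng, 1.0)
            self.presences_ = P
        return self

    def _distance(self, X):
        if self.metric == "euclidean":
            Z = (X - self.centroid_) / self.scale_
            return np.sqrt((Z**2).sum(axis=1))
        if self.metric == "mahalanobis":
            D = X - self.centroid_
            return np.sqrt(np.einsum("ij,jk,ik->i", D, self.precision_, D))
        # gower: min over presences of mean range-scaled absolute difference
        diffs = np.abs(X[:, None, :] - self.presences_[None, :, :]) / self.range_
        return diffs.mean(axis=2).min(axis=1)

    def score_samples(self, X):
        check_is_fitted(self, "centroid_")
        X = check_array(X, dtype=float)
        return 1.0 / (1.0 + self._distance(X))


class LogisticNicheModel(BaseEstimator):
    """Presence/pseudo-absence logistic GLM fit by IRLS.

    Predictors are standardized internally; quadratic terms are on by default
    so the fitted response can be unimodal in each variable. Iteration stops
    at gradient max-norm 1e-8 or ``max_iter``; on complete separation a small
    ridge penalty keeps the coefficients bounded and the fit is flagged.

    Fitted attributes: ``coef_`` (intercept first, on the internal
    standardized design), ``converged_``, ``n_iter_``, ``separation_``.
    """

    def __init__(self, quadratic: bool = True, max_iter: int = 100, tol: float = 1e-8,
                 ridge: float = 1e-6):
        self.quadratic = quadratic
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge

    def _design(self, X):
        Z = (X - self.center_) / self.scale_
        parts = [np.ones((len(Z), 1)), Z]
        if self.quadratic:
            parts.append(Z**2)
        return np.hstack(parts)

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be 0 (pseudo-absence) or 1 (presence)")
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("both classes must be present")
        self.n_features_in_ = X.shape[1]
        self.center_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        D = self._design(X)
        k = D.shape[1]
        beta = np.zeros(k)
        ridge = 0.0
        self.separation_ = False
        for attempt in range(2):
            beta = np.zeros(k)
            for it in range(1, self.max_iter + 1):
                eta = D @ beta
                mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
                w = np.clip(mu * (1 - mu), 1e-10, None)
                grad = D.T @ (y - mu) - ridge * beta
                if np.max(np.abs(grad)) < self.tol:
                    self.converged_ = True
                    break
                H = (D * w[:, None]).T @ D + ridge * np.eye(k)
                try:
                    step = np.linalg.solve(H, grad)
                except np.linalg.LinAlgError:
                    step = np.linalg.lstsq(H, grad, rcond=None)[0]
                beta = beta + step
            else:
                self.converged_ = False
            self.n_iter_ = it
            # diverging coefficients signal complete separation: refit ridged
            if attempt == 0 and (not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 30):
                warnings.warn("possible complete separation; refitting with small ridge")
                self.separation_ = True
                ridge = self.ridge
                continue
            break
        self.coef_ = beta
        return self

    def score_samples(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        eta = self._design(X) @ self.coef_
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))

    # alias: the score is a genuine class probability for this model
    predict_proba_presence = score_samples


MODEL_REGISTRY: dict[str, type | object] = {}


def register_model(name: str, factory) -> None:
    """Register a model factory (callable returning a fresh estimator)."""
    MODEL_REGISTRY[name] = factory


def make_model(name: str):
    """Instantiate a registered niche model by name."""
    try:
        factory = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown niche model {name!r}; registered: {sorted(MODEL_REGISTRY)}"
        ) from None
    return factory()


register_model("bioclim", BioclimEnvelope)
register_model("euclidean", lambda: DistanceNicheModel(metric="euclidean"))
register_model("gower", lambda: DistanceNicheModel(metric="gower"))
register_model("mahalanobis", lambda: DistanceNicheModel(metric="mahalanobis"))
register_model("glm", LogisticNicheModel)

#: whether a registered model needs pseudo-absence labels at fit time
PRESENCE_ABSENCE_MODELS = {"glm"}
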