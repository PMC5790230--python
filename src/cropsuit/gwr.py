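"""Geographically weighted regression and variation partitioning.

GWR fits one weighted least-squares regression per focal location, using all
observations weighted by a distance-decayed kernel — here a bisquare kernel
``w = (1 - (d/b)^2)^2`` for distances below a fixed bandwidth ``b`` (default
5 degrees) and 0 beyond. The coefficient vector therefore varies over space,
capturing non-stationarity a single global OLS fit cannot represent.

Fit statistics follow the standard GWR conventions: the effective number of
parameters is the trace ``v1`` of the hat matrix ``S`` (row i is
``x_i (X'W_i X)^{-1} X'W_i``); adjusted R^2 uses the effective degrees of
freedom ``n - v1``; the small-sample AICc is

    AICc = 2 n ln(sigma_hat) + n ln(2 pi) + n (n + v1) / (n - 2 - v1)

with ``sigma_hat^2 = RSS / n`` (for OLS, ``v1 = p``). The improvement of GWR
over OLS is tested with the ANOVA-style F statistic

    F = [(RSS_OLS - RSS_GWR) / (v1 - p)] / [RSS_GWR / (n - v1)]

on (v1 - p, n - v1) degrees of freedom.

Variation partitioning decomposes the full model's explained variance into a
pure climate (suitability) component, a pure technology component and a
shared component by differencing the (adjusted) R^2 of three nested fits:
pure_climate = R2_all - R2_tec, pure_technology = R2_all - R2_suit,
shared = R2_suit + R2_tec - R2_all. The three components sum to R2_all by
construction, globally and at every location; components can be negative and
are reported unclamped. The global partition uses adjusted R^2; per-location
maps use the (unadjusted) local R^2, because local effective degrees of
freedom are not well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .grids import GridSpec, snap_to_grid

__all__ = [
    "bisquare_weight",
    "pairwise_distances",
    "GWRegressor",
    "OLSModel",
    "fit_ols",
    "aicc",
    "gwr_vs_ols_ftest",
    "forward_select",
    "PartitionResult",
    "variation_partition",
    "municipality_suitability",
]

_EARTH_RADIUS_KM = 6371.0


def bisquare_weight(d, bandwidth: float):
    """Bisquare kernel: (1 - (d/b)^2)^2 for d < b, else 0."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    d = np.asarray(d, dtype=float)
    w = np.where(d < bandwidth, (1.0 - (d / bandwidth) ** 2) ** 2, 0.0)
    return w if w.ndim else float(w)


def pairwise_distances(coords: np.ndarray, metric: str = "planar") -> np.ndarray:
    """All-pairs distances between (lon, lat) points.

    ``planar`` treats decimal degrees as a flat plane (so a "bandwidth of
    5 degrees" is literal); ``great_circle`` returns haversine kilometres.
    """
    coords = np.asarray(coords, dtype=float)
    if metric == "planar":
        diff = coords[:, None, :] - coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "great_circle":
        lon = np.radians(coords[:, 0])
        lat = np.radians(coords[:, 1])
        dlon = lon[:, None] - lon[None, :]
        dlat = lat[:, None] - lat[None, :]
        a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    raise ValueError(f"unknown distance metric {metric!r}")


def aicc(n: int, rss: float, v1: float) -> float:
    """Small-sample corrected AIC with effective parameter count v1."""
    if n - 2 - v1 <= 0:
        raise ValueError("over-parameterized: n - 2 - v1 must be positive")
    if rss <= 0:
        raise ValueError("RSS must be positive for the AICc formula")
    sigma = np.sqrt(rss / n)
    return float(2 * n * np.log(sigma) + n * np.log(2 * np.pi) + n * (n + v1) / (n - 2 - v1))


@dataclass
class OLSModel:
    """Global least-squares fit used as the stationary baseline."""

    coef: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    r2: float
    adj_r2: float
    aicc: float
    n: int
    p: int


def fit_ols(X: np.ndarray, y: np.ndarray, add_intercept: bool = True) -> OLSModel:
    """Ordinary least squares with the same reporting conventions as GWR."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    D = np.column_stack([np.ones(len(y)), X]) if add_intercept else X
    n, p = D.shape
    if n <= p:
        raise ValueError("need more observations than parameters")
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    fitted = D @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    tss_y = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss_y
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    return OLSModel(
        coef=coef, fitted=fitted, residuals=resid, rss=rss, r2=r2, adj_r2=adj,
        aicc=aicc(n, rss, p), n=n, p=p,
    )


class GWRegressor(RegressorMixin, BaseEstimator):
    """Fixed-bandwidth bisquare-kernel geographically weighted regression.

    Parameters
    ----------
    bandwidth : float
        Kernel bandwidth in the units of the distance metric (degrees for
        the default planar metric; default 5).
    distance_metric : {"planar", "great_circle"}
    add_intercept : bool
        Prepend a column of ones to the design matrix (default True).
    ridge : float
        Ridge added to a locally singular weighted normal matrix; affected
        locations are recorded in ``singular_locations_``.
    min_in_bandwidth : int or None
        Minimum in-kernel neighbours each location must have; defaults to the
        number of parameters.

    ``fit(X, y, coords)`` takes coords as an (n, 2) lon/lat array. Fitted
    attributes include ``coef_local_`` (n x p), ``fitted_``, ``residuals_``,
    ``local_r2_``, ``v1_``, ``rss_``, ``r2_``, ``adj_r2_``, ``aicc_``.
    """

    def __init__(
        self,
        bandwidth: float = 5.0,
        kernel: str = "bisquare",
        distance_metric: str = "planar",
        add_intercept: bool = True,
        ridge: float = 1e-8,
        min_in_bandwidth: int | None = None,
    ):
        self.bandwidth = bandwidth
        self.kernel = kernel
        self.distance_metric = distance_metric
        self.add_intercept = add_intercept
        self.ridge = ridge
        self.min_in_bandwidth = min_in_bandwidth

    def fit(self, X, y, coords):
        if self.kernel != "bisquare":
            raise ValueError("only the bisquare kernel is supported")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        coords = np.asarray(coords, dtype=float)
        n = len(y)
        D = np.column_stack([np.ones(n), X]) if self.add_intercept else X.copy()
        p = D.shape[1]
        if n <= p:
            raise ValueError("need more observations than parameters")
        dist = pairwise_distances(coords, self.distance_metric)
        W = bisquare_weight(dist, self.bandwidth)
        min_req = self.min_in_bandwidth if self.min_in_bandwidth is not None else p
        in_bw = (W > 0).sum(axis=1)
        if np.any(in_bw < min_req):
            worst = int(in_bw.min())
            raise ValueError(
                f"bandwidth too small: a location has only {worst} in-bandwidth "
                f"neighbours (need >= {min_req})"
            )

        coef = np.empty((n, p))
        hat_diag = np.empty(n)
        hat_row_sq = np.empty(n)  # ||row i of S||^2, accumulates tr(S'S)
        local_r2 = np.empty(n)
        singular = []
        eye = np.eye(p)
        for i in range(n):
            w = W[i]
            Xw = D * w[:, None]
            A = Xw.T @ D  # X' W_i X
            b = Xw.T @ y
            try:
                beta = np.linalg.solve(A, b)
                C = np.linalg.solve(A, Xw.T)  # (X'W_iX)^{-1} X'W_i
            except np.linalg.LinAlgError:
                singular.append(i)
                A = A + self.ridge * eye
                beta = np.linalg.solve(A, b)
                C = np.linalg.solve(A, Xw.T)
            coef[i] = beta
            hat_row = D[i] @ C
            hat_diag[i] = hat_row[i]
            hat_row_sq[i] = hat_row @ hat_row
            # local weighted R^2 under the focal model's predictions
            yhat_i = D @ beta
            ybar_w = (w @ y) / w.sum()
            ss_res = w @ (y - yhat_i) ** 2
            ss_tot = w @ (y - ybar_w) ** 2
            local_r2[i] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

        fitted = np.einsum("ij,ij->i", D, coef)
        resid = y - fitted
        rss = float(resid @ resid)
        tss_y = float(((y - y.mean()) ** 2).sum())
        v1 = float(hat_diag.sum())
        r2 = 1.0 - rss / tss_y
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - v1)

        self.design_ = D
        self.coords_ = coords
        self.coef_local_ = coef
        self.fitted_ = fitted
        self.residuals_ = resid
        self.local_r2_ = local_r2
        self.hat_diag_ = hat_diag
        self.v1_ = v1
        self.v2_ = float(hat_row_sq.sum())  # tr(S'S)
        self.effective_residual_df_ = n - 2 * v1 + self.v2_
        self.rss_ = rss
        self.r2_ = r2
        self.adj_r2_ = adj
        self.aicc_ = aicc(n, rss, v1)
        self.n_ = n
        self.p_ = p
        self.singular_locations_ = singular
        return self

    def predict(self, X=None, coords=None):
        """In-sample fitted values (GWR coefficients exist at fit locations)."""
        check_is_fitted(self, "coef_local_")
        if X is None:
            return self.fitted_.copy()
        raise NotImplementedError(
            "out-of-sample prediction requires refitting at new focal locations"
        )


def gwr_vs_ols_ftest(gwr: GWRegressor, ols: OLSModel) -> tuple[float, float]:
    """ANOVA-style F test for the improvement of GWR over OLS.

    Uses the linear-smoother residual degrees of freedom of the GWR fit,
    ``delta = n - 2 tr(S) + tr(S'S)`` (for a linear smoother
    ``E[RSS] = sigma^2 * delta``, so this is the denominator df that keeps
    the test calibrated under a stationary truth):

        F = [(RSS_OLS - RSS_GWR) / (n - p - delta)] / [RSS_GWR / delta]

    on ``(n - p - delta, delta)`` degrees of freedom. If GWR numerically
    fits no better than OLS (e.g. the infinite-bandwidth limit, where the
    two models coincide) the statistic is reported as 0 with p-value 1.
    """
    check_is_fitted(gwr, "rss_")
    n, p = gwr.n_, ols.p
    delta = gwr.effective_residual_df_
    df_num = (n - p) - delta
    if df_num <= 1e-6:
        # numerically indistinguishable fits: no extra effective parameters
        return 0.0, 1.0
    if delta <= 0:
        raise ValueError("no residual degrees of freedom for GWR")
    num = (ols.rss - gwr.rss_) / df_num
    if num <= 0:
        import warnings

        warnings.warn("GWR RSS exceeds OLS RSS; reporting F = 0")
        return 0.0, 1.0
    F = num / (gwr.rss_ / delta)
    pval = float(stats.f.sf(F, df_num, delta))
    return float(F), pval


def forward_select(y, candidates, names=None, max_terms: int | None = None):
    """Greedy forward selection of OLS covariates by AICc.

    Starting from an intercept-only model, at each step the candidate giving
    the largest AICc decrease enters; selection stops when no candidate
    decreases AICc. Ties break deterministically toward the earlier
    candidate. Returns the selected names in entry order.
    """
    y = np.asarray(y, dtype=float)
    C = np.asarray(candidates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n, k = C.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(k)]
    if len(names) != k:
        raise ValueError("names length does not match candidate count")
    max_terms = k if max_terms is None else min(max_terms, k)

    selected: list[int] = []
    # intercept-only AICc: regress on a constant
    current = aicc(n, float(((y - y.mean()) ** 2).sum()), 1)
    while len(selected) < max_terms:
        best_j, best_aicc = None, current
        for j in range(k):
            if j in selected:
                continue
            X = C[:, selected + [j]]
            trial = fit_ols(X, y).aicc
            if trial < best_aicc - 1e-12:  # strict improvement, earliest wins ties
                best_j, best_aicc = j, trial
        if best_j is None:
            break
        selected.append(best_j)
        current = best_aicc
    return [names[j] for j in selected]


@dataclass
class PartitionResult:
    """Adjusted-R^2 decomposition into pure and shared components.

    ``pure_climate + pure_technology + shared = r2_all`` exactly, globally
    and (when per-location inputs are given) at every location. Components
    may be negative and are reported unclamped; ``clamped()`` offers a
    floor-at-zero rendering for mapping.
    """

    r2_all: float
    r2_suit: float
    r2_tec: float
    pure_climate: float
    pure_technology: float
    shared: float
    local: dict[str, np.ndarray] = field(default_factory=dict)

    def clamped(self) -> dict[str, float]:
        return {
            "pure_climate": max(self.pure_climate, 0.0),
            "pure_technology": max(self.pure_technology, 0.0),
            "shared": max(self.shared, 0.0),
        }


def variation_partition(
    r2_all: float,
    r2_suit: float,
    r2_tec: float,
    local_all=None,
    local_suit=None,
    local_tec=None,
) -> PartitionResult:
    """Partition explained variance from the three nested fits.

    Inputs are the (adjusted) R^2 of the full model, the suitability-only
    model and the technology-only model, fitted on identical observations
    and locations. Optional per-location R^2 vectors yield local components.
    """
    pure_climate = r2_all - r2_tec
    pure_technology = r2_all - r2_suit
    # the residual form (algebraically r2_suit + r2_tec - r2_all) makes
    # closure bitwise exact: components always sum to r2_all
    shared = r2_all - pure_climate - pure_technology
    result = PartitionResult(
        r2_all=r2_all,
        r2_suit=r2_suit,
        r2_tec=r2_tec,
        pure_climate=pure_climate,
        pure_technology=pure_technology,
        shared=shared,
    )
    if local_all is not None:
        la = np.asarray(local_all, dtype=float)
        ls = np.asarray(local_suit, dtype=float)
        lt = np.asarray(local_tec, dtype=float)
        if not (la.shape == ls.shape == lt.shape):
            raise ValueError("local R^2 vectors must share a shape")
        pc, pt = la - lt, la - ls
        result.local = {
            "r2_all": la,
            "pure_climate": pc,
            "pure_technology": pt,
            "shared": la - pc - pt,
        }
    return result


def municipality_suitability(
    suitability: np.ndarray, grid: GridSpec, lonlat
) -> tuple[np.ndarray, np.ndarray]:
    """Look up per-municipality consensus suitability from the grid.

    Each municipality receives the value of its containing cell. Returns
    ``(values, inside)`` where municipalities outside the grid (or on
    missing cells) get NaN and ``inside`` False, to be excluded (and
    counted) by the caller.
    """
    pts = np.atleast_2d(np.asarray(lonlat, dtype=float))
    inside = np.asarray(grid.contains(pts[:, 0], pts[:, 1]))
    values = np.full(len(pts), np.nan)
    if inside.any():
        cells = snap_to_grid(pts[inside], grid, collapse_duplicates=False)
        values[inside] = suitability[cells[:, 0], cells[:, 1]]
    inside = inside & np.isfinite(values)
    return values, inside
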