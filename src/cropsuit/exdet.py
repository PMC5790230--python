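"""Extrapolation detection (ExDet): univariate and combinatorial climate novelty.

Given a reference (calibration) climate sample, projection points are
classified as

* **type-1 novel** — at least one variable falls outside the reference
  min–max range; quantified by NT1 <= 0, the sum over variables of the range
  exceedance expressed as a (negative) fraction of each variable's reference
  range (more negative = more novel);
* **type-2 novel** — inside every univariate range but a novel *combination*
  of variables; quantified by NT2 = D^2 / D^2_max > 1, the Mahalanobis
  distance to the reference mean scaled by the largest Mahalanobis distance
  attained within the reference sample itself;
* **analog** — NT1 = 0 and NT2 <= 1.

NT1 is translation- and positive-scale-invariant per variable. A
zero-variance reference variable (e.g. a soil layer held constant across
periods) acts as a hard range: equality contributes 0, any departure makes
the point type-1 (contributing one full range, -1, to NT1).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .grids import EnvStack

__all__ = ["ExDet", "classify_projection"]

#: integer codes used in classification grids
CLASS_TYPE1 = 1
CLASS_TYPE2 = 2
CLASS_ANALOG = 0


class ExDet(BaseEstimator):
    """Fit a reference envelope and score projection novelty.

    Parameters
    ----------
    ridge : float
        Relative ridge added to a singular reference covariance
        (``ridge * trace / p`` on the diagonal).

    Fitted attributes: ``mins_``, ``maxs_``, ``mean_``, ``covariance_``,
    ``precision_``, ``d2_max_`` (largest reference Mahalanobis distance).
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n, p = X.shape
        if n < p + 1:
            raise ValueError(f"need >= {p + 1} reference points for {p} variables")
        self.n_features_in_ = p
        self.mins_ = X.min(axis=0)
        self.maxs_ = X.max(axis=0)
        self.mean_ = X.mean(axis=0)
        nonconstant = self.maxs_ > self.mins_
        # constant variables carry no covariance information; excluded from D^2
        self._mahal_vars_ = np.flatnonzero(nonconstant)
        Xm = X[:, self._mahal_vars_]
        cov = np.atleast_2d(np.cov(Xm, rowvar=False))
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn("singular reference covariance; ridge added to diagonal")
            cov = cov + self.ridge * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        self.covariance_ = cov
        self.precision_ = np.linalg.inv(cov)
        d2 = self._d2(X)
        self.d2_max_ = float(d2.max())
        if self.d2_max_ <= 0:
            raise ValueError("degenerate reference: all points at the mean")
        return self

    def _d2(self, X) -> np.ndarray:
        D = X[:, self._mahal_vars_] - self.mean_[self._mahal_vars_]
        return np.einsum("ij,jk,ik->i", D, self.precision_, D)

    def nt1(self, X) -> np.ndarray:
        """Univariate novelty: 0 inside all ranges, negative outside.

        NT1 = sum_j min(x_j - min_j, max_j - x_j, 0) / (max_j - min_j); a
        zero-range variable contributes 0 on equality and -1 otherwise.
        """
        check_is_fitted(self, "mins_")
        X = check_array(X, dtype=float)
        rng = self.maxs_ - self.mins_
        out = np.zeros(X.shape[0])
        for j in range(self.n_features_in_):
            if rng[j] == 0:
                out += np.where(X[:, j] == self.mins_[j], 0.0, -1.0)
            else:
                under = np.minimum(X[:, j] - self.mins_[j], 0.0)
                over = np.minimum(self.maxs_[j] - X[:, j], 0.0)
                out += np.minimum(under, over) / rng[j]
        return out

    def nt2(self, X) -> np.ndarray:
        """Combinatorial novelty D^2/D^2_max; only defined where NT1 = 0."""
        check_is_fitted(self, "d2_max_")
        X = check_array(X, dtype=float)
        if np.any(self.nt1(X) < 0):
            raise ValueError("nt2 requested for a point with NT1 < 0 (type-1 novel)")
        return self._d2(X) / self.d2_max_

    def transform(self, X) -> np.ndarray:
        """Columns [NT1, NT2]; NT2 is NaN where the point is type-1 novel."""
        check_is_fitted(self, "d2_max_")
        X = check_array(X, dtype=float)
        nt1 = self.nt1(X)
        nt2 = np.where(nt1 == 0, self._d2(X) / self.d2_max_, np.nan)
        return np.column_stack([nt1, nt2])

    def classify(self, X) -> np.ndarray:
        """Class codes: 1 type-1 novel, 2 type-2 novel, 0 analog."""
        nt = self.transform(X)
        out = np.full(len(nt), CLASS_ANALOG, dtype=int)
        out[nt[:, 0] < 0] = CLASS_TYPE1
        out[(nt[:, 0] == 0) & (nt[:, 1] > 1)] = CLASS_TYPE2
        return out


def classify_projection(projection: EnvStack, detector: ExDet, variables=None):
    """Classify every valid cell of a projection stack.

    Returns ``(nt1_grid, nt2_grid, class_grid, summary)``; missing cells
    propagate as NaN (class -1) and the summary counts conserve the number of
    valid cells.
    """
    names = list(variables) if variables is not None else projection.variable_names
    env = projection.subset(names)
    valid = env.valid_mask()
    cells = np.argwhere(valid)
    shape = env.grid.shape
    nt1_grid = np.full(shape, np.nan)
    nt2_grid = np.full(shape, np.nan)
    class_grid = np.full(shape, -1, dtype=int)
    if len(cells):
        X = env.as_matrix(cells)
        nt = detector.transform(X)
        classes = detector.classify(X)
        nt1_grid[cells[:, 0], cells[:, 1]] = nt[:, 0]
        nt2_grid[cells[:, 0], cells[:, 1]] = nt[:, 1]
        class_grid[cells[:, 0], cells[:, 1]] = classes
    summary = {
        "n_valid": int(len(cells)),
        "n_type1": int(np.sum(class_grid == CLASS_TYPE1)),
        "n_type2": int(np.sum(class_grid == CLASS_TYPE2)),
        "n_analog": int(np.sum(class_grid == CLASS_ANALOG)),
    }
    return nt1_grid, nt2_grid, class_grid, summary
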