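"""Multivariate adaptive regression splines (additive, degree 1).

Friedman-style forward pass that greedily adds reflected pairs of hinge
basis functions max(0, x - t) / max(0, t - x), followed by a backward
deletion pass pruned by generalized cross-validation:

    GCV = (RSS / n) / (1 - enp / n)^2,   enp = M + penalty * (M - 1) / 2

with M the number of basis terms (intercept included). The estimator follows
the scikit-learn protocol (fit/predict, get_params, trailing-underscore
fitted attributes) so it drops into sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


@dataclass(frozen=True)
class HingeTerm:
    """One basis function: max(0, sign * (x_var - knot))."""

    var: int
    knot: float
    direction: int  # +1 => max(0, x - t); -1 => max(0, t - x)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, self.direction * (X[:, self.var] - self.knot))


def gcv_score(rss: float, n: int, n_terms: int, penalty: float) -> float:
    enp = n_terms + penalty * (n_terms - 1) / 2.0
    if enp >= n:
        return np.inf
    return (rss / n) / (1.0 - enp / n) ** 2


class MarsRegressor(RegressorMixin, BaseEstimator):
    """Additive MARS with GCV-pruned hinge basis.

    Parameters
    ----------
    max_terms : int or None
        Forward-pass cap on basis terms (intercept included); default
        min(21, 2 * n_features + 1), the conventional heuristic for additive
        models.
    penalty : float
        GCV penalty per knot; 2 is the standard additive-model default.
    n_knot_candidates : int
        Candidate knots per predictor; the unique data values are used
        directly when there are fewer, otherwise evenly spaced quantiles of
        the unique values.
    """

    def __init__(
        self,
        max_terms: int | None = None,
        penalty: float = 2.0,
        n_knot_candidates: int = 128,
        min_gain: float = 1e-10,
    ):
        self.max_terms = max_terms
        self.penalty = penalty
        self.n_knot_candidates = n_knot_candidates
        self.min_gain = min_gain

    # -- helpers ----------------------------------------------------------
    def _candidate_knots(self, x: np.ndarray, endspan: int) -> np.ndarray:
        """Candidate knots, excluding the outermost ``endspan`` observations.

        The end-span guard (Friedman's rule) keeps the forward pass from
        planting a hinge that is non-zero for only a handful of extreme
        points, i.e. from chasing individual outliers.
        """
        xs = np.sort(x)
        if endspan > 0 and len(xs) > 2 * endspan:
            xs = xs[endspan:-endspan]
        uniq = np.unique(xs)
        if len(uniq) <= 1:
            return np.empty(0)
        uniq = uniq[:-1]  # a hinge at the maximum is identically zero
        if len(uniq) <= self.n_knot_candidates:
            return uniq
        q = np.linspace(0, 1, self.n_knot_candidates)
        return np.unique(np.quantile(uniq, q, method="nearest"))

    def _basis(self, X: np.ndarray, terms: list[HingeTerm]) -> np.ndarray:
        cols = [np.ones(len(X))]
        cols.extend(t.evaluate(X) for t in terms)
        return np.column_stack(cols)

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        max_terms = (
            self.max_terms if self.max_terms is not None else min(21, 2 * p + 1)
        )
        if max_terms >= n:
            raise ValueError(f"max_terms={max_terms} must be < n={n}")

        # Friedman's end-span: number of edge observations barred from knots
        endspan = int(3 + np.log2(p / 0.05)) if p > 0 else 0
        knots = [self._candidate_knots(X[:, j], endspan) for j in range(p)]
        terms: list[HingeTerm] = []
        B = np.ones((n, 1))
        tss = float(((y - y.mean()) ** 2).sum()) or 1.0

        while len(terms) + 1 < max_terms:
            Q, _ = np.linalg.qr(B)
            r = y - Q @ (Q.T @ y)
            best = None  # (gain, var, knot)
            for j in range(p):
                tj = knots[j]
                if len(tj) == 0:
                    continue
                xj = X[:, j][:, None]
                H1 = np.maximum(0.0, xj - tj[None, :])
                H2 = np.maximum(0.0, tj[None, :] - xj)
                H1 = H1 - Q @ (Q.T @ H1)
                H2 = H2 - Q @ (Q.T @ H2)
                a11 = np.einsum("ij,ij->j", H1, H1)
                a22 = np.einsum("ij,ij->j", H2, H2)
                a12 = np.einsum("ij,ij->j", H1, H2)
                b1 = H1.T @ r
                b2 = H2.T @ r
                det = a11 * a22 - a12 * a12
                eps = 1e-10 * max(a11.max(initial=0.0), a22.max(initial=0.0), 1.0)
                gain = np.zeros(len(tj))
                # full 2x2 solve where well conditioned
                ok = det > eps * np.maximum(a11, a22)
                with np.errstate(divide="ignore", invalid="ignore"):
                    g_pair = (a22 * b1 * b1 - 2 * a12 * b1 * b2 + a11 * b2 * b2) / det
                gain[ok] = g_pair[ok]
                # degenerate: use whichever single hinge explains more
                g1 = np.where(a11 > eps, b1 * b1 / np.where(a11 > 0, a11, 1.0), 0.0)
                g2 = np.where(a22 > eps, b2 * b2 / np.where(a22 > 0, a22, 1.0), 0.0)
                gain[~ok] = np.maximum(g1, g2)[~ok]
                idx = int(np.argmax(gain))
                if best is None or gain[idx] > best[0]:
                    best = (float(gain[idx]), j, float(tj[idx]))
            if best is None or best[0] <= self.min_gain * tss:
                break
            _, j, t = best
            for direction in (1, -1):
                if len(terms) + 1 >= max_terms:
                    break
                term = HingeTerm(var=j, knot=t, direction=direction)
                col = term.evaluate(X)
                resid_norm = col - B @ np.linalg.lstsq(B, col, rcond=None)[0]
                if float(resid_norm @ resid_norm) > 1e-12 * max(
                    float(col @ col), 1.0
                ):
                    terms.append(term)
                    B = np.column_stack([B, col])

        # backward deletion along the GCV path
        def fit_subset(subset: list[HingeTerm]):
            Bs = self._basis(X, subset)
            coef, *_ = np.linalg.lstsq(Bs, y, rcond=None)
            rss = float(((y - Bs @ coef) ** 2).sum())
            return coef, rss

        current = list(terms)
        coef, rss = fit_subset(current)
        best_subset, best_coef = list(current), coef
        best_gcv = gcv_score(rss, n, len(current) + 1, self.penalty)
        while current:
            candidates = []
            for i in range(len(current)):
                subset = current[:i] + current[i + 1 :]
                c, rss_i = fit_subset(subset)
                candidates.append((rss_i, i, c, subset))
            rss_i, _, c, subset = min(candidates, key=lambda t: (t[0], t[1]))
            current = subset
            g = gcv_score(rss_i, n, len(current) + 1, self.penalty)
            if g <= best_gcv:
                best_gcv, best_subset, best_coef = g, list(current), c

        self.terms_ = best_subset
        self.coef_ = best_coef
        self.gcv_ = best_gcv
        self.n_features_in_ = p
        pred = self._basis(X, self.terms_) @ self.coef_
        rss_final = float(((y - pred) ** 2).sum())
        tss_raw = float(((y - y.mean()) ** 2).sum())
        self.rsq_ = 1.0 - rss_final / tss_raw if tss_raw > 0 else 0.0
        return self

    def predict(self, X):
        check_is_fitted(self, "terms_")
        X = check_array(X)
        return self._basis(X, self.terms_) @ self.coef_

    @property
    def knots_(self) -> list[float]:
        check_is_fitted(self, "terms_")
        return [t.knot for t in self.terms_]

    def describe(self) -> pd.DataFrame:
        """Human-readable model terms (intercept first)."""
        check_is_fitted(self, "terms_")
        names = getattr(
            self,
            "feature_names_in_",
            np.array([f"x{i}" for i in range(self.n_features_in_)], dtype=object),
        )
        rows = [{"term": "(intercept)", "coef": float(self.coef_[0])}]
        for t, c in zip(self.terms_, self.coef_[1:]):
            expr = (
                f"h({names[t.var]} - {t.knot:.4g})"
                if t.direction > 0
                else f"h({t.knot:.4g} - {names[t.var]})"
            )
            rows.append({"term": expr, "coef": float(c)})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """JSON-serializable model description."""
        check_is_fitted(self, "terms_")
        return {
            "intercept": float(self.coef_[0]),
            "terms": [
                {
                    "var": int(t.var),
                    "knot": float(t.knot),
                    "direction": int(t.direction),
                    "coef": float(c),
                }
                for t, c in zip(self.terms_, self.coef_[1:])
            ],
            "gcv": float(self.gcv_),
            "rsq": float(self.rsq_),
        }
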