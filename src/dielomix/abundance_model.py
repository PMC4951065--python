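"""Feature screening and per-time-point protein-abundance models.

Screens sequence features by Spearman correlation with mRNA and by
first-order partial correlation with protein given mRNA (bootstrap null that
shuffles the gene labels of the feature while keeping mRNA-protein tuples
intact), then fits one MARS model (and optionally a Gaussian/identity GLM)
per time point predicting time-point-averaged protein log10 abundance from
same-time-point mRNA plus the feature table, evaluated by resubstitution and
10-fold cross-validated R-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from dielomix.mars import MarsRegressor
from dielomix.seqfeatures import FeatureTable


def _feature_frame(features) -> pd.DataFrame:
    return features.values if isinstance(features, FeatureTable) else features


def _tp_means(expr) -> pd.DataFrame:
    return expr.timepoint_means() if hasattr(expr, "timepoint_means") else expr


# ---------------------------------------------------------------------------
# correlation screens

def feature_mrna_correlations(features, mrna) -> pd.DataFrame:
    """Pairwise-complete Spearman rho per (feature, time point)."""
    F = _feature_frame(features)
    M = _tp_means(mrna)
    genes = F.index.intersection(M.index)
    if len(genes) < 10:
        raise ValueError("need >= 10 genes with feature and mRNA values")
    F, M = F.loc[genes], M.loc[genes]
    out = pd.DataFrame(index=F.columns, columns=M.columns, dtype=float)
    for feat in F.columns:
        x = F[feat].to_numpy(float)
        mask = np.isfinite(x)
        if mask.sum() < 3 or np.nanstd(x) == 0:
            warnings.warn(f"feature {feat!r} constant or too sparse; rho set missing")
            continue
        for tp in M.columns:
            out.loc[feat, tp] = stats.spearmanr(x[mask], M.loc[mask, tp]).statistic
    return out


def partial_correlation(x, y, z, method: str = "spearman") -> float:
    """First-order partial correlation r_xy.z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); with
    ``method="spearman"`` the three correlations are Pearson correlations of
    ranks. Collinearity (|r_xz| = 1 or |r_yz| = 1) is an error naming the
    offending pair.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[mask], y[mask], z[mask]
    if method == "spearman":
        x, y, z = (stats.rankdata(v) for v in (x, y, z))
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    for name, r in (("x~z", r_xz), ("y~z", r_yz)):
        if abs(r) >= 1.0 - 1e-12:
            raise ValueError(f"collinear pair {name} (|r| = 1): partial correlation undefined")
    return float((r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2)))


@dataclass
class PartialCorrelationResult:
    rho_mrna: pd.DataFrame        # feature x timepoint Spearman vs mRNA
    partial: pd.DataFrame         # feature x timepoint partial r vs protein | mRNA
    p_partial: pd.DataFrame       # bootstrap two-sided p per cell
    n_boot: int


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def feature_protein_partial_correlations(
    features,
    mrna,
    protein,
    n_boot: int = 10000,
    seed: int | None = None,
    method: str = "spearman",
) -> PartialCorrelationResult:
    """Per-feature, per-time-point partial correlation with bootstrap p.

    The null re-shuffles the gene labels of the feature vector while keeping
    each gene's (mRNA, protein) tuple intact; p is two-sided with the
    add-one estimator. One set of permutations per time point is shared
    across features (the null is feature-exchangeable).
    """
    F = _feature_frame(features)
    M, P = _tp_means(mrna), _tp_means(protein)
    genes = F.index.intersection(M.index).intersection(P.index)
    F, M, P = F.loc[genes], M.loc[genes], P.loc[genes, M.columns]
    rho = feature_mrna_correlations(F, M)
    partial = pd.DataFrame(index=F.columns, columns=M.columns, dtype=float)
    pvals = pd.DataFrame(index=F.columns, columns=M.columns, dtype=float)
    rng = np.random.default_rng(seed)
    for tp in M.columns:
        mcol = M[tp].to_numpy(float)
        pcol = P[tp].to_numpy(float)
        perms = None
        for feat in F.columns:
            x = F[feat].to_numpy(float)
            mask = np.isfinite(x)
            if mask.sum() < 4 or np.nanstd(x) == 0:
                continue
            obs = partial_correlation(x[mask], pcol[mask], mcol[mask], method=method)
            partial.loc[feat, tp] = obs
            if n_boot <= 0:
                continue
            if perms is None:
                perms = np.vstack(
                    [rng.permutation(mask.sum()) for _ in range(n_boot)]
                )
            elif perms.shape[1] != mask.sum():
                perms_local = np.vstack(
                    [rng.permutation(mask.sum()) for _ in range(n_boot)]
                )
                perms = perms_local
            xr = stats.rankdata(x[mask]) if method == "spearman" else x[mask]
            yr = stats.rankdata(pcol[mask]) if method == "spearman" else pcol[mask]
            zr = stats.rankdata(mcol[mask]) if method == "spearman" else mcol[mask]
            xs, ys, zs = _standardize(xr), _standardize(yr), _standardize(zr)
            nn = len(xs)
            r_yz = float(ys @ zs / nn)
            Xp = xs[perms]  # n_boot x n
            r_xy = Xp @ ys / nn
            r_xz = Xp @ zs / nn
            with np.errstate(invalid="ignore", divide="ignore"):
                null = (r_xy - r_xz * r_yz) / np.sqrt(
                    (1 - r_xz**2) * (1 - r_yz**2)
                )
            null = null[np.isfinite(null)]
            p = (1.0 + (np.abs(null) >= abs(obs)).sum()) / (1.0 + len(null))
            pvals.loc[feat, tp] = min(1.0, p)
    return PartialCorrelationResult(rho, partial, pvals, n_boot)


# ---------------------------------------------------------------------------
# regression models

def fit_glm(predictors: pd.DataFrame, response: pd.Series, feature_subset=None):
    """Ordinary least squares (Gaussian GLM, identity link) via statsmodels.

    Rank-deficient designs drop collinear columns with a warning. Returns the
    fitted statsmodels results object (``.params``, ``.rsquared`` available).
    """
    X = predictors[list(feature_subset)] if feature_subset is not None else predictors
    mask = X.notna().all(axis=1) & response.notna()
    X, y = X.loc[mask], response.loc[mask]
    if len(X) < X.shape[1] + 2:
        raise ValueError("need at least n_predictors + 2 complete cases")
    vals = X.to_numpy(float)
    keep = []
    basis = np.ones((len(X), 1))
    for j, col in enumerate(X.columns):
        cand = np.column_stack([basis, vals[:, j]])
        if np.linalg.matrix_rank(cand) > basis.shape[1]:
            keep.append(col)
            basis = cand
    if len(keep) < X.shape[1]:
        dropped = [c for c in X.columns if c not in keep]
        warnings.warn(f"dropped collinear columns: {dropped}")
    design = sm.add_constant(X[keep], has_constant="add")
    return sm.OLS(y, design).fit()


def make_folds(
    y: np.ndarray, folds: int = 10, seed: int | None = None
) -> np.ndarray:
    """Fold assignment stratified by response decile (seeded shuffle)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n = len(y)
    if n < folds:
        raise ValueError("need n >= folds")
    rng = np.random.default_rng(seed)
    deciles = np.minimum((stats.rankdata(y, method="ordinal") - 1) * 10 // n, 9)
    assignment = np.empty(n, dtype=int)
    counter = 0
    for d in range(10):
        idx = np.where(deciles == d)[0]
        rng.shuffle(idx)
        for i in idx:
            assignment[i] = counter % folds
            counter += 1
    return assignment


def cross_validate(model_factory, predictors, response, folds: int = 10, seed=None):
    """Pooled out-of-fold R-squared: 1 - RSS / TSS over all held-out points.

    ``model_factory`` is a zero-argument callable returning an unfitted
    estimator with fit/predict. Returns (r2_cv, out-of-fold predictions).
    """
    X = predictors.to_numpy(float) if isinstance(predictors, pd.DataFrame) else np.asarray(predictors, float)
    y = response.to_numpy(float) if isinstance(response, pd.Series) else np.asarray(response, float)
    assignment = make_folds(y, folds=folds, seed=seed)
    oof = np.full(len(y), np.nan)
    for f in range(folds):
        test = assignment == f
        model = model_factory()
        model.fit(X[~test], y[~test])
        oof[test] = model.predict(X[test])
    rss = float(((y - oof) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return r2, oof


CONSTRAINED_SUBSETS = {
    "full": None,
    "mrna_only": ["mrna"],
    "mrna_cai": ["mrna", "cai"],
}


@dataclass
class TimepointModel:
    timepoint: str
    model: MarsRegressor
    genes: pd.Index
    r2_resub: float
    r2_cv: float
    residuals: pd.Series  # predicted - observed, per gene


@dataclass
class RegressionEvaluation:
    """Per-time-point MARS models with residuals and R-squared summaries."""

    models: dict[str, TimepointModel]
    residuals: pd.DataFrame = field(init=False)  # gene x timepoint
    r2_resub: dict[str, float] = field(init=False)
    r2_cv: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.residuals = pd.DataFrame(
            {tp: m.residuals for tp, m in self.models.items()}
        )
        self.r2_resub = {tp: m.r2_resub for tp, m in self.models.items()}
        self.r2_cv = {tp: m.r2_cv for tp, m in self.models.items()}


def build_predictor_table(
    features, mrna, timepoint: str, feature_subset=None
) -> pd.DataFrame:
    """Per-gene predictors at one time point: mRNA abundance + features."""
    F = _feature_frame(features)
    M = _tp_means(mrna)
    genes = F.index.intersection(M.index)
    table = F.loc[genes].copy()
    table.insert(0, "mrna", M.loc[genes, timepoint])
    if feature_subset is not None:
        table = table[[c for c in feature_subset if c in table.columns]]
    return table


def fit_protein_models(
    features,
    mrna,
    protein,
    feature_subset: str | list[str] | None = "full",
    genes=None,
    max_terms: int | None = None,
    penalty: float = 2.0,
    n_knot_candidates: int = 32,
    folds: int = 10,
    cv: bool = True,
    seed: int | None = None,
) -> RegressionEvaluation:
    """Fit one MARS model per time point on complete-feature genes.

    ``feature_subset`` accepts "full", "mrna_only", "mrna_cai" (the
    constrained variants) or an explicit column list. Residuals use the
    predicted - observed convention throughout.
    """
    if isinstance(feature_subset, str):
        feature_subset = CONSTRAINED_SUBSETS[feature_subset]
    F = _feature_frame(features)
    if isinstance(features, FeatureTable):
        F = F.loc[~features.incomplete]
    P = _tp_means(protein)
    models = {}
    for tp in P.columns:
        X = build_predictor_table(F, mrna, tp, feature_subset)
        y = P[tp]
        shared = X.index.intersection(y.index)
        if genes is not None:
            shared = shared.intersection(pd.Index(genes))
        X, ytp = X.loc[shared], y.loc[shared]
        complete = X.notna().all(axis=1) & ytp.notna()
        X, ytp = X.loc[complete], ytp.loc[complete]
        if len(X) < 30:
            raise ValueError(f"{tp}: need >= 30 complete-case genes, got {len(X)}")
        model = MarsRegressor(
            max_terms=max_terms, penalty=penalty, n_knot_candidates=n_knot_candidates
        )
        model.fit(X, ytp)
        pred = pd.Series(model.predict(X), index=X.index)
        if cv:
            r2_cv, _ = cross_validate(
                lambda: MarsRegressor(
                    max_terms=max_terms,
                    penalty=penalty,
                    n_knot_candidates=n_knot_candidates,
                ),
                X,
                ytp,
                folds=folds,
                seed=seed,
            )
        else:
            r2_cv = float("nan")
        models[tp] = TimepointModel(
            timepoint=tp,
            model=model,
            genes=X.index,
            r2_resub=model.rsq_,
            r2_cv=r2_cv,
            residuals=pred - ytp,
        )
    return RegressionEvaluation(models=models)
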