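"""Lasso identification of pain-scale items predicting movement asymmetry.

Each pain assessment (horse x occasion x phase x observer) is joined to
the total asymmetry score of its associated trot measurement, item scores
are factor-encoded (one indicator per score level above 0, named like
``hgs_orb1``), and horse and observer indicators are added as fixed
effects.  The model

    min  (1 / 2N) * ||y - b0 - X b||^2  +  lambda * ||b||_1

is fit along a log-spaced lambda path with predictors standardized
internally (coefficients reported on the original scale), and the lambda
minimizing the mean 10-fold cross-validated error is selected.  Per-horse
data are truncated at the occasion of maximum total asymmetry score
before fitting, restricting the analysis to the rising phase of the
induced lameness.

The coordinate-descent solve is delegated to scikit-learn's ``Lasso``
(identical objective); optimality is guaranteed by the KKT conditions,
checkable with :func:`kkt_violation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, enet_path

from .scales import ScaleItem

__all__ = [
    "DesignMatrix",
    "LassoFit",
    "build_design",
    "fit_lasso_cv",
    "fit_at_lambda",
    "kkt_violation",
    "select_items",
    "truncate_at_max_score",
]


@dataclass
class DesignMatrix:
    """Factor-encoded predictors and the asymmetry response.

    ``X`` holds 0/1 indicators: one column per observed item-score level
    above 0 (level 0 is the reference), plus horse and observer identity
    columns.  ``keys`` carries the (horse, occasion, phase, observer) of
    each row.
    """

    X: pd.DataFrame
    y: pd.Series                 # total asymmetry score, mm
    keys: pd.DataFrame
    item_columns: list[str]
    effect_columns: list[str]


@dataclass
class LassoFit:
    """A cross-validated lasso path and the fit at ``lambda_min``."""

    lambda_path: np.ndarray
    cv_mean_error: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    coefficients: dict[str, float]   # original scale, at lambda_min
    intercept: float
    path_coefficients: np.ndarray    # (n_lambda, p), original scale, full data
    columns: list[str]
    n_folds: int
    seed: int

    def nonzero(self) -> dict[str, float]:
        return {c: v for c, v in self.coefficients.items() if v != 0.0}


def truncate_at_max_score(asymmetry: pd.DataFrame) -> pd.DataFrame:
    """Keep, per horse, only occasions up to the maximum total asymmetry score.

    ``asymmetry`` must have columns ``horse``, ``occasion``, ``score_mm``
    (and may carry more, e.g. ``repeat``).  Occasions are kept in their
    row order per horse; ties on the maximum take the earliest occasion.
    """
    kept = []
    for horse, grp in asymmetry.groupby("horse", sort=False):
        occ_order = list(dict.fromkeys(grp["occasion"]))
        occ_max = grp.groupby("occasion")["score_mm"].max()
        best = max(occ_order, key=lambda o: (occ_max[o], -occ_order.index(o)))
        keep_occ = occ_order[: occ_order.index(best) + 1]
        kept.append(grp[grp["occasion"].isin(keep_occ)])
    return pd.concat(kept, ignore_index=True)


def _pair_scores(row_phase: str, repeats: pd.DataFrame) -> float:
    """Pairing rule: with one trot repeat both phases share its score; with
    two, the pre-assessment pairs with the first and the post-assessment
    with the second."""
    if len(repeats) == 1:
        return float(repeats["score_mm"].iloc[0])
    ordered = repeats.sort_values("repeat")
    return float(
        ordered["score_mm"].iloc[0] if row_phase == "pre" else ordered["score_mm"].iloc[-1]
    )


def build_design(
    scores: pd.DataFrame,
    asymmetry: pd.DataFrame,
    scales: list[ScaleItem],
    truncate: bool = True,
) -> DesignMatrix:
    """Join assessments to asymmetry scores and factor-encode the items.

    Parameters
    ----------
    scores : long-format table (horse, occasion, phase, observer, scale,
        item, score).
    asymmetry : per-measurement table with columns ``horse``, ``occasion``,
        ``repeat`` (1-based within occasion) and ``score_mm``.
    truncate : apply the per-horse truncation at maximum score.

    Unmatched assessments (no measurement on that horse/occasion) are
    dropped with a warning.
    """
    asym = asymmetry.copy()
    if "repeat" not in asym.columns:
        asym["repeat"] = 1
    if truncate:
        asym = truncate_at_max_score(asym)
    lookup = {k: g for k, g in asym.groupby(["horse", "occasion"])}

    wide = scores.pivot_table(
        index=["horse", "occasion", "phase", "observer"],
        columns=["scale", "item"],
        values="score",
    )
    keys = wide.index.to_frame(index=False)
    responses = np.full(len(keys), np.nan)
    for i, row in enumerate(keys.itertuples(index=False)):
        grp = lookup.get((row.horse, row.occasion))
        if grp is not None:
            responses[i] = _pair_scores(row.phase, grp)
    matched = np.isfinite(responses)
    if not matched.all():
        warnings.warn(
            f"dropping {int((~matched).sum())} assessment rows without a "
            "matching trot measurement",
            stacklevel=2,
        )
    wide = wide.loc[matched]
    keys = keys.loc[matched].reset_index(drop=True)
    responses = responses[matched]

    prefix = {
        (it.scale_id, it.item_id): it.column_prefix for it in scales
    }
    blocks: dict[str, np.ndarray] = {}
    item_cols: list[str] = []
    for scale_id, item_id in wide.columns:
        col = wide[(scale_id, item_id)].to_numpy()
        levels = sorted({int(v) for v in col if np.isfinite(v)} - {0})
        for lev in levels:
            name = f"{prefix[(scale_id, item_id)]}{lev}"
            blocks[name] = (col == lev).astype(float)
            item_cols.append(name)
    effect_cols: list[str] = []
    for field_name in ("horse", "observer"):
        for value in sorted(keys[field_name].unique()):
            name = str(value)
            blocks[name] = (keys[field_name] == value).to_numpy(float)
            effect_cols.append(name)
    X = pd.DataFrame(blocks, index=keys.index)
    return DesignMatrix(
        X=X,
        y=pd.Series(responses, index=keys.index, name="score_mm"),
        keys=keys,
        item_columns=item_cols,
        effect_columns=effect_cols,
    )


def _lasso_path_solve(
    Xs: np.ndarray, yc: np.ndarray, lambdas: np.ndarray, tol: float = 1e-7
) -> np.ndarray:
    """Solve the standardized lasso along a decreasing lambda path with warm
    starts.  Returns (n_lambda, p) standardized-scale coefficients."""
    if len(lambdas) == 1:
        return _lasso_single_solve(Xs, yc, float(lambdas[0]))[None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = enet_path(
            Xs, yc, l1_ratio=1.0, alphas=lambdas, tol=tol, max_iter=10_000
        )
    return coefs.T


def _lasso_single_solve(
    Xs: np.ndarray, yc: np.ndarray, lam: float, tol: float = 1e-12
) -> np.ndarray:
    """High-accuracy single-lambda solve (tight tolerance for KKT checks)."""
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=500_000, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, yc)
    return model.coef_


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    active = sd > 0
    Xs = np.zeros_like(X, dtype=float)
    Xs[:, active] = (X[:, active] - mean[active]) / sd[active]
    return Xs, mean, sd, active


def fit_lasso_cv(
    design: DesignMatrix,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> LassoFit:
    """Fit the lasso path with K-fold cross-validation and keep lambda_min.

    Folds are assigned by a seeded permutation of the rows.  Predictors
    are standardized within each training set (and for the final full-data
    fit); reported coefficients are on the original scale.  The largest
    path lambda is the smallest value with an all-zero solution.
    """
    X = design.X.to_numpy(float)
    y = design.y.to_numpy(float)
    n, p = X.shape
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} rows for {n_folds}-fold CV")
    if np.var(y) == 0:
        raise ValueError("constant response")

    Xs, mean, sd, active = _standardize(X)
    yc = y - y.mean()
    lambda_max = np.max(np.abs(Xs.T @ yc)) / n
    lambdas = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambda)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    fold_mse = np.zeros((n_folds, n_lambda))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        Xtr, mtr, sdtr, atr = _standardize(X[train_idx])
        ytr = y[train_idx]
        coefs = _lasso_path_solve(Xtr, ytr - ytr.mean(), lambdas)
        Xte = np.zeros((len(test_idx), p))
        Xte[:, atr] = (X[test_idx][:, atr] - mtr[atr]) / sdtr[atr]
        preds = ytr.mean() + Xte @ coefs.T
        fold_mse[f] = np.mean((y[test_idx][:, None] - preds) ** 2, axis=0)
    cv_mean = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
    k_min = int(np.argmin(cv_mean))
    lambda_min = float(lambdas[k_min])

    path_std = _lasso_path_solve(Xs, yc, lambdas)
    path_orig = np.zeros_like(path_std)
    path_orig[:, active] = path_std[:, active] / sd[active]
    # high-accuracy solve at the selected lambda (KKT-grade tolerance)
    beta_std = _lasso_single_solve(Xs, yc, lambda_min)
    beta = np.zeros_like(beta_std)
    beta[active] = beta_std[active] / sd[active]
    intercept = float(y.mean() - beta @ mean)
    return LassoFit(
        lambda_path=lambdas,
        cv_mean_error=cv_mean,
        cv_se=cv_se,
        lambda_min=lambda_min,
        coefficients=dict(zip(design.X.columns, beta)),
        intercept=intercept,
        path_coefficients=path_orig,
        columns=list(design.X.columns),
        n_folds=n_folds,
        seed=seed,
    )


def fit_at_lambda(
    design: DesignMatrix,
    lam: float,
    unpenalized: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[dict[str, float], float]:
    """Solve the lasso at a single penalty value, original-scale output.

    ``unpenalized`` columns (e.g. the horse/observer indicators) carry no
    L1 penalty; they are handled by block coordinate descent, alternating
    an exact least-squares solve for the free block with a lasso solve for
    the penalized block until the objective stabilizes.

    Returns ``(coefficients, intercept)``.
    """
    X = design.X.to_numpy(float)
    y = design.y.to_numpy(float)
    cols = list(design.X.columns)
    Xs, mean, sd, active = _standardize(X)
    yc = y - y.mean()
    free = np.array([c in set(unpenalized or []) for c in cols])
    pen = ~free
    beta = np.zeros(X.shape[1])
    if not free.any():
        beta[:] = _lasso_path_solve(Xs, yc, np.array([lam]), tol=min(tol, 1e-10))[0]
    else:
        Xf, Xp = Xs[:, free], Xs[:, pen]
        bf = np.zeros(free.sum())
        bp = np.zeros(pen.sum())
        last = np.inf
        for _ in range(max_iter):
            bf, *_ = np.linalg.lstsq(Xf, yc - Xp @ bp, rcond=None)
            if not pen.any():
                break
            bp = _lasso_path_solve(Xp, yc - Xf @ bf, np.array([lam]), tol=1e-12)[0]
            r = yc - Xf @ bf - Xp @ bp
            obj = 0.5 * np.mean(r**2) + lam * np.abs(bp).sum()
            if last - obj < tol * (1 + abs(obj)):
                break
            last = obj
        beta[free] = bf
        beta[pen] = bp
    beta_orig = np.zeros_like(beta)
    beta_orig[active] = beta[active] / sd[active]
    intercept = float(y.mean() - beta_orig @ mean)
    return dict(zip(cols, beta_orig)), intercept


def kkt_violation(design: DesignMatrix, fit: LassoFit, lam: float | None = None) -> float:
    """Maximum KKT violation of the lambda_min solution.

    On the standardized problem, optimality requires the gradient
    ``g_j = (1/N) x_j' r`` to satisfy ``|g_j| <= lambda`` for zero
    coefficients and ``g_j = lambda * sign(b_j)`` for nonzero ones.
    Returns the largest absolute violation across columns.
    """
    lam = fit.lambda_min if lam is None else lam
    X = design.X.to_numpy(float)
    y = design.y.to_numpy(float)
    Xs, mean, sd, active = _standardize(X)
    yc = y - y.mean()
    beta_std = np.array([fit.coefficients[c] for c in fit.columns])
    beta_std[active] = beta_std[active] * sd[active]
    g = Xs.T @ (yc - Xs @ beta_std) / len(y)
    viol = np.where(
        beta_std == 0.0,
        np.maximum(np.abs(g) - lam, 0.0),
        np.abs(g - lam * np.sign(beta_std)),
    )
    return float(np.max(viol[active])) if active.any() else 0.0


@dataclass
class ItemSelection:
    """Nonzero lambda_min coefficients, items ranked by magnitude."""

    items: list[tuple[str, float]]
    effects: list[tuple[str, float]]


def select_items(fit: LassoFit, design: DesignMatrix) -> ItemSelection:
    """Rank nonzero coefficients by standardized magnitude.

    Values are reported on the original scale (mm per indicator), but the
    ranking uses ``|coefficient| * column sd`` — the coefficient of the
    unit-variance predictor.  Ranking raw mm coefficients would let a
    rare score level observed in one or two rows outrank genuinely
    predictive items, since an indicator's mm coefficient grows as its
    level gets rarer.  Horse/observer effects are reported separately
    from item columns.
    """
    nz = fit.nonzero()
    sds = design.X.std(axis=0, ddof=0)

    def ranked(cols: list[str]) -> list[tuple[str, float]]:
        sub = [(c, v) for c, v in nz.items() if c in set(cols)]
        return sorted(sub, key=lambda cv: -abs(cv[1]) * sds[cv[0]])

    return ItemSelection(
        items=ranked(design.item_columns), effects=ranked(design.effect_columns)
    )
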