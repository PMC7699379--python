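"""Multiple correspondence analysis of scale items and the follow-up
regression of movement asymmetry on the MCA dimensions.

MCA is correspondence analysis of the complete disjunctive (indicator)
coding of the ordinal items: with Q items and J categories in total, the
indicator matrix Z (rows sum to Q) is scaled to correspondence form
``P = Z / z``, the standardized residual matrix

    S = D_r^{-1/2} (P - r c') D_c^{-1/2}

is decomposed by SVD, eigenvalues are the squared singular values, and
principal coordinates follow from the transition formulas.  Raw
(uncorrected) inertia fractions are used; total inertia equals
``J/Q - 1``.  Dimension signs are fixed by forcing the category with the
largest absolute coordinate positive on each dimension.

Dimensions explaining at least a minimum fraction of the inertia (default
1%) enter a linear model of movement asymmetry with random intercepts for
horse and observer; the model is reduced by greedy backward elimination
on AIC and the surviving dimensions with p below a threshold (default
0.01) are interpreted: each contributing category is associated with
asymmetry in the direction ``sign(beta_dim * category_coordinate)``,
which is invariant to the per-dimension sign indeterminacy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scales import ScaleItem

__all__ = [
    "IndicatorMatrix",
    "McaResult",
    "DimensionRegression",
    "build_indicator",
    "fit_mca",
    "select_dims",
    "regress_dims",
    "interpret_dim",
]


@dataclass
class IndicatorMatrix:
    """Complete disjunctive coding of the score table.

    One column per (item, observed level) category, labelled
    ``<scale>_<item><level>``; each item's block sums to 1 in every row.
    Items with a single observed level contribute zero inertia and are
    listed in ``degenerate_items``.
    """

    Z: pd.DataFrame
    row_keys: pd.DataFrame
    n_items: int
    degenerate_items: list[str] = field(default_factory=list)


@dataclass
class McaResult:
    """Eigenstructure of the correspondence analysis."""

    eigenvalues: np.ndarray           # squared singular values, non-increasing
    explained_fraction: np.ndarray    # eigenvalue / total inertia
    total_inertia: float
    row_coords: pd.DataFrame          # principal coordinates, cols dim1..dimK
    col_coords: pd.DataFrame
    col_contributions: pd.DataFrame   # per-category contribution to each dim
    row_masses: np.ndarray
    col_masses: np.ndarray

    @property
    def dims(self) -> list[int]:
        return list(range(1, len(self.eigenvalues) + 1))


@dataclass
class DimensionRegression:
    """Backward-eliminated model of asymmetry on MCA dimensions."""

    included_dims: list[int]
    retained_dims: list[int]
    betas: dict[int, float]
    ses: dict[int, float]
    z_values: dict[int, float]
    p_values: dict[int, float]
    significant_dims: list[int]
    aic_trace: list[tuple[str, float]]
    random_effect_variances: dict[str, float]
    engine: str                      # 'mixed' or 'ols'
    lag1_autocorr: float | None = None
    fallback_warning: str | None = None


def build_indicator(
    scores: pd.DataFrame,
    scales: list[ScaleItem],
    row_mode: str = "observer",
) -> IndicatorMatrix:
    """Build the indicator matrix from a long-format score table.

    ``row_mode='observer'`` makes one row per (horse, occasion, phase,
    observer) — each observer's scoring is its own observation, matching
    the follow-up regression that models observer as a random effect.
    ``row_mode='assessment'`` collapses the observers of an assessment to
    their per-item median score.
    """
    if row_mode not in ("observer", "assessment"):
        raise ValueError("row_mode must be 'observer' or 'assessment'")
    keys = ["horse", "occasion", "phase"] + (["observer"] if row_mode == "observer" else [])
    wide = scores.pivot_table(index=keys, columns=["scale", "item"], values="score",
                              aggfunc="median")
    if wide.isna().any().any():
        raise ValueError("score table has missing item scores for some rows")
    prefix = {(it.scale_id, it.item_id): it.column_prefix for it in scales}
    blocks: dict[str, np.ndarray] = {}
    degenerate: list[str] = []
    for scale_id, item_id in wide.columns:
        col = wide[(scale_id, item_id)].to_numpy()
        levels = sorted({int(round(v)) for v in col})
        if len(levels) == 1:
            degenerate.append(f"{prefix[(scale_id, item_id)]}{levels[0]}")
        for lev in levels:
            blocks[f"{prefix[(scale_id, item_id)]}{lev}"] = (
                np.round(col).astype(int) == lev
            ).astype(float)
    Z = pd.DataFrame(blocks)
    return IndicatorMatrix(
        Z=Z,
        row_keys=wide.index.to_frame(index=False),
        n_items=len(wide.columns),
        degenerate_items=degenerate,
    )


def fit_mca(indicator: IndicatorMatrix, tol: float = 1e-10) -> McaResult:
    """Correspondence analysis of the indicator matrix.

    Eigenvalues below ``tol`` (structural zeros) are dropped from the
    coordinate output but total inertia keeps the full sum, preserving the
    ``J/Q - 1`` identity.
    """
    Z = indicator.Z.to_numpy(float)
    if Z.shape[0] < 2 or Z.shape[1] < 2:
        raise ValueError("indicator matrix too small for MCA")
    total = Z.sum()
    P = Z / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(c == 0):
        raise ValueError("empty category column")
    Dr = 1.0 / np.sqrt(r)
    Dc = 1.0 / np.sqrt(c)
    S = Dr[:, None] * (P - np.outer(r, c)) * Dc[None, :]
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    eig_all = sv**2
    total_inertia = float(eig_all.sum())
    keep = sv > np.sqrt(tol)
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    # principal coordinates via the transition formulas
    row = Dr[:, None] * U * sv[None, :]
    col = Dc[:, None] * Vt.T * sv[None, :]
    # fix signs: largest-|coordinate| category positive on each dimension
    for k in range(len(sv)):
        j = int(np.argmax(np.abs(col[:, k])))
        if col[j, k] < 0:
            col[:, k] *= -1
            row[:, k] *= -1
    contrib = c[:, None] * col**2 / (sv**2)[None, :]
    dim_names = [f"dim{k + 1}" for k in range(len(sv))]
    return McaResult(
        eigenvalues=sv**2,
        explained_fraction=sv**2 / total_inertia,
        total_inertia=total_inertia,
        row_coords=pd.DataFrame(row, columns=dim_names, index=indicator.Z.index),
        col_coords=pd.DataFrame(col, columns=dim_names, index=indicator.Z.columns),
        col_contributions=pd.DataFrame(contrib, columns=dim_names, index=indicator.Z.columns),
        row_masses=r,
        col_masses=c,
    )


def select_dims(mca: McaResult, min_fraction: float = 0.01) -> list[int]:
    """Dimensions (1-based) explaining at least ``min_fraction`` of inertia."""
    return [k + 1 for k, f in enumerate(mca.explained_fraction) if f >= min_fraction]


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Least squares fit; returns (beta, rss, XtX_inv_diag)."""
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    return beta, float(resid @ resid), np.diag(XtX_inv)


def _gaussian_aic(rss: float, n: int, k_params: int) -> float:
    # ML Gaussian AIC up to an additive constant; k_params counts mean
    # parameters, +1 for the residual variance
    return n * np.log(max(rss, 1e-300) / n) + 2 * (k_params + 1)


def _backward_eliminate(
    X: np.ndarray, y: np.ndarray, dims: list[int]
) -> tuple[list[int], list[tuple[str, float]]]:
    """Greedy single-drop backward elimination by AIC on the OLS profile.

    The design is ``[1 | dim columns]``; at each step the dimension whose
    removal lowers AIC most is dropped, until no removal lowers AIC.
    """
    n = len(y)
    current = list(range(X.shape[1]))  # indices into dim columns
    ones = np.ones((n, 1))

    def aic_of(cols: list[int]) -> float:
        M = np.hstack([ones, X[:, cols]]) if cols else ones
        _, rss, _ = _ols_fit(M, y)
        return _gaussian_aic(rss, n, len(cols) + 1)

    trace = [("full", aic_of(current))]
    while current:
        base_aic = trace[-1][1]
        candidates = [
            (aic_of([c for c in current if c != drop]), drop) for drop in current
        ]
        best_aic, best_drop = min(candidates)
        if best_aic < base_aic:
            current.remove(best_drop)
            trace.append((f"-dim{dims[best_drop]}", best_aic))
        else:
            break
    return [dims[c] for c in current], trace


def _lag1_within_groups(resid: np.ndarray, groups: np.ndarray) -> float | None:
    pairs_a, pairs_b = [], []
    for g in pd.unique(groups):
        r = resid[groups == g]
        if len(r) >= 2:
            pairs_a.append(r[:-1])
            pairs_b.append(r[1:])
    if not pairs_a:
        return None
    a = np.concatenate(pairs_a)
    b = np.concatenate(pairs_b)
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def regress_dims(
    row_coords: pd.DataFrame,
    asymmetry: np.ndarray,
    included_dims: list[int] | None = None,
    horse: np.ndarray | None = None,
    observer: np.ndarray | None = None,
    p_threshold: float = 0.01,
) -> DimensionRegression:
    """Model movement asymmetry on MCA dimension scores.

    Backward elimination runs on the fixed-effects (OLS) AIC profile;
    when ``horse``/``observer`` groupings are supplied the retained model
    is refit as a linear mixed model with crossed random intercepts
    (Wald z inference), falling back to OLS (t inference) on singular or
    failed fits.  Residual lag-1 autocorrelation within horse is reported
    as a temporal-dependence diagnostic.
    """
    y = np.asarray(asymmetry, float)
    if included_dims is None:
        included_dims = [int(c.removeprefix("dim")) for c in row_coords.columns]
    cols = [f"dim{d}" for d in included_dims]
    X = row_coords[cols].to_numpy(float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("coordinates and response are not aligned")

    retained, trace = _backward_eliminate(X, y, list(included_dims))
    rcols = [f"dim{d}" for d in retained]
    Xr = row_coords[rcols].to_numpy(float)

    engine = "ols"
    fallback = None
    vc: dict[str, float] = {}
    if retained and horse is not None and observer is not None:
        try:
            import statsmodels.formula.api as smf

            data = pd.DataFrame(Xr, columns=rcols)
            data["y"] = y
            data["horse"] = np.asarray(horse)
            data["observer"] = np.asarray(observer)
            data["all"] = 1
            formula = "y ~ " + " + ".join(rcols)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(
                    formula,
                    data,
                    groups="all",
                    vc_formula={"horse": "0 + C(horse)", "observer": "0 + C(observer)"},
                )
                fit = md.fit(reml=False, method="lbfgs")
            if not np.all(np.isfinite(fit.bse.loc[rcols])):
                raise np.linalg.LinAlgError("non-finite standard errors")
            betas = {d: float(fit.params[f"dim{d}"]) for d in retained}
            ses = {d: float(fit.bse[f"dim{d}"]) for d in retained}
            zs = {d: betas[d] / ses[d] for d in retained}
            ps = {d: 2 * stats.norm.sf(abs(zs[d])) for d in retained}
            vc_names = list(getattr(md.exog_vc, "names", [])) or ["horse", "observer"]
            vc = {k: float(v) for k, v in zip(vc_names, np.asarray(fit.vcomp, float))}
            resid = np.asarray(fit.resid, float)
            engine = "mixed"
        except Exception as exc:  # singular fit, convergence failure
            fallback = f"mixed model fit failed ({exc}); using fixed-intercept OLS"
            warnings.warn(fallback, stacklevel=2)
            engine = "ols"
    if engine == "ols":
        # Wald inference in the full included-dims model: the reduced
        # model's own RSS and covariance are both shrunk by the AIC
        # selection (it drops the columns that absorbed the least noise),
        # which would inflate the type-I rate.  MCA row coordinates are
        # orthogonal across dimensions, so for them the full-model
        # estimates of the retained dims coincide with a refit.
        M_full = np.hstack([np.ones((n, 1)), X])
        beta_full, rss_full, diag_full = _ols_fit(M_full, y)
        dof = max(n - M_full.shape[1], 1)
        sigma2 = rss_full / dof
        pos = {d: list(included_dims).index(d) + 1 for d in retained}
        betas = {d: float(beta_full[pos[d]]) for d in retained}
        ses = {d: float(np.sqrt(sigma2 * diag_full[pos[d]])) for d in retained}
        zs = {d: betas[d] / ses[d] if ses[d] > 0 else np.inf for d in retained}
        ps = {d: 2 * stats.t.sf(abs(zs[d]), dof) for d in retained}
        M = np.hstack([np.ones((n, 1)), Xr]) if retained else np.ones((n, 1))
        beta_r, _, _ = _ols_fit(M, y)
        resid = y - M @ beta_r
    significant = [d for d in retained if ps[d] < p_threshold]
    lag1 = (
        _lag1_within_groups(resid, np.asarray(horse)) if horse is not None else None
    )
    return DimensionRegression(
        included_dims=list(included_dims),
        retained_dims=retained,
        betas=betas,
        ses=ses,
        z_values=zs,
        p_values=ps,
        significant_dims=significant,
        aic_trace=trace,
        random_effect_variances=vc,
        engine=engine,
        lag1_autocorr=lag1,
        fallback_warning=fallback,
    )


def interpret_dim(
    mca: McaResult,
    regression: DimensionRegression,
    dim: int,
    contribution_threshold: float = 0.02,
) -> list[dict]:
    """Signed category associations for one retained dimension.

    For each category whose contribution to the dimension exceeds the
    threshold, the direction of association with movement asymmetry is
    ``sign(beta_dim * category_coordinate)`` — invariant to flipping the
    dimension's sign, since the beta flips with the coordinates.
    """
    if dim not in regression.retained_dims:
        raise ValueError(f"dimension {dim} is not in the final model")
    name = f"dim{dim}"
    beta = regression.betas[dim]
    out = []
    for cat in mca.col_coords.index:
        contrib = float(mca.col_contributions.loc[cat, name])
        if contrib < contribution_threshold:
            continue
        coord = float(mca.col_coords.loc[cat, name])
        out.append(
            {
                "category": cat,
                "association": "positive" if beta * coord > 0 else "negative",
                "contribution": contrib,
                "coordinate": coord,
            }
        )
    out.sort(key=lambda d: -d["contribution"])
    return out
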