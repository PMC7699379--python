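"""Validation experiments quantifying the pipeline's operating characteristics.

Each function runs a self-contained experiment against the synthetic
generator or random inputs and returns a summary number: ground-truth
recovery error of the kinematic chain, agreement of Kendall's W with a
direct-from-definition implementation, lasso optimality and planted-item
recovery, MCA identities, and the calibration of the dimension
regression.  They are used both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import mca as mca_mod
from . import selection as sel
from .reliability import band, kendalls_w
from .scales import load_published_w, load_scales
from .synth import GaitParams, default_design, simulate_gait, simulate_scores

__all__ = [
    "banding_counts",
    "kinematic_recovery_grid",
    "kinematic_recovery_noisy",
    "kendall_oracle_max_diff",
    "lasso_kkt_max",
    "lasso_ols_limit_max_diff",
    "planted_pos_recovery",
    "mca_inertia_identity_max_error",
    "mca_burt_oracle_max_error",
    "null_dim_significance_rate",
    "planted_dim_recovery",
    "study_runs_identical",
]


def banding_counts() -> dict[str, dict[str, int]]:
    """Agreement-band counts per scale from the published W coefficients."""
    table = load_published_w()
    counts: dict[str, dict[str, int]] = {}
    for scale, grp in table.groupby("scale"):
        c = {"very_strong": 0, "strong": 0, "moderate": 0, "weak": 0}
        for w in grp["w"]:
            c[band(w)] += 1
        counts[str(scale)] = c
    return counts


def kinematic_recovery_grid(
    injections=(-60.0, -20.0, -5.0, 5.0, 20.0, 60.0),
    frequencies=(1.1, 1.3, 1.5),
) -> float:
    """Noise-free recovery: max |recovered - injected| (mm) for head and
    pelvis over the injection x stride-frequency grid."""
    worst = 0.0
    for f in frequencies:
        for inj in injections:
            params = GaitParams(
                stride_frequency=f, pelvis_asym_mm=inj, head_asym_mm=inj,
                noise_sd_mm=0.0,
            )
            m = kin.measure_asymmetry(simulate_gait(params))
            worst = max(worst, abs(m.pd_min_mm - inj), abs(m.hd_min_mm - inj))
    return worst


def kinematic_recovery_noisy(
    n_replicates: int = 200,
    noise_sd_mm: float = 2.0,
    tolerance_mm: float = 2.0,
    seed: int = 0,
) -> float:
    """Fraction of noisy measurements (20 strides) recovering the injected
    pelvis asymmetry within ``tolerance_mm``."""
    injections = (-60.0, -20.0, -5.0, 5.0, 20.0, 60.0)
    ok = 0
    for r in range(n_replicates):
        inj = injections[r % len(injections)]
        params = GaitParams(
            pelvis_asym_mm=inj, head_asym_mm=inj / 2, n_strides=20,
            noise_sd_mm=noise_sd_mm, seed=seed * 100_003 + r,
        )
        m = kin.measure_asymmetry(simulate_gait(params))
        if abs(m.pd_min_mm - inj) <= tolerance_mm:
            ok += 1
    return ok / n_replicates


def _bruteforce_w(X: np.ndarray) -> float:
    """Kendall's W straight from the definition with its own mid-ranks."""
    n, m = X.shape
    ranks = np.zeros((n, m))
    for j in range(m):
        for i in range(n):
            less = sum(1 for v in X[:, j] if v < X[i, j])
            eq = sum(1 for v in X[:, j] if v == X[i, j])
            ranks[i, j] = less + (eq + 1) / 2.0
    R = ranks.sum(axis=1)
    S = sum((r - R.mean()) ** 2 for r in R)
    T = 0.0
    for j in range(m):
        for v in set(X[:, j]):
            t = sum(1 for u in X[:, j] if u == v)
            T += t**3 - t
    denom = m * m * (n**3 - n) - m * T
    return 12.0 * S / denom if denom > 0 else float("nan")


def kendall_oracle_max_diff(n_tables: int = 100, seed: int = 0) -> float:
    """Max |W_implementation - W_definition| over random 6x3 rating tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        X = rng.integers(0, 4, size=(6, 3)).astype(float)
        expected = _bruteforce_w(X)
        got = kendalls_w(X)
        if np.isnan(expected):
            assert got.degenerate
            continue
        worst = max(worst, abs(got.w - expected))
    return worst


def _random_design(rng: np.random.Generator, n: int = 60, p: int = 8) -> sel.DesignMatrix:
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[: min(3, p)] = [4.0, -3.0, 2.0][: min(3, p)]
    y = X @ beta + rng.normal(0, 1.0, n)
    cols = [f"x{j}" for j in range(p)]
    return sel.DesignMatrix(
        X=pd.DataFrame(X, columns=cols),
        y=pd.Series(y, name="score_mm"),
        keys=pd.DataFrame({"horse": ["h1"] * n, "occasion": ["b0"] * n,
                           "phase": ["pre"] * n, "observer": ["o1"] * n}),
        item_columns=cols,
        effect_columns=[],
    )


def lasso_kkt_max(n_designs: int = 20, seed: int = 0) -> float:
    """Max KKT violation of the lambda_min solution over random designs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_designs):
        d = _random_design(rng)
        fit = sel.fit_lasso_cv(d, n_folds=5, seed=seed)
        worst = max(worst, sel.kkt_violation(d, fit))
    return worst


def lasso_ols_limit_max_diff(seed: int = 0) -> float:
    """Max |lasso(lambda->0) - OLS| coefficient difference on a full-rank
    design."""
    rng = np.random.default_rng(seed)
    d = _random_design(rng, n=100, p=5)
    coefs, intercept = sel.fit_at_lambda(d, lam=1e-10)
    X1 = np.column_stack([np.ones(len(d.y)), d.X.to_numpy()])
    ols = np.linalg.lstsq(X1, d.y.to_numpy(), rcond=None)[0]
    diffs = [abs(intercept - ols[0])]
    diffs += [abs(coefs[c] - ols[j + 1]) for j, c in enumerate(d.X.columns)]
    return float(max(diffs))


def planted_pos_recovery(n_replicates: int = 100, seed: int = 0) -> float:
    """Fraction of replicates where the top-ranked lasso item column is a
    posture level.

    The experiment plants latent effects of 2 observer-noise sd on the two
    posture items (EPS and CPS 'pos'), with observer noise as the only
    other latent noise source; n = 160 assessment rows (8 horses x 5
    occasions x 2 phases x 2 observers, no truncation); the response is
    the true asymmetry trajectory.
    """
    scales = load_scales()
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_replicates):
            design = default_design(
                seed=seed * 20_011 + r, n_observers_per_assessment=2,
                horse_effect_sd=0.0,
                item_effects={("EPS", "pos"): 2.0, ("CPS", "pos"): 2.0},
            )
            scores, truth = simulate_scores(design, scales)
            asym = pd.DataFrame(
                [
                    {"horse": h, "occasion": occ, "repeat": 1,
                     "score_mm": truth.asymmetry_trajectory[h][oi]}
                    for h in design.horses
                    for oi, occ in enumerate(design.occasions)
                ]
            )
            d = sel.build_design(scores, asym, scales, truncate=False)
            fit = sel.fit_lasso_cv(d, seed=seed * 20_011 + r)
            items = sel.select_items(fit, d).items
            if items and items[0][0].startswith(("eps_pos", "cps_pos")):
                hits += 1
    return hits / n_replicates


def _random_indicator(rng: np.random.Generator, scales) -> mca_mod.IndicatorMatrix:
    items = [it for it in scales if it.scale_id in ("HGS", "EPS")][:6]
    rows = []
    n_rows = int(rng.integers(20, 50))
    for i in range(n_rows):
        for it in items:
            rows.append(
                {
                    "horse": f"h{i % 4 + 1}", "occasion": f"o{i // 4}",
                    "phase": "pre" if i % 2 == 0 else "post", "observer": "o1",
                    "scale": it.scale_id, "item": it.item_id,
                    "score": int(rng.integers(0, it.max_score + 1)),
                }
            )
    return mca_mod.build_indicator(pd.DataFrame(rows), scales)


def mca_inertia_identity_max_error(n_tables: int = 20, seed: int = 0) -> float:
    """Max |total inertia - (J/Q - 1)| over random score tables."""
    scales = load_scales()
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        ind = _random_indicator(rng, scales)
        mca = mca_mod.fit_mca(ind)
        J, Q = ind.Z.shape[1], ind.n_items
        worst = max(worst, abs(mca.total_inertia - (J / Q - 1)))
    return worst


def mca_burt_oracle_max_error(n_tables: int = 20, seed: int = 0) -> float:
    """Max eigenvalue discrepancy against the Burt-matrix route (whose CA
    eigenvalues are the squares of the indicator-route eigenvalues)."""
    scales = load_scales()
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        ind = _random_indicator(rng, scales)
        mca = mca_mod.fit_mca(ind)
        Z = ind.Z.to_numpy()
        B = Z.T @ Z
        P = B / B.sum()
        r = P.sum(axis=1)
        S = (P - np.outer(r, r)) / np.sqrt(np.outer(r, r))
        burt_eig = np.sort(np.linalg.svd(S, compute_uv=False) ** 2)[::-1]
        k = len(mca.eigenvalues)
        worst = max(worst, float(np.max(np.abs(mca.eigenvalues**2 - burt_eig[:k]))))
    return worst


def null_dim_significance_rate(
    n_replicates: int = 1000,
    n_dims: int = 20,
    n_rows: int = 150,
    seed: int = 0,
) -> tuple[float, int]:
    """Fraction of null dimensions retained *and* significant at p < 0.01.

    Pure-noise responses regressed on random orthogonal-in-expectation
    dimension scores; returns ``(rate, n_dim_tests)``.
    """
    hits = 0
    cols = [f"dim{i + 1}" for i in range(n_dims)]
    for r in range(n_replicates):
        rng = np.random.default_rng(seed * 50_021 + r)
        coords = pd.DataFrame(rng.normal(size=(n_rows, n_dims)), columns=cols)
        y = rng.normal(0, 10.0, n_rows)
        reg = mca_mod.regress_dims(coords, y)
        hits += len(reg.significant_dims)
    return hits / (n_replicates * n_dims), n_replicates * n_dims


def planted_dim_recovery(
    n_replicates: int = 100,
    beta: float = 30.0,
    noise_sd: float = 10.0,
    n_rows: int = 150,
    n_dims: int = 10,
    seed: int = 0,
) -> float:
    """Fraction of replicates retaining (and flagging significant) a
    dimension with a true effect of ``beta`` mm per unit score."""
    hits = 0
    cols = [f"dim{i + 1}" for i in range(n_dims)]
    for r in range(n_replicates):
        rng = np.random.default_rng(seed * 70_001 + r)
        X = rng.normal(size=(n_rows, n_dims))
        coords = pd.DataFrame(X, columns=cols)
        y = beta * X[:, 0] + rng.normal(0, noise_sd, n_rows)
        reg = mca_mod.regress_dims(coords, y)
        if 1 in reg.retained_dims and 1 in reg.significant_dims:
            hits += 1
    return hits / n_replicates


def study_runs_identical(seed: int = 1) -> bool:
    """Whether two full study runs with one seed produce byte-identical
    artifact trees."""
    import hashlib

    from .pipeline import StudyConfig, run_study

    def digest(root: Path) -> str:
        h = hashlib.sha256()
        for p in sorted(root.rglob("*")):
            if p.is_file():
                h.update(str(p.relative_to(root)).encode())
                h.update(p.read_bytes())
        return h.hexdigest()

    with tempfile.TemporaryDirectory() as td:
        a, b = Path(td) / "a", Path(td) / "b"
        run_study(StudyConfig(seed=seed), a)
        run_study(StudyConfig(seed=seed), b)
        return digest(a) == digest(b)
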