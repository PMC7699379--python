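"""MCA stage: disjunctive coding, CA identities, the Burt-matrix oracle,
dimension selection, the regression on dimensions, and interpretation."""

import numpy as np
import pandas as pd
import pytest

from equiasym import mca as mca_mod
from equiasym.synth import default_design, simulate_scores


def _random_score_table(rng, scales, n_rows=40):
    """Long-format random scores over a subset of items."""
    items = [it for it in scales if it.scale_id in ("HGS", "EPS")][:6]
    rows = []
    for i in range(n_rows):
        for it in items:
            rows.append(
                {
                    "horse": f"h{i % 4 + 1}", "occasion": f"o{i // 4}",
                    "phase": "pre" if i % 2 == 0 else "post",
                    "observer": "o1", "scale": it.scale_id, "item": it.item_id,
                    "score": int(rng.integers(0, it.max_score + 1)),
                }
            )
    return pd.DataFrame(rows)


def _burt_eigenvalues(Z):
    """Independent oracle: CA eigenvalues of the Burt matrix B = Z'Z must be
    the squares of the indicator-route eigenvalues."""
    B = Z.T @ Z
    total = B.sum()
    P = B / total
    r = P.sum(axis=1)
    S = (P - np.outer(r, r)) / np.sqrt(np.outer(r, r))
    sv = np.linalg.svd(S, compute_uv=False)
    return np.sort(sv**2)[::-1]


class TestIndicator:
    def test_disjunctive_block_structure(self, scales):
        rng = np.random.default_rng(0)
        table = _random_score_table(rng, scales)
        ind = mca_mod.build_indicator(table, scales)
        Z = ind.Z.to_numpy()
        assert (Z.sum(axis=1) == ind.n_items).all()
        assert set(np.unique(Z)) <= {0.0, 1.0}

    def test_two_binary_items_give_four_columns(self, scales):
        rows = []
        for i, (a, b) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            for item, score in (("orb", a), ("ears", b)):
                rows.append(
                    {"horse": "h1", "occasion": f"o{i}", "phase": "pre",
                     "observer": "o1", "scale": "HGS", "item": item, "score": score}
                )
        ind = mca_mod.build_indicator(pd.DataFrame(rows), scales)
        assert ind.Z.shape == (4, 4)
        assert (ind.Z.sum(axis=1) == 2).all()

    def test_constant_item_flagged(self, scales):
        rows = []
        for i in range(4):
            rows.append({"horse": "h1", "occasion": f"o{i}", "phase": "pre",
                         "observer": "o1", "scale": "HGS", "item": "orb",
                         "score": i % 2})
            rows.append({"horse": "h1", "occasion": f"o{i}", "phase": "pre",
                         "observer": "o1", "scale": "HGS", "item": "ears",
                         "score": 1})
        ind = mca_mod.build_indicator(pd.DataFrame(rows), scales)
        assert ind.degenerate_items == ["hgs_ears1"]

    def test_assessment_mode_collapses_observers(self, scales):
        design = default_design(seed=0)
        table, _ = simulate_scores(design, scales)
        ind_obs = mca_mod.build_indicator(table, scales, row_mode="observer")
        ind_ass = mca_mod.build_indicator(table, scales, row_mode="assessment")
        assert len(ind_obs.Z) == 3 * len(ind_ass.Z)


class TestMcaIdentities:
    def test_total_inertia_identity(self, scales):
        rng = np.random.default_rng(1)
        for _ in range(5):
            ind = mca_mod.build_indicator(_random_score_table(rng, scales), scales)
            mca = mca_mod.fit_mca(ind)
            J, Q = ind.Z.shape[1], ind.n_items
            assert mca.total_inertia == pytest.approx(J / Q - 1, abs=1e-8)

    def test_burt_route_oracle(self, scales):
        rng = np.random.default_rng(2)
        for _ in range(5):
            ind = mca_mod.build_indicator(_random_score_table(rng, scales), scales)
            mca = mca_mod.fit_mca(ind)
            burt = _burt_eigenvalues(ind.Z.to_numpy())
            k = len(mca.eigenvalues)
            assert mca.eigenvalues**2 == pytest.approx(burt[:k], abs=1e-8)

    def test_row_coords_mass_centered(self, scales):
        rng = np.random.default_rng(3)
        ind = mca_mod.build_indicator(_random_score_table(rng, scales), scales)
        mca = mca_mod.fit_mca(ind)
        centered = mca.row_masses @ mca.row_coords.to_numpy()
        assert np.abs(centered).max() < 1e-10

    def test_eigenvalues_non_increasing(self, scales):
        rng = np.random.default_rng(4)
        ind = mca_mod.build_indicator(_random_score_table(rng, scales), scales)
        mca = mca_mod.fit_mca(ind)
        assert (np.diff(mca.eigenvalues) <= 1e-12).all()
        assert mca.explained_fraction.sum() <= 1.0 + 1e-9

    def test_explained_fraction_invariant_to_row_duplication(self, scales):
        rng = np.random.default_rng(5)
        table = _random_score_table(rng, scales)
        ind = mca_mod.build_indicator(table, scales)
        dup = mca_mod.IndicatorMatrix(
            Z=pd.concat([ind.Z, ind.Z], ignore_index=True),
            row_keys=pd.concat([ind.row_keys, ind.row_keys], ignore_index=True),
            n_items=ind.n_items,
        )
        f1 = mca_mod.fit_mca(ind).explained_fraction
        f2 = mca_mod.fit_mca(dup).explained_fraction
        assert f2 == pytest.approx(f1, abs=1e-10)

    def test_perfectly_associated_binary_items(self, scales):
        """Two identical binary items: one dimension carries all the
        association between their blocks."""
        rows = []
        for i in range(8):
            s = i % 2
            for item in ("orb", "ears"):
                rows.append({"horse": "h1", "occasion": f"o{i}", "phase": "pre",
                             "observer": "o1", "scale": "HGS", "item": item,
                             "score": s})
        ind = mca_mod.build_indicator(pd.DataFrame(rows), scales)
        mca = mca_mod.fit_mca(ind)
        # J/Q - 1 = 1; a single dimension explains the full inertia
        assert mca.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert len(mca.eigenvalues) == 1


class TestSelectDims:
    def test_threshold(self):
        mca = _fake_mca(np.array([0.10, 0.05, 0.009]))
        assert mca_mod.select_dims(mca) == [1, 2]

    def test_all_above_threshold(self):
        mca = _fake_mca(np.array([0.5, 0.3, 0.2]))
        assert mca_mod.select_dims(mca) == [1, 2, 3]


def _fake_mca(fractions):
    eig = fractions / fractions.sum()
    dims = [f"dim{i+1}" for i in range(len(eig))]
    empty = pd.DataFrame(np.zeros((1, len(eig))), columns=dims)
    return mca_mod.McaResult(
        eigenvalues=eig, explained_fraction=fractions, total_inertia=1.0,
        row_coords=empty, col_coords=empty, col_contributions=empty,
        row_masses=np.array([1.0]), col_masses=np.ones(len(eig)),
    )


class TestRegressDims:
    def _coords(self, rng, n=150, k=10):
        X = rng.normal(size=(n, k))
        return pd.DataFrame(X, columns=[f"dim{i+1}" for i in range(k)]), X

    def test_planted_dimension_retained_and_significant(self):
        hits = 0
        for r in range(10):
            rng = np.random.default_rng(r)
            coords, X = self._coords(rng)
            y = 30.0 * X[:, 0] + rng.normal(0, 10, len(X))
            reg = mca_mod.regress_dims(coords, y)
            if 1 in reg.retained_dims and 1 in reg.significant_dims:
                hits += 1
        assert hits >= 9

    def test_aic_trace_non_increasing(self):
        rng = np.random.default_rng(0)
        coords, X = self._coords(rng)
        y = rng.normal(0, 10, len(X))
        reg = mca_mod.regress_dims(coords, y)
        aics = [a for _, a in reg.aic_trace]
        assert all(b <= a for a, b in zip(aics, aics[1:]))

    def test_significant_subset_of_retained(self):
        rng = np.random.default_rng(1)
        coords, X = self._coords(rng)
        y = 20.0 * X[:, 2] + rng.normal(0, 10, len(X))
        reg = mca_mod.regress_dims(coords, y)
        assert set(reg.significant_dims) <= set(reg.retained_dims)
        assert set(reg.retained_dims) <= set(reg.included_dims)

    def test_mixed_engine_recovers_group_variance(self):
        rng = np.random.default_rng(2)
        coords, X = self._coords(rng, n=200, k=4)
        horse = rng.choice([f"h{i}" for i in range(8)], 200)
        horse_eff = dict(zip([f"h{i}" for i in range(8)], rng.normal(0, 5, 8)))
        obs = rng.choice(["o1", "o2", "o3"], 200)
        y = 25.0 * X[:, 0] + np.array([horse_eff[h] for h in horse])
        y = y + rng.normal(0, 8, 200)
        reg = mca_mod.regress_dims(coords, y, horse=horse, observer=obs)
        assert reg.engine == "mixed"
        assert 1 in reg.significant_dims
        assert reg.betas[1] == pytest.approx(25.0, abs=3.0)
        assert reg.random_effect_variances["horse"] > 1.0
        assert reg.lag1_autocorr is not None

    def test_interpretation_sign_rule_and_flip_invariance(self, scales):
        design = default_design(seed=0)
        table, truth = simulate_scores(design, scales)
        ind = mca_mod.build_indicator(table, scales)
        mca = mca_mod.fit_mca(ind)
        rng = np.random.default_rng(3)
        y = 30.0 * mca.row_coords["dim1"].to_numpy() + rng.normal(0, 5, len(ind.Z))
        reg = mca_mod.regress_dims(mca.row_coords, y, included_dims=[1, 2, 3])
        assert 1 in reg.retained_dims
        interp = mca_mod.interpret_dim(mca, reg, 1)
        assert interp, "expected contributing categories"
        for rec in interp:
            expected = "positive" if reg.betas[1] * rec["coordinate"] > 0 else "negative"
            assert rec["association"] == expected
        # flipping the dimension's sign flips coords and beta together
        flipped = mca_mod.McaResult(
            eigenvalues=mca.eigenvalues,
            explained_fraction=mca.explained_fraction,
            total_inertia=mca.total_inertia,
            row_coords=mca.row_coords.assign(dim1=-mca.row_coords["dim1"]),
            col_coords=mca.col_coords.assign(dim1=-mca.col_coords["dim1"]),
            col_contributions=mca.col_contributions,
            row_masses=mca.row_masses, col_masses=mca.col_masses,
        )
        reg_f = mca_mod.regress_dims(flipped.row_coords, y, included_dims=[1, 2, 3])
        interp_f = mca_mod.interpret_dim(flipped, reg_f, 1)
        assert {(r["category"], r["association"]) for r in interp} == {
            (r["category"], r["association"]) for r in interp_f
        }

    def test_unretained_dim_rejected(self, scales):
        rng = np.random.default_rng(4)
        coords, X = self._coords(rng)
        y = 30.0 * X[:, 0] + rng.normal(0, 5, len(X))
        reg = mca_mod.regress_dims(coords, y)
        missing = next(d for d in reg.included_dims if d not in reg.retained_dims)
        with pytest.raises(ValueError):
            mca_mod.interpret_dim(_fake_mca(np.ones(10) / 10), reg, missing)
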