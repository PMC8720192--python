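"""Residualization, imputation and modality PCA."""

import numpy as np
import pandas as pd
import pytest

from mhbrain import fields as F
from mhbrain.preprocess import (ConfoundRegressor, GroupPCA, PcaModel,
                                build_confound_design, fit_pca_group,
                                knn_impute, project, residualize)

from oracles import knn_impute_oracle


@pytest.fixture()
def design(small_cohort):
    _, table, _ = small_cohort
    return build_confound_design(table[table["timepoint"] == 1])


class TestConfoundDesign:
    def test_expected_columns(self, design):
        for c in ("age", "age_sq", "sex", "age_x_sex", "head_size",
                  "head_motion_rest", "head_motion_task", "date", "date_sq",
                  "intercept"):
            assert c in design.columns
        assert any(c.startswith("site_") for c in design.columns)

    def test_full_rank(self, design):
        D = design.to_numpy()
        assert np.linalg.matrix_rank(D) == D.shape[1]

    def test_continuous_columns_centred_before_squaring(self, design):
        # age_sq is the square of the *centred* age column
        assert np.allclose(design["age_sq"], design["age"] ** 2)


class TestResidualize:
    def test_design_column_residualizes_to_zero(self, design):
        r = residualize(design["age"].to_numpy(), design)
        assert np.max(np.abs(r)) < 1e-9

    def test_intercept_only_centres(self, rng):
        x = rng.normal(5.0, 2.0, 200)
        r = residualize(x, np.ones((200, 1)))
        assert np.allclose(r, x - x.mean())

    def test_residuals_orthogonal_to_design(self, design, rng):
        X = rng.normal(size=(len(design), 7))
        R = residualize(X, design)
        D = design.to_numpy()
        cosine = (D.T @ R) / np.outer(np.linalg.norm(D, axis=0),
                                      np.linalg.norm(R, axis=0))
        assert np.max(np.abs(cosine)) < 1e-8

    def test_idempotence(self, design, rng):
        X = rng.normal(size=(len(design), 4))
        once = residualize(X, design)
        assert np.allclose(residualize(once, design), once, atol=1e-9)

    def test_missing_cells_skipped_and_stay_missing(self, design, rng):
        X = rng.normal(size=(len(design), 3))
        X[::10, 1] = np.nan
        R = residualize(X, design)
        assert np.isnan(R[::10, 1]).all()
        obs = np.isfinite(X[:, 1])
        direct = residualize(X[obs, 1], design.iloc[obs])
        assert np.allclose(R[obs, 1], direct, atol=1e-9)

    def test_rank_deficient_design_named(self, rng):
        D = np.column_stack([np.ones(50), rng.normal(size=50)])
        D = np.column_stack([D, D[:, 1]])          # duplicated column
        with pytest.raises(ValueError, match="collinear"):
            residualize(rng.normal(size=50), D)

    def test_known_confound_betas_recovered(self, small_cohort):
        """Regression on the generator's effect design recovers the planted
        coefficients within standard error."""
        from mhbrain.synthetic import _confound_design_for_effects

        cfg, table, truth = small_cohort
        t1 = table[table["timepoint"] == 1]
        C = _confound_design_for_effects(
            t1["site"].to_numpy(), t1["age"].to_numpy(),
            t1["sex"].to_numpy(), t1["head_size"].to_numpy(),
            t1["head_motion_rest"].to_numpy(),
            t1["head_motion_task"].to_numpy(),
            t1["scan_date"].to_numpy(), cfg.n_sites)
        D = np.column_stack([C, np.ones(len(C))])
        cols = [c for c in truth.idp_columns[:20]
                if t1[c].notna().all()]
        X = t1[cols].to_numpy()
        beta, *_ = np.linalg.lstsq(D, X, rcond=None)
        planted = truth.confound_betas[:, [truth.idp_columns.index(c)
                                           for c in cols]]
        # per-coefficient SE is ~1/sqrt(n) ~ 0.026 at n=1500
        assert np.max(np.abs(beta[:-1] - planted)) < 0.15


class TestConfoundRegressor:
    def test_matches_functional_residualize(self, design, rng):
        X = rng.normal(size=(len(design), 5))
        est = ConfoundRegressor().fit(X, confounds=design.to_numpy())
        out = est.transform(X, confounds=design.to_numpy())
        assert np.allclose(out, residualize(X, design), atol=1e-9)

    def test_sklearn_param_interface(self):
        est = ConfoundRegressor()
        assert est.get_params() == {}
        est.set_params()


class TestKnnImpute:
    def test_twin_row_fills_hole(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, np.nan]])
        out = knn_impute(X, k=1)
        assert out[1, 2] == 3.0

    def test_no_missing_is_identity(self, rng):
        X = rng.normal(size=(20, 4))
        assert np.array_equal(knn_impute(X, k=3), X)

    def test_observed_cells_untouched(self, rng):
        X = rng.normal(size=(30, 5))
        holes = rng.random(X.shape) < 0.1
        Xh = X.copy()
        Xh[holes] = np.nan
        out = knn_impute(Xh, k=2)
        assert np.array_equal(out[~holes], X[~holes])

    def test_hand_matrix_matches_exhaustive_oracle(self):
        X = np.array([
            [1.0, 2.0, 1.5, 0.0],
            [1.1, np.nan, 1.4, 0.2],
            [5.0, 6.0, 5.5, 4.0],
            [5.1, 6.2, np.nan, 4.1],
            [1.05, 2.1, 1.45, np.nan],
            [5.05, 6.1, 5.45, 4.05]])
        out = knn_impute(X, k=2)
        assert np.allclose(out, knn_impute_oracle(X, k=2), rtol=1e-12)

    def test_groups_restrict_donor_distance(self):
        # col 2 belongs to a second group whose values would mislead the
        # neighbour choice if pooled
        X = np.array([[0.0, 1.0, 100.0],
                      [0.0, np.nan, 100.0],
                      [10.0, 7.0, 100.0]])
        groups = np.array([0, 0, 1])
        out = knn_impute(X, k=1, groups=groups)
        assert out[1, 1] == 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            knn_impute(np.array([[1.0, 2.0], [np.nan, np.nan]]), k=1)
        with pytest.raises(ValueError):
            knn_impute(np.array([[1.0, 2.0]]), k=0)


class TestPcaGroup:
    def test_equal_eigenvalues_take_half_the_components(self, rng):
        X = rng.normal(size=(300, 10))
        # whiten so every sample eigenvalue is exactly equal
        Xc = X - X.mean(0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        W = U * np.sqrt(300 - 1)
        model = fit_pca_group(W, variance_target=0.5)
        assert model.n_components == 5

    def test_rank_one_data(self, rng):
        x = rng.normal(size=100)
        X = np.outer(x, [1.0, 2.0, -1.0])
        model = fit_pca_group(X, variance_target=0.5)
        assert model.n_components == 1
        assert model.cumulative_explained_variance == pytest.approx(1.0)

    def test_retained_count_monotone_in_target(self, rng):
        X = rng.normal(size=(200, 12)) @ rng.normal(size=(12, 12))
        counts = [fit_pca_group(X, t).n_components
                  for t in (0.2, 0.4, 0.6, 0.8, 0.999)]
        assert counts == sorted(counts)

    def test_sign_convention(self, rng):
        X = rng.normal(size=(100, 6))
        model = fit_pca_group(X, 0.9)
        for comp in model.loadings:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_projection_consistency_and_serialization(self, rng, tmp_path):
        X = rng.normal(size=(120, 8))
        model = fit_pca_group(X, 0.6)
        scores = project(X, model)
        # zero-vector subject on a centred model projects to the origin
        model0 = PcaModel(np.zeros(8), model.scale, model.loadings,
                          model.explained_variance_ratio)
        assert np.allclose(project(np.zeros((1, 8)), model0), 0.0)
        model.save(tmp_path / "pca.json")
        back = PcaModel.load(tmp_path / "pca.json")
        assert np.array_equal(project(X, back), project(X, model))
        assert np.allclose(scores, project(X, model))

    def test_variable_mismatch_rejected(self, rng):
        model = fit_pca_group(rng.normal(size=(50, 6)), 0.5)
        with pytest.raises(ValueError, match="mismatch"):
            project(rng.normal(size=(10, 5)), model)

    def test_incomplete_data_rejected(self, rng):
        X = rng.normal(size=(30, 4))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_pca_group(X, 0.5)


class TestGroupPCA:
    def test_heldout_projection_equals_hand_product(self, small_cohort):
        _, table, _ = small_cohort
        idp_cols = F.idp_columns(table.columns)
        t1 = table[table["timepoint"] == 1]
        X = t1[idp_cols].copy()
        groups = np.array([F.GROUP_OF_MODALITY[F.modality_of(c)]
                           for c in idp_cols])
        filled = pd.DataFrame(knn_impute(X.to_numpy(), 1, groups),
                              columns=idp_cols)
        train, held = filled.iloc[:1000], filled.iloc[1000:]
        gp = GroupPCA(0.5).fit(train)
        got = gp.transform(held)
        hand = np.hstack([
            ((held[gp.groups_[g]].to_numpy() - gp.models_[g].mean)
             / gp.models_[g].scale) @ gp.models_[g].loadings.T
            for g in gp.groups_])
        assert np.allclose(got, hand)
        assert got.shape[1] == sum(gp.n_components_.values())

    def test_transform_requires_fitted_columns(self, small_cohort):
        _, table, _ = small_cohort
        idp_cols = F.idp_columns(table.columns)
        t1 = table[table["timepoint"] == 1]
        groups = np.array([F.GROUP_OF_MODALITY[F.modality_of(c)]
                           for c in idp_cols])
        filled = pd.DataFrame(knn_impute(t1[idp_cols].to_numpy(), 1, groups),
                              columns=idp_cols)
        gp = GroupPCA(0.5).fit(filled)
        with pytest.raises(ValueError):
            gp.transform(filled.drop(columns=idp_cols[:3]))
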