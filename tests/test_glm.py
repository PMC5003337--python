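import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind

from tfspm import glm


def factorial_obs(n_per_cell, participants=1, hemis=("left", "right"),
                  types=("eyes", "mosaic"), dirs=("averted", "straight")):
    """Balanced factorial observation table; one trial = one (type, dir)
    occurrence contributing one row per hemisphere."""
    rows, tid = [], 0
    for p in range(participants):
        for t in types:
            for d in dirs:
                for _ in range(n_per_cell):
                    for h in hemis:
                        rows.append(dict(participant=f"s{p}", trial_id=tid,
                                         stimulus_type=t, direction=d,
                                         hemisphere=h, is_target=False))
                    tid += 1
    return pd.DataFrame(rows)


class TestDesign:
    def test_paper_scale_dimensions(self):
        """42 trials x 4 sequences x 2 hemispheres x 6 participants gives a
        2016 x 8 cell-means design."""
        obs = factorial_obs(2 * 42 // 2, participants=6)
        d = glm.build_design(obs)
        assert d.X.shape == (2016, 8)
        assert (d.cell_counts() == 252).all()
        assert d.blocks.shape == (1008, 2)

    def test_single_condition_errors_on_empty_cells(self):
        obs = factorial_obs(5, types=("eyes",))
        with pytest.raises(glm.DesignError):
            glm.build_design(obs)

    def test_column_sums_are_cell_counts(self):
        obs = factorial_obs(3)
        d = glm.build_design(obs)
        assert np.array_equal(d.X.sum(axis=0), np.bincount(d.cell_of_obs))

    def test_target_rows_are_dropped(self):
        obs = factorial_obs(3)
        tgt = pd.DataFrame([dict(participant="s0", trial_id=999,
                                 stimulus_type="target", direction="none",
                                 hemisphere="left", is_target=True)])
        d = glm.build_design(pd.concat([obs, tgt], ignore_index=True))
        assert d.n_obs == len(obs)


class TestFit:
    def test_contrast_equals_two_sample_t(self):
        rng = np.random.default_rng(0)
        rows = [dict(participant="s0", trial_id=i,
                     stimulus_type="eyes" if i < 30 else "mosaic",
                     direction="averted", hemisphere="left", is_target=False)
                for i in range(60)]
        d = glm.build_design(pd.DataFrame(rows))
        y = rng.standard_normal((60, 5))
        res = glm.contrast_map(
            glm.fit(y, d),
            glm.Contrast(glm.factorial_weights(
                d.cells, {"stimulus_type": ("eyes", "mosaic")}), "type"))
        expected = ttest_ind(y[:30], y[30:], equal_var=True).statistic
        assert np.abs(res.t - expected).max() < 1e-8

    def test_matches_anova_cell_mean_oracle(self):
        """With identity V the T map equals the textbook fixed-effects
        cell-means formula computed independently."""
        rng = np.random.default_rng(1)
        obs = factorial_obs(6, participants=2)
        d = glm.build_design(obs)
        y = rng.standard_normal((d.n_obs, 7))
        c = glm.factorial_weights(d.cells, {"stimulus_type": ("eyes", "mosaic"),
                                            "hemisphere": ("right", "left")})
        res = glm.contrast_map(glm.fit(y, d), glm.Contrast(c, "txh"))
        # oracle: direct formula
        counts = d.cell_counts().astype(float)
        means = np.stack([y[d.cell_of_obs == k].mean(axis=0)
                          for k in range(8)])
        rss = sum(((y[d.cell_of_obs == k] - means[k]) ** 2).sum(axis=0)
                  for k in range(8))
        s2 = rss / (d.n_obs - 8)
        t_ref = (c @ means) / np.sqrt(s2 * (c ** 2 / counts).sum())
        assert np.abs(res.t - t_ref).max() < 1e-8

    def test_all_zero_data_yields_zero_t(self):
        d = glm.build_design(factorial_obs(3))
        f = glm.fit(np.zeros((d.n_obs, 4)), d)
        res = glm.contrast_map(f, glm.Contrast(
            glm.factorial_weights(d.cells, {"stimulus_type": ("eyes", "mosaic")}),
            "type"))
        assert not res.t.any()
        assert res.n_zero_variance == 4

    def test_constant_shift_leaves_contrasts_unchanged(self):
        rng = np.random.default_rng(2)
        d = glm.build_design(factorial_obs(4))
        y = rng.standard_normal((d.n_obs, 3))
        c = glm.factorial_weights(d.cells, {"stimulus_type": ("eyes", "mosaic")})
        t0 = glm.contrast_map(glm.fit(y, d), glm.Contrast(c, "a")).t
        t1 = glm.contrast_map(glm.fit(y + 11.5, d), glm.Contrast(c, "a")).t
        b0 = glm.fit(y, d).betas
        b1 = glm.fit(y + 11.5, d).betas
        assert np.allclose(t0, t1, atol=1e-10)
        assert np.allclose(b1 - b0, 11.5)

    def test_sign_flip_negates_map(self):
        rng = np.random.default_rng(3)
        d = glm.build_design(factorial_obs(4))
        y = rng.standard_normal((d.n_obs, 3))
        c = glm.factorial_weights(d.cells, {"stimulus_type": ("eyes", "mosaic")})
        f = glm.fit(y, d)
        assert np.allclose(glm.contrast_map(f, glm.Contrast(-c, "n")).t,
                           -glm.contrast_map(f, glm.Contrast(c, "p")).t)

    def test_zero_weights_give_zero_map(self):
        d = glm.build_design(factorial_obs(3))
        f = glm.fit(np.random.default_rng(4).standard_normal((d.n_obs, 2)), d)
        assert not glm.contrast_map(f, glm.Contrast(np.zeros(8), "z")).t.any()


class TestNonSphericity:
    def test_identity_component_reduces_to_pooled_ols(self):
        rng = np.random.default_rng(5)
        d = glm.build_design(factorial_obs(30))
        y = rng.standard_normal((d.n_obs, 50)) * 2.0
        ns = glm.estimate_nonsphericity(y, d, glm.identity_component(d))
        X = d.X
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        s2 = ((y - X @ beta) ** 2).sum() / ((d.n_obs - 8) * y.shape[1])
        assert ns.lambdas[0] == pytest.approx(s2, rel=0.02)
        assert ns.df_effective == d.n_obs - 8

    def test_equal_variances_estimated_near_one(self):
        rng = np.random.default_rng(6)
        d = glm.build_design(factorial_obs(100))
        y = rng.standard_normal((d.n_obs, 120))
        ns = glm.estimate_nonsphericity(y, d)
        cv = ns.cell_variances(d)
        ratios = np.array(list(cv.values())) / np.mean(list(cv.values()))
        assert (ratios > 0.8).all() and (ratios < 1.25).all()

    def test_whitening_restores_identity_covariance(self):
        """Whitened residual blocks from heteroscedastic, within-trial
        correlated noise have near-identity covariance."""
        rng = np.random.default_rng(7)
        d = glm.build_design(factorial_obs(150))
        sd = np.where([c[0] == "eyes" for c in d.cells], 2.0, 1.0)
        y = np.empty((d.n_obs, 200))
        for b in d.blocks:
            s1, s2_ = sd[d.cell_of_obs[b[0]]], sd[d.cell_of_obs[b[1]]]
            # one shared dependence term, as in the component model
            cov = np.array([[s1 ** 2, 0.5], [0.5, s2_ ** 2]])
            y[b] = np.linalg.cholesky(cov) @ rng.standard_normal((2, 200))
        ns = glm.estimate_nonsphericity(y, d)
        yw = glm._apply_blocks(ns.Wb, d.blocks, y)
        emp = np.einsum("bsn,btn->st", yw[d.blocks], yw[d.blocks])
        emp /= d.blocks.shape[0] * y.shape[1]
        scale = np.trace(emp) / 2
        assert np.linalg.norm(emp / scale - np.eye(2)) < 0.1

    def test_satterthwaite_df_decreases_with_heterogeneity(self):
        """Effective df of the unwhitened fit is non-increasing as the
        2-cell variance ratio grows."""
        X = np.kron(np.eye(2), np.ones((20, 1)))
        dfs = []
        for ratio in [1.0, 2.0, 4.0, 8.0, 16.0]:
            V = np.diag(np.r_[np.ones(20), np.full(20, ratio)])
            dfs.append(glm.satterthwaite_df(X, V))
        assert all(a >= b - 1e-9 for a, b in zip(dfs, dfs[1:]))
        assert dfs[0] == pytest.approx(38.0)


class TestMask:
    def test_native_resolution_search_region(self):
        times = np.arange(-200.0, 501.0)
        freqs = np.arange(4.0, 301.0)
        m = glm.explicit_mask(times, freqs)
        assert m.shape == (297, 701)
        assert m.sum() == 501 * 297

    def test_full_window_is_identity(self):
        times = np.arange(0.0, 101.0)
        freqs = np.arange(10.0, 21.0)
        m = glm.explicit_mask(times, freqs, (0, 100), (10, 20))
        assert m.all()

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            glm.explicit_mask(np.arange(-200.0, 0.0), np.arange(4.0, 301.0))
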