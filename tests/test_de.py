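import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import revsig as rs
from revsig.containers import EBayesPrior
from revsig.de import (
    DesignSpec,
    bh_adjust,
    contrast_fit,
    ebayes_moderate,
    estimate_prior,
    fit_linear,
    pca_outlier_screen,
    voom_weights,
)
from revsig.norm import log_cpm, tmm_factors

from conftest import make_count_matrix


def bh_oracle(p):
    """Brute-force step-up: adj_i = min over j with p_j >= p_i of m p_j / rank_j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    adj = np.empty(m)
    for i in range(m):
        cands = [min(1.0, m * p[j] / ranks[j]) for j in range(m) if p[j] >= p[i]]
        adj[i] = min(cands)
    return adj


class TestBH:
    def test_hand_case(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == 0.2

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.4, 0.4, 0.4]), 0.4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    def test_matches_step_up_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=30))
    def test_preserves_p_value_ordering(self, p):
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _design_two_group(n_per=4):
    samples = [f"s{j}" for j in range(2 * n_per)]
    y = np.array([1.0] * n_per + [0.0] * n_per)
    return DesignSpec(
        pd.DataFrame({"test": y, "ref": 1 - y}, index=samples),
        {"effect": np.array([1.0, -1.0])},
    )


class TestFitLinear:
    def test_unit_weights_match_ols_oracle(self):
        rng = np.random.default_rng(0)
        design = _design_two_group(4)
        y = pd.DataFrame(rng.normal(size=(30, 8)), columns=design.sample_ids)
        fit = fit_linear(y, None, design)
        X = design.design.to_numpy()
        for g in range(30):
            beta = np.linalg.solve(X.T @ X, X.T @ y.iloc[g].to_numpy())
            assert np.allclose(fit.coef.iloc[g].to_numpy(), beta)

    def test_two_group_effect_is_mean_difference(self):
        design = _design_two_group(3)
        vals = np.array([[1.0, 2.0, 3.0, 10.0, 11.0, 12.0]])
        y = pd.DataFrame(vals, columns=design.sample_ids)
        fit = fit_linear(y, None, design)
        effect, _ = contrast_fit(fit, "effect")
        assert np.isclose(effect.iloc[0], 2.0 - 11.0)

    def test_s2_is_weighted_rss_over_df(self):
        design = _design_two_group(3)
        rng = np.random.default_rng(1)
        y = pd.DataFrame(rng.normal(size=(5, 6)), columns=design.sample_ids)
        w = pd.DataFrame(rng.uniform(0.5, 2.0, size=(5, 6)),
                         index=y.index, columns=y.columns)
        fit = fit_linear(y, w, design)
        X = design.design.to_numpy()
        g = 2
        W = np.diag(w.iloc[g].to_numpy())
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y.iloc[g].to_numpy())
        rss = (w.iloc[g] * (y.iloc[g] - X @ beta) ** 2).sum()
        assert np.isclose(fit.s2.iloc[g], rss / 4)

    def test_rank_deficient_design_names_columns(self):
        samples = ["a", "b", "c", "d"]
        with pytest.raises(ValueError, match="dup"):
            DesignSpec(
                pd.DataFrame({"x": [1.0, 1, 0, 0], "dup": [1.0, 1, 0, 0]},
                             index=samples),
                {},
            )


class TestVoomWeights:
    def _setup(self, counts):
        cm = make_count_matrix(counts)
        nf = tmm_factors(cm)
        lc = log_cpm(cm, nf)
        design = _design_two_group(counts.shape[1] // 2)
        return lc, cm, nf, design

    def test_weights_positive_finite_for_random_input(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(rng.lognormal(4, 1, 100)[:, None], size=(100, 8))
        lc, cm, nf, design = self._setup(counts)
        w = voom_weights(lc, cm, nf, design)
        assert np.all(np.isfinite(w.to_numpy())) and np.all(w.to_numpy() > 0)

    def test_degenerate_constant_genes_floored(self):
        counts = np.full((20, 6), 50)
        lc, cm, nf, design = self._setup(counts)
        w = voom_weights(lc, cm, nf, design)
        assert np.all(np.isfinite(w.to_numpy())) and np.all(w.to_numpy() > 0)

    def test_near_poisson_counts_get_higher_weight_at_higher_abundance(self):
        rng = np.random.default_rng(4)
        mu = rng.lognormal(3, 1.5, 300)
        counts = rng.poisson(mu[:, None], size=(300, 8))
        lc, cm, nf, design = self._setup(counts)
        w = voom_weights(lc, cm, nf, design).mean(axis=1)
        rho = scipy.stats.spearmanr(mu, w).statistic
        assert rho > 0.8


class TestEBayes:
    def test_d0_zero_limit_is_ordinary_t(self):
        rng = np.random.default_rng(5)
        s2 = rng.chisquare(5, 50) / 5
        eff = rng.normal(size=50)
        sd_un = np.full(50, 0.5)
        prior = EBayesPrior(1e-12, 1.0)
        _, t_mod, _ = ebayes_moderate(s2, 5, eff, sd_un, prior)
        t_ord = eff / (sd_un * np.sqrt(s2))
        assert np.allclose(t_mod, t_ord, rtol=1e-9)

    def test_d0_infinite_limit_uses_prior_variance_only(self):
        rng = np.random.default_rng(6)
        s2 = rng.chisquare(5, 50) / 5
        eff = rng.normal(size=50)
        sd_un = np.full(50, 0.5)
        prior = EBayesPrior(np.inf, 0.25)
        _, t_mod, _ = ebayes_moderate(s2, 5, eff, sd_un, prior)
        assert np.allclose(t_mod, eff / (sd_un * 0.5), rtol=1e-12)

    def test_hyperparameter_recovery_from_scaled_f(self):
        rng = np.random.default_rng(7)
        d0, s0_sq, df = 4.0, 0.25, 10
        s2 = s0_sq * scipy.stats.f.rvs(df, d0, size=5000, random_state=rng)
        prior = estimate_prior(s2, df)
        assert abs(prior.d0 - d0) / d0 < 0.2
        assert abs(prior.s0_sq - s0_sq) / s0_sq < 0.1

    def test_matches_limma_ebayes_hyperparameters(self, tmp_path):
        """Cross-check d0/s0^2 against the reference R implementation."""
        import subprocess

        rng = np.random.default_rng(8)
        s2 = 0.5 * scipy.stats.f.rvs(6, 8, size=2000, random_state=rng)
        prior = estimate_prior(s2, 6)
        csv = tmp_path / "s2.csv"
        pd.Series(s2).to_csv(csv, index=False, header=False)
        script = tmp_path / "eb.R"
        script.write_text(
            "suppressMessages(library(limma));"
            f"s2 <- scan('{csv}');"
            "f <- fitFDist(s2, df1=6);"
            "cat(f$df2, f$scale, sep='\\n')"
        )
        out = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        d0_r, s0_r = (float(v) for v in out.stdout.split())
        assert np.isclose(prior.d0, d0_r, rtol=1e-4)
        assert np.isclose(prior.s0_sq, s0_r, rtol=1e-4)


class TestRunContrast:
    def test_swapping_groups_negates_effects(self):
        cm, _ = rs.simulate_counts(rs.SimulationConfig(n_genes=300, n_per_group=4, seed=9))
        fwd = rs.run_contrast(cm, "A").table
        rev = rs.run_contrast(cm, "WT:veh/disease:veh").table
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["t_mod"], -rev["t_mod"])

    def test_deterministic(self):
        cm, _ = rs.simulate_counts(rs.SimulationConfig(n_genes=200, n_per_group=4, seed=10))
        a = rs.run_contrast(cm, "A").table
        b = rs.run_contrast(cm, "A").table
        pd.testing.assert_frame_equal(a, b)

    def test_absent_group_raises(self):
        cm = make_count_matrix(np.ones((30, 4), int) * 20)
        with pytest.raises(ValueError, match="needs samples"):
            rs.run_contrast(cm, "A")

    def test_result_invariants(self, planted_run):
        _, _, de_a, _ = planted_run
        tab = de_a.table
        assert (tab["adj_p"] >= tab["p"] - 1e-15).all()
        nz = tab["log2fc"] != 0
        assert (np.sign(tab.loc[nz, "t_mod"]) == np.sign(tab.loc[nz, "log2fc"])).all()

    def test_planted_genes_rank_high(self, planted_run):
        from sklearn.metrics import roc_auc_score

        _, truth, de_a, _ = planted_run
        tab = de_a.table
        auc = roc_auc_score(tab.index.isin(truth.disease_genes), np.abs(tab["t_mod"]))
        assert auc > 0.70


class TestPCAOutlierScreen:
    def test_identical_samples_none_flagged(self):
        lc = pd.DataFrame(np.ones((50, 6)), columns=[f"s{j}" for j in range(6)])
        assert pca_outlier_screen(lc) == []

    def test_corrupted_sample_flagged(self):
        rng = np.random.default_rng(11)
        lc = pd.DataFrame(rng.normal(size=(200, 20)),
                          columns=[f"s{j}" for j in range(20)])
        lc["s3"] += 20.0  # library-size-corruption-like global shift
        assert pca_outlier_screen(lc, k_sd=3) == ["s3"]

    def test_flags_invariant_to_sample_order(self):
        rng = np.random.default_rng(12)
        lc = pd.DataFrame(rng.normal(size=(100, 8)),
                          columns=[f"s{j}" for j in range(8)])
        lc["s5"] += 9.0
        shuffled = lc[list(rng.permutation(lc.columns))]
        assert pca_outlier_screen(lc) == pca_outlier_screen(shuffled)

    def test_too_few_samples_raises(self):
        lc = pd.DataFrame(np.ones((10, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="4 samples"):
            pca_outlier_screen(lc)
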