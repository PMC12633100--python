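import numpy as np
import pandas as pd
import pytest
from scipy import stats

import xdprescue as xr
from xdprescue.dge import (
    GlmFit,
    bh_fdr,
    call_signature_genes,
    de_table,
    design_matrix,
    estimate_svs,
    fit_glm,
    wald_test,
)


def _cond(n0, n1):
    idx = [f"a{i}" for i in range(n0)] + [f"b{i}" for i in range(n1)]
    return pd.Series([0.0] * n0 + [1.0] * n1, index=idx)


class TestEstimateSvs:
    def test_pure_noise_selects_k0_in_most_seeds(self, rng):
        hits = 0
        for seed in range(10):
            x = pd.DataFrame(
                np.exp(np.random.default_rng(1000 + seed).normal(3, 0.3, (200, 12))),
                columns=[f"s{i}" for i in range(12)],
            )
            cond = _cond(6, 6)
            cond.index = x.columns
            svs = estimate_svs(x, design_matrix(cond), k="auto", n_perm=50, seed=seed)
            hits += svs.shape[1] == 0
        # parallel analysis at the 95th percentile admits ~5% false factors
        assert hits >= 8

    def test_planted_factor_recovered(self, rng):
        n_genes, n_samples = 300, 16
        factor = rng.normal(0, 1, n_samples)
        # make the factor orthogonal to intercept and condition
        cond_vec = np.array([0.0] * 8 + [1.0] * 8)
        for v in (np.ones(n_samples), cond_vec - cond_vec.mean()):
            factor = factor - (factor @ v) / (v @ v) * v
        loadings = rng.normal(0, 0.5, n_genes)
        logx = 3 + rng.normal(0, 0.2, (n_genes, n_samples)) + np.outer(loadings, factor)
        x = pd.DataFrame(np.exp(logx), columns=[f"s{i}" for i in range(n_samples)])
        cond = pd.Series([0.0] * 8 + [1.0] * 8, index=x.columns)
        svs = estimate_svs(x, design_matrix(cond), k="auto", n_perm=50, seed=0)
        assert svs.shape[1] == 1
        r = np.corrcoef(svs["SV1"], factor)[0, 1]
        assert abs(r) > 0.9

    def test_scores_are_mean_centered(self, rng):
        x = pd.DataFrame(np.exp(rng.normal(3, 1, (100, 10))),
                         columns=[f"s{i}" for i in range(10)])
        cond = pd.Series([0.0] * 5 + [1.0] * 5, index=x.columns)
        svs = estimate_svs(x, design_matrix(cond), k=3)
        assert np.allclose(svs.mean(axis=0), 0.0, atol=1e-12)

    def test_k_too_large_is_an_error(self, rng):
        x = pd.DataFrame(np.exp(rng.normal(3, 1, (50, 6))),
                         columns=[f"s{i}" for i in range(6)])
        cond = pd.Series([0.0] * 3 + [1.0] * 3, index=x.columns)
        with pytest.raises(ValueError, match="SV"):
            estimate_svs(x, design_matrix(cond), k=5)


class TestFitGlm:
    def test_exact_interpolation_of_noiseless_groups(self):
        cond = _cond(3, 3)
        # ln(x+1) of 1 and 2 in the two groups, exactly
        x = pd.DataFrame([np.where(cond == 1, np.e**2 - 1, np.e - 1)],
                         columns=cond.index)
        fit = fit_glm(x, design_matrix(cond))
        assert np.isclose(fit.beta.loc[0, "condition"], 1.0)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_intercept_only_gives_mean_and_centered_residuals(self, rng):
        x = pd.DataFrame(rng.integers(1, 100, (5, 8)).astype(float),
                         columns=[f"s{i}" for i in range(8)])
        design = pd.DataFrame({"intercept": 1.0}, index=x.columns)
        fit = fit_glm(x, design)
        logx = np.log1p(x)
        assert np.allclose(fit.beta["intercept"], logx.mean(axis=1))
        assert np.allclose(fit.residuals, logx.sub(logx.mean(axis=1), axis=0))

    def test_rank_deficient_design_names_columns(self):
        cond = _cond(3, 3)
        design = design_matrix(cond)
        design["dup"] = design["condition"]
        x = pd.DataFrame(np.ones((4, 6)), columns=cond.index)
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(x, design)

    def test_confidence_interval_coverage_on_simulated_genes(self, rng):
        # 2,000 replicate genes, 6+6 design, known coefficient: t-based
        # 95% CIs should cover it ~95% of the time.
        n_rep, beta_true = 2000, 0.8
        cond = _cond(6, 6)
        logx = rng.normal(2.0, 0.3, (n_rep, 12)) + beta_true * cond.to_numpy()
        x = pd.DataFrame(np.expm1(logx), columns=cond.index)
        fit = fit_glm(x, design_matrix(cond))
        t975 = stats.t.ppf(0.975, fit.df_resid)
        lo = fit.beta["condition"] - t975 * fit.se["condition"]
        hi = fit.beta["condition"] + t975 * fit.se["condition"]
        cover = ((lo <= beta_true) & (beta_true <= hi)).mean()
        assert 0.93 <= cover <= 0.97

    def test_negative_binomial_recovers_strong_effect(self, rng):
        cond = _cond(8, 8)
        mu = np.where(cond == 1, 400.0, 100.0)  # ln(4) effect
        counts = rng.poisson(rng.gamma(20.0, mu / 20.0, (10, 16)))
        x = pd.DataFrame(counts.astype(float), columns=cond.index)
        fit = fit_glm(x, design_matrix(cond), family="negative_binomial")
        # per-gene estimates scatter around ln 4 within a few SEs
        assert np.allclose(fit.beta["condition"], np.log(4), atol=0.5)
        assert abs(fit.beta["condition"].mean() - np.log(4)) < 0.15
        de = wald_test(fit, "condition")
        assert (de["p"] < 0.01).all()


class TestWaldTest:
    def _manual_fit(self, lfc, se, family="negative_binomial", df=None):
        genes = [f"g{i}" for i in range(len(lfc))]
        cols = ["condition"]
        return GlmFit(
            beta=pd.DataFrame({"condition": lfc}, index=genes),
            se=pd.DataFrame({"condition": se}, index=genes),
            residuals=pd.DataFrame(np.zeros((len(lfc), 1)), index=genes),
            design=pd.DataFrame({"condition": [1.0]}),
            family=family,
            df_resid=df,
        )

    def test_normal_reference_tail(self):
        fit = self._manual_fit([1.0, 0.0], [0.5, 0.5])
        de = wald_test(fit, "condition")
        assert np.isclose(de.loc["g0", "z"], 2.0)
        assert np.isclose(de.loc["g0", "p"], 0.0455, atol=5e-4)
        assert np.isclose(de.loc["g1", "p"], 1.0)

    def test_t_reference_with_10_df(self):
        fit = self._manual_fit([1.0], [0.5], family="gaussian_log", df=10)
        de = wald_test(fit, "condition")
        assert np.isclose(de.loc["g0", "p"], 2 * stats.t.sf(2.0, 10), atol=1e-12)
        assert np.isclose(de.loc["g0", "p"], 0.0734, atol=5e-4)

    def test_zero_se_warns_and_reports_missing(self):
        fit = self._manual_fit([1.0], [0.0])
        with pytest.warns(UserWarning, match="SE=0"):
            de = wald_test(fit, "condition")
        assert np.isnan(de.loc["g0", "p"])

    def test_unknown_variable_is_an_error(self):
        fit = self._manual_fit([1.0], [0.5])
        with pytest.raises(KeyError):
            wald_test(fit, "nope")


def brute_force_bh(p):
    """Step-up definition applied literally."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestBhFdr:
    def test_manual_step_up_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_tied_pvalues(self):
        assert np.allclose(bh_fdr([0.2]), [0.2])
        assert np.allclose(bh_fdr([0.07, 0.07, 0.07]), [0.07] * 3)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), brute_force_bh(list(p)), atol=1e-12)

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestSignatureCalling:
    def _de(self, q, lfc):
        return pd.DataFrame({"q": q, "lfc": lfc,
                             "p": q, "se": 1.0, "z": 0.0},
                            index=[f"g{i}" for i in range(len(q))])

    def test_threshold_application_and_direction(self):
        sig = call_signature_genes(self._de([0.05, 0.15, 0.09], [1.0, 1.0, -2.0]), 0.10)
        assert list(sig.genes) == ["g0", "g2"]
        assert sig.direction("g0") == "up" and sig.direction("g2") == "down"

    def test_zero_threshold_gives_empty_set(self):
        sig = call_signature_genes(self._de([0.0001], [1.0]), 0.0)
        assert len(sig.genes) == 0


class TestPooling:
    def test_naive_and_unedited_groups_share_expression_profile(self):
        # the two disease subgroups are generated identically: their
        # per-gene mean log expression should be nearly identical.
        cfg = xr.SimulationConfig(
            n_genes=800, treatments=(),
            group_sizes={("CON", "none"): 8, ("XDP", "naive"): 20,
                         ("XDP", "unedited"): 20},
            seed=7,
        )
        counts, sheet, _ = xr.simulate_experiment(cfg)
        meta = sheet.set_index("sample_id")
        naive = counts.loc[:, meta["edit_status"] == "naive"]
        unedited = counts.loc[:, meta["edit_status"] == "unedited"]
        r = np.corrcoef(np.log1p(naive).mean(axis=1),
                        np.log1p(unedited).mean(axis=1))[0, 1]
        assert r > 0.99
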