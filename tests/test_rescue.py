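import math

import numpy as np
import pandas as pd
import pytest

import xdprescue as xr
from xdprescue.dge import SignatureGeneSet, design_matrix, estimate_svs, fit_glm
from xdprescue.rescue import (
    AdjustedCounts,
    PairedEffect,
    SamplePair,
    adjusted_counts,
    call_rescued,
    geneset_enrichment,
    overlap_enrichment,
    paired_effects,
    reversal,
)


def _gaussian_fit(x, design):
    return fit_glm(x, design, family="gaussian_log")


class TestAdjustedCounts:
    def _setup(self, rng, n_genes=50, n=12):
        cond = pd.Series([0.0] * (n // 2) + [1.0] * (n // 2),
                         index=[f"s{i}" for i in range(n)])
        x = pd.DataFrame(np.exp(rng.normal(3, 0.5, (n_genes, n))), columns=cond.index)
        svs = pd.DataFrame({"SV1": rng.normal(0, 1, n) - 0.0}, index=cond.index)
        svs -= svs.mean()
        return x, design_matrix(cond, svs=svs)

    def test_keeping_all_variables_returns_observed(self, rng):
        x, design = self._setup(rng)
        fit = _gaussian_fit(x, design)
        adj = adjusted_counts(fit, list(design.columns))
        assert np.allclose(adj.y, np.log1p(x), atol=1e-10)

    def test_null_adjustment_when_sv_coefficients_are_zero(self, rng):
        x, design = self._setup(rng)
        fit = _gaussian_fit(x, design)
        fit.beta["SV1"] = 0.0  # force null SV contribution
        adj = adjusted_counts(fit, ["intercept", "condition"])
        full = adjusted_counts(fit, ["intercept", "condition", "SV1"])
        assert np.allclose(adj.y, full.y, atol=1e-12)

    def test_dropping_svs_restores_confounder_free_signal(self, rng):
        # plant a strong confounder; adjusted counts without it should
        # track the confounder-free log means
        n_genes, n = 200, 20
        cond = pd.Series([0.0] * 10 + [1.0] * 10, index=[f"s{i}" for i in range(n)])
        clean = rng.normal(3, 1.0, (n_genes, 1)) + 0.5 * cond.to_numpy()
        factor = rng.normal(0, 1, n)
        loadings = rng.normal(0, 0.8, n_genes)
        logx = clean + np.outer(loadings, factor) + rng.normal(0, 0.05, (n_genes, n))
        x = pd.DataFrame(np.expm1(logx), columns=cond.index)
        svs = estimate_svs(x, design_matrix(cond), k=1)
        fit = _gaussian_fit(x, design_matrix(cond, svs=svs))
        adj = adjusted_counts(fit, ["intercept", "condition"])
        r = np.corrcoef(adj.y.to_numpy().ravel(),
                        np.broadcast_to(clean, (n_genes, n)).ravel())[0, 1]
        assert r > 0.95

    def test_unknown_keep_var_is_an_error(self, rng):
        x, design = self._setup(rng)
        fit = _gaussian_fit(x, design)
        with pytest.raises(ValueError, match="keep_vars"):
            adjusted_counts(fit, ["intercept", "nope"])


def _adj(y: pd.DataFrame) -> AdjustedCounts:
    return AdjustedCounts(y=y, treatment="T", keep_vars=("intercept", "condition"))


class TestPairedEffects:
    def test_identical_pairs_give_zero_with_ci_spanning_zero(self):
        y = pd.DataFrame({"t1": [1.0], "u1": [1.0], "t2": [1.3], "u2": [1.3]})
        pairs = [SamplePair("T", "t1", "u1", "c1"), SamplePair("T", "t2", "u2", "c2")]
        eff = paired_effects(_adj(y), pairs)
        assert eff.mean.iloc[0] == 0.0
        assert eff.ci_low.iloc[0] <= 0.0 <= eff.ci_high.iloc[0]

    def test_log_ratio_definition(self):
        y = pd.DataFrame({"t": [math.log(8)], "u": [math.log(4)]})
        eff = paired_effects(_adj(y), [SamplePair("T", "t", "u", "c")])
        assert np.isclose(eff.mean.iloc[0], math.log(2))
        assert np.isnan(eff.ci_low.iloc[0])  # single pair: no interval

    def test_hand_computed_t_interval(self):
        # D = {0.5, 0.7, 0.9}: mean 0.7, sd 0.2, t(0.975, 2) = 4.3027
        y = pd.DataFrame({"t1": [0.5], "u1": [0.0], "t2": [0.7], "u2": [0.0],
                          "t3": [0.9], "u3": [0.0]})
        pairs = [SamplePair("T", f"t{i}", f"u{i}", f"c{i}") for i in (1, 2, 3)]
        eff = paired_effects(_adj(y), pairs)
        assert np.isclose(eff.mean.iloc[0], 0.7)
        assert np.isclose(eff.ci_low.iloc[0], 0.203, atol=5e-4)
        assert np.isclose(eff.ci_high.iloc[0], 1.197, atol=5e-4)

    def test_missing_pair_sample_is_an_error(self):
        y = pd.DataFrame({"t": [1.0]})
        with pytest.raises(ValueError, match="absent"):
            paired_effects(_adj(y), [SamplePair("T", "t", "ghost", "c")])


def _signature(genes, lfc):
    table = pd.DataFrame({
        "lfc": lfc, "q": 0.01,
        "direction": ["up" if v > 0 else "down" for v in lfc],
    }, index=pd.Index(genes, name="gene"))
    return SignatureGeneSet(table=table)


class TestCallRescued:
    def test_inside_acceptance_region_is_rescued(self):
        sig = _signature(["g1"], [-1.2])
        tvc = pd.DataFrame({"lfc": [0.02], "se": [0.15], "z": [0.133], "p": [0.89]},
                           index=["g1"])
        out = call_rescued(sig, tvc)
        assert bool(out.loc["g1", "rescued"]) is True

    def test_non_signature_genes_are_not_evaluated(self):
        sig = _signature(["g1"], [1.0])
        tvc = pd.DataFrame({"lfc": [0.0, 0.0], "se": [1, 1], "z": [0, 0],
                            "p": [0.9, 0.9]}, index=["g1", "g2"])
        out = call_rescued(sig, tvc)
        assert list(out.index) == ["g1"]  # g2 is not a signature gene

    def test_missing_gene_is_unevaluable(self):
        sig = _signature(["g1", "g2"], [1.0, -1.0])
        tvc = pd.DataFrame({"lfc": [0.0], "se": [1.0], "z": [0.0], "p": [0.9]},
                           index=["g1"])
        out = call_rescued(sig, tvc)
        assert not out.loc["g2", "evaluable"]
        assert pd.isna(out.loc["g2", "rescued"])

    def test_significant_shift_is_not_rescued(self):
        sig = _signature(["g1"], [-1.2])
        tvc = pd.DataFrame({"lfc": [1.0], "se": [0.1], "z": [10.0], "p": [1e-8]},
                           index=["g1"])
        assert bool(call_rescued(sig, tvc).loc["g1", "rescued"]) is False


class TestReversal:
    def _inputs(self, xdp_lfc, d_mean, rescued):
        genes = [f"g{i}" for i in range(len(xdp_lfc))]
        sig = _signature(genes, xdp_lfc)
        eff = PairedEffect(
            treatment="T",
            d=pd.DataFrame(index=genes),
            mean=pd.Series(d_mean, index=genes),
            ci_low=pd.Series(np.nan, index=genes),
            ci_high=pd.Series(np.nan, index=genes),
            n_pairs=3,
        )
        resc = pd.DataFrame({"rescued": pd.array(rescued, dtype="boolean")},
                            index=genes)
        return sig, eff, resc

    def test_opposite_sign_is_reversed_same_sign_is_not(self):
        sig, eff, resc = self._inputs([-1.2, -1.2], [0.4, -0.1], [True, True])
        flags, summary = reversal(sig, eff, resc)
        assert bool(flags["g0"]) is True and bool(flags["g1"]) is False
        assert summary == {"rescued": 2, "reversed": 1, "indeterminate": 0,
                           "fraction": 0.5}

    def test_headline_fraction_arithmetic(self):
        # 456 rescued genes of which 424 flip sign: fraction 0.930
        n = 456
        lfc = [-1.0] * n
        d = [0.5] * 424 + [-0.5] * 32
        sig, eff, resc = self._inputs(lfc, d, [True] * n)
        _, summary = reversal(sig, eff, resc)
        assert summary["reversed"] == 424
        assert np.isclose(summary["fraction"], 0.930, atol=5e-4)

    def test_zero_effect_is_indeterminate_and_excluded(self):
        sig, eff, resc = self._inputs([-1.0, -1.0], [0.0, 0.3], [True, True])
        flags, summary = reversal(sig, eff, resc)
        assert pd.isna(flags["g0"])
        assert summary["indeterminate"] == 1
        assert summary["fraction"] == 1.0  # only g1 counted


def enumerate_fisher_greater(table) -> float:
    """Exhaustive enumeration of all 2x2 tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p = 0.0
    for x in range(a, hi + 1):
        p += math.comb(r1, x) * math.comb(r2, c1 - x) / denom
    assert lo <= a <= hi
    return p


class TestOverlapEnrichment:
    def test_hand_enumerated_hypergeometric(self):
        # N=10, |a|=4, |b|=5, overlap 4: p = C(4,4) C(6,1) / C(10,5) = 6/252
        universe = [f"g{i}" for i in range(10)]
        a = universe[:4]
        b = universe[:4] + [universe[5]]
        res = overlap_enrichment(a, b, universe)
        assert np.isclose(res.p, 6 / 252, atol=1e-12)
        assert res.table[0][0] == 4

    def test_overlap_fraction_reporting(self):
        universe = [f"g{i}" for i in range(1000)]
        a = universe[:456]
        b = universe[:197] + universe[600:800]
        res = overlap_enrichment(a, b, universe)
        assert np.isclose(res.overlap_fraction, 197 / 456, atol=1e-12)
        assert round(res.overlap_fraction, 2) == 0.43

    def test_degenerate_full_overlap_has_p_one(self):
        u = ["a", "b", "c"]
        assert overlap_enrichment(u, u, u).p == 1.0

    def test_sets_outside_universe_are_an_error(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_enrichment(["x"], ["a"], ["a", "b"])

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        from xdprescue.rescue import _fisher_greater

        for _ in range(200):
            cells = rng.integers(0, 8, 4)
            table = ((int(cells[0]), int(cells[1])),
                     (int(cells[2]), int(cells[3])))
            if sum(cells) == 0:
                continue
            _, p = _fisher_greater(table)
            assert np.isclose(p, enumerate_fisher_greater(table), atol=1e-10)


class TestGenesetEnrichment:
    def test_hand_enumerated_term(self):
        # universe 20, hits 5, term 4, overlap 3:
        # p = (C(4,3) C(16,2) + C(4,4) C(16,1)) / C(20,5) = (4*120+16)/15504
        universe = [f"g{i}" for i in range(20)]
        hits = universe[:5]
        term = universe[:3] + [universe[10]]
        out = geneset_enrichment(hits, {"T": term}, universe, correction="bh")
        assert np.isclose(out.loc["T", "p"], (4 * 120 + 16) / 15504, atol=1e-12)

    def test_disjoint_term_is_not_enriched(self):
        universe = [f"g{i}" for i in range(30)]
        out = geneset_enrichment(universe[:5], {"T": universe[20:25]}, universe)
        assert np.isclose(out.loc["T", "p"], 1.0, atol=1e-9)

    def test_bonferroni_multiplies_and_caps(self):
        universe = [f"g{i}" for i in range(30)]
        terms = {f"T{j}": universe[5 * j:5 * j + 5] for j in range(4)}
        out = geneset_enrichment(universe[:5], terms, universe,
                                 correction="bonferroni")
        assert np.allclose(out["p_adjusted"],
                           np.minimum(out["p"] * len(out), 1.0))

    def test_empty_term_after_intersection_is_skipped(self):
        universe = ["a", "b"]
        out = geneset_enrichment(["a"], {"T": ["zzz"], "K": ["a", "b"]}, universe)
        assert list(out.index) == ["K"]
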