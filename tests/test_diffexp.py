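import numpy as np
import pandas as pd
import pytest
from scipy import stats

from softspot import diffexp as dx
from softspot.simcounts import CountSimConfig, simulate_counts

from oracles import hypergeom_tail_oracle


def null_counts(n_genes=2000, seed=0, **kw):
    cfg = CountSimConfig(n_genes=n_genes, frac_up=0, frac_down=0,
                         frac_paired_up=0, frac_paired_down=0, effect_lfc=0,
                         paired_effect_lfc=0, mislabeled_controls=0,
                         seed=seed, **kw)
    return simulate_counts(cfg)


def groups_of(cm):
    return cm.sample_meta.set_index("sample_id")["group"].loc[cm.counts.columns]


class TestRpkm:
    def test_formula_forced_examples(self):
        out = dx.rpkm(pd.DataFrame([[10], [0]]), [2000, 500], [1_000_000])
        assert out.iloc[0, 0] == pytest.approx(5.0)
        assert out.iloc[1, 0] == 0.0

    def test_random_matrix_matches_loop_recompute(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (5, 3)))
        lengths = rng.integers(200, 5000, 5)
        libs = rng.integers(int(1e6), int(2e7), 3)
        got = dx.rpkm(counts, lengths, libs)
        for i in range(5):
            for j in range(3):
                want = counts.iloc[i, j] / (lengths[i] / 1e3) / (libs[j] / 1e6)
                assert got.iloc[i, j] == pytest.approx(want)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            dx.rpkm(pd.DataFrame([[1]]), [0], [1e6])
        with pytest.raises(ValueError):
            dx.rpkm(pd.DataFrame([[1]]), [100], [0])


class TestFilterExpressed:
    def matrix(self, mean_a, mean_b):
        cols = ["a1", "a2", "b1", "b2"]
        m = pd.DataFrame([[mean_a, mean_a, mean_b, mean_b]], columns=cols,
                         index=["g"])
        return m, pd.Series(["RS-F", "RS-F", "C-F", "C-F"], index=cols)

    @pytest.mark.parametrize("ma,mb,kept", [
        (1.2, 0.3, True),   # first group passes
        (0.9, 0.9, False),  # neither passes
        (1.0, 1.0, False),  # boundary: strict inequality
        (0.0, 5.0, True),   # second group passes
    ])
    def test_threshold_rule(self, ma, mb, kept):
        m, g = self.matrix(ma, mb)
        assert ("g" in dx.filter_expressed(m, g)) is kept

    def test_empty_group_rejected(self):
        m, g = self.matrix(1, 1)
        with pytest.raises(ValueError):
            dx.filter_expressed(m, g, compare=("RS-F", "RS-NF"))


class TestUnpaired:
    def test_identical_counts_give_zero_fold_change(self):
        cm, _ = null_counts(n_genes=50, seed=1)
        counts = cm.counts.copy()
        counts.iloc[0] = 77  # identical in every sample
        libs = pd.Series(1e6, index=counts.columns)  # equal depth
        tab = dx.de_unpaired(counts, groups_of(cm), library_sizes=libs)
        assert tab["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_gene_convention(self):
        cm, _ = null_counts(n_genes=50, seed=2)
        counts = cm.counts.copy()
        counts.iloc[3] = 0
        tab = dx.de_unpaired(counts, groups_of(cm))
        assert tab["pvalue"].iloc[3] == 1.0 and tab["log2fc"].iloc[3] == 0.0

    def test_null_type_one_error_controlled(self):
        cm, _ = null_counts(n_genes=4000, seed=3)
        tab = dx.de_unpaired(cm.counts, groups_of(cm))
        assert 0.025 <= (tab["pvalue"] < 0.05).mean() <= 0.075

    def test_planted_effects_recovered_with_high_power(self):
        """|log2FC|=2 in all RS fruits, 10 vs 10: nearly every planted gene
        is detected at P < 0.05."""
        cfg = CountSimConfig(n_genes=2000, responder_fraction=1.0,
                             mislabeled_controls=0, seed=4)
        cm, truth = simulate_counts(cfg)
        tab = dx.de_unpaired(cm.counts, groups_of(cm))
        planted = sorted(set(truth.degs_i_up) | set(truth.degs_i_down))
        assert (tab.loc[planted, "pvalue"] < 0.05).mean() >= 0.9

    def test_swapping_groups_flips_all_signs(self):
        cm, _ = null_counts(n_genes=100, seed=5)
        g = groups_of(cm)
        t1 = dx.de_unpaired(cm.counts, g, numerator="RS-F", denominator="C-F")
        t2 = dx.de_unpaired(cm.counts, g, numerator="C-F", denominator="RS-F")
        assert t1["log2fc"].to_numpy() == pytest.approx(
            -t2["log2fc"].to_numpy(), abs=1e-5)

    def test_direction_consistent_with_sign(self):
        cm, _ = simulate_counts(CountSimConfig(n_genes=500, seed=6))
        tab = dx.de_unpaired(cm.counts, groups_of(cm))
        up = tab["direction"] == "up"
        assert (tab.loc[up, "log2fc"] > 0).all()
        assert (tab.loc[tab["direction"] == "down", "log2fc"] < 0).all()

    def test_matches_statsmodels_nb_glm_fit(self):
        """Dual route: the vectorised IRLS coefficients equal per-gene
        statsmodels NB GLM fits at the same fixed dispersion."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        S, G = 12, 15
        X = np.column_stack([np.ones(S), np.repeat([0.0, 1.0], S // 2)])
        offset = np.log(rng.uniform(1e6, 2e6, S))
        alpha = rng.uniform(0.05, 0.5, G)
        mu = np.exp(offset[None, :] - 12 + rng.normal(0, 1, (G, 1))
                    + 0.7 * X[:, 1][None, :])
        y = rng.negative_binomial(1 / alpha[:, None],
                                  1 / (1 + alpha[:, None] * mu)).astype(float)
        beta, _ = dx._irls_nb(y, X, offset, alpha)
        for g in range(G):
            fit = sm.GLM(y[g], X,
                         family=sm.families.NegativeBinomial(alpha=alpha[g]),
                         offset=offset).fit()
            assert beta[g] == pytest.approx(fit.params, rel=1e-4, abs=1e-5)

    def test_too_few_samples_rejected(self):
        cm, _ = null_counts(n_genes=20, seed=8)
        g = groups_of(cm)
        cols = list(g.index[g == "RS-F"][:1]) + list(g.index[g == "C-F"])
        with pytest.raises(ValueError):
            dx.de_unpaired(cm.counts[cols], g[cols])


class TestPaired:
    def test_identical_pairs_give_no_discoveries(self):
        cm, _ = null_counts(n_genes=300, seed=10)
        meta = cm.sample_meta.copy()
        counts = cm.counts.copy()
        # make each RS-NF column an exact copy of its RS-F partner
        m = meta.set_index("sample_id")
        for f in m.loc[m.group == "RS-NF", "fruit_id"]:
            sf = m.index[(m.fruit_id == f) & (m.group == "RS-F")][0]
            sn = m.index[(m.fruit_id == f) & (m.group == "RS-NF")][0]
            counts[sn] = counts[sf]
        tab = dx.de_paired(counts, meta)
        assert (tab["fdr"] < 0.1).sum() == 0

    def test_null_pvalues_near_uniform(self):
        """Null p-value distribution is close to uniform: small KS distance
        and a calibrated lower tail (the part that matters for testing)."""
        cm, _ = null_counts(n_genes=4000, seed=11)
        tab = dx.de_paired(cm.counts, cm.sample_meta)
        ks_d, _ = stats.kstest(tab["pvalue"], "uniform")
        assert ks_d < 0.05
        assert 0.025 <= (tab["pvalue"] < 0.05).mean() <= 0.075

    def test_paired_beats_unpaired_under_strong_fruit_effects(self):
        cfg = CountSimConfig(n_genes=1500, fruit_random_effect_sd=1.0, seed=12)
        cm, truth = simulate_counts(cfg)
        planted = sorted(set(truth.degs_ii_up) | set(truth.degs_ii_down))
        tab_p = dx.de_paired(cm.counts, cm.sample_meta)
        tab_u = dx.de_unpaired(cm.counts, groups_of(cm),
                               numerator="RS-F", denominator="RS-NF")
        power_p = (tab_p.loc[planted, "pvalue"] < 0.05).mean()
        power_u = (tab_u.loc[planted, "pvalue"] < 0.05).mean()
        assert power_p > power_u

    def test_incomplete_pairs_rejected(self):
        cm, _ = null_counts(n_genes=20, seed=13)
        meta = cm.sample_meta.copy()
        m = meta.set_index("sample_id")
        nf = m.index[m.group == "RS-NF"]
        counts = cm.counts.drop(columns=nf[:2])
        meta2 = meta[~meta.sample_id.isin(nf[:2])]
        with pytest.raises(ValueError, match="3 complete"):
            dx.de_paired(counts, meta2)


class TestOverlapConcordance:
    def table(self, genes, lfc, p, fdr):
        return pd.DataFrame({"gene": genes, "log2fc": lfc, "pvalue": p,
                             "fdr": fdr,
                             "direction": np.where(np.asarray(lfc) > 0, "up", "down"),
                             }).set_index("gene")

    def test_disjoint_sets_give_zero_overlap(self):
        t1 = self.table(["a", "b"], [2, -2], [0.01, 0.01], [0.5, 0.5])
        t2 = self.table(["a", "b"], [2, -2], [0.9, 0.9], [0.9, 0.9])
        up, down, _ = dx.overlap_and_concordance(t1, t2)
        assert (up, down) == (0, 0)

    def test_self_comparison_counts_and_unit_correlation(self):
        rng = np.random.default_rng(0)
        n = 40
        lfc = rng.normal(0, 2, n)
        p = rng.random(n) * 0.2
        t = self.table([f"g{i}" for i in range(n)], lfc, p, p)
        up, down, r = dx.overlap_and_concordance(t, t)
        sig = p < 0.05
        assert up == ((lfc > 0) & sig & (p < 0.1)).sum()
        assert down == ((lfc < 0) & sig & (p < 0.1)).sum()
        assert r == pytest.approx(1.0)

    def test_hand_built_ten_gene_instance(self):
        genes = [f"g{i}" for i in range(10)]
        t1 = self.table(genes, [2, 2, -2, -2, 2, -2, 1, -1, 2, -2],
                        [.01, .01, .01, .2, .01, .01, .2, .2, .01, .01],
                        [.5] * 10)
        t2 = self.table(genes, [2, -2, -2, -2, 2, -2, 2, -2, 1, -1],
                        [.5] * 10,
                        [.05, .05, .05, .05, .2, .05, .05, .05, .2, .05])
        up, down, _ = dx.overlap_and_concordance(t1, t2)
        # up overlap: sig_i & sig_ii & up in both -> g0, g4 is fdr .2 -> only g0
        # down overlap: g2, g5, g9
        assert (up, down) == (1, 3)


class TestPca:
    def test_rank_one_matrix_loads_on_first_component(self):
        u = np.linspace(1, 3, 30)[:, None]
        v = np.linspace(0.1, 2, 8)[None, :]
        m = pd.DataFrame(2 ** (u * v) - 1)
        groups = ["RS-F"] * 4 + ["C-F"] * 4
        var_frac, scores, tests = dx.pca_expression(m, groups)
        assert var_frac[0] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(var_frac.sum(), 1.0)

    def test_variance_fractions_sum_to_one(self):
        cm, _ = null_counts(n_genes=300, seed=20)
        rp = dx.rpkm(cm.counts, cm.gene_lengths, cm.counts.sum(axis=0))
        var_frac, scores, tests = dx.pca_expression(rp, groups_of(cm))
        assert var_frac.sum() == pytest.approx(1.0)
        assert {"pc", "pvalue"} <= set(tests.columns)
        assert scores.shape[0] == cm.counts.shape[1]

    def test_constant_matrix_rejected(self):
        m = pd.DataFrame(np.zeros((10, 4)))
        with pytest.raises(ValueError):
            dx.pca_expression(m, ["a", "a", "b", "b"])


class TestEnrichment:
    def test_saturated_deg_set_has_unit_pvalues(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {"s1": universe[:5], "s2": universe[5:9]}
        out = dx.enrichment_hypergeometric(universe, sets, universe)
        assert (out["pvalue"] == 1.0).all()
        assert (out["overlap"] == out["set_size"]).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_combinatorial_sum(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(25)]
        members = list(rng.choice(universe, 7, replace=False))
        degs = list(rng.choice(universe, 9, replace=False))
        out = dx.enrichment_hypergeometric(degs, {"s": members}, universe)
        k = len(set(degs) & set(members))
        want = hypergeom_tail_oracle(k, 25, 7, 9)
        assert out["pvalue"].iloc[0] == pytest.approx(want, rel=1e-10)

    def test_planted_set_ranks_first(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(500)]
        planted = universe[:40]
        degs = planted[:30] + list(rng.choice(universe[40:], 10, replace=False))
        sets = {"planted": planted}
        for k in range(6):
            sets[f"rand{k}"] = list(rng.choice(universe, 40, replace=False))
        out = dx.enrichment_hypergeometric(degs, sets, universe)
        assert out["gene_set"].iloc[0] == "planted"

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            dx.enrichment_hypergeometric([], {"s": []}, [])


class TestMultipleTesting:
    def test_bh_adjusted_values_monotone_in_p_rank(self):
        cm, _ = null_counts(n_genes=500, seed=30)
        tab = dx.de_unpaired(cm.counts, groups_of(cm))
        s = tab.sort_values("pvalue")
        assert (np.diff(s["fdr"].to_numpy()) >= -1e-12).all()
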