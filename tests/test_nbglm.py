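"""NB GLM: design construction, fitting, dispersion, Wald/BH testing."""

import numpy as np
import pandas as pd
import pytest

import repliage as r
from repliage.nbglm import ModelError


def model2_spec():
    """Four genotypes, TRP1, three ages, continuous SEP: 8 design columns."""
    return r.ModelSpec([
        r.Variable("Genotype", "categorical", ["wt", "spt3", "rad52", "sac3"], "wt"),
        r.Variable("TRP1", "categorical", ["present", "not_present"], "present"),
        r.Variable("Age", "categorical", ["log", "24h", "48h"], "log"),
        r.Variable("SEP", "continuous"),
    ])


def model1_spec():
    """ERC abundance (high/low) instead of the SEP covariate: 8 columns."""
    return r.ModelSpec([
        r.Variable("Genotype", "categorical", ["wt", "spt3", "rad52", "sac3"], "wt"),
        r.Variable("TRP1", "categorical", ["absent", "present"], "absent"),
        r.Variable("Age", "categorical", ["log", "24h", "48h"], "log"),
        r.Variable("ERC", "categorical", ["low", "high"], "low"),
    ])


class TestScaleMinmax:
    def test_maps_extremes_to_unit_interval(self):
        assert np.allclose(r.scale_minmax([10, 20, 30]), [0, 0.5, 1])
        assert np.allclose(r.scale_minmax([0, 1]), [0, 1])

    def test_constant_vector_rejected(self):
        with pytest.raises(ModelError, match="constant"):
            r.scale_minmax([5, 5, 5])


class TestBuildDesign:
    @staticmethod
    def _cohort12():
        # TRP1 varies within every genotype so nothing is confounded
        rows = []
        trp1_plan = {"wt": ["present", "not_present", "present"],
                     "spt3": ["not_present", "present", "not_present"],
                     "rad52": ["present", "present", "not_present"],
                     "sac3": ["not_present", "not_present", "present"]}
        rng = np.random.default_rng(0)
        for geno, trp1s in trp1_plan.items():
            for age, trp1 in zip(["log", "24h", "48h"], trp1s):
                rows.append({"Genotype": geno, "TRP1": trp1, "Age": age,
                             "SEP": round(float(rng.uniform()), 3)})
        return pd.DataFrame(rows)

    def test_sep_model_has_eight_columns(self):
        design = r.build_design(self._cohort12(), model2_spec())
        assert design.shape == (12, 8)
        assert (design["Intercept"] == 1).all()

    def test_erc_model_has_eight_columns(self):
        samples = self._cohort12().drop(columns="SEP")
        samples["TRP1"] = samples["TRP1"].replace(
            {"present": "present", "not_present": "absent"})
        samples["ERC"] = ["low", "high", "high", "low", "low", "high",
                          "high", "low", "low", "low", "high", "low"]
        design = r.build_design(samples, model1_spec())
        assert design.shape == (12, 8)

    def test_single_level_factor_is_rank_deficient(self):
        rows = [{"Genotype": "wt", "TRP1": "present", "Age": a, "SEP": s}
                for a, s in zip(["log", "24h", "48h"] * 2, [0, .2, .4, .6, .8, 1])]
        with pytest.raises(ModelError, match="rank deficient"):
            r.build_design(pd.DataFrame(rows), model2_spec())


class TestFit:
    def test_two_group_coefficient_is_exact_log2_ratio(self):
        # NB group MLE equals the group mean: coefficient = log2(400/100)
        counts = pd.DataFrame([[100, 100, 400, 400]], index=["g"],
                              columns=["a1", "a2", "b1", "b2"])
        samples = pd.DataFrame({"g": ["A", "A", "B", "B"]}, index=counts.columns)
        spec = r.ModelSpec([r.Variable("g", "categorical", ["A", "B"], "A")])
        design = r.build_design(samples, spec)
        fit = r.fit_nbglm(counts, design, pd.Series(1.0, index=counts.columns), 0.1)
        assert np.isclose(fit.coef.loc["g", "g[B]"], 2.0, atol=1e-8)
        assert fit.converged.loc["g"]

    def test_intercept_only_identical_counts(self):
        counts = pd.DataFrame([[64, 64, 64]], index=["g"], columns=list("abc"))
        samples = pd.DataFrame(index=counts.columns)
        design = pd.DataFrame({"Intercept": 1.0}, index=counts.columns)
        fit = r.fit_nbglm(counts, design, pd.Series(1.0, index=counts.columns), 0.05)
        assert np.isclose(fit.coef.loc["g", "Intercept"], 6.0, atol=1e-8)
        assert np.allclose(fit.mu.loc["g"], 64.0)
        del samples

    def test_size_factor_offsets_cancel_library_depth(self):
        counts = pd.DataFrame([[100, 200]], index=["g"], columns=["a", "b"])
        design = pd.DataFrame({"Intercept": 1.0}, index=counts.columns)
        factors = pd.Series([1.0, 2.0], index=counts.columns)
        fit = r.fit_nbglm(counts, design, factors, 0.05)
        # normalised counts are equal, so the intercept is log2(100)
        assert np.isclose(fit.coef.loc["g", "Intercept"], np.log2(100), atol=1e-8)

    def test_additivity_of_linear_predictor(self, default_model):
        # fitted mean = 2^(X beta) * size factor, exactly, per sample
        m = default_model
        idx = m.fit.coef.dropna().index[:50]
        pred_log2 = m.fit.coef.loc[idx] @ m.design.T.values
        mu_expected = (2.0 ** pred_log2) * m.factors.values[None, :]
        assert np.allclose(mu_expected, m.fit.mu.loc[idx].values, rtol=1e-6)


class TestDispersion:
    def test_poisson_counts_give_near_zero_alpha(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(200.0, size=(100, 40)),
                              columns=[f"s{i}" for i in range(40)])
        samples = pd.DataFrame({"g": ["A"] * 20 + ["B"] * 20}, index=counts.columns)
        spec = r.ModelSpec([r.Variable("g", "categorical", ["A", "B"], "A")])
        design = r.build_design(samples, spec)
        disp = r.estimate_dispersion(counts, design, pd.Series(1.0, index=counts.columns))
        assert disp["alpha"].median() <= 0.01

    def test_nb_alpha_recovered(self):
        rng = np.random.default_rng(3)
        a, G, n = 0.1, 200, 50
        mu = np.exp(rng.normal(5, 1, G))[:, None] * np.ones((1, n))
        counts = pd.DataFrame(rng.poisson(rng.gamma(1 / a, a * mu)),
                              columns=[f"s{i}" for i in range(n)])
        samples = pd.DataFrame({"g": ["A"] * 25 + ["B"] * 25}, index=counts.columns)
        spec = r.ModelSpec([r.Variable("g", "categorical", ["A", "B"], "A")])
        design = r.build_design(samples, spec)
        disp = r.estimate_dispersion(counts, design, pd.Series(1.0, index=counts.columns))
        assert 0.05 <= disp["alpha"].median() <= 0.2

    def test_all_zero_gene_flagged_and_excluded(self):
        counts = pd.DataFrame([[0] * 8, [10] * 8], index=["z", "g"],
                              columns=[f"s{i}" for i in range(8)])
        samples = pd.DataFrame({"g": ["A"] * 4 + ["B"] * 4}, index=counts.columns)
        spec = r.ModelSpec([r.Variable("g", "categorical", ["A", "B"], "A")])
        design = r.build_design(samples, spec)
        disp = r.estimate_dispersion(counts, design, pd.Series(1.0, index=counts.columns))
        assert np.isnan(disp.loc["z", "alpha"])
        assert disp.loc["z", "note"] == "all_zero"


class TestWald:
    def _fit_from_pvalues(self, pvalues):
        from scipy.stats import norm as normal
        z = normal.isf(np.asarray(pvalues) / 2)
        idx = [f"g{i}" for i in range(len(z))]
        coef = pd.DataFrame({"b": z}, index=idx)
        se = pd.DataFrame({"b": np.ones(len(z))}, index=idx)
        return r.GLMFit(coef=coef, se=se, mu=pd.DataFrame(index=idx),
                        alpha=pd.Series(0.1, index=idx),
                        converged=pd.Series(True, index=idx),
                        iterations=pd.Series(1, index=idx),
                        design=pd.DataFrame(), size_factors=pd.Series(dtype=float))

    def test_bh_adjustment_matches_hand_computation(self):
        fit = self._fit_from_pvalues([0.01, 0.02, 0.03, 0.04])
        de = r.wald_test(fit, "b")
        assert np.allclose(de["padj"], 0.04)

    def test_lfc_threshold_gates_significance(self):
        idx = ["g0"]
        fit = r.GLMFit(coef=pd.DataFrame({"b": [0.4]}, index=idx),
                       se=pd.DataFrame({"b": [0.05]}, index=idx),
                       mu=pd.DataFrame(index=idx),
                       alpha=pd.Series(0.1, index=idx),
                       converged=pd.Series(True, index=idx),
                       iterations=pd.Series(1, index=idx),
                       design=pd.DataFrame(), size_factors=pd.Series(dtype=float))
        de = r.wald_test(fit, "b", fdr=0.05, lfc_threshold=0.5)
        assert de["padj"].iloc[0] < 0.001       # highly significant...
        assert de["call"].iloc[0] == "ns"        # ...but below the LFC filter

    def test_zero_effect_has_unit_pvalue(self):
        fit = self._fit_from_pvalues([1.0])
        de = r.wald_test(fit, "b")
        assert de["pvalue"].iloc[0] == 1.0 and de["call"].iloc[0] == "ns"


class TestPairwiseDE:
    def _simulate(self, fold, seed=0, alpha=0.01, n=6):
        rng = np.random.default_rng(seed)
        G = 50
        mu = np.exp(rng.normal(5, 0.5, G))
        muA = np.tile(mu[:, None], (1, n))
        muB = muA.copy()
        muB[0] *= fold
        Y = np.concatenate([
            rng.poisson(rng.gamma(1 / alpha, alpha * muA)),
            rng.poisson(rng.gamma(1 / alpha, alpha * muB))], axis=1)
        cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        return pd.DataFrame(Y, columns=cols,
                            index=[f"g{i}" for i in range(G)]), cols[:n], cols[n:]

    def test_identical_groups_yield_no_calls(self):
        counts, ga, gb = self._simulate(fold=1.0)
        de = r.pairwise_de(counts, ga, gb)
        assert (de["call"] == "ns").all()

    def test_four_fold_gene_called_up(self):
        counts, ga, gb = self._simulate(fold=4.0)
        de = r.pairwise_de(counts, ga, gb)
        assert de.loc["g0", "call"] == "up"
        assert abs(de.loc["g0", "log2FC"] - 2.0) < 0.5

    def test_swapping_groups_negates_log2fc(self):
        counts, ga, gb = self._simulate(fold=4.0)
        fwd = r.pairwise_de(counts, ga, gb)
        rev = r.pairwise_de(counts, gb, ga)
        assert np.allclose(fwd["log2FC"], -rev["log2FC"], atol=1e-6)

    def test_empty_group_rejected(self):
        counts, ga, gb = self._simulate(fold=1.0)
        with pytest.raises(ModelError):
            r.pairwise_de(counts, [], gb)
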