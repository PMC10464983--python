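"""Chromosome-arm change, enrichment, ERC proxy and marker regressions."""

import numpy as np
import pandas as pd
import pytest

import repliage.chrom_signal as sig
from repliage.chrom_signal import SignalError


def gene_table(n_arm=5, n_other=5, with_probe=False):
    rows = []
    for i in range(n_arm):
        rows.append({"gene_id": f"arm{i}", "chrom": "XII",
                     "start": 500000 + i * 2000, "end": 501000 + i * 2000,
                     "strand": "+", "biotype": "protein_coding",
                     "is_chrxiir": True})
    for i in range(n_other):
        rows.append({"gene_id": f"oth{i}", "chrom": "I",
                     "start": 1000 + i * 2000, "end": 2000 + i * 2000,
                     "strand": "+", "biotype": "protein_coding",
                     "is_chrxiir": False})
    if with_probe:
        rows.append({"gene_id": "IGS2-1AS", "chrom": "XII", "start": 458433,
                     "end": 459675, "strand": "+",
                     "biotype": "rDNA_intergenic", "is_chrxiir": False})
    return pd.DataFrame(rows)


def norm_matrix(genes, ref_value=100.0, arm_factor=1.0, probe_factor=1.0):
    ids = genes["gene_id"]
    ref = pd.DataFrame({"r1": ref_value, "r2": ref_value}, index=ids)
    test = ref_value * np.where(genes["is_chrxiir"], arm_factor, 1.0)
    test = np.where(genes["biotype"] == "rDNA_intergenic",
                    ref_value * probe_factor, test)
    out = ref.copy()
    out["t1"] = test
    out["t2"] = test
    return out


class TestArmChange:
    def test_no_change_gives_zero_medians(self):
        genes = gene_table()
        norm = norm_matrix(genes)
        _, summary = sig.arm_change(norm, genes, ["r1", "r2"], ["t1", "t2"])
        assert np.allclose(summary["median"], 0.0)

    def test_uniform_dosage_shifts_only_the_arm(self):
        genes = gene_table()
        norm = norm_matrix(genes, arm_factor=1.5)
        _, summary = sig.arm_change(norm, genes, ["r1", "r2"], ["t1", "t2"])
        # log2((151)/(101)) with pseudocount, close to log2 1.5
        assert abs(summary.loc["ChrXIIr", "median"] - np.log2(1.5)) < 0.02
        assert summary.loc["other", "median"] == 0.0

    def test_non_arm_xii_genes_belong_to_neither_group(self):
        genes = gene_table()
        genes.loc[len(genes)] = {"gene_id": "left", "chrom": "XII",
                                 "start": 1000, "end": 2000, "strand": "+",
                                 "biotype": "protein_coding",
                                 "is_chrxiir": False}
        norm = norm_matrix(genes)
        table, _ = sig.arm_change(norm, genes, ["r1", "r2"], ["t1", "t2"])
        assert "left" not in table.index

    def test_empty_group_is_an_error(self):
        genes = gene_table(n_arm=0, n_other=5)
        norm = norm_matrix(genes)
        with pytest.raises(SignalError):
            sig.arm_change(norm, genes, ["r1", "r2"], ["t1", "t2"])


class TestChromosomeEnrichment:
    def _toy(self):
        # 100 genes: chrA 10, chrB 40, chrC 50; 20 DE: 6/4/10
        rows, calls = [], {}
        plan = [("A", 10, 6), ("B", 40, 4), ("C", 50, 10)]
        for chrom, n, n_de in plan:
            for i in range(n):
                gid = f"{chrom}{i}"
                rows.append({"gene_id": gid, "chrom": chrom, "start": 1 + i,
                             "end": 2 + i, "strand": "+",
                             "biotype": "protein_coding", "is_chrxiir": False})
                calls[gid] = "up" if i < n_de else "ns"
        genes = pd.DataFrame(rows)
        de = pd.DataFrame({"call": pd.Series(calls)})
        return genes, de

    def test_hand_computed_observed_expected(self):
        genes, de = self._toy()
        table = sig.chromosome_enrichment(de, genes, split_xii=False)
        assert table.loc["A", "observed"] == 6
        assert np.isclose(table.loc["A", "expected"], 2.0)
        assert np.isclose(table.loc["A", "ratio"], 3.0)

    def test_conservation_of_totals(self):
        genes, de = self._toy()
        table = sig.chromosome_enrichment(de, genes, split_xii=False)
        assert table["observed"].sum() == 20
        assert np.isclose(table["expected"].sum(), 20.0)

    def test_zero_de_genes_reported_as_zero_and_flagged(self):
        genes, de = self._toy()
        de["call"] = "ns"
        table = sig.chromosome_enrichment(de, genes, split_xii=False)
        assert (table["observed"] == 0).all()
        assert (table["ratio"] == 0).all()
        assert table["undefined"].all()

    def test_xii_split_into_left_and_arm(self, default_model):
        m = default_model
        genes = m.dataset.genes
        table = sig.chromosome_enrichment(m.de_sep, genes)
        assert "XIIr" in table.index and "XII-left" in table.index
        assert "XII" not in table.index


class TestErcProxy:
    def test_no_change_is_zero(self):
        genes = gene_table(with_probe=True)
        norm = norm_matrix(genes)
        assert sig.erc_proxy(norm, genes, ["r1", "r2"], ["t1", "t2"]) == 0.0

    def test_eightfold_probe_signal(self):
        genes = gene_table(with_probe=True)
        norm = norm_matrix(genes, probe_factor=8.0)
        value = sig.erc_proxy(norm, genes, ["r1", "r2"], ["t1", "t2"])
        assert abs(value - 3.0) < 0.02

    def test_missing_probe_error_names_it(self):
        genes = gene_table(with_probe=False)
        norm = norm_matrix(genes)
        with pytest.raises(SignalError, match="IGS2-1AS"):
            sig.erc_proxy(norm, genes, ["r1"], ["t1"])


class TestChrxiirAmplification:
    def test_unamplified_sample_near_zero(self):
        genes = gene_table()
        norm = norm_matrix(genes)
        assert sig.chrxiir_amplification(norm, genes, ["r1", "r2"], "t1") == 0.0

    def test_uniform_dosage(self):
        genes = gene_table()
        norm = norm_matrix(genes, arm_factor=1.5)
        value = sig.chrxiir_amplification(norm, genes, ["r1", "r2"], "t1")
        assert abs(value - np.log2(1.5)) < 0.02

    def test_median_follows_the_majority_class(self):
        genes = gene_table(n_arm=5)
        norm = norm_matrix(genes)
        # amplify only 2 of 5 arm genes: median stays at 0
        norm.loc[["arm0", "arm1"], ["t1", "t2"]] *= 4
        value = sig.chrxiir_amplification(norm, genes, ["r1", "r2"], "t1")
        assert value == 0.0


class TestMarkerRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        summary = sig.marker_regression(x, 2 * x + 1)
        assert np.isclose(summary.slope, 2.0)
        assert np.isclose(summary.r_squared, 1.0)

    def test_hand_computed_four_points(self):
        summary = sig.marker_regression([0, 1, 2, 3], [0, 1, 1, 2])
        assert np.isclose(summary.slope, 0.6)
        assert np.isclose(summary.r_squared, 0.9)

    def test_r_squared_equals_pearson_squared(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 0.2, 40)
        summary = sig.marker_regression(x, y)
        assert np.isclose(summary.r_squared, np.corrcoef(x, y)[0, 1] ** 2)

    def test_permuted_response_has_low_r_squared(self):
        rng = np.random.default_rng(9)
        x = np.arange(50.0)
        y = rng.permutation(x)
        assert sig.marker_regression(x, y).r_squared < 0.2

    def test_confidence_band_contains_fit_and_widens_at_edges(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 1, 30)
        y = x + rng.normal(0, 0.1, 30)
        summary = sig.marker_regression(x, y)
        lo, hi = summary.confidence_band(x)
        assert (lo < summary.predict(x)).all() and (summary.predict(x) < hi).all()
        width = hi - lo
        assert width[0] > width[len(x) // 2]

    def test_constant_x_rejected(self):
        with pytest.raises(SignalError, match="constant"):
            sig.marker_regression([1, 1, 1], [1, 2, 3])


class TestCorrelateSignature:
    def test_identical_vectors_give_unit_r_squared(self):
        coefs = pd.Series([0.1, 0.5, -0.4, 1.2], index=list("abcd"))
        summary = sig.correlate_signature(coefs, coefs)
        assert np.isclose(summary.r_squared, 1.0)

    def test_disjoint_identifiers_error(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("xyz"))
        with pytest.raises(SignalError, match="shared genes"):
            sig.correlate_signature(a, b)

    def test_designed_correlation_recovered(self):
        # construct vectors with population R^2 = 0.7: y = x + noise,
        # Var(noise) = Var(x) * (1/0.7 - 1)
        rng = np.random.default_rng(11)
        x = pd.Series(rng.normal(0, 1, 300),
                      index=[f"g{i}" for i in range(300)])
        y = x + rng.normal(0, np.sqrt(1 / 0.7 - 1), 300)
        summary = sig.correlate_signature(x, y)
        assert abs(summary.r_squared - 0.7) <= 0.1

    def test_gene_subset_restriction(self):
        rng = np.random.default_rng(12)
        x = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        summary = sig.correlate_signature(x, x, gene_subset=[f"g{i}" for i in range(5)])
        assert summary.n == 5
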