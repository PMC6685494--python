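"""Proportion tables, clade tests, PCA and SINE-LINE correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tedyn.accumulation import (
    clade_proportion_test,
    pca_species_by_element,
    proportion_table,
    sine_line_correlation,
)
from tedyn.divergence import AgeClass
from conftest import make_hit


def _random_hits(rng, species, n=1000):
    hits = {sp: [] for sp in species}
    for _ in range(n):
        sp = species[int(rng.integers(0, len(species)))]
        fam = int(rng.integers(0, 8))
        hits[sp].append(make_hit(
            species=sp,
            family=f"Fam{fam}",
            cls=["SINE", "LINE", "LTR", "DNA"][fam % 4],
            divergence=float(rng.uniform(0, 0.3)),
            length=int(rng.integers(100, 2000))))
    return hits


class TestProportionTable:
    def test_simple_arithmetic(self):
        hits = {"sp1": [make_hit(length=300, divergence=0.01),
                        make_hit(length=200, divergence=0.02)]}
        t = proportion_table(hits, {"sp1": 1_000_000}, group_by="class",
                             stratum="recent")
        assert t.loc["sp1", "SINE"] == pytest.approx(5e-4)

    def test_recent_plus_old_equals_all(self, rng):
        species = ["sp1", "sp2", "sp3"]
        hits = _random_hits(rng, species)
        genomes = {sp: 5_000_000 for sp in species}
        for group_by in ("class", "family"):
            tables = {s: proportion_table(hits, genomes, group_by, s)
                      for s in ("recent", "old", "all")}
            total = tables["recent"] + tables["old"]
            assert np.allclose(total.values, tables["all"].values, atol=1e-12)

    def test_class_cells_equal_family_sums(self, rng):
        hits = _random_hits(rng, ["sp1", "sp2"])
        genomes = {"sp1": 5_000_000, "sp2": 5_000_000}
        by_class = proportion_table(hits, genomes, "class", "all")
        by_family = proportion_table(hits, genomes, "family", "all")
        fam_class = {h.family_name: h.class_label
                     for sp_hits in hits.values() for h in sp_hits}
        for cls in by_class.columns:
            fams = [f for f, c in fam_class.items() if c == cls]
            assert np.allclose(by_class[cls].values,
                               by_family[fams].sum(axis=1).values, atol=1e-12)

    def test_species_without_hits_gets_zero_row(self):
        hits = {"sp1": [make_hit()], "sp2": []}
        t = proportion_table(hits, {"sp1": 1000, "sp2": 1000})
        assert (t.loc["sp2"] == 0).all()

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="genome size"):
            proportion_table({"sp1": [make_hit()]}, {"other": 1000})

    def test_unknown_class_excluded_from_class_table(self):
        hits = {"sp1": [make_hit(cls="Unknown"), make_hit(cls="SINE")]}
        t = proportion_table(hits, {"sp1": 1000}, group_by="class")
        assert "Unknown" not in t.columns


class TestCladeTest:
    def test_identical_groups_give_t_zero(self):
        table = pd.DataFrame({"SINE": [1, 2, 3, 1, 2, 3]},
                             index=[f"s{i}" for i in range(6)])
        t, p = clade_proportion_test(table, ["s0", "s1", "s2"],
                                     ["s3", "s4", "s5"], "SINE")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self, rng):
        vals = np.concatenate([rng.normal(0, 1e-4, 3), 1 + rng.normal(0, 1e-4, 3)])
        table = pd.DataFrame({"SINE": vals}, index=[f"s{i}" for i in range(6)])
        t, p = clade_proportion_test(table, ["s0", "s1", "s2"],
                                     ["s3", "s4", "s5"], "SINE")
        assert p < 0.01
        # Welch: agree with scipy run the other way round (sign flips)
        t2, p2 = clade_proportion_test(table, ["s3", "s4", "s5"],
                                       ["s0", "s1", "s2"], "SINE")
        assert t2 == pytest.approx(-t)
        assert p2 == pytest.approx(p)

    def test_singleton_group_rejected(self):
        table = pd.DataFrame({"SINE": [1, 2, 3]}, index=["a", "b", "c"])
        with pytest.raises(ValueError):
            clade_proportion_test(table, ["a"], ["b", "c"], "SINE")


class TestPCA:
    def test_rank_one_matrix_explained_by_pc1(self, rng):
        u = rng.normal(size=5)
        v = rng.normal(size=4)
        m = pd.DataFrame(np.outer(u, v),
                         index=[f"s{i}" for i in range(5)],
                         columns=[f"f{i}" for i in range(4)])
        res = pca_species_by_element(m)
        assert res["variance_explained"][0] == pytest.approx(1.0)

    def test_reconstruction_from_all_components(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 4)),
                         index=[f"s{i}" for i in range(5)],
                         columns=[f"f{i}" for i in range(4)])
        res = pca_species_by_element(m)
        recon = res["scores"].values @ res["loadings"].values.T + \
            res["column_means"].values
        assert np.allclose(recon, m.values, atol=1e-10)

    def test_loadings_orthonormal_and_variance_sorted(self, rng):
        m = pd.DataFrame(rng.normal(size=(8, 5)))
        res = pca_species_by_element(m)
        L = res["loadings"].values
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        ve = res["variance_explained"]
        assert all(ve[i] >= ve[i + 1] - 1e-12 for i in range(len(ve) - 1))

    def test_deterministic_sign(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 3)))
        a = pca_species_by_element(m)
        b = pca_species_by_element(m.copy())
        assert np.array_equal(a["loadings"].values, b["loadings"].values)
        for col in a["loadings"].columns:
            lo = a["loadings"][col]
            assert lo.iloc[np.argmax(np.abs(lo.values))] > 0

    def test_constant_matrix_rejected(self):
        m = pd.DataFrame(np.ones((4, 3)))
        with pytest.raises(ValueError):
            pca_species_by_element(m)


class TestSineLineCorrelation:
    def test_self_and_anticorrelation(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        table = pd.DataFrame({"S1": x, "L1": x, "L2": -x},
                             index=[f"s{i}" for i in range(4)])
        mat = sine_line_correlation(table, ["S1"], ["L1", "L2"])
        assert mat.loc["S1", "L1"] == pytest.approx(1.0)
        assert mat.loc["S1", "L2"] == pytest.approx(-1.0)

    def test_planted_coamplifying_pair(self, rng):
        n = 12
        driver = rng.uniform(0.001, 0.01, size=n)
        table = pd.DataFrame({
            "S1": driver + rng.normal(0, 2e-4, n),
            "L1": driver * 2 + rng.normal(0, 2e-4, n),
            "S2": rng.uniform(0.001, 0.01, n),
            "L2": rng.uniform(0.001, 0.01, n),
        }, index=[f"s{i}" for i in range(n)])
        mat = sine_line_correlation(table, ["S1", "S2"], ["L1", "L2"])
        assert mat.loc["S1", "L1"] > 0.8
        # sanity: matches scipy directly
        assert mat.loc["S2", "L2"] == pytest.approx(
            stats.pearsonr(table["S2"], table["L2"]).statistic)

    def test_constant_column_reported_missing(self):
        table = pd.DataFrame({"S1": [1, 2, 3], "L1": [5, 5, 5]},
                             index=["a", "b", "c"])
        mat = sine_line_correlation(table, ["S1"], ["L1"])
        assert np.isnan(mat.loc["S1", "L1"])

    def test_too_few_species_rejected(self):
        table = pd.DataFrame({"S1": [1, 2], "L1": [2, 1]}, index=["a", "b"])
        with pytest.raises(ValueError):
            sine_line_correlation(table, ["S1"], ["L1"])
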