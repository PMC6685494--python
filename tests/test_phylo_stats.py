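"""Z-transform, independent contrasts vs a GLS oracle, PIC regression,
multiple-testing adjustment."""

import numpy as np
import pytest
from scipy import stats

from tedyn.phylo_stats import (
    adjust_pvalues,
    genome_size_model,
    independent_contrasts,
    z_transform,
)
from tedyn.repeat_io import DatedTree, read_tree
from conftest import random_ultrametric_newick


def _phylo_cov(tree: DatedTree) -> tuple:
    """Brownian covariance matrix: shared path length from the root."""
    tips = tree.tip_labels
    root = tree.root_age
    n = len(tips)
    C = np.zeros((n, n))
    clades = tree.clade_tip_sets()
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            if i == j:
                C[i, j] = root
                continue
            # shared height = root age - age of the MRCA
            mrca = min((cl for cl in clades if {a, b} <= cl), key=len)
            mrca_age = next(br.child_age for br in tree.branches()
                            if br.tips == mrca) if mrca != set(tips) else None
            if frozenset(mrca) == frozenset(tips):
                C[i, j] = 0.0
            else:
                C[i, j] = root - mrca_age
    return C, tips


class TestZTransform:
    def test_simple_case(self):
        z = z_transform({"a": 1.0, "b": 2.0, "c": 3.0})
        assert z == pytest.approx({"a": -1.0, "b": 0.0, "c": 1.0})

    def test_output_standardized(self, rng):
        vals = {f"s{i}": float(v) for i, v in enumerate(rng.normal(5, 3, 20))}
        z = np.array(list(z_transform(vals).values()))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            z_transform({"a": 5.0, "b": 5.0, "c": 5.0})


class TestIndependentContrasts:
    def test_two_tip_closed_form(self):
        tree = read_tree("(A:1,B:1);")
        cs = independent_contrasts(tree, {"A": 3.0, "B": 1.0})
        assert len(cs.contrasts) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(2 / np.sqrt(2))

    def test_constant_trait_gives_zero_contrasts(self, five_tip_tree):
        cs = independent_contrasts(five_tip_tree, {t: 7.0 for t in "ABCDE"})
        assert np.allclose(cs.contrasts, 0.0)

    def test_contrast_count(self, five_tip_tree):
        cs = independent_contrasts(five_tip_tree,
                                   dict(zip("ABCDE", [1., 2., 3., 4., 5.])))
        assert len(cs.contrasts) == 4
        assert len(cs.node_ids) == 4

    def test_whitening_against_gls_oracle(self, rng):
        """PIC is a linear map A with A C A' = I: each contrast has unit
        variance and contrasts are mutually independent under Brownian
        motion -- checked against a covariance matrix built directly from
        shared root-to-MRCA path lengths on 100 random 8-tip trees."""
        for _ in range(100):
            tree = read_tree(random_ultrametric_newick(rng, 8))
            tips = tree.tip_labels
            n = len(tips)
            A = np.zeros((n - 1, n))
            for j, tip in enumerate(tips):
                unit = {t: 1.0 if t == tip else 0.0 for t in tips}
                A[:, j] = independent_contrasts(tree, unit).contrasts
            C, order = _phylo_cov(tree)
            perm = [order.index(t) for t in tips]
            C = C[np.ix_(perm, perm)]
            assert np.allclose(A @ C @ A.T, np.eye(n - 1), atol=1e-8)

    def test_missing_tip_rejected(self, five_tip_tree):
        with pytest.raises(ValueError):
            independent_contrasts(five_tip_tree, {"A": 1.0})


class TestGenomeSizeModel:
    def test_exact_linear_ols(self):
        x = {f"s{i}": float(i) for i in range(6)}
        y = {f"s{i}": 2.0 * i for i in range(6)}
        res = genome_size_model(y, x)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_pic_slope_matches_gls(self, rng):
        """Contrast regression through the origin equals the GLS slope of
        y on x with intercept under the Brownian covariance."""
        for _ in range(20):
            tree = read_tree(random_ultrametric_newick(rng, 8))
            tips = tree.tip_labels
            C, order = _phylo_cov(tree)
            perm = [order.index(t) for t in tips]
            C = C[np.ix_(perm, perm)]
            L = np.linalg.cholesky(C)
            x = dict(zip(tips, (L @ rng.normal(size=8)).tolist()))
            y = dict(zip(tips, (L @ rng.normal(size=8)).tolist()))
            res = genome_size_model(y, x, tree=tree)
            Ci = np.linalg.inv(C)
            X = np.column_stack([np.ones(8), [x[t] for t in tips]])
            yv = np.array([y[t] for t in tips])
            beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ yv)
            assert res.slope == pytest.approx(beta[1], abs=1e-8)

    def test_brownian_slope_recovery_within_2se(self, rng):
        # 32 tips so +/-2 SE carries close to its nominal ~95% coverage
        n = 32
        tree = read_tree(random_ultrametric_newick(np.random.default_rng(5), n))
        tips = tree.tip_labels
        C, order = _phylo_cov(tree)
        perm = [order.index(t) for t in tips]
        C = C[np.ix_(perm, perm)]
        L = np.linalg.cholesky(C)
        beta_true = 1.7
        covered = 0
        n_reps = 200
        for _ in range(n_reps):
            x = L @ rng.normal(size=n)
            y = beta_true * x + L @ rng.normal(size=n)
            res = genome_size_model(dict(zip(tips, y)), dict(zip(tips, x)),
                                    tree=tree)
            if abs(res.slope - beta_true) <= 2 * res.stderr:
                covered += 1
        assert covered / n_reps >= 0.93

    def test_null_pvalues_uniform(self, rng):
        """With a response evolving independently of the predictor the
        contrast-regression p-value is uniform on (0, 1)."""
        tree = read_tree(random_ultrametric_newick(np.random.default_rng(6), 8))
        tips = tree.tip_labels
        C, order = _phylo_cov(tree)
        perm = [order.index(t) for t in tips]
        C = C[np.ix_(perm, perm)]
        L = np.linalg.cholesky(C)
        x = dict(zip(tips, rng.normal(size=8)))   # arbitrary fixed predictor
        pvals = []
        for _ in range(400):
            y = dict(zip(tips, (L @ rng.normal(size=8)).tolist()))
            pvals.append(genome_size_model(y, x, tree=tree).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_predictor_rejected(self):
        x = {f"s{i}": 1.0 for i in range(5)}
        y = {f"s{i}": float(i) for i in range(5)}
        with pytest.raises(ValueError):
            genome_size_model(y, x)


class TestAdjustPvalues:
    def test_bonferroni_example(self):
        out = adjust_pvalues([0.01, 0.04, 0.03], method="bonferroni")
        assert out == pytest.approx([0.03, 0.12, 0.09])

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.2], "holm") == pytest.approx([0.2])

    def test_holm_dominates_bonferroni(self, rng):
        p = rng.uniform(size=30).tolist()
        holm = adjust_pvalues(p, "holm")
        bonf = adjust_pvalues(p, "bonferroni")
        assert all(h <= b + 1e-12 for h, b in zip(holm, bonf))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])
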