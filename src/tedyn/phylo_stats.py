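"""Genome-size versus TE-content statistics with phylogenetic correction.

Species are not independent samples: traits covary with shared ancestry.
Phylogenetic independent contrasts (Felsenstein) convert n tip values on
a dated tree into n-1 standardized differences that are independent
under Brownian-motion evolution; regression of response contrasts on
predictor contrasts through the origin then replaces ordinary least
squares.  Per-family tests are corrected for multiple comparisons
(Holm by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .repeat_io import DatedTree

__all__ = [
    "ContrastSet",
    "z_transform",
    "independent_contrasts",
    "genome_size_model",
    "adjust_pvalues",
]


def z_transform(values: Mapping[str, float]) -> dict:
    """Center and scale tip values to mean 0, sample SD 1 (n-1 denominator)."""
    keys = sorted(values)
    x = np.array([values[k] for k in keys], dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input has no Z-transform")
    z = (x - x.mean()) / sd
    return dict(zip(keys, z.tolist()))


@dataclass
class ContrastSet:
    """Standardized independent contrasts with their node order."""

    contrasts: np.ndarray       # length n_tips - 1
    variances: np.ndarray       # expected variance (sum of adjusted lengths)
    node_ids: list              # clade tip-set labels, same order


def independent_contrasts(tree: DatedTree, trait: Mapping[str, float]) -> ContrastSet:
    """Felsenstein's phylogenetic independent contrasts.

    Post-order traversal of the (bifurcating) tree: at each internal
    node the contrast is (x_left - x_right) / sqrt(v_left + v_right),
    the ancestral value is the variance-weighted average of the child
    values, and the parent branch is inflated by v_l*v_r/(v_l+v_r).
    Branch lengths must be strictly positive.
    """
    missing = set(tree.tip_labels) - set(trait)
    if missing:
        raise ValueError(f"trait missing for tips: {sorted(missing)}")
    dtree = tree.as_dendropy()
    x: dict = {}
    v: dict = {}
    contrasts = []
    variances = []
    node_ids = []
    for node in dtree.postorder_node_iter():
        bl = node.edge.length if node.parent_node is not None else 0.0
        if node.is_leaf():
            x[node] = float(trait[node.taxon.label])
            v[node] = float(bl)
            if node.parent_node is not None and bl <= 0:
                raise ValueError("zero-length terminal branch")
        else:
            kids = node.child_nodes()
            if len(kids) != 2:
                raise ValueError("independent contrasts require a bifurcating tree")
            l, r = kids
            vsum = v[l] + v[r]
            if vsum <= 0:
                raise ValueError("zero-length internal branch pair")
            contrasts.append((x[l] - x[r]) / np.sqrt(vsum))
            variances.append(vsum)
            tips = sorted(t.taxon.label for t in node.leaf_iter())
            node_ids.append("+".join(tips))
            x[node] = (x[l] / v[l] + x[r] / v[r]) / (1.0 / v[l] + 1.0 / v[r])
            v[node] = float(bl) + v[l] * v[r] / vsum
            if node.parent_node is not None and bl <= 0:
                raise ValueError("zero-length internal branch")
    return ContrastSet(contrasts=np.array(contrasts),
                       variances=np.array(variances),
                       node_ids=node_ids)


@dataclass
class RegressionResult:
    slope: float
    intercept: float | None
    r_squared: float
    pvalue: float
    stderr: float
    df: int
    phylogenetic: bool


def genome_size_model(response: Mapping[str, float],
                      predictor: Mapping[str, float],
                      tree: DatedTree | None = None) -> RegressionResult:
    """Linear model of one tip trait on another, optionally PIC-corrected.

    Without a tree: ordinary least squares with intercept.  With a tree:
    both traits are converted to independent contrasts and the response
    contrasts are regressed on the predictor contrasts through the
    origin (the standard contrast regression).  Two-sided p-value from
    the t distribution.
    """
    keys = sorted(set(response) & set(predictor))
    if len(keys) < 4:
        raise ValueError("need >= 4 species")
    if tree is None:
        y = np.array([response[k] for k in keys], dtype=float)
        x = np.array([predictor[k] for k in keys], dtype=float)
        if np.std(x) == 0:
            raise ValueError("degenerate (constant) predictor")
        res = stats.linregress(x, y)
        return RegressionResult(
            slope=float(res.slope), intercept=float(res.intercept),
            r_squared=float(res.rvalue ** 2), pvalue=float(res.pvalue),
            stderr=float(res.stderr), df=len(keys) - 2, phylogenetic=False,
        )
    yc = independent_contrasts(tree, response).contrasts
    xc = independent_contrasts(tree, predictor).contrasts
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("degenerate predictor contrasts")
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    df = len(xc) - 1
    if df <= 0:
        raise ValueError("not enough contrasts for inference")
    sigma2 = float(resid @ resid) / df
    stderr = np.sqrt(sigma2 / sxx)
    tstat = slope / stderr if stderr > 0 else np.inf
    pvalue = 2.0 * stats.t.sf(abs(tstat), df)
    syy = float(yc @ yc)
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else np.nan
    return RegressionResult(slope=slope, intercept=None, r_squared=r2,
                            pvalue=float(pvalue), stderr=float(stderr),
                            df=df, phylogenetic=True)


def adjust_pvalues(pvalues: Sequence[float], method: str = "holm") -> list:
    """Holm or Bonferroni multiple-testing adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("holm", "bonferroni"):
        raise ValueError("method must be 'holm' or 'bonferroni'")
    return multipletests(p, method=method)[1].tolist()
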