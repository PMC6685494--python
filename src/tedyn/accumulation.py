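"""Stratified genome-proportion tables and comparative summaries.

Proportions are raw annotated bp divided by genome size, computed per
species and per class/family in recent, old, or all strata.  On top of
those tables: Welch t-tests between clades, PCA of species-by-element
matrices, and SINE x LINE Pearson correlation matrices of recent
accumulation.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import AgeClass, classify_age
from .repeat_io import RepeatHit

__all__ = [
    "proportion_table",
    "clade_proportion_test",
    "pca_species_by_element",
    "sine_line_correlation",
]

STRATA = ("recent", "old", "all")


def proportion_table(hits_by_species: Mapping[str, Sequence[RepeatHit]],
                     genomes: Mapping[str, int],
                     group_by: str = "class",
                     stratum: str = "all",
                     age_class: AgeClass | None = None,
                     include_unknown: bool = False) -> pd.DataFrame:
    """Genome proportion per species (rows) and grouping key (columns).

    ``group_by`` is "class" or "family"; ``stratum`` selects hits by the
    recent/old dichotomy.  Overlapping hits are counted as annotated (no
    collapsing), so cells are raw masked bp over genome size.  Hits with
    class Unknown are excluded from class-level tables unless
    ``include_unknown`` is set.
    """
    if group_by not in ("class", "family"):
        raise ValueError("group_by must be 'class' or 'family'")
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}")
    age_class = age_class or AgeClass()
    missing = set(hits_by_species) - set(genomes)
    if missing:
        raise ValueError(f"species without genome size: {sorted(missing)}")

    bp: dict[tuple[str, str], int] = {}
    keys: set[str] = set()
    for sp, hits in hits_by_species.items():
        for h in hits:
            if stratum != "all" and classify_age(h.divergence, age_class) != stratum:
                continue
            key = h.class_label if group_by == "class" else h.family_name
            if group_by == "class" and key == "Unknown" and not include_unknown:
                continue
            keys.add(key)
            bp[(sp, key)] = bp.get((sp, key), 0) + h.length_bp

    species = sorted(hits_by_species)
    columns = sorted(keys)
    data = np.zeros((len(species), len(columns)))
    for i, sp in enumerate(species):
        for j, key in enumerate(columns):
            data[i, j] = bp.get((sp, key), 0) / genomes[sp]
    df = pd.DataFrame(data, index=pd.Index(species, name="species_id"),
                      columns=columns)
    df.attrs["stratum"] = stratum
    df.attrs["group_by"] = group_by
    return df


def clade_proportion_test(table: pd.DataFrame, clade_a: Iterable[str],
                          clade_b: Iterable[str], key: str) -> tuple[float, float]:
    """Welch unpaired two-sided t-test on one column between two clades."""
    a = sorted(set(clade_a))
    b = sorted(set(clade_b))
    if key not in table.columns:
        raise KeyError(key)
    xa = table.loc[[s for s in a if s in table.index], key].to_numpy(float)
    xb = table.loc[[s for s in b if s in table.index], key].to_numpy(float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each clade needs >= 2 members with values")
    res = stats.ttest_ind(xa, xb, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pca_species_by_element(matrix: pd.DataFrame, scale: bool = False,
                           n_components: int | None = None) -> dict:
    """PCA of a species-by-element proportion matrix.

    Columns are centered (and optionally scaled to unit variance) before
    SVD.  The sign of each component is fixed so its largest-magnitude
    loading is positive, making the output deterministic.  Returns scores,
    loadings (columns orthonormal) and variance-explained fractions.
    """
    X = matrix.to_numpy(float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("need >= 3 species and >= 2 element columns")
    means = X.mean(axis=0)
    Xc = X - means
    sds = None
    if scale:
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0):
            raise ValueError("constant column cannot be scaled")
        Xc = Xc / sds
    if np.allclose(Xc, 0):
        raise ValueError("matrix has no variance")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, p) if n_components is None else n_components
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic sign: largest-magnitude loading positive
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    scores = U * S
    var = S ** 2 / (n - 1)
    total_var = (Xc ** 2).sum() / (n - 1)
    return {
        "scores": pd.DataFrame(scores, index=matrix.index,
                               columns=[f"PC{i+1}" for i in range(k)]),
        "loadings": pd.DataFrame(Vt.T, index=matrix.columns,
                                 columns=[f"PC{i+1}" for i in range(k)]),
        "variance_explained": var / total_var,
        "column_means": pd.Series(means, index=matrix.columns),
        "column_sds": None if sds is None else pd.Series(sds, index=matrix.columns),
    }


def sine_line_correlation(table: pd.DataFrame, sine_families: Iterable[str],
                          line_families: Iterable[str]) -> pd.DataFrame:
    """Pearson r of recent accumulation between SINE and LINE families.

    Rows are SINE families, columns LINE families; r is computed across
    species.  Families with constant proportions across species have
    undefined r, reported as NaN.
    """
    if len(table.index) < 3:
        raise ValueError("need >= 3 species for correlation")
    sines = sorted(set(sine_families) & set(table.columns))
    lines = sorted(set(line_families) & set(table.columns))
    out = pd.DataFrame(np.nan, index=pd.Index(sines, name="sine_family"),
                       columns=lines)
    for s in sines:
        xs = table[s].to_numpy(float)
        for l in lines:
            ys = table[l].to_numpy(float)
            if np.std(xs) == 0 or np.std(ys) == 0:
                continue
            out.loc[s, l] = float(stats.pearsonr(xs, ys).statistic)
    return out
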