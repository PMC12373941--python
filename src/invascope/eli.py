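"""ELI scoring: cross-species correlation of fibroblast expression with
placental invasion depth.

Each species carries an ordinal placental invasion index (0 = epitheliochorial,
non-invasive, up to 3 = deeply invasive hemochorial). The ELI score of a gene
is the correlation (Spearman by default, Pearson selectable) between its
log2 expression across species and that index; genes scoring above a threshold
(0.5 by default, strict inequality) are the "ELI genes" fed to downstream
set construction.

For Spearman with few species the asymptotic t approximation of the p-value is
poor, so up to ``exact_p_max`` species the exact permutation null is used: all
n! relabelings of the index ranks, evaluated for every gene at once with a
single matrix product (the null only mixes the two fixed rank multisets).
"""

from __future__ import annotations

import itertools
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSet

__all__ = [
    "compute_eli_scores",
    "select_eli_genes",
    "read_expression_tsv",
    "read_invasion_index_tsv",
]


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x species (or samples) expression table, first column gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_invasion_index_tsv(path) -> pd.Series:
    """Two-column TSV (species, index) -> Series of ints indexed by species."""
    df = pd.read_csv(path, sep="\t")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    return s.astype(int)


def _validate(expr: pd.DataFrame, idx: pd.Series) -> tuple[pd.DataFrame, np.ndarray]:
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if expr.columns.duplicated().any():
        raise ValueError("duplicate species ids in expression matrix")
    common = [s for s in expr.columns if s in set(idx.index)]
    if len(common) < 4:
        raise ValueError(
            f"need >=4 species shared between expression matrix and invasion index, got {len(common)}"
        )
    expr = expr[common]
    vals = expr.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        bad = expr.index[~np.isfinite(vals).all(axis=1)][0]
        raise ValueError(f"non-finite expression values (first offending gene: {bad})")
    iv = idx.loc[common].to_numpy(dtype=float)
    if len(np.unique(iv)) < 2:
        raise ValueError("invasion index is constant across the shared species")
    return expr, iv


@lru_cache(maxsize=8)
def _perm_rank_matrix(idx_ranks: tuple[float, ...]) -> np.ndarray:
    """All n! permutations of the index rank vector, centered (rows)."""
    r = np.array(idx_ranks, dtype=float)
    perms = np.array(list(itertools.permutations(r)), dtype=float)
    return perms - perms.mean(axis=1, keepdims=True)


def _exact_spearman_p(gene_ranks: np.ndarray, idx_ranks: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Exact two-sided permutation p for Spearman rho, vectorized over genes.

    Valid because the null statistic only depends on the (fixed) rank
    multisets of the index and of each gene: one centered matmul scores all
    n! relabelings against all genes simultaneously.
    """
    perms = _perm_rank_matrix(tuple(idx_ranks))  # (n!, n), centered
    g = gene_ranks - gene_ranks.mean(axis=1, keepdims=True)  # (G, n)
    num = perms @ g.T  # (n!, G)
    denom = np.sqrt((perms[0] ** 2).sum()) * np.sqrt((g**2).sum(axis=1))  # (G,)
    with np.errstate(invalid="ignore", divide="ignore"):
        null_rho = num / denom
    # count |null| >= |observed| with a tolerance against float jitter
    hits = (np.abs(null_rho) >= np.abs(rho)[None, :] - 1e-12).sum(axis=0)
    return hits / perms.shape[0]


def _asymptotic_p(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.clip(np.where(np.abs(r) >= 1.0, 0.0, p), 0.0, 1.0)


def compute_eli_scores(
    expr: pd.DataFrame,
    idx: pd.Series,
    method: str = "spearman",
    exact_p_max: int = 8,
) -> pd.DataFrame:
    """Per-gene ELI score table.

    Parameters
    ----------
    expr
        Genes x species log2 expression matrix.
    idx
        Ordinal invasion index per species (values in {0,1,2,3}).
    method
        "spearman" (default; rank correlation suits the ordinal phenotype) or
        "pearson".
    exact_p_max
        Largest species count for which Spearman p-values come from the exact
        permutation null rather than the t approximation.

    Returns a DataFrame with columns ``gene, score, p_value, n_species_used,
    degenerate`` (one row per gene; zero-variance genes score 0 with p 1).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    expr, iv = _validate(expr, idx)
    X = expr.to_numpy(dtype=float)
    n = X.shape[1]
    degenerate = X.std(axis=1) == 0.0

    if method == "spearman":
        gr = stats.rankdata(X, axis=1)
        ir = stats.rankdata(iv)
    else:
        gr, ir = X, iv.astype(float)
    gc = gr - gr.mean(axis=1, keepdims=True)
    ic = ir - ir.mean()
    denom = np.sqrt((gc**2).sum(axis=1)) * np.sqrt((ic**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        score = (gc @ ic) / denom
    score = np.where(degenerate, 0.0, np.clip(score, -1.0, 1.0))

    if method == "spearman" and n <= exact_p_max:
        p = _exact_spearman_p(gr, ir, score)
    else:
        p = _asymptotic_p(score, n)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "gene": expr.index.to_numpy(),
            "score": score,
            "p_value": p,
            "n_species_used": n,
            "degenerate": degenerate,
        }
    )


def select_eli_genes(table: pd.DataFrame, threshold: float = 0.5, name: str = "ELI") -> GeneSet:
    """Genes with ELI score strictly above ``threshold`` (degenerate genes excluded).

    Returns a :class:`GeneSet` with lexicographically ordered members; empty
    selection warns rather than raising.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    keep = table.loc[(table["score"] > threshold) & ~table["degenerate"].astype(bool), "gene"]
    members = tuple(sorted(keep.astype(str)))
    if not members:
        warnings.warn(f"no genes exceed ELI score threshold {threshold}")
        return GeneSet(name, (), f"ELI score > {threshold}")
    return GeneSet(name, members, f"ELI score > {threshold}")
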