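"""Gene set enrichment across tumor stage transitions.

Implements the weighted Kolmogorov-Smirnov-style running-sum enrichment
statistic from scratch: genes are ranked by a later-vs-earlier differential
metric (signal-to-noise by default), the running sum gains
``|metric|^p / sum_members |metric|^p`` at set members and loses
``1/(N - N_H)`` at non-members, and the enrichment score (ES) is the signed
maximal deviation. Significance comes from a permutation null — phenotype
(stage-label) permutation for adequately sized groups, gene-set permutation
otherwise — with the plus-one correction so p is never exactly 0, and the
normalized ES (NES) divides by the mean |ES| of same-sign permutations.

A negative ES for the stromal-vulnerability set at the T1->T2 transition is
the signature of interest: those genes drop as tumors reach the stage that
typically precedes dissemination into the stroma.

The single-cell path aggregates cells of one annotated type (fibroblasts /
CAFs) into per-patient pseudobulk samples before the same transition scan.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet

logger = logging.getLogger("invascope.enrichment")

__all__ = [
    "StageCohort",
    "RankedList",
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "gsea",
    "transition_scan",
    "transitions_table",
    "fibroblast_pseudobulk",
    "read_cohort_tsv",
    "cohort_from_anndata",
]

METRICS = ("s2n", "log2fc", "t")
_MIN_PHENOTYPE_GROUP = 7  # below this, phenotype permutation falls back to gene_set


@dataclass
class StageCohort:
    """Expression cohort with ordered stage annotations.

    ``values`` is a genes x samples DataFrame; ``meta`` is indexed by sample
    with at least a ``stage`` column (``patient`` and ``cell_type`` optional,
    required for the pseudobulk path); ``stage_order`` declares the ordered
    stage vocabulary.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    stage_order: list[str]

    def __post_init__(self):
        if list(self.values.columns) != list(self.meta.index):
            self.meta = self.meta.loc[self.values.columns]
        if "stage" not in self.meta.columns:
            raise ValueError("cohort metadata requires a 'stage' column")
        unknown = set(self.meta["stage"].astype(str)) - set(map(str, self.stage_order))
        if unknown:
            raise ValueError(f"stages {sorted(unknown)} not in declared stage order {self.stage_order}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index.astype(str))

    def samples_for(self, stage: str) -> list[str]:
        return list(self.meta.index[self.meta["stage"].astype(str) == str(stage)])

    def transitions(self) -> list[tuple[str, str]]:
        return list(zip(self.stage_order[:-1], self.stage_order[1:]))


@dataclass(frozen=True)
class RankedList:
    """Genes ordered best-to-worst with their ranking metric (ties broken by id)."""

    genes: tuple[str, ...]
    metric: np.ndarray
    transition: str = ""

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    set_name: str
    transition: str
    es: float
    nes: float
    p_value: float
    leading_edge: tuple[str, ...]
    running_sum: np.ndarray = field(repr=False)
    n_perm: int
    perm_type: str
    p_adjusted: float | None = None


def read_cohort_tsv(expr_path, meta_path, stage_order: list[str] | None = None) -> StageCohort:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    values.columns = values.columns.astype(str)
    if stage_order is None:
        stage_order = sorted(meta["stage"].astype(str).unique())
    return StageCohort(values, meta, list(stage_order))


def read_single_cell_mtx(
    mtx_dir,
    meta_tsv,
    stage_order: list[str],
    matrix_name: str = "matrix.mtx",
    features_name: str = "features.tsv",
    barcodes_name: str = "barcodes.tsv",
) -> StageCohort:
    """Cell-level cohort from an MTX triplet (genes x cells) plus cell metadata.

    ``meta_tsv`` is indexed by barcode with columns stage / patient /
    cell_type as in :func:`read_cohort_tsv`.
    """
    import pathlib

    from scipy.io import mmread

    d = pathlib.Path(mtx_dir)
    X = np.asarray(mmread(d / matrix_name).todense())
    genes = [l.split("\t")[0].strip() for l in open(d / features_name) if l.strip()]
    cells = [l.strip().split("\t")[0] for l in open(d / barcodes_name) if l.strip()]
    values = pd.DataFrame(X, index=genes, columns=cells)
    meta = pd.read_csv(meta_tsv, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return StageCohort(values, meta, list(stage_order))


def cohort_from_anndata(
    adata,
    stage_order: list[str],
    stage_col: str = "stage",
    patient_col: str = "patient",
    cell_type_col: str = "cell_type",
) -> StageCohort:
    """Wrap an AnnData of cells (obs) x genes (var) as a cell-level cohort."""
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    values = pd.DataFrame(np.asarray(X).T, index=adata.var_names.astype(str), columns=adata.obs_names.astype(str))
    meta = pd.DataFrame(index=adata.obs_names.astype(str))
    meta["stage"] = adata.obs[stage_col].astype(str).to_numpy()
    if patient_col in adata.obs:
        meta["patient"] = adata.obs[patient_col].astype(str).to_numpy()
    if cell_type_col in adata.obs:
        meta["cell_type"] = adata.obs[cell_type_col].astype(str).to_numpy()
    return StageCohort(values, meta, list(stage_order))


# ---------------------------------------------------------------------------
# ranking


def _metric_batch(X: np.ndarray, mask_later: np.ndarray, metric: str) -> np.ndarray:
    """Ranking metric for each permutation row of ``mask_later``.

    X: genes x samples; mask_later: n_perm x samples boolean. Returns
    (n_perm, genes).
    """
    M2 = mask_later.astype(float)
    M1 = 1.0 - M2
    n2 = M2.sum(axis=1)
    n1 = M1.sum(axis=1)
    m2 = (X @ M2.T) / n2  # genes x n_perm
    m1 = (X @ M1.T) / n1
    if metric == "log2fc":
        return (m2 - m1).T
    e2 = (X**2 @ M2.T) / n2
    e1 = (X**2 @ M1.T) / n1
    v2 = np.maximum(0.0, e2 - m2**2) * (n2 / np.maximum(1.0, n2 - 1.0))
    v1 = np.maximum(0.0, e1 - m1**2) * (n1 / np.maximum(1.0, n1 - 1.0))
    if metric == "s2n":
        s2 = np.maximum(np.sqrt(v2), 0.2 * np.abs(m2))
        s1 = np.maximum(np.sqrt(v1), 0.2 * np.abs(m1))
        denom = s2 + s1
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, (m2 - m1) / denom, 0.0)
        return out.T
    if metric == "t":
        denom = np.sqrt(v2 / n2 + v1 / n1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, (m2 - m1) / denom, 0.0)
        return out.T
    raise ValueError(f"unknown ranking metric {metric!r}")


def _check_groups(cohort: StageCohort, earlier: str, later: str, metric: str) -> tuple[list[str], list[str]]:
    need = 3 if metric == "s2n" else 2
    s1, s2 = cohort.samples_for(earlier), cohort.samples_for(later)
    for label, ss in ((earlier, s1), (later, s2)):
        if len(ss) == 0:
            raise ValueError(f"stage {label!r} absent from cohort")
        if len(ss) < need:
            raise ValueError(f"stage {label!r} has {len(ss)} samples; need >= {need} for metric {metric!r}")
    return s1, s2


def rank_genes(cohort: StageCohort, earlier: str, later: str, metric: str = "s2n") -> RankedList:
    """Rank genes by later-vs-earlier differential expression (descending).

    Positive metric = up in the later stage. Ties (including the all-zero
    degenerate case) are broken lexicographically by gene id.
    """
    s1, s2 = _check_groups(cohort, earlier, later, metric)
    sub = cohort.values[s1 + s2].sort_index(kind="stable")
    X = sub.to_numpy(dtype=float)
    mask = np.zeros((1, X.shape[1]), dtype=bool)
    mask[0, len(s1):] = True
    m = _metric_batch(X, mask, metric)[0]
    order = np.argsort(-m, kind="stable")  # stable keeps lexicographic ids on ties
    return RankedList(tuple(sub.index[order].astype(str)), m[order], f"{earlier}->{later}")


# ---------------------------------------------------------------------------
# enrichment score


def _es_batch(member: np.ndarray, absw: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Running-sum ES for each row. member/absw: (K, N). Returns es, peak index,
    running sums."""
    member = np.atleast_2d(member)
    absw = np.atleast_2d(absw)
    K, N = member.shape
    nh = member.sum(axis=1)
    denom = (absw * member).sum(axis=1)
    hit = np.where(
        member,
        np.where(denom[:, None] > 0, absw / np.where(denom[:, None] > 0, denom[:, None], 1.0), 1.0 / nh[:, None]),
        0.0,
    )
    miss = np.where(~member, -1.0 / (N - nh)[:, None], 0.0)
    run = np.cumsum(hit + miss, axis=1)
    peak = np.argmax(np.abs(run), axis=1)
    es = np.take_along_axis(run, peak[:, None], axis=1)[:, 0]
    return es, peak, run


def enrichment_score(
    ranked: RankedList, gs: GeneSet, exponent: float = 1.0
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """ES, running-sum curve, and leading-edge genes for one set on one ranking.

    The leading edge is the set members at or before the running-sum peak for
    positive ES, at or after the trough for negative ES.
    """
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    genes = np.array(ranked.genes)
    member = np.isin(genes, np.array(list(gs.members), dtype=genes.dtype))
    nh = int(member.sum())
    if nh == 0:
        raise ValueError(f"gene set {gs.name!r} has no overlap with the ranked universe")
    if nh == len(genes):
        raise ValueError("gene set equals the whole ranked universe; ES undefined")
    absw = np.abs(np.asarray(ranked.metric, dtype=float)) ** exponent
    es, peak, run = _es_batch(member[None, :], absw[None, :])
    es, peak, run = float(es[0]), int(peak[0]), run[0]
    if es >= 0:
        le = tuple(genes[: peak + 1][member[: peak + 1]])
    else:
        le = tuple(genes[peak:][member[peak:]])
    return es, run, le


# ---------------------------------------------------------------------------
# permutation machinery


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _phenotype_masks(n1: int, n2: int, n_perm: int, rng: np.random.Generator, exact: bool) -> np.ndarray:
    n = n1 + n2
    if exact:
        total = math.comb(n, n2)
        if total > 200_000:
            raise ValueError(f"{total} relabelings; too many for exact phenotype enumeration")
        masks = np.zeros((total, n), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n), n2)):
            masks[i, list(combo)] = True
        return masks
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=n2, replace=False)] = True
    return masks


def _perm_es_phenotype(
    X: np.ndarray, member0: np.ndarray, n1: int, masks: np.ndarray, metric: str, exponent: float
) -> np.ndarray:
    """ES under stage-label permutation. ``member0`` is the membership vector
    over genes in the (lexicographic) row order of X."""
    m = _metric_batch(X, masks, metric)  # (K, genes)
    order = np.argsort(-m, axis=1, kind="stable")
    member = np.take_along_axis(np.broadcast_to(member0, m.shape), order, axis=1)
    absw = np.take_along_axis(np.abs(m) ** exponent, order, axis=1)
    es, _, _ = _es_batch(member, absw)
    return es


def _perm_es_geneset(
    absw_ranked: np.ndarray, nh: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    N = absw_ranked.size
    member = np.zeros((n_perm, N), dtype=bool)
    for i in range(n_perm):
        member[i, rng.choice(N, size=nh, replace=False)] = True
    es, _, _ = _es_batch(member, np.broadcast_to(absw_ranked, member.shape))
    return es


def _summarize_null(es: float, perm_es: np.ndarray) -> tuple[float, float]:
    """Sign-conditional permutation p (plus-one) and NES."""
    same = perm_es >= 0 if es >= 0 else perm_es < 0
    n_same = int(same.sum())
    extreme = int((same & (np.abs(perm_es) >= abs(es) - 1e-12)).sum())
    p = (1 + extreme) / (1 + n_same)
    nes = es / float(np.mean(np.abs(perm_es[same]))) if n_same else float("nan")
    return p, nes


def gsea(
    cohort: StageCohort,
    earlier: str,
    later: str,
    gs: GeneSet,
    n_perm: int = 1000,
    perm_type: str = "phenotype",
    exponent: float = 1.0,
    metric: str = "s2n",
    seed=None,
) -> EnrichmentResult:
    """One gene set on one stage transition with a permutation null.

    ``perm_type``: "phenotype" permutes stage labels (falls back to
    "gene_set" with a warning when either group has < 7 samples),
    "phenotype_exact" enumerates every distinct relabeling (never falls
    back; for tiny cohorts), "gene_set" draws random same-size member sets.
    """
    if perm_type not in ("phenotype", "phenotype_exact", "gene_set"):
        raise ValueError(f"unknown perm_type {perm_type!r}")
    rng = _rng(seed)
    ranked = rank_genes(cohort, earlier, later, metric)
    es, run, le = enrichment_score(ranked, gs, exponent)

    s1, s2 = cohort.samples_for(earlier), cohort.samples_for(later)
    used = perm_type
    if perm_type == "phenotype" and min(len(s1), len(s2)) < _MIN_PHENOTYPE_GROUP:
        msg = (
            f"group sizes {len(s1)}/{len(s2)} too small for phenotype permutation; "
            "falling back to gene_set permutation"
        )
        logger.warning(msg)
        warnings.warn(msg)
        used = "gene_set"

    genes = np.array(ranked.genes)
    member_ranked = np.isin(genes, np.array(list(gs.members), dtype=genes.dtype))
    if used == "gene_set":
        absw = np.abs(np.asarray(ranked.metric)) ** exponent
        perm_es = _perm_es_geneset(absw, int(member_ranked.sum()), n_perm, rng)
    else:
        sub = cohort.values[s1 + s2].sort_index(kind="stable")
        X = sub.to_numpy(dtype=float)
        member0 = np.isin(sub.index.astype(str).to_numpy(), np.array(list(gs.members)))
        masks = _phenotype_masks(len(s1), len(s2), n_perm, rng, exact=used == "phenotype_exact")
        perm_es = _perm_es_phenotype(X, member0, len(s1), masks, metric, exponent)
    p, nes = _summarize_null(es, perm_es)
    return EnrichmentResult(
        set_name=gs.name,
        transition=f"{earlier}->{later}",
        es=es,
        nes=nes,
        p_value=p,
        leading_edge=le,
        running_sum=run,
        n_perm=len(perm_es),
        perm_type=used,
    )


def transition_scan(
    cohort: StageCohort,
    gs: GeneSet,
    n_perm: int = 1000,
    perm_type: str = "phenotype",
    exponent: float = 1.0,
    metric: str = "s2n",
    seed=None,
) -> list[EnrichmentResult]:
    """Run GSEA on every consecutive stage pair; BH-correct across transitions.

    Transitions whose groups are too small are skipped with a logged reason;
    the others still run.
    """
    if len(gs) == 0:
        raise ValueError("empty gene set")
    ss = np.random.SeedSequence(seed if isinstance(seed, int) else None)
    children = ss.spawn(len(cohort.transitions()))
    results: list[EnrichmentResult] = []
    for (earlier, later), child in zip(cohort.transitions(), children):
        try:
            _check_groups(cohort, earlier, later, metric)
        except ValueError as exc:
            logger.warning("skipping transition %s->%s: %s", earlier, later, exc)
            continue
        results.append(
            gsea(
                cohort, earlier, later, gs,
                n_perm=n_perm, perm_type=perm_type, exponent=exponent,
                metric=metric, seed=np.random.default_rng(child),
            )
        )
    if results:
        padj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [replace(r, p_adjusted=float(a)) for r, a in zip(results, padj)]
    return results


def transitions_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Bubble-plot table: one row per transition (transition, es, nes, p...)."""
    return pd.DataFrame(
        {
            "transition": [r.transition for r in results],
            "set_name": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "n_perm": [r.n_perm for r in results],
            "perm_type": [r.perm_type for r in results],
        }
    )


def fibroblast_pseudobulk(cells: StageCohort, target_type: str, min_cells: int = 10) -> StageCohort:
    """Per-patient mean expression over cells of one annotated type.

    Cells are filtered to ``target_type``; each surviving patient becomes one
    pseudobulk sample carrying the patient's stage. Patients with fewer than
    ``min_cells`` matching cells are dropped (logged).
    """
    for col in ("cell_type", "patient"):
        if col not in cells.meta.columns:
            raise ValueError(f"pseudobulk requires a {col!r} annotation")
    keep = cells.meta["cell_type"].astype(str) == str(target_type)
    meta = cells.meta[keep]
    n_dropped = 0
    cols, stages = [], []
    profiles = {}
    for patient, grp in meta.groupby("patient", sort=True):
        if len(grp) < min_cells:
            n_dropped += 1
            continue
        profiles[str(patient)] = cells.values[list(grp.index)].mean(axis=1)
        stage_vals = grp["stage"].astype(str).unique()
        stages.append(stage_vals[0])
        cols.append(str(patient))
    if n_dropped:
        logger.info("pseudobulk: dropped %d patients with < %d %s cells", n_dropped, min_cells, target_type)
    if not profiles:
        raise ValueError(f"no patient has >= {min_cells} cells of type {target_type!r}")
    values = pd.DataFrame(profiles)
    new_meta = pd.DataFrame({"stage": stages, "patient": cols}, index=cols)
    return StageCohort(values, new_meta, cells.stage_order)


def plot_running_sum(result: EnrichmentResult, path) -> None:
    """Write a running-sum (mountain) plot for one enrichment result."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(result.running_sum, lw=1.2)
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.set_xlabel("rank")
    ax.set_ylabel("running enrichment")
    ax.set_title(f"{result.set_name} {result.transition} ES={result.es:.2f} p={result.p_value:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
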