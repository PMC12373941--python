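"""GSEA engine: ranking metrics, running-sum ES, permutation nulls, pseudobulk."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from invascope import enrichment, synthetic
from invascope.enrichment import StageCohort
from invascope.genesets import GeneSet

from _oracles import es_oracle, s2n_oracle


def _cohort(values: np.ndarray, stages: list[str], stage_order=None) -> StageCohort:
    genes = [f"G{i:03d}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    vals = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.DataFrame({"stage": stages, "patient": samples}, index=samples)
    return StageCohort(vals, meta, stage_order or sorted(set(stages)))


# --- ranking ----------------------------------------------------------------


def test_identical_groups_rank_lexicographically():
    X = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 6))
    c = _cohort(X, ["T1"] * 3 + ["T2"] * 3)
    ranked = enrichment.rank_genes(c, "T1", "T2")
    assert np.all(ranked.metric == 0.0)
    assert list(ranked.genes) == sorted(ranked.genes)


def test_shifted_gene_ranks_first(rng):
    X = rng.normal(0, 1, size=(20, 10))
    X[7, 5:] += 5.0
    c = _cohort(X, ["T1"] * 5 + ["T2"] * 5)
    ranked = enrichment.rank_genes(c, "T1", "T2")
    assert ranked.genes[0] == "G007"


def test_s2n_matches_closed_form_oracle(rng):
    X = rng.normal(8, 2, size=(20, 12))
    c = _cohort(X, ["T1"] * 6 + ["T2"] * 6)
    ranked = enrichment.rank_genes(c, "T1", "T2", metric="s2n")
    lookup = dict(zip(ranked.genes, ranked.metric))
    for gi in range(20):
        expected = s2n_oracle(list(X[gi, :6]), list(X[gi, 6:]))
        assert lookup[f"G{gi:03d}"] == pytest.approx(expected, abs=1e-12)


def test_reversing_stage_pair_negates_metric(rng):
    X = rng.normal(0, 1, size=(15, 8))
    c = _cohort(X, ["T1"] * 4 + ["T2"] * 4)
    fwd = enrichment.rank_genes(c, "T1", "T2", metric="log2fc")
    rev = enrichment.rank_genes(c, "T2", "T1", metric="log2fc")
    f = dict(zip(fwd.genes, fwd.metric))
    r = dict(zip(rev.genes, rev.metric))
    for g in f:
        assert f[g] == pytest.approx(-r[g], abs=1e-12)


def test_absent_stage_named_in_error(rng):
    c = _cohort(rng.normal(size=(5, 6)), ["T1"] * 3 + ["T2"] * 3)
    with pytest.raises(ValueError, match="T9"):
        enrichment.rank_genes(c, "T1", "T9")


# --- enrichment score -------------------------------------------------------


def _ranked(metric, genes=None):
    genes = genes or [f"G{i:03d}" for i in range(len(metric))]
    return enrichment.RankedList(tuple(genes), np.asarray(metric, dtype=float))


def test_single_member_analytic_cases():
    """A lone member at the very top (bottom) gives the extreme two-sample KS
    deviation +1 (-1), symmetric under list reversal."""
    metric = list(np.linspace(2, -2, 10))
    top = GeneSet("top", ("G000",))
    es, _, le = enrichment.enrichment_score(_ranked(metric), top, exponent=0.0)
    assert es == pytest.approx(1.0, abs=1e-12)
    assert le == ("G000",)
    bottom = GeneSet("bottom", ("G009",))
    es, _, le = enrichment.enrichment_score(_ranked(metric), bottom, exponent=0.0)
    assert es == pytest.approx(-1.0, abs=1e-12)
    assert le == ("G009",)


@pytest.mark.parametrize("exponent", [0.0, 1.0])
def test_running_sum_matches_oracle_random_placements(rng, exponent):
    metric = sorted(rng.normal(0, 1, size=12), reverse=True)
    for _ in range(25):
        members = rng.choice(12, size=4, replace=False)
        gs = GeneSet("s", tuple(f"G{i:03d}" for i in members))
        es, run, _ = enrichment.enrichment_score(_ranked(metric), gs, exponent)
        flags = [i in set(members) for i in range(12)]
        es_o, run_o = es_oracle(metric, flags, exponent)
        assert es == pytest.approx(es_o, abs=1e-12)
        np.testing.assert_allclose(run, run_o, atol=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 10))
def test_running_sum_returns_to_zero(seed, nh):
    rng = np.random.default_rng(seed)
    metric = np.sort(rng.normal(0, 1, size=30))[::-1]
    members = rng.choice(30, size=nh, replace=False)
    gs = GeneSet("s", tuple(f"G{i:03d}" for i in members))
    _, run, _ = enrichment.enrichment_score(_ranked(list(metric)), gs, exponent=1.0)
    assert abs(run[-1]) < 1e-9


def test_no_overlap_and_full_universe_errors():
    with pytest.raises(ValueError, match="no overlap"):
        enrichment.enrichment_score(_ranked([1.0, 0.5, -1.0]), GeneSet("s", ("ZZZ",)))
    with pytest.raises(ValueError, match="whole ranked universe"):
        enrichment.enrichment_score(
            _ranked([1.0, 0.5, -1.0]), GeneSet("s", ("G000", "G001", "G002"))
        )


# --- permutation GSEA -------------------------------------------------------


def test_gsea_p_never_zero_and_deterministic(rng, small_gene_set):
    cohort, _ = synthetic.gen_stage_cohort(
        n_genes=200, n_per_stage=10, stages=("T1", "T2"),
        target_set=GeneSet("t", tuple(f"G{i:04d}" for i in range(20))),
        shift_d=3.0, seed=11,
    )
    gs = GeneSet("t", tuple(f"G{i:04d}" for i in range(20)))
    a = enrichment.gsea(cohort, "T1", "T2", gs, n_perm=200, seed=5)
    b = enrichment.gsea(cohort, "T1", "T2", gs, n_perm=200, seed=5)
    assert a.p_value > 0.0
    assert a.es == b.es and a.p_value == b.p_value and a.nes == b.nes


def test_small_groups_fall_back_to_gene_set_permutation(rng):
    cohort, _ = synthetic.gen_stage_cohort(
        n_genes=100, n_per_stage=4, stages=("T1", "T2"),
        target_set=GeneSet("t", ("G0000", "G0001", "G0002")), shift_d=1.0, seed=3,
    )
    gs = GeneSet("t", ("G0000", "G0001", "G0002"))
    with pytest.warns(UserWarning, match="falling back"):
        res = enrichment.gsea(cohort, "T1", "T2", gs, n_perm=100, perm_type="phenotype", seed=1)
    assert res.perm_type == "gene_set"


def test_transition_scan_counts_and_empty_set(rng, small_gene_set):
    cohort, _ = synthetic.gen_stage_cohort(
        n_genes=150, n_per_stage=8, stages=("T1", "T2", "T3", "T4"),
        target_set=GeneSet("t", ("G0000",)), shift_d=0.0, seed=9,
    )
    gs = GeneSet("t", tuple(f"G{i:04d}" for i in range(10)))
    res = enrichment.transition_scan(cohort, gs, n_perm=100, perm_type="gene_set", seed=2)
    assert [r.transition for r in res] == ["T1->T2", "T2->T3", "T3->T4"]
    assert all(r.p_adjusted is not None for r in res)
    with pytest.raises(ValueError, match="empty"):
        enrichment.transition_scan(cohort, GeneSet("e", ()), seed=0)


def test_transition_scan_skips_underpopulated_stage(rng):
    values = pd.DataFrame(
        rng.normal(size=(20, 7)),
        index=[f"G{i:03d}" for i in range(20)],
        columns=[f"s{i}" for i in range(7)],
    )
    meta = pd.DataFrame(
        {"stage": ["T1"] * 3 + ["T2"] * 3 + ["T3"], "patient": values.columns},
        index=values.columns,
    )
    cohort = StageCohort(values, meta, ["T1", "T2", "T3"])
    gs = GeneSet("t", ("G000", "G001", "G002"))
    res = enrichment.transition_scan(cohort, gs, n_perm=50, perm_type="gene_set", seed=1)
    assert [r.transition for r in res] == ["T1->T2"]  # T2->T3 skipped, T1->T2 kept


# --- pseudobulk -------------------------------------------------------------


def _cell_cohort(rng, extreme_other=False):
    sc, _ = synthetic.gen_single_cell_cohort(
        n_genes=50, stages=("T1", "T2"), n_patients_per_stage=3,
        n_cells_per_patient=30, frac_target=0.5,
        target_set=GeneSet("t", ("G0000", "G0001")), shift_d=1.0, seed=21,
    )
    if extreme_other:
        other = sc.meta.index[sc.meta["cell_type"] == "tumor"]
        sc.values.loc[:, other] += 1e6
    return sc


def test_pseudobulk_one_sample_per_patient(rng):
    sc = _cell_cohort(rng)
    pb = enrichment.fibroblast_pseudobulk(sc, "fibroblast")
    assert pb.values.shape[1] == 6  # 3 patients x 2 stages
    assert set(pb.meta["stage"]) == {"T1", "T2"}


def test_pseudobulk_ignores_other_cell_types(rng):
    clean = enrichment.fibroblast_pseudobulk(_cell_cohort(rng), "fibroblast")
    spiked = enrichment.fibroblast_pseudobulk(_cell_cohort(rng, extreme_other=True), "fibroblast")
    pd.testing.assert_frame_equal(clean.values, spiked.values)


def test_pseudobulk_min_cells_and_no_survivors(rng):
    sc = _cell_cohort(rng)
    with pytest.raises(ValueError, match="no patient"):
        enrichment.fibroblast_pseudobulk(sc, "fibroblast", min_cells=1000)
    pb = enrichment.fibroblast_pseudobulk(sc, "fibroblast", min_cells=15)
    assert pb.values.shape[1] == 6


def test_celltype_restriction_recovers_diluted_signal():
    """A fibroblast-only shift is detected after cell-type filtering but washed
    out in whole-tissue pseudobulk at the same effect size."""
    gs = GeneSet("t", tuple(f"G{i:04d}" for i in range(15)))
    detected, diluted = 0, 0
    for seed in range(10):
        sc, _ = synthetic.gen_single_cell_cohort(
            n_genes=200, stages=("T1", "T2"), n_patients_per_stage=8,
            n_cells_per_patient=40, frac_target=0.1, target_set=gs,
            shift_d=1.0, seed=seed,
        )
        fib = enrichment.fibroblast_pseudobulk(sc, "fibroblast", min_cells=3)
        res_f = enrichment.gsea(fib, "T1", "T2", gs, n_perm=200, seed=seed)
        whole = sc.meta.assign(cell_type="all")
        sc_all = StageCohort(sc.values, whole, sc.stage_order)
        allpb = enrichment.fibroblast_pseudobulk(sc_all, "all", min_cells=2)
        res_a = enrichment.gsea(allpb, "T1", "T2", gs, n_perm=200, seed=seed)
        detected += res_f.es < 0 and res_f.p_value <= 0.05
        diluted += res_a.es < 0 and res_a.p_value <= 0.05
    assert detected >= 8
    assert diluted < detected


def test_single_cell_mtx_and_anndata_ingest(tmp_path, rng):
    import anndata
    from scipy import io as sio
    from scipy.sparse import csr_matrix

    X = rng.poisson(2.0, size=(6, 8)).astype(float)  # genes x cells
    genes = [f"G{i}" for i in range(6)]
    cells = [f"c{i}" for i in range(8)]
    sio.mmwrite(tmp_path / "matrix.mtx", csr_matrix(X))
    (tmp_path / "features.tsv").write_text("\n".join(genes) + "\n")
    (tmp_path / "barcodes.tsv").write_text("\n".join(cells) + "\n")
    meta = pd.DataFrame(
        {"stage": ["T1"] * 4 + ["T2"] * 4, "patient": ["P1"] * 4 + ["P2"] * 4,
         "cell_type": "fibroblast"},
        index=cells,
    )
    meta.rename_axis("cell").reset_index().to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
    cohort = enrichment.read_single_cell_mtx(
        tmp_path, tmp_path / "meta.tsv", ["T1", "T2"],
        matrix_name="matrix.mtx.mtx" if (tmp_path / "matrix.mtx.mtx").exists() else "matrix.mtx",
    )
    np.testing.assert_allclose(cohort.values.to_numpy(), X)

    ad = anndata.AnnData(X.T, obs=meta, var=pd.DataFrame(index=genes))
    via_ad = enrichment.cohort_from_anndata(ad, ["T1", "T2"])
    pd.testing.assert_frame_equal(cohort.values, via_ad.values, check_names=False)
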