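"""End-to-end orchestration: scores -> candidate set -> stage enrichment;
motifs -> copy-number regression; masks -> front profiles.

A single declarative YAML config drives the run; every artifact lands in the
run directory with a manifest entry (stage, path, sha256), so a rerun with
the same config is byte-identical and fully reproducible from the manifest
alone. Defaults mirror the study parameters: ELI threshold 0.5, promoter
window 5 kb upstream / 1 kb downstream, fork thresholds 100 and 200 um.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import eli, enrichment, genesets, invasion, synthetic, tfbs

logger = logging.getLogger("invascope.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "RunResult", "run_pipeline", "write_bundle", "bundle_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GseaParams(_Strict):
    n_perm: int = 1000
    exponent: float = 1.0
    metric: str = "s2n"
    perm_type: str = "phenotype"
    seed: int = 0


class ScanParams(_Strict):
    window: tuple[int, int] = (5000, 1000)
    p_threshold: float = 1e-4


class ProfilingParams(_Strict):
    stride_px: int = 1
    smooth: int = 0
    thresholds_um: tuple[float, ...] = (100.0, 200.0)
    pixel_size_um: float = 2.0
    baseline_row: int = 50


class SingleCellInputs(_Strict):
    expr_tsv: str
    meta_tsv: str
    target_type: str = "fibroblast"
    min_cells: int = 10


class PipelineConfig(_Strict):
    """Declarative pipeline configuration (unknown keys rejected)."""

    out_dir: str
    expression_tsv: str
    invasion_index_tsv: str
    pathways_gmt: str
    cohort_expr_tsv: str
    cohort_meta_tsv: str
    stage_order: list[str]
    decidual_fc_tsv: str | None = None
    single_cell: SingleCellInputs | None = None
    pwms_meme: str | None = None
    promoters_fasta: str | None = None
    masks_a: list[str] = []
    masks_b: list[str] = []
    eli_threshold: float = 0.5
    eli_method: str = "spearman"
    gsea: GseaParams = GseaParams()
    scan: ScanParams = ScanParams()
    profiling: ProfilingParams = ProfilingParams()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunResult:
    run_dir: Path
    manifest: dict
    scores: pd.DataFrame = None
    eli_set: genesets.GeneSet = None
    eli_d1: genesets.GeneSet = None
    overlap: pd.DataFrame = None
    transitions: pd.DataFrame = None
    sc_transitions: pd.DataFrame | None = None
    regressions: pd.DataFrame = None
    tf_ranking: pd.DataFrame = None
    profile_summary: pd.DataFrame = None
    comparisons: pd.DataFrame = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Run all configured stages in dependency order; see module docstring."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[dict] = []

    def emit(stage: str, name: str, writer) -> Path:
        path = run_dir / name
        writer(path)
        artifacts.append({"stage": stage, "name": name, "path": str(path), "sha256": _sha256(path)})
        return path

    result = RunResult(run_dir=run_dir, manifest={})

    # --- stage 1: ELI scoring -------------------------------------------------
    stage = "eli_scoring"
    try:
        expr = eli.read_expression_tsv(config.expression_tsv)
        idx = eli.read_invasion_index_tsv(config.invasion_index_tsv)
        scores = eli.compute_eli_scores(expr, idx, method=config.eli_method)
        result.scores = scores
        emit(stage, "eli_scores.tsv", lambda p: scores.to_csv(p, sep="\t", index=False))
        result.eli_set = eli.select_eli_genes(scores, config.eli_threshold)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 2: ELI-D1 construction ----------------------------------------
    stage = "geneset_builder"
    try:
        pathways = genesets.read_gmt(config.pathways_gmt)
        if len(result.eli_set) == 0:
            result.eli_d1 = genesets.GeneSet("ELI-D1", ())
        else:
            result.eli_d1, result.overlap = genesets.build_eli_d1(result.eli_set, pathways)
            emit(stage, "eli_d1.gmt", lambda p: genesets.write_gmt([result.eli_d1], p))
            emit(stage, "pathway_overlap.tsv", lambda p: result.overlap.to_csv(p, sep="\t", index=False))
            if config.decidual_fc_tsv:
                fc = pd.read_csv(config.decidual_fc_tsv, sep="\t")
                ann = genesets.annotate_decidual_fc(result.eli_d1, fc, scores=result.scores)
                emit(stage, "eli_d1_annotated.tsv", lambda p: ann.to_csv(p, sep="\t", index=False))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 3: stage-transition enrichment ---------------------------------
    stage = "enrichment"
    if len(result.eli_d1) == 0:
        raise PipelineError(stage, "no gene set: ELI selection/intersection left ELI-D1 empty")
    try:
        cohort = enrichment.read_cohort_tsv(
            config.cohort_expr_tsv, config.cohort_meta_tsv, config.stage_order
        )
        runs = enrichment.transition_scan(
            cohort, result.eli_d1,
            n_perm=config.gsea.n_perm, perm_type=config.gsea.perm_type,
            exponent=config.gsea.exponent, metric=config.gsea.metric, seed=config.gsea.seed,
        )
        result.transitions = enrichment.transitions_table(runs)
        emit(stage, "transition_enrichment.tsv",
             lambda p: result.transitions.to_csv(p, sep="\t", index=False))
        if config.single_cell is not None:
            cells = enrichment.read_cohort_tsv(
                config.single_cell.expr_tsv, config.single_cell.meta_tsv, config.stage_order
            )
            pb = enrichment.fibroblast_pseudobulk(
                cells, config.single_cell.target_type, config.single_cell.min_cells
            )
            sc_runs = enrichment.transition_scan(
                pb, result.eli_d1,
                n_perm=config.gsea.n_perm, perm_type=config.gsea.perm_type,
                exponent=config.gsea.exponent, metric=config.gsea.metric,
                seed=config.gsea.seed + 1,
            )
            result.sc_transitions = enrichment.transitions_table(sc_runs)
            emit(stage, "sc_transition_enrichment.tsv",
                 lambda p: result.sc_transitions.to_csv(p, sep="\t", index=False))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 4: TFBS regression --------------------------------------------
    stage = "tfbs_regression"
    if config.pwms_meme and config.promoters_fasta:
        try:
            pwms = tfbs.read_meme(config.pwms_meme)
            promoters = tfbs.read_promoters_fasta(config.promoters_fasta, config.scan.window)
            counts = tfbs.count_tfbs(pwms, promoters, config.scan.p_threshold)
            emit(stage, "tfbs_counts.tsv", lambda p: counts.to_csv(p, sep="\t", index=False))
            reg = tfbs.fit_tf_gene_regression(counts, expr)
            result.regressions = reg
            emit(stage, "tf_gene_regression.tsv", lambda p: reg.to_csv(p, sep="\t", index=False))
            bubble, rank = tfbs.tf_summary(reg, result.eli_d1)
            result.tf_ranking = rank
            emit(stage, "tf_ranking.tsv", lambda p: rank.to_csv(p, sep="\t", index=False))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # --- stage 5: invasion profiling ------------------------------------------
    stage = "invasion_profiling"
    if config.masks_a:
        try:
            prof = config.profiling

            def load(paths):
                return [
                    invasion.front_profile(
                        invasion.read_mask(p, prof.pixel_size_um, prof.baseline_row),
                        stride_px=prof.stride_px, smooth=prof.smooth,
                    )
                    for p in paths
                ]

            pa, pb = load(config.masks_a), load(config.masks_b) if config.masks_b else []
            rows = []
            for cond, profs in (("a", pa), ("b", pb)):
                for i, pr in enumerate(profs):
                    row = {"condition": cond, "replicate": i, "mean_depth_um": pr.depths_um.mean()}
                    for thr in prof.thresholds_um:
                        row[f"n_deeper_{int(thr)}um"] = invasion.count_deep_forks(pr, thr)
                    rows.append(row)
            result.profile_summary = pd.DataFrame(rows)
            emit(stage, "profile_summary.tsv",
                 lambda p: result.profile_summary.to_csv(p, sep="\t", index=False))
            if pa and pb:
                comps = []
                eff, pv = invasion.compare_conditions(pa, pb, "mean_depth")
                comps.append({"statistic": "mean_depth", "threshold_um": np.nan,
                              "effect": eff, "p_value": pv})
                for thr in prof.thresholds_um:
                    eff, pv = invasion.compare_conditions(pa, pb, "deep_fraction", thr)
                    comps.append({"statistic": "deep_fraction", "threshold_um": thr,
                                  "effect": eff, "p_value": pv})
                result.comparisons = pd.DataFrame(comps)
                emit(stage, "condition_comparison.tsv",
                     lambda p: result.comparisons.to_csv(p, sep="\t", index=False))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "artifacts": artifacts,
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    result.manifest = manifest
    return result


# ---------------------------------------------------------------------------
# synthetic bundle: one seeded directory exercising every stage


def write_bundle(
    out_dir,
    seed: int = 0,
    n_genes: int = 500,
    n_species: int = 9,
    n_eli_d1: int = 12,
    beta: float = 1.5,
    shift_d: float = 2.0,
    n_per_stage: int = 20,
    stages: tuple[str, ...] = ("T1", "T2", "T3"),
    n_decoy_tfs: int = 4,
    include_single_cell: bool = True,
    promoter_window: tuple[int, int] = (5000, 1000),
) -> tuple[dict, synthetic.SyntheticTruth]:
    """Write a complete synthetic input bundle with one coherent ground truth.

    The planted story mirrors the biological model end to end: two
    regulator TFs carry binding-site copy numbers that increase with the
    placental invasion index, driving expression of the planted candidate
    genes (hence high ELI scores); those genes sit in the decidual pathway
    files (hence they form ELI-D1); the tumor cohort loses them at the first
    stage transition (negative enrichment); and condition-B invasion masks
    carry uniformly shallower forks than condition A.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # invasion index over species (each level present)
    base_expr, index, _ = synthetic.gen_species_expression(
        n_genes=n_genes, n_species=n_species, n_planted=0, rho=0.0,
        noise_sd=1.0, seed=rng,
    )
    genes = list(base_expr.index)
    planted = sorted(rng.choice(genes, size=n_eli_d1, replace=False))
    half = n_eli_d1 // 2
    tf_targets = {"TF01": planted[:half], "TF02": planted[half:]}
    slope_map = {(tf, g): beta for tf, gs_ in tf_targets.items() for g in gs_}

    # planted copy numbers track the invasion index; decoy TFs get
    # index-independent counts (variance but no expression effect)
    idx_counts = (1 + index.to_numpy()).astype(int)
    counts = {pair: idx_counts for pair in slope_map}
    tf_names = [f"TF{i + 1:02d}" for i in range(2 + n_decoy_tfs)]
    for tf in tf_names[2:]:
        for g in planted:
            counts[(tf, g)] = rng.integers(0, 4, size=n_species)

    pwms, promoters, tf_expr, tf_truth = synthetic.gen_promoters_and_pwms(
        n_tfs=len(tf_names), n_genes=n_eli_d1, n_species=n_species,
        slope_map=slope_map, counts=counts, window=promoter_window,
        noise_sd=0.3, gene_names=planted, seed=rng,
    )
    expr = base_expr.copy()
    expr.loc[planted] = tf_expr.loc[planted].to_numpy()

    paths = {
        "expression_tsv": out / "expression.tsv",
        "invasion_index_tsv": out / "invasion_index.tsv",
        "pathways_gmt": out / "decidual_pathways.gmt",
        "decidual_fc_tsv": out / "decidual_fc.tsv",
        "cohort_expr_tsv": out / "cohort_expression.tsv",
        "cohort_meta_tsv": out / "cohort_meta.tsv",
        "pwms_meme": out / "tf_motifs.meme",
        "promoters_fasta": out / "promoters.fasta",
    }
    expr.to_csv(paths["expression_tsv"], sep="\t", index_label="gene")
    index.rename_axis("species").reset_index().to_csv(paths["invasion_index_tsv"], sep="\t", index=False)

    # decidual pathway files: planted genes split across three pathways plus decoys
    decoy_pool = [g for g in genes if g not in set(planted)]
    pw_members = {
        "CAMP_PKA_SIGNALING": planted[: half + 2],
        "PROGESTERONE_SIGNALING": planted[half + 2 : n_eli_d1 - 2],
        "PROSTAGLANDIN_BIOSYNTHESIS": planted[n_eli_d1 - 2 :],
    }
    pathway_sets = []
    for name, members in pw_members.items():
        decoys = list(rng.choice(decoy_pool, size=6, replace=False))
        externals = [f"EXT_{name[:4]}_{i}" for i in range(6)]
        pathway_sets.append(genesets.GeneSet(name, tuple(list(members) + decoys + externals)))
    genesets.write_gmt(genesets.GeneSetCollection(pathway_sets), paths["pathways_gmt"])

    fc = pd.DataFrame({
        "gene": genes,
        "log2fc": np.where(np.isin(genes, planted),
                           rng.normal(-1.2, 0.3, size=n_genes),
                           rng.normal(0.0, 0.3, size=n_genes)),
        "p_adj": np.clip(rng.uniform(0, 1, size=n_genes), 1e-6, 1.0),
    })
    fc.to_csv(paths["decidual_fc_tsv"], sep="\t", index=False)

    target = genesets.GeneSet("planted", tuple(planted))
    cohort, cohort_truth = synthetic.gen_stage_cohort(
        n_genes=n_genes, n_per_stage=n_per_stage, stages=stages,
        target_set=target, shift_d=shift_d, transition=(stages[0], stages[1]), seed=rng,
    )
    cohort.values.to_csv(paths["cohort_expr_tsv"], sep="\t", index_label="gene")
    cohort.meta.rename_axis("sample").reset_index().to_csv(paths["cohort_meta_tsv"], sep="\t", index=False)

    tfbs.write_meme(pwms, paths["pwms_meme"])
    tfbs.write_promoters_fasta(promoters, paths["promoters_fasta"])

    if include_single_cell:
        sc, _ = synthetic.gen_single_cell_cohort(
            n_genes=n_genes, stages=stages, n_patients_per_stage=4,
            n_cells_per_patient=40, frac_target=0.5, target_set=target,
            shift_d=shift_d, transition=(stages[0], stages[1]), seed=rng,
        )
        paths["sc_expr_tsv"] = out / "sc_expression.tsv"
        paths["sc_meta_tsv"] = out / "sc_meta.tsv"
        sc.values.to_csv(paths["sc_expr_tsv"], sep="\t", index_label="gene")
        sc.meta.rename_axis("cell").reset_index().to_csv(paths["sc_meta_tsv"], sep="\t", index=False)

    fork_sets_a = [
        [(60, 10, 150.0), (150, 8, 250.0), (300, 12, 120.0), (420, 6, 300.0)],
        [(80, 10, 180.0), (200, 8, 260.0), (350, 12, 140.0)],
        [(50, 10, 160.0), (180, 8, 240.0), (320, 12, 130.0), (440, 6, 280.0)],
    ]
    masks_a, masks_b = [], []
    all_forks = []
    for i, forks in enumerate(fork_sets_a):
        ma, ta = synthetic.gen_invasion_mask(forks=forks, seed=rng)
        shallow = [(c, w, d * 0.5) for c, w, d in forks]
        mb, _ = synthetic.gen_invasion_mask(forks=shallow, seed=rng)
        pa_, pb_ = out / f"mask_a_{i}.png", out / f"mask_b_{i}.png"
        invasion.write_mask(ma, pa_)
        invasion.write_mask(mb, pb_)
        masks_a.append(pa_)
        masks_b.append(pb_)
        all_forks += list(ta.planted_forks)
    paths["masks_a"] = masks_a
    paths["masks_b"] = masks_b

    truth = synthetic.SyntheticTruth(
        seed=seed,
        planted_eli_genes=tuple(planted),
        planted_enrichment_effect=shift_d,
        planted_transition=cohort_truth.planted_transition,
        planted_slopes=slope_map,
        planted_counts=tf_truth.planted_counts,
        planted_forks=tuple(all_forks),
        extras={"planted_tfs": ["TF01", "TF02"], "tf_names": tf_names,
                "pathways": {k: list(v) for k, v in pw_members.items()}},
    )
    truth.to_json(out / "truth.json")
    return paths, truth


def bundle_config(paths: dict, out_dir, seed: int = 0, stage_order=("T1", "T2", "T3")) -> PipelineConfig:
    """PipelineConfig pointing at a bundle written by :func:`write_bundle`."""
    cfg = PipelineConfig(
        out_dir=str(out_dir),
        expression_tsv=str(paths["expression_tsv"]),
        invasion_index_tsv=str(paths["invasion_index_tsv"]),
        pathways_gmt=str(paths["pathways_gmt"]),
        decidual_fc_tsv=str(paths["decidual_fc_tsv"]),
        cohort_expr_tsv=str(paths["cohort_expr_tsv"]),
        cohort_meta_tsv=str(paths["cohort_meta_tsv"]),
        stage_order=list(stage_order),
        pwms_meme=str(paths["pwms_meme"]),
        promoters_fasta=str(paths["promoters_fasta"]),
        masks_a=[str(p) for p in paths["masks_a"]],
        masks_b=[str(p) for p in paths["masks_b"]],
        gsea=GseaParams(seed=seed),
    )
    if "sc_expr_tsv" in paths:
        cfg.single_cell = SingleCellInputs(
            expr_tsv=str(paths["sc_expr_tsv"]), meta_tsv=str(paths["sc_meta_tsv"])
        )
    return cfg
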