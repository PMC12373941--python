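"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its arguments (including the seed) and
returns, alongside its outputs, a :class:`SyntheticTruth` describing exactly
what was planted — correlated genes, enrichment shifts, TF-gene slopes, fork
geometries — so downstream stages can be tested for parameter recovery
without any external data.

Modeling conventions: expression is simulated on the log2 scale with
Gaussian noise (matching the correlation / OLS assumptions downstream);
planted motif occurrences are exact consensus strings, which makes
binding-site copy numbers unambiguous at any sensible scan threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import StageCohort
from .genesets import GeneSet
from .invasion import InvasionMask
from .tfbs import DEFAULT_WINDOW, PWM, PromoterSet

__all__ = [
    "SyntheticTruth",
    "gen_species_expression",
    "gen_stage_cohort",
    "gen_single_cell_cohort",
    "gen_promoters_and_pwms",
    "gen_tf_counts_expression",
    "gen_invasion_mask",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SyntheticTruth:
    """Record of what a generator planted; must exactly describe its output."""

    seed: int | None = None
    planted_eli_genes: tuple[str, ...] = ()
    planted_enrichment_effect: float = 0.0
    planted_transition: str = ""
    planted_slopes: dict = field(default_factory=dict)  # (tf, gene) -> beta
    planted_counts: dict = field(default_factory=dict)  # (tf, gene) -> per-species counts
    planted_forks: tuple = ()  # (col_px, width_px, depth_um)
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def key(k):
            return "|".join(map(str, k)) if isinstance(k, tuple) else str(k)

        payload = {
            "seed": self.seed,
            "planted_eli_genes": list(self.planted_eli_genes),
            "planted_enrichment_effect": self.planted_enrichment_effect,
            "planted_transition": self.planted_transition,
            "planted_slopes": {key(k): v for k, v in self.planted_slopes.items()},
            "planted_counts": {key(k): (list(v) if hasattr(v, "__len__") else v)
                               for k, v in self.planted_counts.items()},
            "planted_forks": [list(f) for f in self.planted_forks],
            "extras": self.extras,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# cross-species expression


def gen_species_expression(
    n_genes: int = 1000,
    n_species: int = 9,
    n_planted: int = 10,
    rho: float = 0.9,
    noise_sd: float = 1.0,
    baseline: float = 8.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Species x gene expression with genes planted to track the invasion index.

    The invasion index takes values in {0,1,2,3} with each level represented
    at least once (hence ``n_species >= 4``). Planted genes follow
    ``baseline + a*index + N(0, noise_sd)`` with the slope ``a`` set from the
    realized index spread so the expected Pearson correlation with the index
    equals ``rho``; all other genes are index-independent noise.
    """
    if n_species < 4:
        raise ValueError("n_species must be >= 4 (each invasion level represented once)")
    if not 0 <= n_planted <= n_genes:
        raise ValueError("n_planted must lie in [0, n_genes]")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = _rng(seed)
    idx = np.concatenate([np.arange(4), rng.integers(0, 4, size=n_species - 4)])
    species = [f"sp{i + 1:02d}" for i in range(n_species)]
    genes = _gene_ids(n_genes)
    planted = tuple(sorted(rng.choice(genes, size=n_planted, replace=False))) if n_planted else ()

    noise = rng.normal(0.0, 1.0, size=(n_genes, n_species))
    expr = baseline + noise_sd * noise
    if n_planted:
        sd_idx = idx.std()
        if noise_sd == 0.0 or rho >= 1.0:
            a = 1.0
            if rho < 1.0 and noise_sd == 0.0:
                raise ValueError("noise_sd=0 forces correlation 1; set rho=1")
            if rho >= 1.0 and noise_sd > 0.0:
                raise ValueError("rho=1 requires noise_sd=0")
        else:
            a = noise_sd * rho / (sd_idx * np.sqrt(1.0 - rho**2))
        rows = [genes.index(g) for g in planted]
        expr[rows, :] = baseline + a * idx[None, :] + noise_sd * noise[rows, :]
    df = pd.DataFrame(expr, index=genes, columns=species)
    index = pd.Series(idx.astype(int), index=species, name="invasion_index")
    truth = SyntheticTruth(seed=seed if isinstance(seed, int) else None,
                           planted_eli_genes=planted, extras={"rho": rho, "noise_sd": noise_sd})
    return df, index, truth


# ---------------------------------------------------------------------------
# stage cohorts


def gen_stage_cohort(
    n_genes: int = 1000,
    n_per_stage: int = 20,
    stages: tuple[str, ...] = ("T1", "T2", "T3"),
    target_set: GeneSet | None = None,
    shift_d: float = 2.0,
    transition: tuple[str, str] | None = None,
    base_sd: float = 1.0,
    seed: int | None = None,
) -> tuple[StageCohort, SyntheticTruth]:
    """Stage-annotated cohort with a negative shift planted at one transition.

    From the later stage of the named transition onward, target-set genes are
    shifted by ``-shift_d * base_sd`` (the downward shift models loss of the
    vulnerability set as tumors progress). Applying the shift cumulatively
    keeps every other consecutive stage pair exchangeable, so only the named
    transition carries signal.
    """
    if len(stages) < 2:
        raise ValueError("need >= 2 stages")
    if target_set is not None and len(target_set) == 0:
        raise ValueError("target_set is empty")
    rng = _rng(seed)
    genes = _gene_ids(n_genes)
    if target_set is not None:
        missing = set(target_set.members) - set(genes)
        if missing:
            raise ValueError(f"target_set genes outside the universe: {sorted(missing)[:5]}")
    transition = transition or (stages[0], stages[1])
    if transition[0] not in stages or transition[1] not in stages:
        raise ValueError(f"transition {transition} not within stages {stages}")
    later_pos = list(stages).index(transition[1])

    mu = rng.normal(8.0, 1.0, size=n_genes)
    samples, stage_labels = [], []
    blocks = []
    for s_i, stage in enumerate(stages):
        X = mu[:, None] + base_sd * rng.normal(0.0, 1.0, size=(n_genes, n_per_stage))
        if target_set is not None and s_i >= later_pos and shift_d != 0.0:
            rows = [genes.index(g) for g in target_set.members]
            X[rows, :] -= shift_d * base_sd
        blocks.append(X)
        samples += [f"{stage}_s{j + 1:02d}" for j in range(n_per_stage)]
        stage_labels += [stage] * n_per_stage
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=samples)
    meta = pd.DataFrame({"stage": stage_labels, "patient": samples}, index=samples)
    cohort = StageCohort(values, meta, list(stages))
    truth = SyntheticTruth(
        seed=seed if isinstance(seed, int) else None,
        planted_eli_genes=tuple(target_set.members) if target_set is not None else (),
        planted_enrichment_effect=shift_d,
        planted_transition=f"{transition[0]}->{transition[1]}",
    )
    return cohort, truth


def gen_single_cell_cohort(
    n_genes: int = 300,
    stages: tuple[str, ...] = ("T1", "T2", "T3"),
    n_patients_per_stage: int = 4,
    n_cells_per_patient: int = 60,
    frac_target: float = 0.5,
    target_type: str = "fibroblast",
    other_type: str = "tumor",
    target_set: GeneSet | None = None,
    shift_d: float = 2.0,
    transition: tuple[str, str] | None = None,
    cell_sd: float = 1.0,
    patient_sd: float = 0.5,
    seed: int | None = None,
) -> tuple[StageCohort, SyntheticTruth]:
    """Cell-level cohort where the planted shift lives only in one cell type.

    Emulates the single-cell path: each patient contributes a mix of
    ``target_type`` cells (fibroblasts/CAFs, which carry the planted shift in
    stages at/after the named transition's later stage) and ``other_type``
    cells that never shift — so cell-type-restricted pseudobulk detects the
    signal while whole-tissue aggregation dilutes it. ``patient_sd`` adds a
    per-(patient, gene) random effect so pseudobulk variance stays
    patient-dominated, as in real cohorts, instead of vanishing with the
    cell count.
    """
    if target_set is not None and len(target_set) == 0:
        raise ValueError("target_set is empty")
    rng = _rng(seed)
    genes = _gene_ids(n_genes)
    transition = transition or (stages[0], stages[1])
    later_pos = list(stages).index(transition[1])
    rows = [genes.index(g) for g in target_set.members] if target_set is not None else []

    mu = rng.normal(8.0, 1.0, size=n_genes)
    n_target = int(round(frac_target * n_cells_per_patient))
    cols, stage_l, patient_l, type_l, blocks = [], [], [], [], []
    p_counter = 0
    for s_i, stage in enumerate(stages):
        for _ in range(n_patients_per_stage):
            p_counter += 1
            pid = f"P{p_counter:02d}"
            X = (
                mu[:, None]
                + patient_sd * rng.normal(0.0, 1.0, size=(n_genes, 1))
                + cell_sd * rng.normal(0.0, 1.0, size=(n_genes, n_cells_per_patient))
            )
            ctypes = [target_type] * n_target + [other_type] * (n_cells_per_patient - n_target)
            if rows and s_i >= later_pos and shift_d != 0.0:
                X[np.ix_(rows, range(n_target))] -= shift_d * cell_sd
            for j in range(n_cells_per_patient):
                cols.append(f"{pid}_c{j + 1:03d}")
            stage_l += [stage] * n_cells_per_patient
            patient_l += [pid] * n_cells_per_patient
            type_l += ctypes
            blocks.append(X)
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)
    meta = pd.DataFrame({"stage": stage_l, "patient": patient_l, "cell_type": type_l}, index=cols)
    cohort = StageCohort(values, meta, list(stages))
    truth = SyntheticTruth(
        seed=seed if isinstance(seed, int) else None,
        planted_eli_genes=tuple(target_set.members) if target_set is not None else (),
        planted_enrichment_effect=shift_d,
        planted_transition=f"{transition[0]}->{transition[1]}",
        extras={"target_type": target_type, "frac_target": frac_target},
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# promoters, PWMs, TFBS counts


def _random_consensi(n_tfs: int, length: int, rng: np.random.Generator) -> list[str]:
    """Distinct consensus strings with pairwise Hamming distance >= 3 in both
    orientations, so no motif's exact-match threshold can fire on another's
    planted sites."""

    def hamming(a: str, b: str) -> int:
        return sum(x != y for x, y in zip(a, b))

    def revcomp(s: str) -> str:
        return s.translate(_COMPLEMENT)[::-1]

    out: list[str] = []
    while len(out) < n_tfs:
        cand = "".join(rng.choice(_BASES, size=length))
        if all(min(hamming(cand, c), hamming(cand, revcomp(c))) >= 3 for c in out):
            out.append(cand)
    return out


def _consensus_pwm(name: str, consensus: str, major: float = 0.97) -> PWM:
    minor = (1.0 - major) / 3.0
    m = np.full((len(consensus), 4), minor)
    for i, b in enumerate(consensus):
        m[i, "ACGT".index(b)] = major
    return PWM(name, m)


def _find_all(seq: str, pattern: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = seq.find(pattern, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def gen_promoters_and_pwms(
    n_tfs: int = 4,
    n_genes: int = 10,
    n_species: int = 9,
    slope_map: dict[tuple[str, str], float] | None = None,
    window: tuple[int, int] = DEFAULT_WINDOW,
    counts: dict[tuple[str, str], np.ndarray] | None = None,
    noise_sd: float = 0.5,
    motif_length: int = 8,
    expr_baseline: float = 8.0,
    gene_names: list[str] | None = None,
    seed: int | None = None,
) -> tuple[list[PWM], PromoterSet, pd.DataFrame, SyntheticTruth]:
    """Per-species promoter FASTA material with planted motif copy numbers.

    For each (tf, gene) in ``counts`` (defaulting, for pairs in
    ``slope_map``, to a random assignment of 1..n_species sites across
    species), exact consensus occurrences are embedded non-overlapping in
    that gene's promoter in each species; background sequence is scrubbed of
    chance exact-consensus (or reverse-complement) occurrences so the scan
    count equals the planted count. Expression is generated as
    ``baseline + sum_tf beta * count + N(0, noise_sd)`` for genes with
    planted slopes, pure noise otherwise.
    """
    up, down = window
    length = up + down
    if length < motif_length:
        raise ValueError("promoter window shorter than the motif length")
    rng = _rng(seed)
    slope_map = dict(slope_map or {})
    tf_names = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    gene_names = list(gene_names) if gene_names is not None else _gene_ids(n_genes)
    n_genes = len(gene_names)
    for tf, gene in slope_map:
        if tf not in tf_names or gene not in gene_names:
            raise ValueError(f"slope_map pair ({tf}, {gene}) outside the declared grid")
    species = [f"sp{i + 1:02d}" for i in range(n_species)]

    consensi = _random_consensi(n_tfs, motif_length, rng)
    pwms = [_consensus_pwm(tf, cons) for tf, cons in zip(tf_names, consensi)]

    counts = dict(counts or {})
    for pair in slope_map:
        if pair not in counts:
            counts[pair] = rng.permutation(np.arange(1, n_species + 1))
    counts = {pair: np.asarray(c, dtype=int) for pair, c in counts.items()}
    for pair, c in counts.items():
        if c.size != n_species or (c < 0).any():
            raise ValueError(f"counts for {pair} must be {n_species} nonnegative integers")

    promoters = PromoterSet(window)
    for gene in gene_names:
        plant_here = {tf: counts[(tf, gene)] for tf in tf_names if (tf, gene) in counts}
        for s_i, sp in enumerate(species):
            seq = rng.choice(_BASES, size=length)
            protected = np.zeros(length, dtype=bool)
            # plant exact-consensus occurrences, non-overlapping
            for tf, per_species in plant_here.items():
                cons = consensi[tf_names.index(tf)]
                need = int(per_species[s_i])
                placed = 0
                attempts = 0
                while placed < need:
                    attempts += 1
                    if attempts > 10000:
                        raise RuntimeError("could not place non-overlapping motif occurrences")
                    start = int(rng.integers(0, length - motif_length + 1))
                    if protected[start : start + motif_length].any():
                        continue
                    seq[start : start + motif_length] = list(cons)
                    protected[start : start + motif_length] = True
                    placed += 1
            # scrub chance matches from the unprotected background
            for _ in range(60):
                dirty = False
                s = "".join(seq)
                for cons in consensi:
                    for pat in (cons, cons.translate(_COMPLEMENT)[::-1]):
                        for pos in _find_all(s, pat):
                            win = np.arange(pos, pos + motif_length)
                            free = win[~protected[win]]
                            if free.size == 0:
                                continue  # a planted site itself
                            seq[free] = rng.choice(_BASES, size=free.size)
                            dirty = True
                if not dirty:
                    break
            else:
                raise RuntimeError("background scrub did not converge")
            promoters.add(sp, gene, "".join(seq))

    expr = expr_baseline + noise_sd * rng.normal(0.0, 1.0, size=(n_genes, n_species))
    for (tf, gene), beta in slope_map.items():
        expr[gene_names.index(gene), :] += beta * counts[(tf, gene)]
    expr_df = pd.DataFrame(expr, index=gene_names, columns=species)
    truth = SyntheticTruth(
        seed=seed if isinstance(seed, int) else None,
        planted_slopes=dict(slope_map),
        planted_counts={pair: c.tolist() for pair, c in counts.items()},
        extras={"consensi": dict(zip(tf_names, consensi)), "window": list(window),
                "species": species, "noise_sd": noise_sd},
    )
    return pwms, promoters, expr_df, truth


def gen_tf_counts_expression(
    slope_map: dict[tuple[str, str], float],
    n_species: int = 9,
    counts: dict[tuple[str, str], np.ndarray] | None = None,
    noise_sd: float = 0.5,
    expr_baseline: float = 8.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Planted TFBS count table + expression, skipping sequence synthesis.

    Fast path for regression calibration: same statistical model as
    :func:`gen_promoters_and_pwms` (expression = baseline + beta * count +
    Gaussian noise) but counts are emitted directly as the long-format table
    :func:`invascope.tfbs.count_tfbs` would produce.
    """
    rng = _rng(seed)
    species = [f"sp{i + 1:02d}" for i in range(n_species)]
    counts = dict(counts or {})
    for pair in slope_map:
        if pair not in counts:
            counts[pair] = rng.permutation(np.arange(1, n_species + 1))
    counts = {pair: np.asarray(c, dtype=int) for pair, c in counts.items()}
    genes = sorted({g for _, g in counts})
    expr = pd.DataFrame(
        expr_baseline + noise_sd * rng.normal(0.0, 1.0, size=(len(genes), n_species)),
        index=genes, columns=species,
    )
    for (tf, gene), beta in slope_map.items():
        expr.loc[gene] += beta * counts[(tf, gene)]
    rows = [
        {"tf": tf, "gene": gene, "species": sp, "count": float(c[s_i]), "missing": False}
        for (tf, gene), c in sorted(counts.items())
        for s_i, sp in enumerate(species)
    ]
    truth = SyntheticTruth(
        seed=seed if isinstance(seed, int) else None,
        planted_slopes=dict(slope_map),
        planted_counts={pair: c.tolist() for pair, c in counts.items()},
        extras={"noise_sd": noise_sd},
    )
    return pd.DataFrame(rows), expr, truth


# ---------------------------------------------------------------------------
# invasion masks


def gen_invasion_mask(
    width_px: int = 500,
    height_px: int = 300,
    pixel_size_um: float = 2.0,
    baseline_row: int = 50,
    forks: list[tuple[int, int, float]] | None = None,
    noise_frac: float = 0.0,
    seed: int | None = None,
) -> tuple[InvasionMask, SyntheticTruth]:
    """Binary invasion mask: a filled front down to the baseline row plus
    rectangular forks of stated depths.

    Each fork is (column_px, width_px, depth_um); a fork of depth d um
    occupies the round(d / pixel_size) rows strictly below the baseline row,
    so with ``noise_frac = 0`` the per-column depth profile equals the
    planted geometry exactly. ``noise_frac`` flips that fraction of pixels
    (salt noise).
    """
    forks = list(forks or [])
    rng = _rng(seed)
    px = np.zeros((height_px, width_px), dtype=np.uint8)
    px[: baseline_row + 1, :] = 1  # undisturbed front occupies rows 0..baseline_row
    occupied: list[tuple[int, int]] = []
    for col, w, depth_um in forks:
        depth_px = int(round(depth_um / pixel_size_um))
        if col < 0 or col + w > width_px or w < 1:
            raise ValueError(f"fork at col={col} width={w} outside the image")
        if baseline_row + depth_px > height_px - 1:
            raise ValueError(
                f"fork depth {depth_um} um exceeds available depth "
                f"{(height_px - 1 - baseline_row) * pixel_size_um} um"
            )
        for lo, hi in occupied:
            if col < hi and col + w > lo:
                raise ValueError("forks overlap")
        occupied.append((col, col + w))
        px[baseline_row + 1 : baseline_row + 1 + depth_px, col : col + w] = 1
    if noise_frac:
        n_flip = int(round(noise_frac * px.size))
        flat = rng.choice(px.size, size=n_flip, replace=False)
        px.flat[flat] = 1 - px.flat[flat]
    mask = InvasionMask(px, pixel_size_um, baseline_row)
    truth = SyntheticTruth(
        seed=seed if isinstance(seed, int) else None,
        planted_forks=tuple((int(c), int(w), float(d)) for c, w, d in forks),
        extras={"noise_frac": noise_frac, "pixel_size_um": pixel_size_um},
    )
    return mask, truth
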