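"""TF binding-site scanning and cross-species copy-number regression.

Promoter windows (by default 5 kb upstream to 1 kb downstream of the
translation start) are scanned on both strands with position weight matrices.
A window is a hit when the p-value of its log-odds score under the background
base model is at or below the match threshold (1e-4 by default). The null
score distribution is exact: log-odds are discretized to integers at 1/1000
granularity and convolved position-by-position under the background
frequencies, the standard dynamic program used by FIMO-style scanners.

Per (TF, gene), the binding-site copy numbers across species are regressed
(ordinary least squares) on that gene's expression; the slope beta measures
how much expression moves per gained site over the evolutionary comparison,
and Benjamini-Hochberg across all (TF, gene) pairs flags significant fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PWM",
    "Hit",
    "read_meme",
    "write_meme",
    "PromoterSet",
    "read_promoters_fasta",
    "write_promoters_fasta",
    "scan_sequence",
    "count_tfbs",
    "fit_tf_gene_regression",
    "tf_summary",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
GRANULARITY = 1e-3  # log-odds discretization step for the exact null DP
DEFAULT_WINDOW = (5000, 1000)  # bp upstream / downstream of the translation start


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with background and pseudocount.

    ``matrix`` is (length, 4) over A,C,G,T; each row sums to 1. The
    pseudocount is mixed in as ``(p + c*bg) / (1 + c)`` before taking
    log-odds, so zero-probability entries stay finite.
    """

    tf_name: str
    matrix: np.ndarray
    background: np.ndarray = None  # type: ignore[assignment]
    pseudocount: float = 0.1

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 4:
            raise ValueError("PWM matrix must be (length >= 4) x 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM rows must sum to 1 (motif {self.tf_name})")
        object.__setattr__(self, "matrix", m)
        bg = np.full(4, 0.25) if self.background is None else np.asarray(self.background, dtype=float)
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.tf_name, self.matrix[::-1, ::-1], self.background[::-1], self.pseudocount)

    def log_odds(self) -> np.ndarray:
        p = (self.matrix + self.pseudocount * self.background[None, :]) / (1.0 + self.pseudocount)
        return np.log2(p / self.background[None, :])

    def int_scores(self) -> np.ndarray:
        """Log-odds discretized to integer units of GRANULARITY (length x 5;
        the 5th column scores N as background, i.e. 0)."""
        ints = np.rint(self.log_odds() / GRANULARITY).astype(np.int64)
        return np.hstack([ints, np.zeros((self.length, 1), dtype=np.int64)])

    def null_score_sf(self) -> tuple[np.ndarray, int]:
        """Exact survival function of the integer score under the background.

        Returns (sf, offset): ``sf[s - offset]`` = P(score >= s) for an
        integer score s, computed by convolving the four-point per-position
        distributions (dynamic programming over discretized scores). Cached
        on the instance after the first call.
        """
        cached = self.__dict__.get("_null_sf")
        if cached is not None:
            return cached
        ints = self.int_scores()[:, :4]
        lo = int(ints.min(axis=1).sum())
        hi = int(ints.max(axis=1).sum())
        cur = np.array([1.0])  # delta at score 0, convolved position by position
        cur_lo = 0
        for pos in range(self.length):
            row = ints[pos]
            rlo, rhi = int(row.min()), int(row.max())
            nxt = np.zeros(cur.size + (rhi - rlo))
            for b in range(4):
                nxt[row[b] - rlo : row[b] - rlo + cur.size] += self.background[b] * cur
            cur = nxt
            cur_lo += rlo
        assert cur_lo == lo and cur.size == hi - lo + 1
        sf = np.cumsum(cur[::-1])[::-1]
        object.__setattr__(self, "_null_sf", (sf, lo))
        return sf, lo

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest integer score whose null tail probability <= p_threshold."""
        sf, lo = self.null_score_sf()
        ok = np.nonzero(sf <= p_threshold)[0]
        if ok.size == 0:
            return lo + sf.size  # unattainable: no window can be a hit
        return lo + int(ok[0])


@dataclass(frozen=True)
class Hit:
    position: int  # 0-based window start on the forward strand
    strand: str  # '+' or '-'
    score: float  # log-odds (bits)
    p_value: float


def read_meme(path) -> list[PWM]:
    """Read motifs from MEME (minimal) motif format."""
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    lines = open(path).read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freqs = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freqs.get(b, 0.25) for b in _BASES])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = lines[i].strip()
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(1, w + 1):
                rows.append([float(x) for x in lines[i + j].split()[:4]])
            pwms.append(PWM(name, np.array(rows), background))
            i += w
        i += 1
    return pwms


def write_meme(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(_BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.tf_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= 20 E= 0\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


class PromoterSet:
    """Promoter sequences keyed by (species, gene), with a shared window.

    FASTA ids follow the convention ``<species>|<gene>``. Duplicate
    (species, gene) records are an error.
    """

    def __init__(self, window: tuple[int, int] = DEFAULT_WINDOW):
        self.window = tuple(window)
        self._seqs: dict[tuple[str, str], str] = {}

    def add(self, species: str, gene: str, sequence: str) -> None:
        key = (str(species), str(gene).upper())
        if key in self._seqs:
            raise ValueError(f"duplicate promoter record for species={key[0]} gene={key[1]}")
        self._seqs[key] = str(sequence).upper()

    def get(self, species: str, gene: str) -> str | None:
        return self._seqs.get((str(species), str(gene).upper()))

    def __len__(self) -> int:
        return len(self._seqs)

    def items(self):
        return self._seqs.items()

    @property
    def species(self) -> list[str]:
        return sorted({s for s, _ in self._seqs})

    @property
    def genes(self) -> list[str]:
        return sorted({g for _, g in self._seqs})


def read_promoters_fasta(path, window: tuple[int, int] = DEFAULT_WINDOW) -> PromoterSet:
    ps = PromoterSet(window)
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"promoter id {rec.id!r} does not follow '<species>|<gene>'")
        species, gene = rec.id.split("|", 1)
        ps.add(species, gene, str(rec.seq))
    return ps


def write_promoters_fasta(ps: PromoterSet, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=f"{species}|{gene}", description="")
        for (species, gene), seq in sorted(ps.items())
    ]
    SeqIO.write(recs, str(path), "fasta")


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(ints: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Integer score of every length-L window of enc (L x 5 integer table)."""
    L = ints.shape[0]
    n = enc.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    scores = np.zeros(n, dtype=np.int64)
    for pos in range(L):
        scores += ints[pos, enc[pos : pos + n]]
    return scores


def scan_sequence(pwm: PWM, seq: str, p_threshold: float = 1e-4, both_strands: bool = True) -> list[Hit]:
    """All motif hits in a sequence at the given match p-value threshold.

    Every window on the forward (and optionally reverse) strand is scored;
    windows whose exact null p-value is <= ``p_threshold`` are reported,
    overlaps included. Positions are 0-based window starts on the forward
    strand. Sequences shorter than the motif yield an empty list.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    enc = encode_sequence(seq)
    sf, lo = pwm.null_score_sf()
    hi = lo + sf.size - 1

    def pval(s: int) -> float:
        if s <= lo:
            return 1.0
        if s > hi:
            return float(sf[-1])
        return float(sf[s - lo])

    thr = pwm.score_threshold(p_threshold)
    hits: list[Hit] = []
    strands = [("+", pwm)] + ([("-", pwm.reverse_complement())] if both_strands else [])
    for strand, mat in strands:
        ints = mat.int_scores()
        scores = _window_scores(ints, enc)
        for pos in np.nonzero(scores >= thr)[0]:
            s = int(scores[pos])
            hits.append(Hit(int(pos), strand, s * GRANULARITY, pval(s)))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def count_tfbs(
    pwms: list[PWM],
    promoters: PromoterSet,
    p_threshold: float = 1e-4,
    species: list[str] | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Binding-site counts over the full (tf, gene, species) grid.

    Both strands are scanned and overlapping hits all count. Missing
    promoters yield ``count = NaN`` with ``missing = True`` (never a silent
    zero). Returns a long DataFrame (tf, gene, species, count, missing).
    """
    species = promoters.species if species is None else list(species)
    genes = promoters.genes if genes is None else list(genes)
    rows = []
    for pwm in pwms:
        for gene in genes:
            for sp in species:
                seq = promoters.get(sp, gene)
                if seq is None:
                    rows.append({"tf": pwm.tf_name, "gene": gene, "species": sp,
                                 "count": np.nan, "missing": True})
                else:
                    n = len(scan_sequence(pwm, seq, p_threshold))
                    rows.append({"tf": pwm.tf_name, "gene": gene, "species": sp,
                                 "count": float(n), "missing": False})
    return pd.DataFrame(rows)


def fit_tf_gene_regression(counts: pd.DataFrame, expr: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """OLS of expression on TFBS copy number across species, per (TF, gene).

    ``counts`` is the long table from :func:`count_tfbs`; ``expr`` is the
    genes x species log2 expression matrix. Pairs with fewer than 4 species
    carrying both values are skipped; zero count variance marks the fit
    degenerate (beta reported, no p). Benjamini-Hochberg across all tested
    pairs sets ``significant``.
    """
    expr = expr.copy()
    expr.index = expr.index.astype(str).str.upper()
    out = []
    for (tf, gene), grp in counts.groupby(["tf", "gene"], sort=True):
        g = str(gene).upper()
        if g not in expr.index:
            continue
        sp = [s for s in grp["species"] if s in expr.columns]
        sub = grp.set_index("species").loc[sp]
        ok = ~sub["missing"].astype(bool) & np.isfinite(sub["count"].astype(float))
        x = sub.loc[ok, "count"].to_numpy(dtype=float)
        y = expr.loc[g, sub.index[ok]].to_numpy(dtype=float)
        if x.size < 4:
            continue
        if np.var(x) == 0.0:
            out.append({"tf": tf, "gene": g, "beta": np.nan, "se": np.nan,
                        "p_value": np.nan, "n": x.size, "degenerate": True})
            continue
        fit = stats.linregress(x, y)
        out.append({"tf": tf, "gene": g, "beta": fit.slope, "se": fit.stderr,
                    "p_value": fit.pvalue, "n": x.size, "degenerate": False})
    table = pd.DataFrame(out)
    if len(table):
        table["significant"] = False
        tested = ~table["degenerate"]
        if tested.any():
            rej = multipletests(table.loc[tested, "p_value"], alpha=alpha, method="fdr_bh")[0]
            table.loc[tested, "significant"] = rej
    return table


def tf_summary(regressions: pd.DataFrame, gene_set=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bubble table plus per-TF ranking by number of significant target genes.

    Restricting to ``gene_set`` (when given) mirrors asking which TFs explain
    the candidate set's cross-species expression variance. Ranking ties break
    on TF id.
    """
    reg = regressions
    if gene_set is not None:
        members = set(gene_set.members)
        reg = reg[reg["gene"].isin(members)]
    bubble = reg[["tf", "gene", "beta", "p_value", "significant"]].reset_index(drop=True)
    rank = (
        reg.groupby("tf", sort=True)["significant"]
        .sum()
        .astype(int)
        .reset_index()
        .rename(columns={"significant": "n_significant"})
        .sort_values(["n_significant", "tf"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return bubble, rank


def tf_scatter_export(
    regressions: pd.DataFrame, counts: pd.DataFrame, expr: pd.DataFrame, tf: str
) -> pd.DataFrame:
    """Per-species export for one TF: copy number alongside each gene's raw
    expression and its deviation from the cross-species mean (the plotting
    transform is left to the caller)."""
    expr = expr.copy()
    expr.index = expr.index.astype(str).str.upper()
    sub = counts[(counts["tf"] == tf) & ~counts["missing"].astype(bool)]
    rows = []
    for _, r in sub.iterrows():
        g = str(r["gene"]).upper()
        if g not in expr.index or r["species"] not in expr.columns:
            continue
        e = float(expr.loc[g, r["species"]])
        rows.append({"tf": tf, "gene": g, "species": r["species"], "count": r["count"],
                     "expression": e, "deviation": e - float(expr.loc[g].mean())})
    return pd.DataFrame(rows)
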