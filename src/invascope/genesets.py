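"""Named gene sets, GMT I/O, and construction of the ELI-D1 candidate set.

The ELI-D1 set is the intersection of high-ELI-score genes (stromal genes
whose cross-species expression tracks placental invasion depth) with the
pathways that drive decidualization of endometrial fibroblasts
(prostaglandin biosynthesis, cAMP/PKA signaling, progesterone signaling).
Gene identity is matched on upper-cased symbols; an optional alias map can
be applied first to absorb synonym drift between resources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "build_eli_d1",
    "annotate_decidual_fc",
]


def _normalize(genes: Iterable[str], alias_map: Mapping[str, str] | None = None) -> tuple[str, ...]:
    out = []
    seen = set()
    for g in genes:
        g = str(g).strip().upper()
        if alias_map:
            g = str(alias_map.get(g, g)).upper()
        if g and g not in seen:
            seen.add(g)
            out.append(g)
    return tuple(out)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene symbols (upper-cased)."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValueError("GeneSet requires a nonempty name")
        object.__setattr__(self, "members", _normalize(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in set(self.members)

    def intersect(self, genes: Iterable[str]) -> "GeneSet":
        other = set(_normalize(genes))
        return GeneSet(self.name, tuple(g for g in self.members if g in other), self.description)


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets with unique names."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene set names in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def union_members(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out.update(s.members)
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, member genes)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
            sets.append(GeneSet(parts[0], tuple(parts[2:]), parts[1]))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection | Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or ".", *s.members]) + "\n")


def build_eli_d1(
    eli_genes: GeneSet,
    pathways: GeneSetCollection,
    alias_map: Mapping[str, str] | None = None,
    name: str = "ELI-D1",
) -> tuple[GeneSet, pd.DataFrame]:
    """Intersect selected ELI genes with decidualization pathway sets.

    Returns the combined candidate set (ELI genes that belong to the union of
    the pathways, each gene counted once) and a per-pathway overlap table with
    columns ``pathway`` and ``n_overlap`` (a gene in several pathways counts
    once in the set but once per pathway here), sorted by pathway name.
    """
    if len(eli_genes) == 0 or len(pathways) == 0:
        raise ValueError("build_eli_d1 requires nonempty ELI genes and pathways")
    eli = set(_normalize(eli_genes.members, alias_map))
    counts = []
    union: set[str] = set()
    for pw in pathways:
        mem = set(_normalize(pw.members, alias_map))
        union.update(mem)
        counts.append({"pathway": pw.name, "n_overlap": len(eli & mem)})
    members = tuple(sorted(eli & union))
    if not members:
        warnings.warn("ELI genes and decidual pathways are disjoint: ELI-D1 is empty")
    table = pd.DataFrame(counts).sort_values("pathway", kind="stable").reset_index(drop=True)
    gs = GeneSet(name, members, "ELI genes intersected with decidualization pathways")
    return gs, table


def annotate_decidual_fc(
    gs: GeneSet,
    fc: pd.DataFrame,
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate a gene set with decidualization fold changes (and ELI scores).

    ``fc`` needs columns ``gene`` and ``log2fc`` (``p_adj`` carried if
    present). Every member yields a row; members absent from ``fc`` keep NaN
    values and ``present=False`` rather than being dropped.
    """
    out = pd.DataFrame({"gene": list(gs.members)})
    cols = [c for c in ("log2fc", "p_adj") if c in fc.columns] if len(fc) else ["log2fc"]
    if len(fc):
        fc = fc.assign(gene=fc["gene"].astype(str).str.upper())
        out = out.merge(fc[["gene", *cols]], on="gene", how="left")
    else:
        for c in cols:
            out[c] = float("nan")
    out["present"] = out["log2fc"].notna() if "log2fc" in out.columns else False
    if scores is not None and "gene" in scores.columns and "score" in scores.columns:
        sc = scores.assign(gene=scores["gene"].astype(str).str.upper())
        out = out.merge(sc[["gene", "score"]], on="gene", how="left")
    return out
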