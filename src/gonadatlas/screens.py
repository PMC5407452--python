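"""Gene-set screens: early/late splits, Venn partitions, candidate
intersections, chromosome-Y and secreted-protein filters.

These are the set-operation procedures that turn per-contrast DE tables
into candidate lists: the pre-/post-steroidogenesis split of testis samples
around a boundary stage, the intersection of adrenal-up and late-testis-up
genes that nominates steroidogenesis components, exclusivity filters
between tissues, and annotation-driven screens (chromosome Y for
testis-determining candidates; signal-peptide/secreted flags for
circulating biomarkers). Gene symbols are upper-cased before any set
operation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diffexpr import GeneSet, select_de
from .synthetic_data import STAGE_ORDER

__all__ = [
    "VennResult",
    "split_early_late",
    "venn_counts",
    "steroidogenesis_candidates",
    "exclusive_set",
    "chrY_screen",
    "secreted_screen",
    "categorize_candidates",
]

VALID_CHROMOSOMES = {str(i) for i in range(1, 23)} | {"X", "Y", "MT", "unknown"}


@dataclass
class VennResult:
    """Region memberships of a 2- or 3-set Venn partition.

    Regions are keyed by a frozenset of the set names whose intersection
    (minus all other sets) the region is; e.g. for sets {A, B},
    frozenset({'A'}) is A-only and frozenset({'A','B'}) the overlap.
    """

    set_names: tuple[str, ...]
    regions: dict[frozenset, tuple[str, ...]]

    @property
    def counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def count(self, *names: str) -> int:
        return len(self.regions[frozenset(names)])


def split_early_late(meta: pd.DataFrame, tissue: str,
                     boundary: str = "CS23",
                     stage_order: Sequence[str] = STAGE_ORDER,
                     ) -> tuple[list[str], list[str]]:
    """Split a tissue's samples around a boundary stage.

    Returns (early, late) sample ids: early samples are at stages strictly
    before the boundary, late samples strictly after. Samples *at* the
    boundary stage sit on neither side of the time point and are excluded
    from both groups, mirroring the pre-/post-onset contrast design.
    """
    if boundary not in stage_order:
        raise ValueError(f"unknown boundary stage {boundary!r}")
    rank = {s: i for i, s in enumerate(stage_order)}
    cut = rank[boundary]
    sub = meta[meta["tissue"] == tissue]
    unknown = set(sub["stage"]) - set(rank)
    if unknown:
        raise ValueError(f"stages not in stage order: {sorted(unknown)}")
    early = sub.loc[sub["stage"].map(rank) < cut, "sample_id"].tolist()
    late = sub.loc[sub["stage"].map(rank) > cut, "sample_id"].tolist()
    return early, late


def venn_counts(sets: Sequence[GeneSet]) -> VennResult:
    """Exact region memberships for 2 or 3 gene sets."""
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"venn_counts supports 2 or 3 sets, got {len(sets)}")
    names = tuple(s.name for s in sets)
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    member = {s.name: s.as_set() for s in sets}
    union = sorted(set().union(*member.values()))
    regions: dict[frozenset, list[str]] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = []
    for gene in union:
        inside = frozenset(n for n in names if gene in member[n])
        regions[inside].append(gene)
    return VennResult(set_names=names,
                      regions={k: tuple(v) for k, v in regions.items()})


def _check_provenance(gene_set: GeneSet, expected_lfc: float) -> None:
    lfc = gene_set.provenance.get("lfc_cut")
    if lfc is None:
        warnings.warn(
            f"gene set {gene_set.name!r} carries no threshold provenance",
            RuntimeWarning)
    elif lfc != expected_lfc:
        warnings.warn(
            f"gene set {gene_set.name!r} was built with lfc_cut={lfc}, "
            f"expected {expected_lfc}", RuntimeWarning)


def steroidogenesis_candidates(adrenal_up: GeneSet, testis_late_up: GeneSet,
                               adrenal_lfc: Mapping[str, float] | None = None,
                               ) -> GeneSet:
    """Intersect adrenal-up (log2FC>=2 vs control) with late-testis-up
    (log2FC>=1 vs early) genes.

    Genes up-regulated in both screens are the steroidogenesis candidates;
    ordered by descending adrenal log2FC when provided, otherwise by the
    adrenal set's own order.
    """
    _check_provenance(adrenal_up, 2.0)
    _check_provenance(testis_late_up, 1.0)
    testis_members = testis_late_up.as_set()
    hits = [g for g in adrenal_up if g in testis_members]
    if adrenal_lfc is not None:
        lfc = {str(k).upper(): v for k, v in adrenal_lfc.items()}
        hits.sort(key=lambda g: (-lfc.get(g, float("-inf")), g))
    return GeneSet(name="steroidogenesis_candidates", members=tuple(hits),
                   provenance={"adrenal_set": adrenal_up.name,
                               "testis_set": testis_late_up.name})


def exclusive_set(target: GeneSet, others: Iterable[GeneSet],
                  name: str | None = None) -> GeneSet:
    """Members of ``target`` absent from every set in ``others``."""
    excluded = set()
    for s in others:
        excluded |= s.as_set()
    members = tuple(g for g in target if g not in excluded)
    return GeneSet(name=name or f"{target.name}_exclusive", members=members,
                   provenance={"target": target.name})


def chrY_screen(table: pd.DataFrame, annot: pd.DataFrame,
                lfc_cut: float = 1.0, q_cut: float = 0.05,
                protein_coding_only: bool = True) -> GeneSet:
    """Significantly up-regulated genes restricted to chromosome Y.

    ``annot`` is indexed by gene with a ``chromosome`` column (and
    optionally ``biotype``; when present and ``protein_coding_only`` is
    set, non-coding genes are dropped). Genes missing from the annotation
    are treated as chromosome 'unknown' and excluded with a warning.
    """
    up = select_de(table, lfc_cut, q_cut, direction="up", name="chrY_input")
    chrom = annot["chromosome"].astype(str).str.upper() \
        if len(annot) else pd.Series(dtype=str)
    covered = set(chrom.index.astype(str).str.upper())
    uncovered = [g for g in up if g not in covered]
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} selected genes lack annotation and are "
            "treated as chromosome 'unknown'", RuntimeWarning)
    chrom_map = {str(g).upper(): c for g, c in chrom.items()}
    hits = [g for g in up if chrom_map.get(g) == "Y"]
    if protein_coding_only and "biotype" in annot.columns:
        bt = {str(g).upper(): str(v) for g, v in annot["biotype"].items()}
        hits = [g for g in hits if bt.get(g, "protein_coding") == "protein_coding"]
    if not any(c == "Y" for c in chrom_map.values()):
        warnings.warn("annotation contains no chromosome-Y genes", RuntimeWarning)
    return GeneSet(name="chrY_up", members=tuple(hits),
                   provenance={"lfc_cut": lfc_cut, "q_cut": q_cut})


def secreted_screen(candidates: GeneSet, annot: pd.DataFrame) -> GeneSet:
    """Candidates flagged as secreted (signal-peptide annotation)."""
    if "secreted" not in annot.columns:
        raise ValueError("annotation lacks a 'secreted' column")
    flag = {str(g).upper(): bool(v) for g, v in annot["secreted"].items()}
    members = tuple(g for g in candidates if flag.get(g, False))
    return GeneSet(name=f"{candidates.name}_secreted", members=members,
                   provenance={"source": candidates.name})


def categorize_candidates(candidates: GeneSet, annot: pd.DataFrame,
                          novel_label: str = "Novel") -> pd.DataFrame:
    """Partition a candidate set by annotation category.

    Candidates without a category (missing from the annotation or with an
    empty label) fall into ``novel_label``. Returns a DataFrame with
    columns category, genes (comma-joined, input order), count; counts sum
    to the candidate set size.
    """
    cat_map = {}
    if "category" in annot.columns:
        cat_map = {str(g).upper(): str(v) for g, v in annot["category"].items()}
    buckets: dict[str, list[str]] = {}
    for g in candidates:
        cat = cat_map.get(g, "") or novel_label
        buckets.setdefault(cat, []).append(g)
    rows = [{"category": c, "genes": ",".join(genes), "count": len(genes)}
            for c, genes in sorted(buckets.items())]
    return pd.DataFrame(rows, columns=["category", "genes", "count"])
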