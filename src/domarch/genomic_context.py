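"""Codirectional gene neighborhoods around PDZ-coding genes.

A gene is a neighbor when it is codirectional (same strand, same replicon)
and within ``max_gap`` nucleotides of the growing cluster (default 50;
E. coli-style analyses use 300).  Extension is transitive by default —
operon-style runs of genes each within the gap of the previous one — with a
pairwise-to-anchor-only mode available.  Replicons are treated as linear;
the origin junction of circular replicons is not joined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import GeneRecord

__all__ = [
    "NeighborhoodCluster",
    "intergenic_distance",
    "gene_gap",
    "find_neighborhood",
    "find_all_neighborhoods",
    "conserved_neighbors",
    "write_clusters",
]


@dataclass(frozen=True)
class NeighborhoodCluster:
    """One codirectional gene cluster anchored on a PDZ-coding gene."""

    genome_id: str
    anchor: GeneRecord
    members: tuple[GeneRecord, ...]
    gaps: tuple[int, ...]
    max_gap: int = 50

    def __post_init__(self) -> None:
        if self.anchor not in self.members:
            raise ValueError("anchor must be a cluster member")
        if len(self.gaps) != max(0, len(self.members) - 1):
            raise ValueError("need one gap per consecutive member pair")

    @property
    def neighbor_keys(self) -> tuple[str, ...]:
        """Gene names (locus tag fallback) of non-anchor members."""
        return tuple(
            (g.gene_name or g.locus_tag) for g in self.members if g != self.anchor
        )


def intergenic_distance(a: GeneRecord, b: GeneRecord) -> int:
    """Number of bases strictly between two genes: start(b) - end(a) - 1.

    Requires ``a`` upstream of and disjoint from ``b`` on the same replicon;
    for possibly-overlapping neighbors use :func:`gene_gap`.
    """
    if a.replicon_id != b.replicon_id:
        raise ValueError(f"genes on different replicons: {a.replicon_id!r} vs {b.replicon_id!r}")
    if a.end >= b.start:
        raise ValueError("intergenic_distance requires a.end < b.start")
    return b.start - a.end - 1


def gene_gap(a: GeneRecord, b: GeneRecord) -> int:
    """Intergenic distance clamped at zero: overlapping or abutting genes
    (common in prokaryotes) count as distance 0."""
    if a.replicon_id != b.replicon_id:
        raise ValueError(f"genes on different replicons: {a.replicon_id!r} vs {b.replicon_id!r}")
    first, second = (a, b) if a.start <= b.start else (b, a)
    return max(0, second.start - first.end - 1)


def find_neighborhood(
    genes: Sequence[GeneRecord],
    anchor: GeneRecord,
    max_gap: int = 50,
    genome_id: str = "",
    pairwise_only: bool = False,
) -> NeighborhoodCluster:
    """Extend the codirectional cluster around ``anchor`` in both directions.

    ``genes`` must be sorted by start.  A candidate joins while it is on the
    anchor's replicon and strand and its gap — to the previous member
    (transitive chain, default) or to the anchor itself (``pairwise_only``) —
    is at most ``max_gap``; extension stops at the first violation in each
    direction.
    """
    if anchor not in genes:
        raise ValueError(f"anchor {anchor.locus_tag!r} not in gene list")
    starts = [g.start for g in genes]
    if starts != sorted(starts):
        raise ValueError("genes must be sorted by start")
    same_rep = [g for g in genes if g.replicon_id == anchor.replicon_id]
    i = same_rep.index(anchor)

    left: list[GeneRecord] = []
    prev = anchor
    for g in reversed(same_rep[:i]):
        if g.strand != anchor.strand:
            break
        ref = anchor if pairwise_only else prev
        if gene_gap(g, ref) > max_gap:
            break
        left.append(g)
        prev = g
    right: list[GeneRecord] = []
    prev = anchor
    for g in same_rep[i + 1 :]:
        if g.strand != anchor.strand:
            break
        ref = anchor if pairwise_only else prev
        if gene_gap(ref, g) > max_gap:
            break
        right.append(g)
        prev = g

    members = tuple(reversed(left)) + (anchor,) + tuple(right)
    gaps = tuple(gene_gap(members[k], members[k + 1]) for k in range(len(members) - 1))
    return NeighborhoodCluster(
        genome_id=genome_id, anchor=anchor, members=members, gaps=gaps, max_gap=max_gap
    )


def find_all_neighborhoods(
    genes: Sequence[GeneRecord],
    anchors: Iterable[GeneRecord],
    max_gap: int = 50,
    genome_id: str = "",
    pairwise_only: bool = False,
) -> list[NeighborhoodCluster]:
    genes = sorted(genes, key=lambda g: (g.start, g.end, g.locus_tag))
    return [
        find_neighborhood(genes, a, max_gap=max_gap, genome_id=genome_id,
                          pairwise_only=pairwise_only)
        for a in anchors
    ]


def conserved_neighbors(
    clusters: Sequence[NeighborhoodCluster],
    key: str = "gene_name",
) -> pd.DataFrame:
    """Count, per non-anchor neighbor key, the distinct genomes whose
    cluster contains it.

    ``key`` is ``"gene_name"`` (locus-tag fallback for unnamed genes) or
    ``"product"``.  Genes with an empty key aggregate under ``"unnamed"``.
    Returns a DataFrame with columns ``neighbor`` and ``n_genomes`` sorted by
    descending count, then name.
    """
    if not clusters:
        raise ValueError("need at least one cluster")
    if key not in ("gene_name", "product"):
        raise ValueError(f"unknown key {key!r}")
    genomes_by_key: dict[str, set[str]] = {}
    for c in clusters:
        for g in c.members:
            if g == c.anchor:
                continue
            if key == "gene_name":
                k = g.gene_name or g.locus_tag
            else:
                k = g.product
            k = k or "unnamed"
            genomes_by_key.setdefault(k, set()).add(c.genome_id)
    rows = sorted(
        ((k, len(v)) for k, v in genomes_by_key.items()),
        key=lambda t: (-t[1], t[0]),
    )
    return pd.DataFrame(rows, columns=["neighbor", "n_genomes"])


def write_clusters(clusters: Sequence[NeighborhoodCluster], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("genome_id\tanchor_locus\tmember_loci\tmember_names\tgaps\tstrand\n")
        for c in clusters:
            fh.write(
                f"{c.genome_id}\t{c.anchor.locus_tag}\t"
                f"{','.join(g.locus_tag for g in c.members)}\t"
                f"{','.join((g.gene_name or g.locus_tag) for g in c.members)}\t"
                f"{','.join(str(g) for g in c.gaps)}\t{c.anchor.strand.value}\n"
            )
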