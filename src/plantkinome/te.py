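"""Transposable-element proximity analysis.

A kinase gene is "TE-associated" when at least one TE lies within a fixed
genomic window (default 100 kb) of the gene on the same chromosome, with
distance measured between nearest feature boundaries (0 for overlap).
The association is computed with an interval index over TE intervals
extended by the window, so each gene query is a single stab plus distance
check.  Summaries report the associated fraction of the kinome, the overlap
with tandem duplication status, and the TE class composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .duplication import TandemCluster, tandem_gene_ids
from .identify import KinaseGene
from .io import TERecord

DEFAULT_WINDOW = 100_000


@dataclass(frozen=True)
class TEAssociation:
    gene_id: str
    te: TERecord
    distance: int  # 0 when overlapping


def _gene_te_distance(gene: KinaseGene, te: TERecord) -> int:
    """Boundary distance between a gene (1-based inclusive) and a TE (0-based half-open)."""
    g_start0, g_end0 = gene.start - 1, gene.end  # to 0-based half-open
    if te.end <= g_start0:
        return g_start0 - te.end
    if te.start >= g_end0:
        return te.start - g_end0
    return 0


def associate_tes(
    genes: Sequence[KinaseGene],
    tes: Sequence[TERecord],
    window: int = DEFAULT_WINDOW,
    known_chromosomes: set[str] | None = None,
) -> dict[str, list[TEAssociation]]:
    """Map each gene to the TEs within ``window`` bp on its chromosome.

    TEs on chromosomes absent from the gene set (or from
    ``known_chromosomes`` when given) trigger a warning and are skipped.
    Returns an entry for every gene (possibly empty).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    gene_chroms = {g.chromosome for g in genes}
    valid = known_chromosomes if known_chromosomes is not None else gene_chroms
    trees: dict[str, IntervalTree] = {}
    for te in tes:
        if te.chromosome not in valid:
            warnings.warn(
                f"TE {te.te_id} on unknown chromosome {te.chromosome}; skipped",
                stacklevel=2,
            )
            continue
        trees.setdefault(te.chromosome, IntervalTree()).addi(
            max(0, te.start - window), te.end + window, te
        )
    out: dict[str, list[TEAssociation]] = {}
    for gene in genes:
        hits: list[TEAssociation] = []
        tree = trees.get(gene.chromosome)
        if tree is not None:
            for iv in tree.overlap(gene.start - 1, gene.end):
                te = iv.data
                d = _gene_te_distance(gene, te)
                if d <= window:
                    hits.append(TEAssociation(gene.gene_id, te, d))
        hits.sort(key=lambda a: (a.distance, a.te.start, a.te.te_id))
        out[gene.gene_id] = hits
    return out


def associations_brute_force(
    genes: Sequence[KinaseGene], tes: Sequence[TERecord], window: int = DEFAULT_WINDOW
) -> dict[str, set[str]]:
    """All-pairs reference implementation (for cross-checking the index)."""
    out: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    for g in genes:
        for te in tes:
            if te.chromosome == g.chromosome and _gene_te_distance(g, te) <= window:
                out[g.gene_id].add(te.te_id)
    return out


def summarize_te_overlap(
    associations: Mapping[str, list[TEAssociation]],
    kinome: Sequence[KinaseGene],
    tandem_clusters: Sequence[TandemCluster],
) -> dict:
    """Counts and fractions linking TE proximity with tandem duplication.

    Fractions are percentages: associated/kinome, associated-and-tandem/
    associated, and the TE class composition of associated TEs.
    """
    n_kinome = len(kinome)
    associated = {g for g, hits in associations.items() if hits}
    tandem = tandem_gene_ids(tandem_clusters)
    assoc_tandem = associated & tandem
    class_counts: dict[str, int] = {}
    te_seen: set[str] = set()
    for hits in associations.values():
        for a in hits:
            if a.te.te_id not in te_seen:
                te_seen.add(a.te.te_id)
                class_counts[a.te.te_class] = class_counts.get(a.te.te_class, 0) + 1
    group_counts: dict[str, int] = {}
    for k in kinome:
        if k.gene_id in associated:
            group_counts[k.group] = group_counts.get(k.group, 0) + 1
    n_te = sum(class_counts.values())
    return {
        "n_kinome": n_kinome,
        "n_associated": len(associated),
        "pct_associated": 100.0 * len(associated) / n_kinome if n_kinome else 0.0,
        "n_associated_tandem": len(assoc_tandem),
        "pct_associated_tandem": (
            100.0 * len(assoc_tandem) / len(associated) if associated else 0.0
        ),
        "te_class_counts": dict(sorted(class_counts.items())),
        "te_class_pct": {
            c: 100.0 * n / n_te for c, n in sorted(class_counts.items())
        } if n_te else {},
        "group_counts": dict(sorted(group_counts.items())),
    }


def associations_to_frame(
    associations: Mapping[str, list[TEAssociation]]
) -> pd.DataFrame:
    rows = [
        {
            "gene_id": g, "te_id": a.te.te_id, "te_class": a.te.te_class,
            "distance": a.distance,
        }
        for g in sorted(associations)
        for a in associations[g]
    ]
    return pd.DataFrame(rows, columns=["gene_id", "te_id", "te_class", "distance"])
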