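"""Tandem and segmental duplication detection among kinase genes.

Duplication calls rest on all-vs-all nucleotide similarity of kinase CDSs.
The search is an ungapped seed-and-extend scan (shared k-mer seeds, X-drop
extension) scored with the classic nucleotide scheme (+2 match / -3
mismatch); significance uses the Karlin-Altschul formula
``E = K * m * n * exp(-lambda * S)`` with the ungapped parameters for that
scheme (lambda = 0.625, K = 0.41).

A tandem duplication event (TDE) is a single-linkage connected component
(size >= 2) of same-chromosome gene pairs separated by at most 25 kb
(nearest gene boundaries) with identity >= 95%, coverage >= 75% of the
shorter CDS and E <= 1e-10.  Segmental correspondences are pairs separated
by more than 100 kb or on different chromosomes, tiered by identity
(> 90% / 75% / 50% by default); tiers are nested by construction.  Pairs in
the 25-100 kb same-chromosome dead zone are reported separately as
"unclassified proximal".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .identify import KinaseGene

# Karlin-Altschul parameters for the ungapped +2/-3 nucleotide scheme.
KA_LAMBDA = 0.625
KA_K = 0.41
MATCH_SCORE = 2
MISMATCH_SCORE = -3
SEED_K = 11
XDROP = 40

DEFAULT_ID_MIN = 0.95
DEFAULT_COV_MIN = 0.75
DEFAULT_EVALUE_MAX = 1e-10
DEFAULT_MAX_GAP = 25_000
DEFAULT_MIN_SEPARATION = 100_000
DEFAULT_TIERS = (0.90, 0.75, 0.50)


@dataclass(frozen=True)
class SimilarityPair:
    """An unordered pair of similar CDSs (stored with gene_id_a < gene_id_b)."""

    gene_id_a: str
    gene_id_b: str
    identity: float
    coverage: float
    evalue: float

    def __post_init__(self) -> None:
        if self.gene_id_a >= self.gene_id_b:
            raise ValueError("pair must be stored with gene_id_a < gene_id_b")
        if not (0 <= self.identity <= 1 and 0 <= self.coverage <= 1):
            raise ValueError("identity and coverage must be fractions")


@dataclass
class TandemCluster:
    cluster_id: int
    chromosome: str
    members: list[str]
    subfamilies: dict[str, str] = field(default_factory=dict)


@dataclass
class SegmentalTier:
    threshold: float
    pairs: list[SimilarityPair] = field(default_factory=list)


# --------------------------------------------------------------------------
# Seed-and-extend similarity search
# --------------------------------------------------------------------------

def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i:i + k], []).append(i)
    return idx


def _extend_hsp(a: str, b: str, i: int, j: int, k: int) -> tuple[int, int, int, int]:
    """Extend an exact k-mer seed at (i, j) in both directions with X-drop.

    Returns (a_start, length, matches, score) of the best ungapped HSP
    through the seed.
    """
    score = k * MATCH_SCORE
    matches = k
    best_score, best_left, best_right = score, 0, 0
    # right extension
    s, m, step = score, matches, 0
    x, y = i + k, j + k
    right_m = 0
    while x < len(a) and y < len(b):
        step += 1
        if a[x] == b[y]:
            s += MATCH_SCORE
            m += 1
        else:
            s += MISMATCH_SCORE
        if s > best_score:
            best_score, best_right, right_m = s, step, m - matches
        if s < best_score - XDROP:
            break
        x += 1
        y += 1
    score_after_right = best_score
    matches += right_m
    # left extension
    s, m, step = score_after_right, 0, 0
    x, y = i - 1, j - 1
    left_m = 0
    while x >= 0 and y >= 0:
        step += 1
        if a[x] == b[y]:
            s += MATCH_SCORE
            m += 1
        else:
            s += MISMATCH_SCORE
        if s > best_score:
            best_score, best_left, left_m = s, step, m
        if s < best_score - XDROP:
            break
        x -= 1
        y -= 1
    matches += left_m
    length = k + best_left + best_right
    return i - best_left, length, matches, best_score


def align_pair(
    a: str, b: str, index_a: dict[str, list[int]] | None = None
) -> tuple[float, float, float] | None:
    """Best ungapped HSP between two sequences.

    Returns (identity, coverage_of_shorter, evalue) or None when no seed is
    shared.  ``index_a`` may supply a precomputed k-mer index of the
    shorter sequence.
    """
    if len(a) < SEED_K or len(b) < SEED_K:
        return None
    if len(a) > len(b):  # index the shorter sequence
        a, b = b, a
        index_a = None
    index = index_a if index_a is not None else _kmer_positions(a, SEED_K)
    best = None  # (score, a_start, length, matches)
    seen: set[int] = set()  # diagonals already explained by an HSP
    for j in range(len(b) - SEED_K + 1):
        kmer = b[j:j + SEED_K]
        for i in index.get(kmer, ()):
            diag = j - i
            if diag in seen:
                continue
            a0, length, matches, score = _extend_hsp(a, b, i, j, SEED_K)
            seen.add(diag)
            if best is None or score > best[0]:
                best = (score, a0, length, matches)
    if best is None:
        return None
    score, _, length, matches = best
    identity = matches / length
    coverage = length / min(len(a), len(b))
    evalue = KA_K * len(a) * len(b) * math.exp(-KA_LAMBDA * score)
    return identity, coverage, evalue


def similarity_search(
    cds: Mapping[str, str],
    id_min: float = 0.0,
    cov_min: float = 0.0,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[SimilarityPair]:
    """All-vs-all CDS similarity.

    Reports every unordered pair whose best HSP satisfies all three
    thresholds; self-pairs are excluded.
    """
    if len(cds) < 2:
        raise ValueError("need at least two sequences")
    ids = sorted(cds)
    kmer_index = {g: _kmer_positions(cds[g], SEED_K) for g in ids}
    pairs: list[SimilarityPair] = []
    for idx_a in range(len(ids)):
        for idx_b in range(idx_a + 1, len(ids)):
            ga, gb = ids[idx_a], ids[idx_b]
            if len(cds[ga]) > len(cds[gb]):
                ga_s, gb_s = gb, ga
            else:
                ga_s, gb_s = ga, gb
            result = align_pair(cds[ga_s], cds[gb_s], index_a=kmer_index[ga_s])
            if result is None:
                continue
            identity, coverage, evalue = result
            if identity >= id_min and coverage >= cov_min and evalue <= evalue_max:
                pairs.append(SimilarityPair(ga, gb, identity, min(coverage, 1.0), evalue))
    return pairs


# --------------------------------------------------------------------------
# Tandem clusters
# --------------------------------------------------------------------------

def boundary_gap(a: KinaseGene, b: KinaseGene) -> int | None:
    """Distance between nearest gene boundaries; 0 if overlapping; None across chromosomes."""
    if a.chromosome != b.chromosome:
        return None
    if a.start > b.start:
        a, b = b, a
    return max(0, b.start - a.end)


def detect_tandem_clusters(
    kinases: Sequence[KinaseGene],
    pairs: Sequence[SimilarityPair],
    max_gap: int = DEFAULT_MAX_GAP,
    id_min: float = DEFAULT_ID_MIN,
    cov_min: float = DEFAULT_COV_MIN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[TandemCluster]:
    """Single-linkage tandem clusters from qualifying similarity pairs.

    A qualifying edge requires same chromosome, boundary gap <= ``max_gap``,
    identity >= ``id_min``, coverage >= ``cov_min`` and E <= ``evalue_max``.
    Clusters are connected components of size >= 2; each gene belongs to at
    most one cluster.
    """
    genes = {k.gene_id: k for k in kinases}
    parent: dict[str, str] = {g: g for g in genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in pairs:
        if p.gene_id_a not in genes or p.gene_id_b not in genes:
            raise KeyError(f"pair references unknown gene: {p.gene_id_a}/{p.gene_id_b}")
        if p.identity < id_min or p.coverage < cov_min or p.evalue > evalue_max:
            continue
        gap = boundary_gap(genes[p.gene_id_a], genes[p.gene_id_b])
        if gap is None or gap > max_gap:
            continue
        ra, rb = find(p.gene_id_a), find(p.gene_id_b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    components: dict[str, list[str]] = {}
    for g in sorted(genes):
        components.setdefault(find(g), []).append(g)
    clusters: list[TandemCluster] = []
    for root in sorted(components):
        members = components[root]
        if len(members) < 2:
            continue
        clusters.append(
            TandemCluster(
                cluster_id=len(clusters),
                chromosome=genes[members[0]].chromosome,
                members=members,
                subfamilies={g: genes[g].subfamily for g in members},
            )
        )
    return clusters


def tandem_gene_ids(clusters: Sequence[TandemCluster]) -> set[str]:
    return {g for cl in clusters for g in cl.members}


def per_chromosome_summary(clusters: Sequence[TandemCluster]) -> pd.DataFrame:
    """TDE and member-gene counts per chromosome."""
    rows: dict[str, dict[str, int]] = {}
    for cl in clusters:
        entry = rows.setdefault(cl.chromosome, {"n_clusters": 0, "n_genes": 0})
        entry["n_clusters"] += 1
        entry["n_genes"] += len(cl.members)
    return (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("chromosome")
        .sort_index()
        .reset_index()
    )


# --------------------------------------------------------------------------
# Segmental tiers
# --------------------------------------------------------------------------

def tier_segmental(
    kinases: Sequence[KinaseGene],
    pairs: Sequence[SimilarityPair],
    thresholds: Sequence[float] = DEFAULT_TIERS,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> list[SegmentalTier]:
    """Tier long-range/cross-chromosome correspondences by identity.

    A pair enters tier ``t`` iff identity > t AND (different chromosomes OR
    boundary gap > ``min_separation``); thresholds must be descending and
    the resulting tiers are nested.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be descending")
    genes = {k.gene_id: k for k in kinases}
    tiers = [SegmentalTier(threshold=t) for t in thresholds]
    for p in pairs:
        gap = boundary_gap(genes[p.gene_id_a], genes[p.gene_id_b])
        segmental = gap is None or gap > min_separation
        if not segmental:
            continue
        for tier in tiers:
            if p.identity > tier.threshold:
                tier.pairs.append(p)
    return tiers


def unclassified_proximal(
    kinases: Sequence[KinaseGene],
    pairs: Sequence[SimilarityPair],
    max_gap: int = DEFAULT_MAX_GAP,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> list[SimilarityPair]:
    """Same-chromosome pairs in the gap dead zone (> max_gap, <= min_separation)."""
    genes = {k.gene_id: k for k in kinases}
    out = []
    for p in pairs:
        gap = boundary_gap(genes[p.gene_id_a], genes[p.gene_id_b])
        if gap is not None and max_gap < gap <= min_separation:
            out.append(p)
    return out


def pairs_to_frame(pairs: Sequence[SimilarityPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id_a": p.gene_id_a, "gene_id_b": p.gene_id_b,
                "identity": p.identity, "coverage": p.coverage, "evalue": p.evalue,
            }
            for p in pairs
        ]
    )


def clusters_to_frame(clusters: Sequence[TandemCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": cl.cluster_id, "chromosome": cl.chromosome,
                "genes": ",".join(cl.members),
                "subfamilies": ",".join(sorted(set(cl.subfamilies.values()))),
            }
            for cl in clusters
        ]
    )
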