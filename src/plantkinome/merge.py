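"""Non-redundant merge of kinase sets from two genome assemblies.

When a genome is available both as a chromosome-level and a scaffold-level
assembly, the kinases identified in each are combined into a single
kinome with greedy incremental identity clustering (the CD-HIT strategy:
sequences sorted by descending length, each joining the first cluster
whose representative it matches) followed by two retention rules:

* rule i  — a cluster with exactly one member from each source keeps the
  longest member;
* rule ii — a cluster with more than one member in either source keeps all
  members of the source contributing more members (a putative duplication
  should not be collapsed by the other assembly's single copy);
* singletons are kept as-is.

Defaults: minimum pairwise identity 0.95 and minimum length ratio
(shorter/longer) 0.75, the CD-HIT ``-c``/``-s`` semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from Bio import Align

from .identify import KinaseGene

DEFAULT_ID_MIN = 0.95
DEFAULT_LEN_RATIO_MIN = 0.75


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _local_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Identity and coverage of the best local alignment of two sequences.

    identity = matches / alignment columns; coverage = aligned length of
    the shorter sequence / its full length.  Returns (0.0, 0.0) when no
    positive-scoring local alignment exists.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    try:
        alignment = _ALIGNER.align(seq_a, seq_b)[0]
    except (IndexError, ValueError):
        return 0.0, 0.0
    if alignment.score <= 0:
        return 0.0, 0.0
    matches = 0
    columns = 0
    aligned_short = 0
    shorter_is_a = len(seq_a) <= len(seq_b)
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            columns += 1
            if seq_a[i] == seq_b[j]:
                matches += 1
        aligned_short += (a1 - a0) if shorter_is_a else (b1 - b0)
    # count gap columns between aligned blocks
    blocks_a, blocks_b = alignment.aligned
    for k in range(1, len(blocks_a)):
        columns += (blocks_a[k][0] - blocks_a[k - 1][1]) + (blocks_b[k][0] - blocks_b[k - 1][1])
    if columns == 0:
        return 0.0, 0.0
    identity = matches / columns
    coverage = aligned_short / min(len(seq_a), len(seq_b))
    return identity, coverage


def global_identity(seq_a: str, seq_b: str) -> float:
    """CD-HIT-style identity: matched residues over the shorter sequence length.

    Unlike the per-column identity of :func:`pairwise_identity`, this cannot
    be inflated by a short high-identity local segment, which is what the
    clustering threshold must guard against.
    """
    identity, coverage = pairwise_identity(seq_a, seq_b)
    return identity * coverage


@dataclass
class MergeCluster:
    """A cluster of cross-assembly sequences judged redundant."""

    cluster_id: int
    members: list[str] = field(default_factory=list)  # protein ids
    sources: dict[str, str] = field(default_factory=dict)  # protein id -> source
    representative: str = ""
    retained: list[str] = field(default_factory=list)
    rule_applied: str = ""


def greedy_cluster(
    sequences: dict[str, str],
    id_min: float = DEFAULT_ID_MIN,
    len_ratio_min: float = DEFAULT_LEN_RATIO_MIN,
) -> list[MergeCluster]:
    """CD-HIT-style greedy incremental clustering.

    Sequences are visited by descending length (ties by id); each joins the
    first existing cluster whose representative satisfies both the identity
    and the length-ratio threshold, otherwise it seeds a new cluster.  The
    representative is the longest (first) member.  Identity against the
    representative is :func:`global_identity` (matches over the shorter
    sequence), the semantics of the clustering tool this mirrors.
    """
    if not (0 < id_min <= 1 and 0 < len_ratio_min <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    clusters: list[MergeCluster] = []
    for sid in order:
        seq = sequences[sid]
        placed = False
        for cl in clusters:
            rep_seq = sequences[cl.representative]
            if len(seq) / len(rep_seq) < len_ratio_min:
                continue
            if global_identity(rep_seq, seq) >= id_min:
                cl.members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(
                MergeCluster(cluster_id=len(clusters), members=[sid], representative=sid)
            )
    return clusters


def merge_kinomes(
    set_a: Sequence[KinaseGene],
    set_b: Sequence[KinaseGene],
    id_min: float = DEFAULT_ID_MIN,
    len_ratio_min: float = DEFAULT_LEN_RATIO_MIN,
    sequences: dict[str, str] | None = None,
) -> tuple[list[KinaseGene], list[MergeCluster]]:
    """Merge two per-assembly kinase sets into one non-redundant kinome.

    ``sequences`` maps protein id -> protein sequence; if omitted the
    sequences are translated lazily from each gene's CDS.  Returns the
    retained kinases plus the cluster report.
    """
    by_pid: dict[str, KinaseGene] = {}
    for k in list(set_a) + list(set_b):
        if k.protein_id in by_pid:
            raise ValueError(f"duplicate protein id across sets: {k.protein_id}")
        by_pid[k.protein_id] = k
    if sequences is None:
        from Bio.Seq import Seq

        sequences = {
            pid: str(Seq(k.cds_sequence).translate().rstrip("*"))
            for pid, k in by_pid.items()
        }
    source_of = {k.protein_id: k.source_assembly for k in by_pid.values()}
    sources = sorted({k.source_assembly for k in by_pid.values()})

    clusters = greedy_cluster(
        {pid: sequences[pid] for pid in by_pid}, id_min, len_ratio_min
    )
    retained: list[KinaseGene] = []
    for cl in clusters:
        cl.sources = {pid: source_of[pid] for pid in cl.members}
        counts = {s: sum(1 for v in cl.sources.values() if v == s) for s in sources}
        if len(cl.members) == 1:
            cl.rule_applied = "unique"
            cl.retained = list(cl.members)
        elif all(c <= 1 for c in counts.values()):
            # one copy in each source: keep the longest (rule i)
            cl.rule_applied = "singleton-both"
            cl.retained = [
                min(cl.members, key=lambda p: (-len(sequences[p]), p))
            ]
        else:
            # putative duplication: keep every member of the larger source
            # (rule ii); ties go to the source holding the longest member
            cl.rule_applied = "duplicated"
            best = max(counts.values())
            tied = sorted(s for s, c in counts.items() if c == best)
            if len(tied) > 1:
                longest = min(cl.members, key=lambda p: (-len(sequences[p]), p))
                winner = source_of[longest]
            else:
                winner = tied[0]
            cl.retained = [p for p in cl.members if source_of[p] == winner]
        retained.extend(by_pid[p] for p in cl.retained)
    retained.sort(key=lambda k: k.protein_id)
    return retained, clusters


def cluster_report(clusters: Sequence[MergeCluster]) -> pd.DataFrame:
    """Flat TSV-ready view: one row per cluster member."""
    rows = []
    for cl in clusters:
        for pid in cl.members:
            rows.append(
                {
                    "cluster_id": cl.cluster_id,
                    "member": pid,
                    "source": cl.sources.get(pid, ""),
                    "retained": pid in cl.retained,
                    "rule": cl.rule_applied,
                }
            )
    return pd.DataFrame(rows)
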