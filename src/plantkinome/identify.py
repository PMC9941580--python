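"""Kinase identification and subfamily classification.

A "typical" protein kinase is a protein with at least one hit to a kinase
domain model (Pkinase or Pkinase_Tyr) at E-value <= 1e-10 covering at least
50% of the domain model.  Proteins failing the coverage rule are treated as
atypical (probable pseudogenes) and dropped.  One protein — the longest
isoform — is kept per gene, and the kinase-domain region is classified into
a subfamily with an "Unknown" fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import DomainHit, GeneModel, read_domtblout, read_fasta, read_gene_models
from .profiles import ProfileSet, default_profile_set

KINASE_DOMAINS = frozenset({"Pkinase", "Pkinase_Tyr"})

DEFAULT_EVALUE_MAX = 1e-10
DEFAULT_COVERAGE_MIN = 0.5


@dataclass
class KinaseGene:
    """An identified protein kinase gene."""

    gene_id: str
    protein_id: str
    source_assembly: str
    chromosome: str
    start: int
    end: int
    strand: str
    n_kinase_domains: int
    subfamily: str = "Unknown"
    group: str = "Unknown"
    intron_count: int = 0
    protein_length: int = 0
    cds_sequence: str = ""
    classification_score: float = float("nan")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.n_kinase_domains < 1:
            raise ValueError(f"{self.gene_id}: n_kinase_domains < 1")
        if self.subfamily == "Unknown":
            self.group = "Unknown"


def parse_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read a domain-hit table (see :mod:`plantkinome.io` for the dialect)."""
    return read_domtblout(path)


def _count_nonoverlapping(hits: list[DomainHit]) -> int:
    """Greedy non-overlapping domain count, best (lowest) E-value first.

    Overlap is measured on protein (envelope) coordinates, so a region hit
    by both Pkinase and Pkinase_Tyr is counted once.
    """
    chosen: list[DomainHit] = []
    for h in sorted(hits, key=lambda h: (h.evalue, h.env_from, h.domain_name)):
        if all(h.env_to < c.env_from or h.env_from > c.env_to for c in chosen):
            chosen.append(h)
    return len(chosen)


def filter_kinases(
    hits: list[DomainHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
) -> dict[str, int]:
    """Select typical kinases from domain hits.

    A protein is retained iff it has >= 1 hit to Pkinase or Pkinase_Tyr with
    E-value <= ``evalue_max`` AND model coverage >= ``coverage_min``.
    Returns ``{protein_id: n_kinase_domains}`` where the count is the number
    of non-overlapping passing hits.
    """
    if not 0 < coverage_min <= 1:
        raise ValueError("coverage_min must be in (0, 1]")
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    passing: dict[str, list[DomainHit]] = {}
    for h in hits:
        if h.domain_name not in KINASE_DOMAINS:
            continue
        if h.evalue <= evalue_max and h.model_coverage >= coverage_min:
            passing.setdefault(h.protein_id, []).append(h)
    return {pid: _count_nonoverlapping(hs) for pid, hs in sorted(passing.items())}


def select_longest_isoform(
    protein_lengths: dict[str, int],
    isoform_groups: dict[str, list[str]],
) -> dict[str, str]:
    """Pick one protein per gene: maximal length, ties broken by smallest id.

    ``isoform_groups`` maps gene id -> isoform protein ids; isoforms absent
    from ``protein_lengths`` are ignored.  Returns ``{gene_id: protein_id}``.
    """
    selected: dict[str, str] = {}
    for gene_id in sorted(isoform_groups):
        candidates = [p for p in isoform_groups[gene_id] if p in protein_lengths]
        if not candidates:
            continue
        selected[gene_id] = min(candidates, key=lambda p: (-protein_lengths[p], p))
    return selected


def classify_subfamily(
    domain_sequence: str, profile_set: ProfileSet
) -> tuple[str, str, float]:
    """Assign the best-scoring subfamily, or "Unknown".

    The best profile wins iff its score reaches its threshold and exceeds
    the runner-up by at least its margin; otherwise the sequence is
    "Unknown" (reported with the best score observed).
    """
    if len(profile_set) == 0:
        raise ValueError("empty profile set")
    if not domain_sequence:
        raise ValueError("empty domain sequence")
    scores = [(p.score(domain_sequence), p) for p in profile_set]
    scores.sort(key=lambda t: (-t[0], t[1].subfamily_name))
    best_score, best = scores[0]
    second = scores[1][0] if len(scores) > 1 else float("-inf")
    if best_score >= best.score_threshold and best_score - second >= best.margin_threshold:
        return best.subfamily_name, best.group_name, best_score
    return "Unknown", "Unknown", best_score


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

def _gene_of_protein(genes: dict[str, GeneModel]) -> dict[str, str]:
    return {
        tid: g.gene_id for g in genes.values() for tid in g.transcripts
    }


def isoform_groups_from_genes(genes: dict[str, GeneModel]) -> dict[str, list[str]]:
    return {gid: sorted(g.transcripts) for gid, g in genes.items()}


def identify_kinome(
    hits_path: str | Path,
    proteins_path: str | Path,
    gff_path: str | Path,
    cds_path: str | Path | None = None,
    profile_set: ProfileSet | None = None,
    source_assembly: str = "assembly",
    evalue_max: float = DEFAULT_EVALUE_MAX,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
) -> list[KinaseGene]:
    """Run the full identification stage on one assembly.

    Parses hits, applies the E-value/coverage filter, keeps the longest
    isoform per gene, classifies the kinase-domain region of each retained
    protein, and attaches gene coordinates and intron counts.
    """
    if profile_set is None:
        profile_set = default_profile_set()
    hits = parse_domain_hits(hits_path)
    proteins = read_fasta(proteins_path)
    genes = read_gene_models(gff_path)
    cds = read_fasta(cds_path) if cds_path else {}

    domain_counts = filter_kinases(hits, evalue_max, coverage_min)
    lengths = {pid: len(seq) for pid, seq in proteins.items() if pid in domain_counts}
    groups = isoform_groups_from_genes(genes)
    selected = select_longest_isoform(lengths, groups)

    best_hit: dict[str, DomainHit] = {}
    for h in hits:
        if h.domain_name in KINASE_DOMAINS and (
            h.protein_id not in best_hit or h.evalue < best_hit[h.protein_id].evalue
        ):
            best_hit[h.protein_id] = h

    kinome: list[KinaseGene] = []
    for gene_id in sorted(selected):
        pid = selected[gene_id]
        g = genes[gene_id]
        hit = best_hit[pid]
        domain_seq = proteins[pid][hit.env_from - 1:hit.env_to]
        subfamily, group, score = classify_subfamily(domain_seq, profile_set)
        tr = g.transcripts[pid]
        kinome.append(
            KinaseGene(
                gene_id=gene_id, protein_id=pid, source_assembly=source_assembly,
                chromosome=g.chromosome, start=g.start, end=g.end, strand=g.strand,
                n_kinase_domains=domain_counts[pid], subfamily=subfamily,
                group=group, intron_count=tr.n_introns,
                protein_length=len(proteins[pid]),
                cds_sequence=cds.get(pid, ""),
                classification_score=score,
            )
        )
    return kinome


def kinome_to_frame(kinome: list[KinaseGene]) -> pd.DataFrame:
    """Tabular view of a kinase set (without sequences)."""
    return pd.DataFrame(
        [
            {
                "gene_id": k.gene_id, "protein_id": k.protein_id,
                "source_assembly": k.source_assembly, "chromosome": k.chromosome,
                "start": k.start, "end": k.end, "strand": k.strand,
                "n_kinase_domains": k.n_kinase_domains, "subfamily": k.subfamily,
                "group": k.group, "intron_count": k.intron_count,
                "protein_length": k.protein_length,
            }
            for k in kinome
        ]
    )
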