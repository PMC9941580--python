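"""Readers and writers for the file formats the pipeline consumes and emits.

Coordinate conventions follow the formats themselves: GFF3 is 1-based
inclusive, BED is 0-based half-open.  FASTA is wrapped at 60 columns.
The domain-hit table is the whitespace-delimited per-domain tabular output
of ``hmmsearch --domtblout`` (one row per domain alignment, 22 fixed
columns followed by a free-text description).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DomainHit",
    "Exon",
    "Transcript",
    "GeneModel",
    "TERecord",
    "read_fasta",
    "write_fasta",
    "read_domtblout",
    "write_domtblout",
    "read_gene_models",
    "write_gff3",
    "read_te_bed",
    "write_te_bed",
    "read_tsv_matrix",
    "write_tsv_matrix",
]


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an insertion-ordered ``{id: sequence}`` dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns, in mapping order."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# --------------------------------------------------------------------------
# Domain-hit tables (hmmsearch --domtblout dialect)
# --------------------------------------------------------------------------

#: Column order of the per-domain table.  ``qlen`` is the length of the
#: domain model; ``i_evalue`` is the independent E-value of the single
#: domain; ``hmm_from``/``hmm_to`` are 1-based inclusive coordinates on the
#: model and ``env_from``/``env_to`` on the target protein.
DOMTBL_COLUMNS = (
    "target_name", "target_accession", "tlen",
    "query_name", "query_accession", "qlen",
    "full_evalue", "full_score", "full_bias",
    "dom_num", "dom_of", "c_evalue", "i_evalue",
    "dom_score", "dom_bias",
    "hmm_from", "hmm_to", "ali_from", "ali_to",
    "env_from", "env_to", "acc",
)


@dataclass(frozen=True)
class DomainHit:
    """One domain-model alignment on a protein."""

    protein_id: str
    domain_name: str
    evalue: float
    model_length: int
    hmm_from: int
    hmm_to: int
    env_from: int
    env_to: int
    score: float = 0.0

    @property
    def model_coverage(self) -> float:
        """Fraction of the domain model covered by the alignment."""
        return (self.hmm_to - self.hmm_from + 1) / self.model_length


class DomtblParseError(ValueError):
    """Raised when a domain-hit table row cannot be interpreted."""


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a domain-hit table into :class:`DomainHit` records.

    Comment lines (``#``) are skipped.  Malformed rows raise
    :class:`DomtblParseError` naming the 1-based line number.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < len(DOMTBL_COLUMNS):
                raise DomtblParseError(
                    f"line {lineno}: expected >= {len(DOMTBL_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[0],
                    domain_name=fields[3],
                    evalue=float(fields[12]),
                    model_length=int(fields[5]),
                    hmm_from=int(fields[15]),
                    hmm_to=int(fields[16]),
                    env_from=int(fields[19]),
                    env_to=int(fields[20]),
                    score=float(fields[13]),
                )
            except ValueError as exc:
                raise DomtblParseError(f"line {lineno}: {exc}") from exc
            if hit.hmm_to < hit.hmm_from:
                raise DomtblParseError(
                    f"line {lineno}: hmm_to {hit.hmm_to} < hmm_from {hit.hmm_from}"
                )
            if hit.env_to < hit.env_from:
                raise DomtblParseError(
                    f"line {lineno}: env_to {hit.env_to} < env_from {hit.env_from}"
                )
            if not 0 < hit.model_coverage <= 1:
                raise DomtblParseError(
                    f"line {lineno}: model coverage {hit.model_coverage:.3f} "
                    "outside (0, 1]"
                )
            hits.append(hit)
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the per-domain tabular dialect read by :func:`read_domtblout`."""
    with open(path, "w") as fh:
        fh.write("#" + " ".join(DOMTBL_COLUMNS) + " description\n")
        for i, h in enumerate(hits):
            ali_len = h.env_to - h.env_from + 1
            row = (
                h.protein_id, "-", str(h.env_to + 50),
                h.domain_name, "-", str(h.model_length),
                f"{h.evalue:.1e}", f"{h.score:.1f}", "0.0",
                "1", "1", f"{h.evalue:.1e}", f"{h.evalue:.1e}",
                f"{h.score:.1f}", "0.0",
                str(h.hmm_from), str(h.hmm_to),
                str(h.env_from), str(h.env_to),
                str(h.env_from), str(h.env_to), "0.90",
                "-",
            )
            fh.write(" ".join(row) + "\n")


# --------------------------------------------------------------------------
# GFF3 gene models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Exon:
    start: int  # 1-based inclusive
    end: int


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Exon] = field(default_factory=list)

    @property
    def coding_length(self) -> int:
        return sum(e.end - e.start + 1 for e in self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Load gene/mRNA/exon models from a GFF3 file.

    Uses an in-memory gffutils database; exons are returned sorted by start
    within each transcript.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        model = GeneModel(
            gene_id=g.id, chromosome=g.seqid, start=g.start, end=g.end,
            strand=g.strand,
        )
        for m in db.children(g, featuretype="mRNA", order_by="start"):
            tr = Transcript(transcript_id=m.id)
            for e in db.children(m, featuretype="exon", order_by="start"):
                tr.exons.append(Exon(e.start, e.end))
            model.transcripts[m.id] = tr
        genes[model.gene_id] = model
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon), 1-based inclusive."""
    src = "plantkinome"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\t{src}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for tid in sorted(g.transcripts):
                tr = g.transcripts[tid]
                t_start = min(e.start for e in tr.exons)
                t_end = max(e.end for e in tr.exons)
                fh.write(
                    f"{g.chromosome}\t{src}\tmRNA\t{t_start}\t{t_end}\t.\t{g.strand}\t.\t"
                    f"ID={tid};Parent={g.gene_id}\n"
                )
                for k, e in enumerate(tr.exons, start=1):
                    fh.write(
                        f"{g.chromosome}\t{src}\texon\t{e.start}\t{e.end}\t.\t{g.strand}\t.\t"
                        f"ID={tid}.exon{k};Parent={tid}\n"
                    )


# --------------------------------------------------------------------------
# TE BED
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TERecord:
    """A transposable-element interval, 0-based half-open."""

    chromosome: str
    start: int
    end: int
    te_id: str
    te_class: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"TE {self.te_id}: start {self.start} >= end {self.end}")


def read_te_bed(path: str | Path) -> list[TERecord]:
    """Read TEs from BED4; the name field is ``<id>#<class>`` (RepeatMasker style)."""
    tes: list[TERecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            te_id, _, te_class = name.strip().partition("#")
            tes.append(TERecord(chrom, int(start), int(end), te_id, te_class or "Unknown"))
    return tes


def write_te_bed(tes: Iterable[TERecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for te in tes:
            fh.write(f"{te.chromosome}\t{te.start}\t{te.end}\t{te.te_id}#{te.te_class}\n")


# --------------------------------------------------------------------------
# TSV matrices
# --------------------------------------------------------------------------

def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV with the feature id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)
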