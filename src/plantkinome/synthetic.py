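"""Seeded synthetic genomes, domain-hit tables and expression matrices.

The generator emulates the statistical structure the kinome pipeline
assumes about a real plant genome, with planted ground truth so that every
downstream stage is testable without external data:

* multi-chromosome gene sets in which each kinase protein embeds a mutated
  copy of a subfamily consensus domain flanked by random sequence, with a
  fraction of decoy (non-kinase) genes;
* tandem arrays planted by copy-and-mutate of a seed CDS — substitution
  positions are disjoint across copies, so the pairwise CDS identity of
  array members equals the requested planting identity exactly;
* optional long-range ("segmental") duplicate copies on other chromosomes;
* interspersed transposable elements dominated by LTR retrotransposons;
* domain-hit tables in which every planted kinase passes the E-value and
  coverage filter and every decoy hit violates at least one criterion;
* a latent-factor expression model: subfamilies in a planted block share a
  Gaussian factor on the log scale chosen so the factor-to-noise variance
  ratio gives the requested within-block correlation (r = v / (v + sigma^2));
  exponentiated means drive Poisson counts (deterministic rounding when the
  subfamily noise is zero, so the no-noise correlation is exactly 1).

All randomness flows from a single ``numpy`` generator per call, so a fixed
seed yields byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io import (
    Exon,
    GeneModel,
    TERecord,
    Transcript,
    write_domtblout,
    write_fasta,
    write_gff3,
    write_te_bed,
)
from .io import DomainHit
from .profiles import AA_ALPHABET, ProfileSet, default_profile_set

DNA = "ACGT"
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_OF = {}
for codon, aa in sorted(_STANDARD_TABLE.forward_table.items()):
    _CODONS_OF.setdefault(aa, []).append(codon)
_STOP_CODONS = set(_STANDARD_TABLE.stop_codons)

PKINASE_LENGTH = 264
PKINASE_TYR_LENGTH = 279

GENOTYPES = ("RRIM600", "GT1", "PR255", "PB235")
TE_CLASSES = ("LTR/Gypsy", "LTR/Copia", "DNA/hAT", "LINE/L1")
TE_CLASS_P = (0.50, 0.38, 0.07, 0.05)  # LTR-dominated, ~88% LTR


@dataclass
class CorrelatedBlock:
    subfamilies: tuple[str, ...]
    target_r: float | None = None


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic genome."""

    tandem_cluster_membership: dict[str, str] = field(default_factory=dict)
    te_associated_genes: set[str] = field(default_factory=set)
    subfamily_of_gene: dict[str, str] = field(default_factory=dict)
    correlated_blocks: list[CorrelatedBlock] = field(default_factory=list)
    isoform_groups: dict[str, list[str]] = field(default_factory=dict)
    # extras used by later generator stages and recovery tests
    decoy_genes: set[str] = field(default_factory=set)
    kinase_genes: set[str] = field(default_factory=set)
    domain_span: dict[str, tuple[int, int]] = field(default_factory=dict)
    cluster_gap_bp: dict[str, int] = field(default_factory=dict)
    cluster_identity: dict[str, float] = field(default_factory=dict)
    segmental_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def longest_isoform(self, gene_id: str) -> str:
        return self.isoform_groups[gene_id][0]


@dataclass
class GenomeBundle:
    """Paths of the emitted files plus the planted truth."""

    proteins_fasta: Path
    cds_fasta: Path
    gff3: Path
    te_bed: Path
    truth: SyntheticTruth
    chromosome_lengths: dict[str, int]
    assembly_label: str = "chromosome-level"


# --------------------------------------------------------------------------
# sequence helpers
# --------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AA_ALPHABET if a != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for aa in protein:
        options = _CODONS_OF[aa]
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


def _mutate_cds(
    rng: np.random.Generator, cds: str, positions: np.ndarray
) -> str:
    """Substitute the given positions, never creating an in-frame stop codon."""
    out = list(cds)
    for pos in positions:
        pos = int(pos)
        codon_start = (pos // 3) * 3
        original = out[pos]
        bases = [b for b in DNA if b != original]
        order = rng.permutation(len(bases))
        for k in order:
            out[pos] = bases[int(k)]
            codon = "".join(out[codon_start:codon_start + 3])
            if codon not in _STOP_CODONS:
                break
        else:
            out[pos] = original  # no safe substitution at this site
    return "".join(out)


def _translate(cds: str) -> str:
    return str(Seq(cds).translate())


# --------------------------------------------------------------------------
# genome generation
# --------------------------------------------------------------------------

@dataclass
class _GenePlan:
    gene_id: str
    chromosome: str
    cds: str  # primary-isoform CDS
    subfamily: str | None  # None for decoys
    domain_span_aa: tuple[int, int] | None
    exon_cuts: list[int]  # nt offsets (codon-aligned) splitting the CDS
    second_isoform: bool
    start: int = 0
    end: int = 0
    strand: str = "+"


def _plan_structure(
    rng: np.random.Generator, cds_len: int, domain_end_nt: int | None
) -> list[int]:
    """Codon-aligned exon cut offsets; the last exon starts after the domain."""
    n_codons = cds_len // 3
    n_exons = int(rng.integers(1, 9))
    if n_exons == 1:
        return []
    lo_codon = (domain_end_nt // 3 + 1) if domain_end_nt else 1
    lo_codon = min(lo_codon, n_codons - 1)
    # last cut sits between domain end and CDS end so a truncated isoform
    # (which drops the final exon) still carries the whole domain
    last_cut = int(rng.integers(lo_codon, n_codons))
    inner_pool = np.arange(1, last_cut)
    n_inner = min(n_exons - 2, inner_pool.size)
    inner = sorted(
        int(c) for c in rng.choice(inner_pool, size=n_inner, replace=False)
    ) if n_inner > 0 else []
    return [c * 3 for c in inner + [last_cut]]


def _exon_sizes(cds_len: int, cuts: list[int]) -> list[int]:
    bounds = [0] + list(cuts) + [cds_len]
    return [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]


def generate_genome(
    n_chromosomes: int,
    n_genes: int,
    tandem_spec: list[tuple[int, int, float]],
    te_density: float,
    seed: int,
    out_dir: str | Path,
    profile_set: ProfileSet | None = None,
    decoy_fraction: float = 0.2,
    isoform_fraction: float = 0.25,
    segmental_spec: tuple[float, ...] = (),
    block_sizes: tuple[int, ...] = (3, 3),
    domain_mutation_rate: float = 0.05,
    intergenic_range: tuple[int, int] = (35_000, 80_000),
    te_window: int = 100_000,
    chromosome_length: int | None = None,
    assembly_label: str = "chromosome-level",
    gene_prefix: str = "gene",
) -> GenomeBundle:
    """Generate one synthetic genome with planted ground truth.

    ``n_genes`` counts kinase genes, including tandem-array members and
    long-range duplicate copies; decoy genes are added on top at
    ``decoy_fraction`` of ``n_genes``.  ``tandem_spec`` is a list of
    (cluster size, boundary gap bp, pairwise CDS identity) arrays.
    ``te_density`` is TEs per Mbp.  Files are written under ``out_dir``.
    """
    if n_chromosomes < 1 or n_genes < 1:
        raise ValueError("counts must be positive")
    if te_density < 0:
        raise ValueError("te_density must be >= 0")
    for size, gap, identity in tandem_spec:
        if size < 2:
            raise ValueError("tandem cluster size must be >= 2")
        if gap < 0:
            raise ValueError("tandem gap must be >= 0")
        if not 0 < identity <= 1:
            raise ValueError("tandem identity must be in (0, 1]")
    n_planted = sum(size for size, _, _ in tandem_spec) + len(segmental_spec)
    if n_planted > n_genes:
        raise ValueError(
            f"tandem/segmental plants need {n_planted} genes but n_genes={n_genes}"
        )

    # fit check against the (possibly auto-sized) shortest chromosome
    margin = 20_000
    est_gene_span = 10_000
    genes_per_chrom = math.ceil(n_genes * (1 + decoy_fraction) / n_chromosomes)
    auto_length = 2 * margin + genes_per_chrom * (est_gene_span + intergenic_range[1])
    capacity = (chromosome_length or auto_length) - 2 * margin
    for size, gap, _ in tandem_spec:
        span = size * est_gene_span + (size - 1) * gap
        if span > capacity:
            raise ValueError(
                f"tandem array of {size} genes with gap {gap} bp (span ~{span} bp) "
                f"cannot fit on the shortest chromosome (capacity {capacity} bp)"
            )

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if profile_set is None:
        profile_set = default_profile_set()
    subfam_cycle = profile_set.subfamilies

    truth = SyntheticTruth()
    plans: list[_GenePlan] = []
    gene_counter = 0

    def new_gene_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"{gene_prefix}{gene_counter:04d}"

    def make_kinase(subfamily: str) -> tuple[str, tuple[int, int]]:
        consensus = profile_set[subfamily].consensus
        nflank = int(rng.integers(20, 61))
        cflank = int(rng.integers(25, 61))
        domain = _mutate_protein(rng, consensus, domain_mutation_rate)
        protein = _random_protein(rng, nflank) + domain + _random_protein(rng, cflank)
        cds = _back_translate(rng, protein)
        return cds, (nflank + 1, nflank + len(domain))

    n_tandem_members = sum(size for size, _, _ in tandem_spec)
    n_base = n_genes - n_tandem_members - len(segmental_spec)

    # --- tandem arrays -----------------------------------------------------
    tandem_plans: list[list[_GenePlan]] = []
    for a_idx, (size, gap, identity) in enumerate(tandem_spec):
        subfamily = subfam_cycle[a_idx % len(subfam_cycle)]
        seed_cds, span_aa = make_kinase(subfamily)
        L = len(seed_cds)
        m = int(math.floor((1.0 - identity) * L / 2.0))
        pool = rng.permutation(L)
        cluster_id = f"tde{a_idx:02d}"
        members: list[_GenePlan] = []
        for k in range(size):
            positions = np.sort(pool[k * m:(k + 1) * m])
            cds = _mutate_cds(rng, seed_cds, positions)
            gid = new_gene_id()
            chrom = f"chr{(a_idx % n_chromosomes) + 1:02d}"
            cuts = _plan_structure(rng, len(cds), span_aa[1] * 3)
            members.append(
                _GenePlan(
                    gene_id=gid, chromosome=chrom, cds=cds, subfamily=subfamily,
                    domain_span_aa=span_aa, exon_cuts=cuts, second_isoform=False,
                )
            )
            truth.tandem_cluster_membership[gid] = cluster_id
            truth.subfamily_of_gene[gid] = subfamily
            truth.kinase_genes.add(gid)
        truth.cluster_gap_bp[cluster_id] = gap
        truth.cluster_identity[cluster_id] = identity
        tandem_plans.append(members)

    # --- base kinase genes -------------------------------------------------
    base_plans: list[_GenePlan] = []
    for i in range(n_base):
        subfamily = subfam_cycle[i % len(subfam_cycle)]
        cds, span_aa = make_kinase(subfamily)
        gid = new_gene_id()
        chrom = f"chr{(i % n_chromosomes) + 1:02d}"
        cuts = _plan_structure(rng, len(cds), span_aa[1] * 3)
        second = bool(rng.random() < isoform_fraction) and len(cuts) >= 1
        base_plans.append(
            _GenePlan(
                gene_id=gid, chromosome=chrom, cds=cds, subfamily=subfamily,
                domain_span_aa=span_aa, exon_cuts=cuts, second_isoform=second,
            )
        )
        truth.subfamily_of_gene[gid] = subfamily
        truth.kinase_genes.add(gid)

    # --- long-range (segmental) duplicate copies ---------------------------
    seg_plans: list[_GenePlan] = []
    for s_idx, identity in enumerate(segmental_spec):
        if not 0 < identity <= 1:
            raise ValueError("segmental identity must be in (0, 1]")
        if not base_plans:
            raise ValueError("segmental_spec requires at least one base gene")
        donor = base_plans[s_idx % len(base_plans)]
        L = len(donor.cds)
        m = int(math.floor((1.0 - identity) * L))
        positions = np.sort(rng.permutation(L)[:m])
        cds = _mutate_cds(rng, donor.cds, positions)
        gid = new_gene_id()
        donor_chrom_idx = int(donor.chromosome[3:]) - 1
        chrom = f"chr{((donor_chrom_idx + 1) % n_chromosomes) + 1:02d}" \
            if n_chromosomes > 1 else donor.chromosome
        cuts = _plan_structure(
            rng, len(cds),
            donor.domain_span_aa[1] * 3 if donor.domain_span_aa else None,
        )
        seg_plans.append(
            _GenePlan(
                gene_id=gid, chromosome=chrom, cds=cds,
                subfamily=donor.subfamily, domain_span_aa=donor.domain_span_aa,
                exon_cuts=cuts, second_isoform=False,
            )
        )
        truth.subfamily_of_gene[gid] = donor.subfamily
        truth.kinase_genes.add(gid)
        truth.segmental_pairs.append((donor.gene_id, gid, identity))

    # --- decoy (non-kinase) genes ------------------------------------------
    n_decoys = int(round(decoy_fraction * n_genes))
    decoy_plans: list[_GenePlan] = []
    for i in range(n_decoys):
        protein = _random_protein(rng, int(rng.integers(200, 401)))
        cds = _back_translate(rng, protein)
        gid = new_gene_id()
        chrom = f"chr{(i % n_chromosomes) + 1:02d}"
        cuts = _plan_structure(rng, len(cds), None)
        decoy_plans.append(
            _GenePlan(
                gene_id=gid, chromosome=chrom, cds=cds, subfamily=None,
                domain_span_aa=None, exon_cuts=cuts, second_isoform=False,
            )
        )
        truth.decoy_genes.add(gid)

    # --- placement ---------------------------------------------------------
    chroms = [f"chr{i + 1:02d}" for i in range(n_chromosomes)]
    cursors = {c: margin for c in chroms}

    def place(plan: _GenePlan, forced_start: int | None = None) -> None:
        sizes = _exon_sizes(len(plan.cds), plan.exon_cuts)
        introns = [int(rng.integers(100, 501)) for _ in range(len(sizes) - 1)]
        span = sum(sizes) + sum(introns)
        start = forced_start if forced_start is not None else cursors[plan.chromosome]
        plan.start = start
        plan.end = start + span - 1
        plan.strand = "+" if rng.random() < 0.5 else "-"
        plan._exon_sizes = sizes  # type: ignore[attr-defined]
        plan._intron_sizes = introns  # type: ignore[attr-defined]
        cursors[plan.chromosome] = plan.end + int(
            rng.integers(intergenic_range[0], intergenic_range[1] + 1)
        )

    for members in tandem_plans:
        chrom = members[0].chromosome
        place(members[0])
        gap = truth.cluster_gap_bp[truth.tandem_cluster_membership[members[0].gene_id]]
        for prev, plan in zip(members, members[1:]):
            place(plan, forced_start=prev.end + gap)
    for plan in base_plans + seg_plans + decoy_plans:
        place(plan)

    plans = [p for members in tandem_plans for p in members]
    plans += base_plans + seg_plans + decoy_plans
    plans.sort(key=lambda p: (p.chromosome, p.start))

    chrom_lengths = {c: cursors[c] + margin for c in chroms}
    if chromosome_length is not None:
        for c in chroms:
            if chrom_lengths[c] > chromosome_length:
                raise ValueError(
                    f"{c}: placed genes need {chrom_lengths[c]} bp but "
                    f"chromosome_length={chromosome_length}"
                )
            chrom_lengths[c] = chromosome_length

    # --- gene models, sequences --------------------------------------------
    proteins: dict[str, str] = {}
    cds_out: dict[str, str] = {}
    models: list[GeneModel] = []
    for plan in plans:
        sizes = plan._exon_sizes  # type: ignore[attr-defined]
        introns = plan._intron_sizes  # type: ignore[attr-defined]
        exons = []
        pos = plan.start
        for k, sz in enumerate(sizes):
            exons.append(Exon(pos, pos + sz - 1))
            pos += sz + (introns[k] if k < len(introns) else 0)
        model = GeneModel(
            gene_id=plan.gene_id, chromosome=plan.chromosome,
            start=plan.start, end=plan.end, strand=plan.strand,
        )
        t1 = f"{plan.gene_id}.t1"
        model.transcripts[t1] = Transcript(transcript_id=t1, exons=exons)
        isoforms = [t1]
        protein1 = _translate(plan.cds)
        proteins[t1] = protein1
        cds_out[t1] = plan.cds
        if plan.domain_span_aa is not None:
            truth.domain_span[t1] = plan.domain_span_aa
        if plan.second_isoform and len(exons) >= 2:
            t2 = f"{plan.gene_id}.t2"
            model.transcripts[t2] = Transcript(transcript_id=t2, exons=exons[:-1])
            cds2 = plan.cds[: sum(sizes[:-1])]
            cds_out[t2] = cds2
            proteins[t2] = _translate(cds2)
            isoforms.append(t2)
            if plan.domain_span_aa is not None:
                dspan = (
                    plan.domain_span_aa[0],
                    min(plan.domain_span_aa[1], len(proteins[t2])),
                )
                truth.domain_span[t2] = dspan
        truth.isoform_groups[plan.gene_id] = isoforms
        models.append(model)

    # --- transposable elements ---------------------------------------------
    tes: list[TERecord] = []
    te_counter = 0
    for c in chroms:
        lam = te_density * chrom_lengths[c] / 1e6
        n_te = int(rng.poisson(lam)) if lam > 0 else 0
        for _ in range(n_te):
            te_counter += 1
            length = int(rng.integers(300, 8001))
            start = int(rng.integers(0, max(1, chrom_lengths[c] - length)))
            end = min(start + length, chrom_lengths[c])
            te_class = TE_CLASSES[
                int(rng.choice(len(TE_CLASSES), p=TE_CLASS_P))
            ]
            tes.append(TERecord(c, start, end, f"TE{te_counter:05d}", te_class))
    tes.sort(key=lambda t: (t.chromosome, t.start, t.te_id))

    # TE-associated kinase genes, by brute-force boundary distance
    for plan in plans:
        if plan.gene_id not in truth.kinase_genes:
            continue
        g_start0, g_end0 = plan.start - 1, plan.end
        for te in tes:
            if te.chromosome != plan.chromosome:
                continue
            if te.end <= g_start0:
                d = g_start0 - te.end
            elif te.start >= g_end0:
                d = te.start - g_end0
            else:
                d = 0
            if d <= te_window:
                truth.te_associated_genes.add(plan.gene_id)
                break

    # --- correlated blocks --------------------------------------------------
    present = sorted({s for s in truth.subfamily_of_gene.values()})
    order = [present[int(i)] for i in rng.permutation(len(present))]
    pos = 0
    for size in block_sizes:
        block = tuple(sorted(order[pos:pos + size]))
        if len(block) >= 2:
            truth.correlated_blocks.append(CorrelatedBlock(subfamilies=block))
        pos += size

    # --- write files --------------------------------------------------------
    bundle = GenomeBundle(
        proteins_fasta=out_dir / "proteins.faa",
        cds_fasta=out_dir / "cds.fna",
        gff3=out_dir / "genes.gff3",
        te_bed=out_dir / "tes.bed",
        truth=truth,
        chromosome_lengths=chrom_lengths,
        assembly_label=assembly_label,
    )
    write_fasta(dict(sorted(proteins.items())), bundle.proteins_fasta)
    write_fasta(dict(sorted(cds_out.items())), bundle.cds_fasta)
    write_gff3(models, bundle.gff3)
    write_te_bed(tes, bundle.te_bed)
    return bundle


# --------------------------------------------------------------------------
# domain hits
# --------------------------------------------------------------------------

def generate_domain_hits(
    bundle: GenomeBundle,
    out_path: str | Path,
    noise_spec: float = 0.0,
    seed: int = 0,
) -> Path:
    """Write a domain-hit table for a synthetic genome.

    Every planted kinase isoform receives one passing hit (E <= 1e-10,
    model coverage >= 0.5); ``noise_spec`` is the fraction of decoy genes
    that additionally receive a disqualifying hit (either a sub-threshold
    E-value or coverage below 50%).
    """
    if not 0 <= noise_spec <= 1:
        raise ValueError("noise_spec must be in [0, 1]")
    from .io import read_fasta

    rng = np.random.default_rng(seed)
    truth = bundle.truth
    proteins = read_fasta(bundle.proteins_fasta)
    hits: list[DomainHit] = []

    kinase_isoforms = sorted(
        iso for g in sorted(truth.kinase_genes) for iso in truth.isoform_groups[g]
    )
    for pid in kinase_isoforms:
        if pid not in proteins:
            raise ValueError(f"planted kinase isoform {pid} missing from protein FASTA")
        subfamily = truth.subfamily_of_gene[pid.rsplit(".", 1)[0]]
        tyr = subfamily.startswith("TKL")
        domain = "Pkinase_Tyr" if tyr else "Pkinase"
        model_len = PKINASE_TYR_LENGTH if tyr else PKINASE_LENGTH
        coverage = float(rng.uniform(0.55, 0.95))
        span = int(math.ceil(coverage * model_len))
        hmm_from = 1 + int(rng.integers(0, model_len - span + 1))
        evalue = float(10.0 ** -rng.uniform(15, 40))
        env_from, env_to = truth.domain_span[pid]
        env_to = min(env_to, len(proteins[pid]))
        hits.append(
            DomainHit(
                protein_id=pid, domain_name=domain, evalue=evalue,
                model_length=model_len, hmm_from=hmm_from,
                hmm_to=hmm_from + span - 1, env_from=env_from, env_to=env_to,
                score=float(rng.uniform(150, 400)),
            )
        )

    decoys = sorted(truth.decoy_genes)
    n_noisy = int(round(noise_spec * len(decoys)))
    for gid in decoys[:n_noisy]:
        pid = truth.isoform_groups.get(gid, [f"{gid}.t1"])[0]
        plen = len(proteins[pid])
        bad_coverage = bool(rng.random() < 0.5)
        if bad_coverage:
            coverage = float(rng.uniform(0.20, 0.49))
            evalue = float(10.0 ** -rng.uniform(15, 30))
        else:
            coverage = float(rng.uniform(0.55, 0.90))
            evalue = float(10.0 ** -rng.uniform(2, 9.5))
        span = int(math.ceil(coverage * PKINASE_LENGTH))
        hmm_from = 1 + int(rng.integers(0, PKINASE_LENGTH - span + 1))
        env_from = 1 + int(rng.integers(0, max(1, plen // 3)))
        env_to = min(plen, env_from + span - 1)
        hits.append(
            DomainHit(
                protein_id=pid, domain_name="Pkinase", evalue=evalue,
                model_length=PKINASE_LENGTH, hmm_from=hmm_from,
                hmm_to=hmm_from + span - 1, env_from=env_from, env_to=env_to,
                score=float(rng.uniform(5, 40)),
            )
        )

    hits.sort(key=lambda h: (h.protein_id, h.domain_name))
    out_path = Path(out_path)
    write_domtblout(hits, out_path)
    return out_path


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def generate_expression(
    truth: SyntheticTruth,
    samples_spec: list[tuple[str, str, int]],
    block_correlation: float = 0.9,
    noise_sd: float = 0.1,
    seed: int = 0,
    out_dir: str | Path = "synthetic_expression",
    cds_lengths: dict[str, int] | None = None,
    bundle: GenomeBundle | None = None,
    base_log_mean: tuple[float, float] = (math.log(200.0), math.log(2000.0)),
    background_log_mean: tuple[float, float] = (math.log(2_000.0), math.log(20_000.0)),
    background_sd: float = 0.2,
) -> tuple[Path, Path, Path]:
    """Write counts, lengths and sample-metadata TSVs.

    ``samples_spec`` lists (tissue, condition, n_replicates) replicate
    groups; conditions are ``"control"`` or ``"stress:<type>"``.  Genes of
    subfamilies in a planted block share a latent Gaussian factor on the
    log scale with variance v = sigma^2 * r / (1 - r), so the within-block
    subfamily correlation approaches ``block_correlation`` (= v/(v+sigma^2))
    as samples grow.  Counts are Poisson draws around the exponentiated
    means, or deterministically rounded means when ``noise_sd`` is zero.

    Decoy genes play the role of the non-kinase background transcriptome:
    they are expressed about an order of magnitude higher
    (``background_log_mean``) with modest variability (``background_sd``),
    so per-sample totals are dominated by stable background and the
    compositional coupling TPM introduces between unrelated features stays
    weak — as in real libraries, where kinases are a small fraction of the
    transcriptome.
    """
    if not samples_spec:
        raise ValueError("samples_spec must not be empty")
    if not 0 <= block_correlation < 1:
        raise ValueError("block_correlation must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for tissue, condition, n_rep in samples_spec:
        if n_rep < 1:
            raise ValueError(f"{tissue}/{condition}: n_replicates must be >= 1")
        if condition != "control" and not condition.startswith("stress"):
            raise ValueError(f"unknown condition label {condition!r}")

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cds_lengths is None:
        if bundle is None:
            raise ValueError("need cds_lengths or bundle")
        from .io import read_fasta

        cds_seqs = read_fasta(bundle.cds_fasta)
        cds_lengths = {pid: len(s) for pid, s in cds_seqs.items()}

    transcripts = sorted(
        truth.longest_isoform(g) for g in truth.isoform_groups
    )
    gene_of = {t: t.rsplit(".", 1)[0] for t in transcripts}

    for block in truth.correlated_blocks:
        block.target_r = block_correlation
        for sf in block.subfamilies:
            if sf not in set(truth.subfamily_of_gene.values()):
                raise ValueError(f"block subfamily {sf} absent from the kinome")

    sigma = noise_sd
    if sigma > 0:
        factor_sd = sigma * math.sqrt(block_correlation / (1.0 - block_correlation))
    else:
        factor_sd = 0.4  # pure shared factor: correlation is exactly 1
    total_sd = math.hypot(factor_sd, sigma)

    block_of_subfamily: dict[str, int] = {}
    for b_idx, block in enumerate(truth.correlated_blocks):
        for sf in block.subfamilies:
            block_of_subfamily[sf] = b_idx

    subfamilies = sorted(set(truth.subfamily_of_gene.values()))
    mu = {
        t: float(
            rng.uniform(*background_log_mean)
            if gene_of[t] in truth.decoy_genes
            else rng.uniform(*base_log_mean)
        )
        for t in transcripts
    }

    # expand replicate groups
    groups: list[tuple[str, str, str, str]] = []  # (group_id, tissue, condition, genotype)
    samples: list[tuple[str, str]] = []  # (sample_id, group_id)
    for g_idx, (tissue, condition, n_rep) in enumerate(samples_spec):
        cond_tag = condition.replace(":", "-")
        group_id = f"{tissue}_{cond_tag}_g{g_idx:02d}"
        genotype = GENOTYPES[g_idx % len(GENOTYPES)]
        groups.append((group_id, tissue, condition, genotype))
        for r in range(1, n_rep + 1):
            samples.append((f"{group_id}_rep{r}", group_id))

    counts = np.zeros((len(transcripts), len(samples)), dtype=np.int64)
    t_index = {t: i for i, t in enumerate(transcripts)}
    sample_col = 0
    for group_id, tissue, condition, genotype in groups:
        z = rng.normal(size=len(truth.correlated_blocks))
        eps = {sf: float(rng.normal()) for sf in subfamilies}
        decoy_eps = {
            g: float(rng.normal()) for g in sorted(truth.decoy_genes)
        }
        signal: dict[str, float] = {}
        for sf in subfamilies:
            if sf in block_of_subfamily:
                signal[sf] = factor_sd * z[block_of_subfamily[sf]] + sigma * eps[sf]
            else:
                signal[sf] = total_sd * eps[sf]
        n_rep = sum(1 for _, g in samples if g == group_id)
        for _ in range(n_rep):
            for t in transcripts:
                g = gene_of[t]
                if g in truth.subfamily_of_gene:
                    s = signal[truth.subfamily_of_gene[g]]
                else:
                    s = background_sd * decoy_eps[g]
                mean = math.exp(mu[t] + s)
                if sigma > 0:
                    counts[t_index[t], sample_col] = rng.poisson(mean)
                else:
                    counts[t_index[t], sample_col] = int(round(mean))
            sample_col += 1

    counts_df = pd.DataFrame(
        counts, index=pd.Index(transcripts, name="transcript"),
        columns=[s for s, _ in samples],
    )
    lengths_df = pd.DataFrame(
        {"length": [cds_lengths[t] for t in transcripts]},
        index=pd.Index(transcripts, name="transcript"),
    )
    meta_df = pd.DataFrame(
        [
            {
                "sample": sample_id,
                "tissue": next(t for g, t, _, _ in groups if g == group_id),
                "genotype": next(gt for g, _, _, gt in groups if g == group_id),
                "condition": next(c for g, _, c, _ in groups if g == group_id),
                "replicate_group": group_id,
            }
            for sample_id, group_id in samples
        ]
    ).set_index("sample")

    counts_path = out_dir / "counts.tsv"
    lengths_path = out_dir / "lengths.tsv"
    meta_path = out_dir / "samples.tsv"
    counts_df.to_csv(counts_path, sep="\t")
    lengths_df.to_csv(lengths_path, sep="\t")
    meta_df.to_csv(meta_path, sep="\t")
    return counts_path, lengths_path, meta_path


# --------------------------------------------------------------------------
# a second (scaffold-level) assembly derived from the first
# --------------------------------------------------------------------------

def derive_second_assembly(
    bundle: GenomeBundle,
    seed: int,
    out_dir: str | Path,
    keep_fraction: float = 0.8,
    dup_fraction: float = 0.1,
    n_unique: int = 3,
    mutation_rate: float = 0.01,
    profile_set: ProfileSet | None = None,
) -> GenomeBundle:
    """Synthesize a scaffold-level assembly overlapping the given genome.

    Each kinase gene of the source is carried over with probability
    ``keep_fraction`` as a lightly mutated (and sometimes 3'-truncated)
    copy; a fraction appears twice (putative duplications for merge rule
    ii); ``n_unique`` new kinase genes exist only in this assembly.
    """
    from .io import read_fasta

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if profile_set is None:
        profile_set = default_profile_set()
    src_cds = read_fasta(bundle.cds_fasta)
    src_truth = bundle.truth

    truth = SyntheticTruth()
    proteins: dict[str, str] = {}
    cds_out: dict[str, str] = {}
    models: list[GeneModel] = []
    cursor: dict[str, int] = {}
    counter = 0

    def add_gene(cds: str, subfamily: str | None, span_aa, scaffold: str) -> str:
        nonlocal counter
        counter += 1
        gid = f"sgene{counter:04d}"
        tid = f"{gid}.t1"
        start = cursor.get(scaffold, 10_000)
        cuts = _plan_structure(
            rng, len(cds), span_aa[1] * 3 if span_aa is not None else None
        )
        sizes = _exon_sizes(len(cds), cuts)
        exons = []
        pos = start
        for k, sz in enumerate(sizes):
            exons.append(Exon(pos, pos + sz - 1))
            pos += sz + (int(rng.integers(100, 501)) if k < len(sizes) - 1 else 0)
        end = exons[-1].end
        cursor[scaffold] = end + 40_000
        model = GeneModel(gene_id=gid, chromosome=scaffold, start=start, end=end, strand="+")
        model.transcripts[tid] = Transcript(transcript_id=tid, exons=exons)
        models.append(model)
        proteins[tid] = _translate(cds)
        cds_out[tid] = cds
        truth.isoform_groups[gid] = [tid]
        if subfamily is not None:
            truth.subfamily_of_gene[gid] = subfamily
            truth.kinase_genes.add(gid)
            truth.domain_span[tid] = (
                span_aa[0], min(span_aa[1], len(proteins[tid]))
            )
        else:
            truth.decoy_genes.add(gid)
        return gid

    for i, src_gid in enumerate(sorted(src_truth.kinase_genes)):
        tid = src_truth.longest_isoform(src_gid)
        cds = src_cds[tid]
        scaffold = f"scaffold{(i % 10) + 1:03d}"
        if rng.random() > keep_fraction:
            continue
        n_copies = 2 if rng.random() < dup_fraction else 1
        for _ in range(n_copies):
            m = int(math.floor(mutation_rate * len(cds)))
            positions = np.sort(rng.permutation(len(cds))[:m])
            mutated = _mutate_cds(rng, cds, positions)
            if rng.random() < 0.25:  # 3' truncation by a few codons
                cut = int(rng.integers(3, 13)) * 3
                mutated = mutated[:-cut]
            add_gene(
                mutated, src_truth.subfamily_of_gene[src_gid],
                src_truth.domain_span[tid], scaffold,
            )

    subfams = profile_set.subfamilies
    for i in range(n_unique):
        subfamily = subfams[(i * 3 + 1) % len(subfams)]
        consensus = profile_set[subfamily].consensus
        nflank = int(rng.integers(20, 61))
        domain = _mutate_protein(rng, consensus, 0.05)
        protein = (
            _random_protein(rng, nflank) + domain + _random_protein(rng, 30)
        )
        cds = _back_translate(rng, protein)
        add_gene(cds, subfamily, (nflank + 1, nflank + len(domain)), "scaffold999")

    out = GenomeBundle(
        proteins_fasta=out_dir / "proteins.faa",
        cds_fasta=out_dir / "cds.fna",
        gff3=out_dir / "genes.gff3",
        te_bed=out_dir / "tes.bed",
        truth=truth,
        chromosome_lengths={c: cursor[c] + 10_000 for c in sorted(cursor)},
        assembly_label="scaffold-level",
    )
    write_fasta(dict(sorted(proteins.items())), out.proteins_fasta)
    write_fasta(dict(sorted(cds_out.items())), out.cds_fasta)
    write_gff3(models, out.gff3)
    write_te_bed([], out.te_bed)
    return out
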