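"""End-to-end synthetic pipeline: generate, identify, merge, analyse, report.

One call runs every stage of the kinome analysis on a seeded synthetic
dataset and persists all intermediate tables, so two runs with the same
seed produce byte-identical output trees.  The stages mirror a real-data
run: identify kinases in a chromosome-level and a scaffold-level assembly,
merge them into a non-redundant kinome, detect tandem/segmental
duplications and TE associations on the chromosome-anchored genes, quantify
subfamily expression, and build control vs stress coexpression networks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import duplication, merge, network, report, synthetic, te
from .expression import (
    aggregate_subfamily,
    average_replicates,
    compute_tpm,
    qc_filter_samples,
    read_sample_metadata,
)
from .identify import identify_kinome, kinome_to_frame
from .io import read_fasta, read_te_bed, read_tsv_matrix, write_tsv_matrix
from .profiles import default_profile_set

_CONTROL_TISSUES = (
    "leaf", "latex", "bark", "root", "seed", "flower", "petiole", "leaf",
    "latex", "bark", "leaf", "latex", "seed", "root", "leaf", "latex",
)
_STRESS = (
    ("leaf", "stress:cold"), ("leaf", "stress:drought"),
    ("latex", "stress:overexploitation"), ("bark", "stress:cold"),
    ("root", "stress:drought"), ("leaf", "stress:cold"),
    ("latex", "stress:drought"), ("bark", "stress:drought"),
    ("leaf", "stress:drought"), ("latex", "stress:cold"),
    ("bark", "stress:overexploitation"), ("leaf", "stress:cold"),
    ("root", "stress:cold"), ("latex", "stress:drought"),
)
DEFAULT_SAMPLES: tuple[tuple[str, str, int], ...] = tuple(
    [(t, "control", 2) for t in _CONTROL_TISSUES]
    + [(t, c, 2) for t, c in _STRESS]
)


@dataclass
class PipelineConfig:
    """Problem sizes and thresholds of a synthetic end-to-end run."""

    n_chromosomes: int = 6
    n_genes: int = 48
    tandem_spec: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(3, 5_000, 0.98), (2, 8_000, 0.975), (2, 12_000, 0.97)]
    )
    segmental_spec: tuple[float, ...] = (0.92, 0.80)
    # ~2 TEs/Mbp keeps the 100 kb association window informative: a minority
    # of genes associated, rather than none or all
    te_density: float = 2.0
    decoy_fraction: float = 0.25
    samples_spec: tuple[tuple[str, str, int], ...] = DEFAULT_SAMPLES
    block_correlation: float = 0.9
    noise_sd: float = 0.1
    evalue_max: float = 1e-10
    coverage_min: float = 0.5
    merge_id_min: float = 0.95
    merge_len_ratio_min: float = 0.75
    tandem_max_gap: int = 25_000
    tandem_id_min: float = 0.95
    tandem_cov_min: float = 0.75
    te_window: int = 100_000
    qc_min_detected: float = 0.10
    pcc_min: float = 0.7


def run_synthetic_pipeline(
    seed: int, out_dir: str | Path, config: PipelineConfig | None = None
) -> dict:
    """Run every stage on synthetic data; returns the summary report dict.

    Output tree: ``genome_chr/``, ``genome_scaf/``, ``expr/`` with the
    generated inputs, plus ``kinome.tsv``, ``merge_clusters.tsv``,
    ``tandem_clusters.tsv``, ``te_associations.tsv``,
    ``subfamily_tpm.tsv``, per-condition network tables and
    ``report.json``.
    """
    cfg = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profile_set = default_profile_set()

    # --- generate two assemblies and their domain hits ---------------------
    bundle = synthetic.generate_genome(
        n_chromosomes=cfg.n_chromosomes, n_genes=cfg.n_genes,
        tandem_spec=cfg.tandem_spec, te_density=cfg.te_density,
        seed=seed, out_dir=out_dir / "genome_chr", profile_set=profile_set,
        decoy_fraction=cfg.decoy_fraction, segmental_spec=cfg.segmental_spec,
        te_window=cfg.te_window,
    )
    hits_chr = synthetic.generate_domain_hits(
        bundle, out_dir / "genome_chr" / "hits.domtbl", noise_spec=0.5,
        seed=seed + 1,
    )
    scaffold = synthetic.derive_second_assembly(
        bundle, seed=seed + 2, out_dir=out_dir / "genome_scaf",
        profile_set=profile_set,
    )
    hits_scaf = synthetic.generate_domain_hits(
        scaffold, out_dir / "genome_scaf" / "hits.domtbl", noise_spec=0.5,
        seed=seed + 3,
    )

    # --- identify per assembly, then merge ---------------------------------
    kinome_chr = identify_kinome(
        hits_chr, bundle.proteins_fasta, bundle.gff3, bundle.cds_fasta,
        profile_set=profile_set, source_assembly="Hb_chr",
        evalue_max=cfg.evalue_max, coverage_min=cfg.coverage_min,
    )
    kinome_scaf = identify_kinome(
        hits_scaf, scaffold.proteins_fasta, scaffold.gff3, scaffold.cds_fasta,
        profile_set=profile_set, source_assembly="Hb_scaf",
        evalue_max=cfg.evalue_max, coverage_min=cfg.coverage_min,
    )
    proteins = {**read_fasta(bundle.proteins_fasta), **read_fasta(scaffold.proteins_fasta)}
    merged, clusters = merge.merge_kinomes(
        kinome_chr, kinome_scaf, id_min=cfg.merge_id_min,
        len_ratio_min=cfg.merge_len_ratio_min,
        sequences={k.protein_id: proteins[k.protein_id] for k in kinome_chr + kinome_scaf},
    )
    kinome_to_frame(merged).to_csv(out_dir / "kinome.tsv", sep="\t", index=False)
    merge.cluster_report(clusters).to_csv(
        out_dir / "merge_clusters.tsv", sep="\t", index=False
    )
    source_counts: dict[str, int] = {}
    for k in merged:
        source_counts[k.source_assembly] = source_counts.get(k.source_assembly, 0) + 1

    # --- duplication analysis on the chromosome-anchored genes -------------
    # tandem/segmental/TE analyses need chromosome coordinates, which only
    # the chromosome-level assembly provides
    anchored = kinome_chr
    cds = {k.gene_id: k.cds_sequence for k in anchored}
    pairs = duplication.similarity_search(cds, evalue_max=cfg.evalue_max)
    tandem = duplication.detect_tandem_clusters(
        anchored, pairs, max_gap=cfg.tandem_max_gap, id_min=cfg.tandem_id_min,
        cov_min=cfg.tandem_cov_min, evalue_max=cfg.evalue_max,
    )
    tiers = duplication.tier_segmental(anchored, pairs)
    duplication.pairs_to_frame(pairs).to_csv(
        out_dir / "similarity_pairs.tsv", sep="\t", index=False
    )
    duplication.clusters_to_frame(tandem).to_csv(
        out_dir / "tandem_clusters.tsv", sep="\t", index=False
    )

    # --- TE association -----------------------------------------------------
    tes = read_te_bed(bundle.te_bed)
    associations = te.associate_tes(
        anchored, tes, window=cfg.te_window,
        known_chromosomes=set(bundle.chromosome_lengths),
    )
    te_summary = te.summarize_te_overlap(associations, anchored, tandem)
    te.associations_to_frame(associations).to_csv(
        out_dir / "te_associations.tsv", sep="\t", index=False
    )

    # --- expression ---------------------------------------------------------
    counts_p, lengths_p, meta_p = synthetic.generate_expression(
        bundle.truth, list(cfg.samples_spec), cfg.block_correlation,
        cfg.noise_sd, seed + 4, out_dir / "expr", bundle=bundle,
    )
    counts = read_tsv_matrix(counts_p)
    lengths = read_tsv_matrix(lengths_p)["length"]
    metadata = read_sample_metadata(meta_p)
    tpm = compute_tpm(counts, lengths, metadata)
    tpm, qc_log = qc_filter_samples(tpm, cfg.qc_min_detected)
    averaged = average_replicates(tpm)
    subfamily_of_transcript = {
        k.protein_id: k.subfamily for k in merged if k.subfamily != "Unknown"
    }
    subfam_expr, member_counts = aggregate_subfamily(averaged, subfamily_of_transcript)
    write_tsv_matrix(subfam_expr.values, out_dir / "subfamily_tpm.tsv")
    qc_log.to_csv(out_dir / "qc_excluded.tsv", sep="\t", index=False)

    # --- networks ------------------------------------------------------------
    net_control = network.build_network(subfam_expr, "control", cfg.pcc_min)
    net_stress = network.build_network(subfam_expr, "stress", cfg.pcc_min)
    comparison = network.compare_networks(net_control, net_stress)
    for net, label in ((net_control, "control"), (net_stress, "stress")):
        network.topology_frame(net).to_csv(
            out_dir / f"network_{label}_nodes.tsv", sep="\t", index=False
        )
        network.edge_frame(net).to_csv(
            out_dir / f"network_{label}_edges.tsv", sep="\t", index=False
        )

    # --- summary -------------------------------------------------------------
    summary = report.summary_report(
        merged, tandem, te_summary, comparison, merge_sources=source_counts
    )
    summary["segmental_tier_sizes"] = {
        f"{t.threshold:.2f}": len(t.pairs) for t in tiers
    }
    summary["qc_excluded_samples"] = list(qc_log["sample"]) if len(qc_log) else []
    report.write_report_json(summary, out_dir / "report.json")

    return {
        "config": dataclasses.asdict(cfg),
        "bundle": bundle,
        "scaffold": scaffold,
        "kinome": merged,
        "merge_clusters": clusters,
        "pairs": pairs,
        "tandem": tandem,
        "tiers": tiers,
        "te_summary": te_summary,
        "subfamily_expression": subfam_expr,
        "net_control": net_control,
        "net_stress": net_stress,
        "comparison": comparison,
        "report": summary,
    }
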