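"""Kinome summary report assembly.

Percentages are computed as 100 * numerator / denominator and rounded
half-up at a per-field precision: two decimals for the assembly-source
composition, one decimal elsewhere — the conventions under which every
printed ratio of the study this pipeline reproduces recomputes exactly
from its numerator and denominator.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .duplication import TandemCluster, tandem_gene_ids
from .identify import KinaseGene


def percent(numerator: int | float, denominator: int | float, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def summary_report(
    kinome: Sequence[KinaseGene],
    tandem_clusters: Sequence[TandemCluster] = (),
    te_summary: Mapping | None = None,
    network_comparison: Mapping | None = None,
    merge_sources: Mapping[str, int] | None = None,
) -> dict:
    """Assemble the kinome-wide summary from the pipeline stage outputs.

    Fields with a zero denominator are omitted (with a ``warnings`` entry)
    rather than reported as undefined ratios.
    """
    report: dict = {"schema_version": 1}
    warnings: list[str] = []
    n = len(kinome)
    report["n_kinases"] = n

    group_counts: dict[str, int] = {}
    subfamily_counts: dict[str, int] = {}
    per_chromosome: dict[str, int] = {}
    n_unknown = n_intronless = n_multidomain = 0
    for k in kinome:
        group_counts[k.group] = group_counts.get(k.group, 0) + 1
        subfamily_counts[k.subfamily] = subfamily_counts.get(k.subfamily, 0) + 1
        per_chromosome[k.chromosome] = per_chromosome.get(k.chromosome, 0) + 1
        n_unknown += k.subfamily == "Unknown"
        n_intronless += k.intron_count == 0
        n_multidomain += k.n_kinase_domains > 1
    report["group_counts"] = dict(sorted(group_counts.items()))
    report["subfamily_counts"] = dict(sorted(subfamily_counts.items()))
    report["per_chromosome_counts"] = dict(sorted(per_chromosome.items()))
    report["n_multidomain"] = n_multidomain
    if n:
        report["pct_unknown"] = percent(n_unknown, n)
        report["pct_intronless"] = percent(n_intronless, n)
    else:
        warnings.append("empty kinome: fractions omitted")

    if merge_sources is not None:
        total = sum(merge_sources.values())
        report["source_counts"] = dict(sorted(merge_sources.items()))
        if total:
            report["source_pct"] = {
                s: percent(c, total, decimals=2)
                for s, c in sorted(merge_sources.items())
            }
        else:
            warnings.append("empty merge source counts")

    tandem_genes = tandem_gene_ids(tandem_clusters)
    report["n_tandem_clusters"] = len(tandem_clusters)
    report["n_tandem_genes"] = len(tandem_genes)
    if n:
        report["pct_tandem_genes"] = percent(len(tandem_genes), n)
    tandem_subfams = sorted(
        {sf for cl in tandem_clusters for sf in cl.subfamilies.values()}
    )
    report["n_tandem_subfamilies"] = len(tandem_subfams)

    if te_summary is not None:
        report["te"] = {
            "n_associated": te_summary["n_associated"],
            "pct_associated": (
                percent(te_summary["n_associated"], n) if n else None
            ),
            "n_associated_tandem": te_summary["n_associated_tandem"],
            "pct_associated_tandem": (
                percent(
                    te_summary["n_associated_tandem"], te_summary["n_associated"]
                )
                if te_summary["n_associated"]
                else 0.0
            ),
            "te_class_counts": dict(te_summary["te_class_counts"]),
        }

    if network_comparison is not None:
        report["network"] = {
            k: network_comparison[k]
            for k in (
                "n_edges_control", "n_edges_stress", "n_shared_edges",
                "n_unique_control", "n_unique_stress", "pct_edge_loss",
                "isolated_control", "isolated_stress",
            )
        }

    if warnings:
        report["warnings"] = warnings
    return report


def write_report_json(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def properties_frame(
    kinome: Sequence[KinaseGene], proteins: Mapping[str, str]
) -> pd.DataFrame:
    """Per-gene property table (MW, pI, introns, domain counts)."""
    from .properties import isoelectric_point, molecular_weight

    rows = []
    for k in kinome:
        seq = proteins[k.protein_id]
        rows.append(
            {
                "gene_id": k.gene_id,
                "protein_id": k.protein_id,
                "subfamily": k.subfamily,
                "group": k.group,
                "protein_length": len(seq),
                "molecular_weight": round(molecular_weight(seq), 2),
                "isoelectric_point": round(isoelectric_point(seq), 2),
                "intron_count": k.intron_count,
                "n_kinase_domains": k.n_kinase_domains,
                "intronless": k.intron_count == 0,
            }
        )
    return pd.DataFrame(rows)
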