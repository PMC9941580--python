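"""TPM normalization, sample QC, replicate averaging and subfamily aggregation.

Quantifications arrive as a transcripts x samples count table plus a
transcript-length table (plain CDS lengths; effective-length modelling
belongs to the quantifier).  TPM divides each count by its transcript
length and rescales every sample to one million, so columns are directly
comparable.  Replicate samples are combined by the arithmetic mean and
transcript-level values are averaged within each subfamily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_META_COLUMNS = ("tissue", "genotype", "condition", "replicate_group")


@dataclass
class ExpressionMatrix:
    """A transcripts-or-subfamilies x samples matrix with sample metadata."""

    values: pd.DataFrame
    metadata: pd.DataFrame  # indexed by sample id
    zero_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

    def condition_samples(self, condition: str) -> list[str]:
        """Samples for a condition; ``"stress"`` matches every ``stress:*`` label."""
        conds = self.metadata.loc[list(self.values.columns), "condition"]
        if condition == "stress":
            mask = conds.str.startswith("stress")
        else:
            mask = conds == condition
        return list(conds.index[mask])


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    return meta


def compute_tpm(
    counts: pd.DataFrame, lengths: pd.Series, metadata: pd.DataFrame
) -> ExpressionMatrix:
    """Transcripts-per-million normalization.

    Per sample: rate_i = count_i / length_i, TPM_i = 1e6 * rate_i / sum(rate).
    All-zero samples come out all-zero and are flagged in ``zero_samples``.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise KeyError(f"no length for transcripts: {list(missing)[:5]}")
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero_samples = list(totals.index[totals == 0])
    safe_totals = totals.replace(0, np.nan)
    tpm = rates.div(safe_totals, axis=1).fillna(0.0) * 1e6
    return ExpressionMatrix(values=tpm, metadata=metadata, zero_samples=zero_samples)


def qc_filter_samples(
    matrix: ExpressionMatrix, min_detected_fraction: float = 0.10
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop samples whose detected (TPM > 0) transcript fraction is too low.

    Returns the filtered matrix and a log of exclusions with the computed
    fraction per excluded sample.
    """
    if not 0 <= min_detected_fraction <= 1:
        raise ValueError("min_detected_fraction must be in [0, 1]")
    detected = (matrix.values > 0).mean(axis=0)
    excluded = detected[detected < min_detected_fraction]
    keep = [s for s in matrix.values.columns if s not in excluded.index]
    log = (
        excluded.rename("detected_fraction")
        .rename_axis("sample")
        .reset_index()
    )
    filtered = ExpressionMatrix(
        values=matrix.values[keep],
        metadata=matrix.metadata,
        zero_samples=[s for s in matrix.zero_samples if s in keep],
    )
    return filtered, log


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Mean expression per replicate group; metadata collapses to one row per group.

    Replicates of one group must agree on tissue and condition.
    """
    meta = matrix.metadata.loc[list(matrix.values.columns)]
    for group, sub in meta.groupby("replicate_group"):
        if sub["condition"].nunique() > 1:
            raise ValueError(f"replicate group {group!r} mixes conditions")
        if sub["tissue"].nunique() > 1:
            raise ValueError(f"replicate group {group!r} mixes tissues")
    groups = sorted(meta["replicate_group"].unique())
    values = pd.DataFrame(
        {
            g: matrix.values[meta.index[meta["replicate_group"] == g]].mean(axis=1)
            for g in groups
        }
    )
    collapsed = (
        meta.drop_duplicates("replicate_group")
        .set_index("replicate_group")
        .loc[groups]
    )
    collapsed.index.name = "sample"
    return ExpressionMatrix(values=values, metadata=collapsed)


def aggregate_subfamily(
    matrix: ExpressionMatrix, subfamily_of: dict[str, str]
) -> tuple[ExpressionMatrix, pd.Series]:
    """Mean expression of member transcripts per subfamily per sample.

    Transcripts without a subfamily assignment are ignored; subfamilies with
    no quantified member are absent from the output.  Also returns the
    member count per subfamily.
    """
    mapped = [t for t in matrix.values.index if t in subfamily_of]
    labels = pd.Series({t: subfamily_of[t] for t in mapped})
    grouped = matrix.values.loc[mapped].groupby(labels).mean()
    grouped = grouped.sort_index()
    counts = labels.value_counts().sort_index().rename("n_members")
    return (
        ExpressionMatrix(values=grouped, metadata=matrix.metadata),
        counts,
    )


def heatmap_order(values: pd.DataFrame) -> list[str]:
    """Row order from average-linkage hierarchical clustering on Euclidean distance.

    Presentation helper for subfamily heatmaps; returns the leaf order.
    """
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import pdist

    if len(values) < 3:
        return list(values.index)
    linkage = average(pdist(values.values))
    return [values.index[i] for i in leaves_list(linkage)]
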