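"""Gene-level expression summarization and differential expression.

Transcript-cluster values can lump together distinct genes sharing only
a few probesets, so gene expression is instead summarized from the
probesets mapped to the gene's *known isoforms* (non-empty isoform
membership in the annotation).  The per-sample gene summary feeds a
log2 fold change (normal - pathological, matching the exon-level sign
convention) and a Student's t-test.

Genes whose annotation carries no isoform-mapped probesets fall back to
all of their probesets, with a logged warning, rather than being
dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import Dataset
from .exon_stats import _two_group_indices, exon_ttest
from .summarize import summarize_matrix

__all__ = ["summarize_gene", "gene_fold_change_and_test", "compute_gene_stats"]

logger = logging.getLogger(__name__)


def summarize_gene(
    expression: pd.DataFrame,
    probeset_ids,
    method: str = "median_polish",
) -> pd.Series:
    """Per-sample gene expression from the given probesets.

    ``median_polish``: overall + sample effect of a Tukey median polish
    (max 10 sweeps, tolerance 1e-6); ``mean``: column means.
    """
    probeset_ids = list(probeset_ids)
    if not probeset_ids:
        raise ValueError("summarize_gene needs a non-empty probeset set")
    missing = [p for p in probeset_ids if p not in expression.index]
    if missing:
        raise ValueError(f"probeset {missing[0]!r} absent from the expression matrix")
    return summarize_matrix(expression.loc[probeset_ids], method=method)


def gene_fold_change_and_test(
    summary: pd.Series,
    groups: pd.Series,
    paired: bool = False,
    pairing: pd.Series | None = None,
) -> tuple[float, float]:
    """Gene log2 fold change (normal - pathological) and t-test p-value."""
    a, b = _two_group_indices(groups)
    x = summary.to_numpy(dtype=float)
    fc = float(x[a].mean() - x[b].mean())
    frame = summary.to_frame().T
    p = float(exon_ttest(frame, groups, paired=paired, pairing=pairing).iloc[0])
    return fc, p


def isoform_mapped_probesets(dataset: Dataset, gene_id: str) -> list[str]:
    """Probesets of the gene with non-empty isoform membership, falling
    back to all of the gene's probesets when none are isoform-mapped."""
    ann = dataset.probesets
    members = ann.index[ann["gene_id"] == gene_id]
    mapped = [p for p in members if len(ann.at[p, "isoform_ids"]) > 0]
    if not mapped:
        logger.warning(
            "gene %s has no isoform-mapped probesets; falling back to all %d probesets",
            gene_id,
            len(members),
        )
        return list(members)
    return mapped


def compute_gene_stats(
    dataset: Dataset,
    method: str = "median_polish",
    paired: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level table plus the per-sample gene summary matrix.

    Returns ``(stats, summaries)`` where ``stats`` has one row per gene
    (symbol, log2 fold change, t-test p, number of probesets used) and
    ``summaries`` is genes x samples.
    """
    groups = dataset.condition
    pairing = dataset.samples["patient_id"] if "patient_id" in dataset.samples else None
    rows = []
    summaries = {}
    for gene_id in dataset.genes.index:
        probesets = isoform_mapped_probesets(dataset, gene_id)
        probesets = [p for p in probesets if p in dataset.expression.index]
        if not probesets:
            logger.warning("gene %s has no probesets in the expression matrix", gene_id)
            continue
        summary = summarize_gene(dataset.expression, probesets, method=method)
        fc, p = gene_fold_change_and_test(summary, groups, paired=paired, pairing=pairing)
        rows.append(
            {
                "gene_id": gene_id,
                "symbol": dataset.genes.at[gene_id, "symbol"],
                "gene_log2_fc": fc,
                "gene_t_p": p,
                "n_probesets_used": len(probesets),
            }
        )
        summaries[gene_id] = summary
    stats = pd.DataFrame(rows).set_index("gene_id")
    summary_matrix = pd.DataFrame.from_dict(summaries, orient="index")
    summary_matrix.index.name = "gene_id"
    if len(summary_matrix):
        summary_matrix = summary_matrix.loc[:, dataset.expression.columns]
    return stats, summary_matrix
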