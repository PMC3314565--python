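"""End-to-end analysis orchestration.

``run_analyze`` executes the full statistics chain on a loaded dataset —
transcript-cluster normalization, exon-level statistics, DABG filtering,
gene-level statistics, meta statistics — and writes one TSV per stage
plus a JSON run manifest.  Re-running with identical inputs and seed
reproduces byte-identical tables.

``run_trees`` fits a conditional-inference tree per requested probeset
on its cluster-normalized expression and writes one JSON tree per
probeset, a summary TSV and the suggested sample groupings.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import pandas as pd

from . import __version__
from .datamodel import Dataset
from .exon_stats import cluster_summary, compute_exon_stats, normalize_exons
from .gene_stats import compute_gene_stats
from .io import write_table
from .meta_stats import compute_meta
from .tree import TreeConfig, grow_tree, suggest_groups

__all__ = ["AnalyzeParams", "run_analyze", "run_trees"]


@dataclass(frozen=True)
class AnalyzeParams:
    """Thresholds and switches of the analysis chain (all report-time
    tunable; defaults follow the package's documented conventions)."""

    paired: bool = False
    summary_method: str = "median_polish"
    dabg_threshold: float = 0.05
    dabg_min_fraction: float = 0.5
    dabg_mode: str = "either"
    adjust: str = "none"
    si_threshold: float = 0.5
    p_threshold: float = 0.05
    seed: int = 0


def run_analyze(
    dataset: Dataset,
    outdir: str | os.PathLike,
    params: AnalyzeParams = AnalyzeParams(),
) -> dict[str, str]:
    """Run normalize -> exon stats -> DABG filter -> gene stats -> meta
    stats and write ``exon_stats.tsv``, ``gene_stats.tsv``,
    ``meta_stats.tsv`` and ``manifest.json`` into ``outdir``.

    Returns the mapping of output names to paths.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    exon = compute_exon_stats(
        dataset,
        paired=params.paired,
        summary_method=params.summary_method,
        dabg_threshold=params.dabg_threshold,
        dabg_min_fraction=params.dabg_min_fraction,
        dabg_mode=params.dabg_mode,
        adjust=params.adjust,
        si_threshold=params.si_threshold,
        p_threshold=params.p_threshold,
    )
    paths["exon_stats"] = os.path.join(outdir, "exon_stats.tsv")
    write_table(exon, paths["exon_stats"])

    gene, _ = compute_gene_stats(
        dataset, method=params.summary_method, paired=params.paired
    )
    paths["gene_stats"] = os.path.join(outdir, "gene_stats.tsv")
    write_table(gene, paths["gene_stats"])

    meta = compute_meta(exon, use_filtered=False)
    paths["meta_stats"] = os.path.join(outdir, "meta_stats.tsv")
    write_table(meta, paths["meta_stats"])

    manifest = {
        "tool": "exonflow",
        "version": __version__,
        "params": asdict(params),
        "n_probesets": int(len(exon)),
        "n_probesets_filtered": int(exon["filtered"].sum()),
        "n_genes": int(len(gene)),
        "n_genes_meta": int(len(meta)),
        "n_samples": int(dataset.expression.shape[1]),
    }
    paths["manifest"] = os.path.join(outdir, "manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def run_trees(
    dataset: Dataset,
    probeset_ids: list[str],
    outdir: str | os.PathLike,
    config: TreeConfig = TreeConfig(),
    summary_method: str = "median_polish",
    include_condition: bool = True,
) -> dict[str, str]:
    """Fit one conditional-inference tree per probeset.

    The response is the probeset's cluster-normalized expression; the
    covariates are condition (optional) plus every clinical covariate in
    the metadata.  Writes ``tree_<probeset>.json`` per probeset plus
    ``tree_summary.tsv`` (root variable, root adjusted p, depth, number
    of leaves) and ``tree_groups.tsv`` (per-sample leaf labels).
    """
    os.makedirs(outdir, exist_ok=True)
    missing = [p for p in probeset_ids if p not in dataset.expression.index]
    if missing:
        raise KeyError(f"probeset {missing[0]!r} absent from the expression matrix")
    g = cluster_summary(dataset.expression, dataset.probesets, method=summary_method)
    e = normalize_exons(dataset.expression, g, dataset.probesets)
    covariates = dataset.covariate_table(include_condition=include_condition)

    paths: dict[str, str] = {}
    summary_rows = []
    group_cols = {}
    for ps in probeset_ids:
        tree = grow_tree(e.loc[ps], covariates, config)
        tree_path = os.path.join(outdir, f"tree_{ps}.json")
        with open(tree_path, "w") as fh:
            fh.write(tree.to_json(indent=2))
            fh.write("\n")
        paths[f"tree_{ps}"] = tree_path
        labels, rules = suggest_groups(tree, covariates)
        group_cols[ps] = labels.map(lambda leaf: rules[leaf])
        summary_rows.append(
            {
                "probeset_id": ps,
                "root_variable": tree.variable if tree.kind == "internal" else "",
                "root_adjusted_p": tree.adjusted_p if tree.kind == "internal" else "",
                "depth": tree.max_depth(),
                "n_leaves": len(tree.leaves()),
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("probeset_id")
    paths["tree_summary"] = os.path.join(outdir, "tree_summary.tsv")
    write_table(summary, paths["tree_summary"])
    groups = pd.DataFrame(group_cols)
    groups.index.name = "sample_id"
    paths["tree_groups"] = os.path.join(outdir, "tree_groups.tsv")
    write_table(groups, paths["tree_groups"])
    return paths
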