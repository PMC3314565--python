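"""Per-gene result reports.

A gene report bundles, in three sections, everything the analysis knows
about one gene:

1. **annotation** — symbol, aliases, genomic position, pathway and GO
   membership;
2. **exon level** — the per-probeset statistics ordered along the gene
   in transcription order, the splicing-index profile with a
   traffic-light significance colour per probeset (green: MiDAS
   p >= 0.05, amber: 0.01 <= p < 0.05, red: p < 0.01), flagged
   probesets marked, and the isoform-membership matrix showing which
   probesets each isoform contains;
3. **gene level** — fold change and t-test p, meta statistics, and the
   pathway/GO neighbours ranked by scaled Euclidean distance.

Every number in the report is copied from the stage tables — nothing is
recomputed — so report content and TSV outputs can never drift apart.
"""

from __future__ import annotations

import math

import pandas as pd

from .datamodel import Dataset
from .meta_stats import rank_within_set, scale_meta

__all__ = ["traffic_light", "isoform_matrix", "build_gene_report", "plot_gene"]


def traffic_light(p: float) -> str:
    """Significance colour for a MiDAS p-value."""
    if math.isnan(p):
        return "grey"
    if p < 0.01:
        return "red"
    if p < 0.05:
        return "amber"
    return "green"


def isoform_matrix(dataset: Dataset, gene_id: str) -> pd.DataFrame:
    """Isoforms x probesets boolean membership for one gene."""
    ann = dataset.probesets
    members = ann.loc[ann["gene_id"] == gene_id]
    isoforms = sorted({iso for s in members["isoform_ids"] for iso in s})
    return pd.DataFrame(
        {ps: [iso in members.at[ps, "isoform_ids"] for iso in isoforms] for ps in members.index},
        index=pd.Index(isoforms, name="isoform_id"),
    )


def _transcription_order(members: pd.DataFrame) -> list[str]:
    """Probesets ordered by genomic start, flipped on the minus strand so
    exon index increases left to right."""
    ascending = (members["strand"].iloc[0] == "+") if len(members) else True
    return list(members.sort_values("start", ascending=ascending).index)


def build_gene_report(
    gene_id: str,
    dataset: Dataset,
    exon_stats: pd.DataFrame,
    gene_stats: pd.DataFrame,
    meta_stats: pd.DataFrame,
    tree_summary: pd.DataFrame | None = None,
    max_neighbors: int = 10,
) -> dict:
    """Assemble the three-section report for one gene as a JSON-ready dict."""
    if gene_id not in dataset.genes.index:
        raise KeyError(f"unknown gene {gene_id!r}")
    gene = dataset.genes.loc[gene_id]
    members = dataset.probesets.loc[dataset.probesets["gene_id"] == gene_id]
    order = _transcription_order(members)

    exon_rows = []
    for ps in order:
        if ps not in exon_stats.index:
            continue
        rec = exon_stats.loc[ps]
        exon_rows.append(
            {
                "probeset_id": ps,
                "exon_index": int(members.at[ps, "exon_index"]),
                "start": int(members.at[ps, "start"]),
                "stop": int(members.at[ps, "stop"]),
                "splicing_index": float(rec["splicing_index"]),
                "log2_fold_change": float(rec["log2_fold_change"]),
                "t_p": float(rec["t_p"]),
                "midas_p": float(rec["midas_p"]),
                "filtered": bool(rec.get("filtered", False)),
                "flagged": bool(rec.get("flagged", False)),
                "color": traffic_light(float(rec["midas_p"])),
            }
        )

    iso = isoform_matrix(dataset, gene_id)

    neighbors: dict[str, dict[str, list]] = {"pathway": {}, "go": {}}
    if len(meta_stats) >= 2 and dataset.gene_sets is not None:
        scaled, _ = scale_meta(meta_stats)
        if gene_id in scaled.index:
            for kind, key in (("pathway", "pathway_ids"), ("go", "go_ids")):
                for set_id in sorted(gene[key]):
                    ranked = rank_within_set(gene_id, set_id, scaled, dataset.gene_sets)
                    neighbors[kind][set_id] = [
                        {"gene_id": g, "distance": d} for g, d in ranked[:max_neighbors]
                    ]

    report = {
        "gene": {
            "gene_id": gene_id,
            "symbol": gene["symbol"],
            "aliases": list(gene["aliases"]),
            "chrom": gene["chrom"],
            "start": int(gene["start"]),
            "stop": int(gene["stop"]),
            "strand": gene["strand"],
            "pathways": sorted(gene["pathway_ids"]),
            "go_terms": sorted(gene["go_ids"]),
        },
        "exon_level": {
            "probesets": exon_rows,
            "isoform_matrix": {
                "isoforms": list(iso.index),
                "probesets": list(iso.columns),
                "membership": iso.to_numpy().tolist(),
            },
        },
        "gene_level": {
            "stats": (
                {
                    "gene_log2_fc": float(gene_stats.at[gene_id, "gene_log2_fc"]),
                    "gene_t_p": float(gene_stats.at[gene_id, "gene_t_p"]),
                    "n_probesets_used": int(gene_stats.at[gene_id, "n_probesets_used"]),
                }
                if gene_id in gene_stats.index
                else None
            ),
            "meta": (
                meta_stats.loc[gene_id].to_dict() if gene_id in meta_stats.index else None
            ),
            "neighbors": neighbors,
        },
    }
    if tree_summary is not None:
        trees = tree_summary.loc[tree_summary.index.isin(order)]
        report["trees"] = trees.reset_index().to_dict(orient="records")
    return report


def plot_gene(report: dict, path: str) -> None:
    """Static splicing-index profile with traffic-light colouring."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = report["exon_level"]["probesets"]
    if not rows:
        raise ValueError("gene report has no probesets to plot")
    xs = range(len(rows))
    si = [r["splicing_index"] for r in rows]
    colors = [r["color"] for r in rows]
    color_map = {"green": "#2ca02c", "amber": "#ff9f1c", "red": "#d62728", "grey": "#999999"}
    fig, ax = plt.subplots(figsize=(max(4, len(rows) * 0.6), 3))
    ax.axhline(0.0, color="#cccccc", lw=1)
    ax.plot(xs, si, color="#555555", lw=1, zorder=1)
    ax.scatter(xs, si, c=[color_map[c] for c in colors], s=60, zorder=2)
    for x, r in zip(xs, rows):
        if r["flagged"]:
            ax.annotate("*", (x, r["splicing_index"]), textcoords="offset points",
                        xytext=(0, 8), ha="center")
    ax.set_xticks(list(xs))
    ax.set_xticklabels([r["probeset_id"] for r in rows], rotation=90, fontsize=7)
    ax.set_ylabel("splicing index")
    ax.set_title(report["gene"]["symbol"])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
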