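"""Per-gene meta statistics and distance-based gene ranking.

A gene with a genuine splicing event shows a characteristic profile
across its probesets: a very low p-value for the spliced exon(s) and
unremarkable values elsewhere.  Meta statistics capture this profile as
the minimum, maximum, mean and sample variance of each exon-level base
statistic (t-test p, MiDAS p, splicing index, log2 fold change) over
the gene's probesets — a 16-component feature vector per gene.

Genes are compared in this feature space by Euclidean distance after
per-component z-score standardization ("variables scaling"), which
makes ranking the whole case study against a query point — or against a
focal gene within a pathway or GO term — a single cheap vector
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BASE_STATISTICS",
    "META_COMPONENTS",
    "QueryPoint",
    "ScalingParams",
    "compute_meta",
    "scale_meta",
    "unscale_meta",
    "rank_by_distance",
    "rank_within_set",
    "search_genes",
    "default_as_query",
]

BASE_STATISTICS = ("t_p", "midas_p", "splicing_index", "log2_fold_change")
SUMMARIES = ("min", "max", "mean", "var")
#: the 16 named meta-statistic components, in canonical column order
META_COMPONENTS = tuple(f"{s}_{m}" for s in BASE_STATISTICS for m in SUMMARIES)


@dataclass(frozen=True)
class QueryPoint:
    """A search-page query: target values for a subset of components.

    Components present in ``values`` are active; all others are ignored
    by the distance.  At least one component must be active for ranking.
    """

    values: dict[str, float] = field(default_factory=dict)

    @property
    def active(self) -> tuple[str, ...]:
        return tuple(self.values)

    def validate(self) -> "QueryPoint":
        unknown = [c for c in self.values if c not in META_COMPONENTS]
        if unknown:
            raise ValueError(f"unknown meta component {unknown[0]!r}")
        if not self.values:
            raise ValueError("query has no active components")
        return self


@dataclass(frozen=True)
class ScalingParams:
    """Per-component centre/scale so queries map into the scaled space."""

    mean: pd.Series
    sd: pd.Series

    def transform(self, values: dict[str, float]) -> dict[str, float]:
        out = {}
        for comp, v in values.items():
            sd = self.sd[comp]
            out[comp] = 0.0 if sd == 0 else (v - self.mean[comp]) / sd
        return out


def compute_meta(
    exon_stats: pd.DataFrame,
    annotation: pd.DataFrame | pd.Series | None = None,
    use_filtered: bool = False,
) -> pd.DataFrame:
    """Min/max/mean/variance of each base statistic per gene.

    ``use_filtered=False`` (default) excludes DABG-filtered probesets;
    genes left with no eligible probeset are omitted.  Sample variance
    uses the n-1 denominator and is defined as 0 for single-probeset
    genes.
    """
    table = exon_stats
    if "gene_id" not in table.columns:
        if annotation is None:
            raise ValueError("exon stats lack gene_id and no annotation was given")
        gene_of = (
            annotation["gene_id"] if isinstance(annotation, pd.DataFrame) else annotation
        )
        table = table.join(gene_of.rename("gene_id"))
    if not use_filtered and "filtered" in table.columns:
        table = table.loc[~table["filtered"].astype(bool)]
    rows = []
    for gene_id, sub in table.groupby("gene_id", sort=True):
        row: dict[str, object] = {"gene_id": gene_id, "n_probesets": len(sub)}
        for stat in BASE_STATISTICS:
            v = sub[stat].to_numpy(dtype=float)
            row[f"{stat}_min"] = v.min()
            row[f"{stat}_max"] = v.max()
            row[f"{stat}_mean"] = v.mean()
            row[f"{stat}_var"] = v.var(ddof=1) if len(v) > 1 else 0.0
        rows.append(row)
    out = pd.DataFrame(rows, columns=["gene_id", "n_probesets", *META_COMPONENTS])
    return out.set_index("gene_id")


def scale_meta(table: pd.DataFrame, method: str = "zscore") -> tuple[pd.DataFrame, ScalingParams]:
    """Standardize each meta component across genes.

    ``zscore``: (x - mean) / sd with population sd; a zero-variance
    component maps to all zeros.  ``minmax``: (x - min) / (max - min).
    Returns the scaled table and the parameters needed to place query
    points into the same space.
    """
    if len(table) < 2:
        raise ValueError("scaling needs >= 2 genes")
    cols = [c for c in META_COMPONENTS if c in table.columns]
    x = table[cols].astype(float)
    if method == "zscore":
        centre = x.mean(axis=0)
        scale = x.std(axis=0, ddof=0)
    elif method == "minmax":
        centre = x.min(axis=0)
        scale = x.max(axis=0) - centre
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    safe = scale.replace(0.0, 1.0)
    scaled = (x - centre) / safe
    scaled.loc[:, scale == 0.0] = 0.0
    return scaled, ScalingParams(mean=centre, sd=scale)


def unscale_meta(scaled: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Inverse of :func:`scale_meta` (degenerate components return the
    common centre value)."""
    return scaled * params.sd.replace(0.0, 1.0) + params.mean


def _distances(scaled: pd.DataFrame, point: dict[str, float]) -> pd.Series:
    comps = list(point)
    diff = scaled[comps].to_numpy(dtype=float) - np.array([point[c] for c in comps])
    return pd.Series(np.sqrt((diff**2).sum(axis=1)), index=scaled.index)


def rank_by_distance(
    scaled: pd.DataFrame, query: QueryPoint, params: ScalingParams | None = None
) -> list[tuple[str, float]]:
    """Genes ordered by Euclidean distance to the query over its active
    components (ascending; ties broken by gene id).

    If ``params`` is given the query is expressed on the original
    statistic scale and mapped into the scaled space first; otherwise it
    is taken to be already scaled.
    """
    query.validate()
    point = params.transform(query.values) if params is not None else dict(query.values)
    d = _distances(scaled, point)
    order = sorted(d.items(), key=lambda kv: (kv[1], kv[0]))
    return [(gid, float(dist)) for gid, dist in order]


def rank_within_set(
    focal_gene: str,
    set_id: str,
    scaled: pd.DataFrame,
    gene_sets: pd.DataFrame,
) -> list[tuple[str, float]]:
    """Members of a pathway/GO set ranked by full-vector distance to the
    focal gene (which must itself belong to the set; it is excluded from
    the result)."""
    members = gene_sets.loc[gene_sets["set_id"] == set_id, "gene_id"]
    if len(members) == 0:
        raise KeyError(f"unknown gene set {set_id!r}")
    members = [g for g in members if g in scaled.index]
    if focal_gene not in members:
        raise KeyError(f"gene {focal_gene!r} is not an analyzed member of {set_id!r}")
    others = [g for g in members if g != focal_gene]
    if not others:
        return []
    point = scaled.loc[focal_gene, list(META_COMPONENTS)].to_dict()
    d = _distances(scaled.loc[others], point)
    return [(g, float(v)) for g, v in sorted(d.items(), key=lambda kv: (kv[1], kv[0]))]


def search_genes(
    genes: pd.DataFrame,
    meta: pd.DataFrame,
    symbol: str | None = None,
    gene_id: str | None = None,
    chrom: str | None = None,
    start: int | None = None,
    stop: int | None = None,
    pathway: str | None = None,
    go: str | None = None,
    query: QueryPoint | None = None,
    scaled: pd.DataFrame | None = None,
    params: ScalingParams | None = None,
) -> pd.DataFrame:
    """Filter genes by annotation predicates, optionally ranking by a
    meta-statistics query.

    Filters are conjunctive: symbol/alias substring (case-insensitive),
    exact gene id, chromosome, genomic interval overlap, pathway and GO
    membership.  Without a query, survivors are ordered by gene id;
    with one, by :func:`rank_by_distance` (a ``distance`` column is
    appended).
    """
    if (start is None) != (stop is None):
        raise ValueError("start and stop must be given together")
    if start is not None and start > stop:
        raise ValueError(f"malformed interval: start {start} > stop {stop}")
    mask = pd.Series(True, index=genes.index)
    if symbol is not None:
        needle = symbol.lower()
        mask &= genes.apply(
            lambda rec: needle in str(rec["symbol"]).lower()
            or any(needle in a.lower() for a in rec["aliases"]),
            axis=1,
        )
    if gene_id is not None:
        mask &= genes.index == gene_id
    if chrom is not None:
        mask &= genes["chrom"] == chrom
    if start is not None:
        mask &= (genes["start"] <= stop) & (genes["stop"] >= start)
    if pathway is not None:
        mask &= genes["pathway_ids"].map(lambda s: pathway in s)
    if go is not None:
        mask &= genes["go_ids"].map(lambda s: go in s)
    survivors = genes.loc[mask].copy()
    survivors = survivors.join(meta, how="left")
    if query is None:
        return survivors.sort_index()
    if scaled is None:
        raise ValueError("a meta query needs the scaled meta table")
    ranked = rank_by_distance(scaled.loc[scaled.index.isin(survivors.index)], query, params)
    order = [g for g, _ in ranked]
    out = survivors.loc[order]
    out["distance"] = [d for _, d in ranked]
    return out


def default_as_query(meta: pd.DataFrame) -> QueryPoint:
    """A reconstruction of a sensible default splicing-event query: an
    isolated strong signal (minimum p-values at 0) against an otherwise
    quiet gene (mean t-test p at 1), with the splicing-index peak set to
    the largest magnitude observed in the case study."""
    si_peak = float(meta["splicing_index_max"].abs().max())
    return QueryPoint(
        values={
            "t_p_min": 0.0,
            "midas_p_min": 0.0,
            "t_p_mean": 1.0,
            "splicing_index_max": si_peak,
        }
    )
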