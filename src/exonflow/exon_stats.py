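"""Exon-level alternative-splicing statistics.

Each probeset interrogates (at most) one exon.  To separate exon-specific
changes from changes of the whole gene, probeset log2 intensities are
first normalized by subtracting the transcript-cluster summary of their
cluster, per sample:

    e[ps, s] = x[ps, s] - g[tc(ps), s]

(the log-space equivalent of dividing linear intensities by the gene
estimate).  On the normalized values the module computes, per probeset:

* **splicing index** — mean(e, normal) - mean(e, pathological); positive
  when the normal signal is higher;
* **Student's t-test** — two-sample equal-variance t on e (or a paired t
  on within-pair differences), two-sided;
* **MiDAS-style p-value** — one-way fixed-effects ANOVA across the
  experimental groups on e; for two groups this reduces exactly to the
  unpaired t-test (F = t^2);
* **fold change** — the group difference of the *raw* log2 intensities,
  deliberately not normalized for overall gene expression;
* **DABG detection fractions** — per group, the fraction of samples in
  which the probeset is detected above background, used to flag
  unreliable probesets.

Degenerate zero-variance inputs yield p = 1 (no evidence), never NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special

from .datamodel import Dataset, NORMAL, PATHOLOGICAL, ValidationError
from .summarize import summarize_matrix

__all__ = [
    "cluster_summary",
    "normalize_exons",
    "splicing_index",
    "exon_fold_change",
    "exon_ttest",
    "midas_pvalue",
    "dabg_detection",
    "filter_by_dabg",
    "adjust_pvalues",
    "compute_exon_stats",
]

DEFAULT_SI_THRESHOLD = 0.5
DEFAULT_P_THRESHOLD = 0.05


def _group_columns(groups: pd.Series) -> dict[str, np.ndarray]:
    """Map each group label to the positional column indices it owns."""
    labels = pd.Series(groups)
    return {
        str(g): np.flatnonzero((labels == g).to_numpy())
        for g in labels.dropna().unique()
    }


def cluster_summary(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    method: str = "median_polish",
) -> pd.DataFrame:
    """Transcript-cluster expression: one summary row per cluster.

    Computed over ALL probesets of each cluster (the gene-level module
    uses a different, isoform-filtered probeset selection).  The robust
    median-polish default keeps the cluster estimate insensitive to a
    single spliced exon.
    """
    cluster_of = annotation.loc[expression.index, "transcript_cluster_id"]
    rows = {}
    for tc, sub_idx in expression.groupby(cluster_of, sort=True).groups.items():
        rows[tc] = summarize_matrix(expression.loc[sub_idx], method=method)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "transcript_cluster_id"
    return out.loc[:, expression.columns]


def normalize_exons(
    expression: pd.DataFrame,
    cluster_values: pd.DataFrame,
    annotation: pd.DataFrame | pd.Series,
) -> pd.DataFrame:
    """Subtract each probeset's transcript-cluster summary, per sample."""
    if isinstance(annotation, pd.DataFrame):
        cluster_of = annotation.loc[expression.index, "transcript_cluster_id"]
    else:
        cluster_of = annotation.loc[expression.index]
    unknown = cluster_of[~cluster_of.isin(cluster_values.index)]
    if len(unknown):
        raise ValidationError(
            f"probeset {unknown.index[0]!r} maps to cluster {unknown.iloc[0]!r} "
            "absent from the cluster summary"
        )
    g = cluster_values.loc[cluster_of, expression.columns].to_numpy()
    return pd.DataFrame(
        expression.to_numpy() - g, index=expression.index, columns=expression.columns
    )


def _two_group_indices(groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    by = _group_columns(groups)
    if NORMAL in by and PATHOLOGICAL in by:
        a, b = by[NORMAL], by[PATHOLOGICAL]
    elif len(by) == 2:
        keys = sorted(by)
        a, b = by[keys[0]], by[keys[1]]
    else:
        raise ValueError(f"expected two groups, got {sorted(by)}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    return a, b


def splicing_index(normalized: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Per-probeset SI = mean(normal) - mean(pathological) of normalized
    values; positive peaks mean the normal signal is higher."""
    a, b = _two_group_indices(groups)
    x = normalized.to_numpy()
    si = x[:, a].mean(axis=1) - x[:, b].mean(axis=1)
    return pd.Series(si, index=normalized.index, name="splicing_index")


def exon_fold_change(expression: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Signed log2 fold change on raw probeset intensities (same sign
    convention as the splicing index); ``2 ** FC`` gives the ratio."""
    fc = splicing_index(expression, groups)
    return fc.rename("log2_fold_change")


def _ttest_from_stats(t: np.ndarray, df: float, degenerate: np.ndarray) -> np.ndarray:
    p = 2.0 * special.stdtr(df, -np.abs(t))
    p = np.where(degenerate, 1.0, p)
    return np.clip(p, 0.0, 1.0)


def exon_ttest(
    normalized: pd.DataFrame,
    groups: pd.Series,
    paired: bool = False,
    pairing: pd.Series | None = None,
) -> pd.Series:
    """Two-sided Student's t-test per probeset on normalized values.

    Unpaired mode pools variances (classical equal-variance t); paired
    mode runs a one-sample t on within-pair (normal - pathological)
    differences, with pairs defined by ``pairing`` (patient ids).  Zero
    variance with zero mean difference gives p = 1; zero variance with a
    nonzero difference gives p = 0.
    """
    a, b = _two_group_indices(groups)
    x = normalized.to_numpy(dtype=float)
    if not paired:
        na, nb = len(a), len(b)
        if na < 2 or nb < 2:
            raise ValueError("unpaired t-test needs >= 2 samples per group")
        xa, xb = x[:, a], x[:, b]
        ma, mb = xa.mean(axis=1), xb.mean(axis=1)
        ssa = ((xa - ma[:, None]) ** 2).sum(axis=1)
        ssb = ((xb - mb[:, None]) ** 2).sum(axis=1)
        df = na + nb - 2
        pooled = (ssa + ssb) / df
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        diff = ma - mb
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        degenerate = (se == 0) & (diff == 0)
        t = np.where(se == 0, np.where(diff == 0, 0.0, np.copysign(np.inf, diff)), t)
        p = _ttest_from_stats(t, df, degenerate)
    else:
        if pairing is None:
            raise ValueError("paired t-test needs a pairing key (patient ids)")
        pairing = pairing.loc[normalized.columns]
        norm_of = {
            pairing.iloc[i]: i for i in a if pd.notna(pairing.iloc[i])
        }
        diff_cols = []
        for j in b:
            pt = pairing.iloc[j]
            if pd.notna(pt) and pt in norm_of:
                diff_cols.append((norm_of[pt], j))
        if len(diff_cols) < 2:
            raise ValueError("paired t-test needs >= 2 complete pairs")
        d = np.stack([x[:, i] - x[:, j] for i, j in diff_cols], axis=1)
        n = d.shape[1]
        md = d.mean(axis=1)
        sd = d.std(axis=1, ddof=1)
        se = sd / np.sqrt(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = md / se
        degenerate = (se == 0) & (md == 0)
        t = np.where(se == 0, np.where(md == 0, 0.0, np.copysign(np.inf, md)), t)
        p = _ttest_from_stats(t, n - 1, degenerate)
    return pd.Series(p, index=normalized.index, name="t_p")


def midas_pvalue(normalized: pd.DataFrame, group_labels: pd.Series) -> pd.Series:
    """One-way fixed-effects ANOVA p-value per probeset across >= 2
    experimental groups of normalized values.

    For the standard two-group (normal vs pathological) design this is
    algebraically identical to the unpaired Student t (F = t^2).  A zero
    between-group sum of squares gives p = 1; a zero within-group sum of
    squares with between-group signal gives p = 0.
    """
    by = _group_columns(group_labels)
    if len(by) < 2:
        raise ValueError("MiDAS ANOVA needs >= 2 groups")
    sizes = {g: len(ix) for g, ix in by.items()}
    if min(sizes.values()) < 2:
        small = min(sizes, key=sizes.get)
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    x = normalized.to_numpy(dtype=float)
    cols = np.concatenate(list(by.values()))
    n_total = len(cols)
    k = len(by)
    grand = x[:, cols].mean(axis=1)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    for ix in by.values():
        sub = x[:, ix]
        m = sub.mean(axis=1)
        ssb += len(ix) * (m - grand) ** 2
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)
    dfb, dfw = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = special.fdtrc(dfb, dfw, f)
    p = np.where(ssb == 0, 1.0, p)
    p = np.where((ssw == 0) & (ssb > 0), 0.0, p)
    return pd.Series(np.clip(p, 0.0, 1.0), index=normalized.index, name="midas_p")


def dabg_detection(
    dabg: pd.DataFrame, groups: pd.Series, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Fraction of samples per group with DABG p <= threshold."""
    by = _group_columns(groups)
    x = dabg.to_numpy(dtype=float)
    out = {
        f"dabg_frac_{g}": (x[:, ix] <= p_threshold).mean(axis=1) for g, ix in by.items()
    }
    return pd.DataFrame(out, index=dabg.index)


def filter_by_dabg(
    records: pd.DataFrame,
    min_fraction: float = 0.5,
    mode: str = "either",
) -> tuple[pd.DataFrame, int]:
    """Flag probesets whose detection fraction falls below ``min_fraction``.

    ``either``: keep when at least one group is detected; ``both``: both
    groups must be detected.  Filtered probesets are retained in the
    table with ``filtered=True`` — statistics are never deleted.
    Returns the annotated table and the number of newly filtered rows.
    """
    if mode not in ("either", "both"):
        raise ValueError(f"unknown DABG filter mode {mode!r}")
    frac_cols = [c for c in records.columns if c.startswith("dabg_frac_")]
    out = records.copy()
    if not frac_cols:
        out["filtered"] = False
        return out, 0
    fractions = out[frac_cols].to_numpy(dtype=float)
    ok = fractions >= min_fraction
    keep = ok.any(axis=1) if mode == "either" else ok.all(axis=1)
    out["filtered"] = ~keep
    return out, int((~keep).sum())


def adjust_pvalues(pvalues: pd.Series | np.ndarray, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (``method='none'`` passes
    through).  Raises on p outside [0, 1]."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    if method in (None, "none"):
        return p
    if method.upper() != "BH":
        raise ValueError(f"unknown adjustment method {method!r}")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def compute_exon_stats(
    dataset: Dataset,
    paired: bool = False,
    summary_method: str = "median_polish",
    dabg_threshold: float = 0.05,
    dabg_min_fraction: float = 0.5,
    dabg_mode: str = "either",
    adjust: str = "none",
    si_threshold: float = DEFAULT_SI_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Run the full exon-level analysis for a two-condition case study.

    Returns one row per probeset: splicing index, log2 fold change,
    t-test and MiDAS p-values, DABG detection fractions and filter flag,
    optional BH q-values, and a ``flagged`` column marking probesets that
    pass all significance thresholds (midas_p and t_p below
    ``p_threshold`` and |SI| >= ``si_threshold``; thresholds are
    report-time choices, not baked into the statistics).
    """
    groups = dataset.condition
    g = cluster_summary(dataset.expression, dataset.probesets, method=summary_method)
    e = normalize_exons(dataset.expression, g, dataset.probesets)
    stats = pd.DataFrame(index=dataset.expression.index)
    stats.index.name = "probeset_id"
    stats["gene_id"] = dataset.probesets.loc[stats.index, "gene_id"]
    stats["transcript_cluster_id"] = dataset.probesets.loc[
        stats.index, "transcript_cluster_id"
    ]
    stats["splicing_index"] = splicing_index(e, groups)
    stats["log2_fold_change"] = exon_fold_change(dataset.expression, groups)
    pairing = dataset.samples["patient_id"] if "patient_id" in dataset.samples else None
    stats["t_p"] = exon_ttest(e, groups, paired=paired, pairing=pairing)
    stats["midas_p"] = midas_pvalue(e, groups)
    if dataset.dabg is not None:
        stats = stats.join(dabg_detection(dataset.dabg, groups, dabg_threshold))
        stats, _ = filter_by_dabg(stats, dabg_min_fraction, dabg_mode)
    else:
        stats["filtered"] = False
    if adjust not in (None, "none"):
        stats["t_q"] = adjust_pvalues(stats["t_p"], adjust)
        stats["midas_q"] = adjust_pvalues(stats["midas_p"], adjust)
    stats["flagged"] = (
        (stats["midas_p"] < p_threshold)
        & (stats["t_p"] < p_threshold)
        & (stats["splicing_index"].abs() >= si_threshold)
    )
    return stats
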