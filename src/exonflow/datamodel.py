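"""Core data structures for exon-array analysis.

Expression data live in pandas DataFrames: probesets (rows) x samples
(columns), holding log2 intensities as produced by RMA-style probe
summarization.  Probeset annotation links each probeset to its transcript
cluster, gene, genomic interval and the set of known isoforms containing
it; sample metadata carries the experimental condition plus optional
clinical covariates (gender, age of onset, stage, ...).

All coordinates are 1-based inclusive.  Expression values are required to
be on the log2 scale; no statistic in this package exponentiates except
where a ratio-scale fold change is explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NORMAL = "normal"
PATHOLOGICAL = "pathological"
CONDITIONS = (NORMAL, PATHOLOGICAL)

#: annotation table columns, in canonical order
ANNOTATION_COLUMNS = [
    "transcript_cluster_id",
    "gene_id",
    "chrom",
    "start",
    "stop",
    "strand",
    "exon_index",
    "isoform_ids",
]

#: metadata columns that are not free-form covariates
RESERVED_METADATA_COLUMNS = {"sample_id", "condition", "patient_id"}


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract.

    The message always names the offending record (probeset, sample or
    gene id) so that malformed files are diagnosable without a debugger.
    """


def infer_covariate_kind(values: pd.Series) -> str:
    """Classify a covariate column as ``numeric`` or ``categorical``.

    A column is numeric when every non-missing entry parses as a number;
    otherwise it is categorical.  Empty strings count as missing, never
    as zero.
    """
    non_missing = values.dropna()
    non_missing = non_missing[non_missing.astype(str).str.strip() != ""]
    if len(non_missing) == 0:
        return "categorical"
    coerced = pd.to_numeric(non_missing, errors="coerce")
    return "numeric" if not coerced.isna().any() else "categorical"


@dataclass
class Dataset:
    """A validated bundle of expression data, metadata and annotation.

    Attributes
    ----------
    expression : DataFrame
        log2 intensities, index ``probeset_id``, columns sample ids.
    dabg : DataFrame or None
        Detection-above-background p-values, same shape/index as
        ``expression``.
    samples : DataFrame
        index ``sample_id``; columns ``condition`` (required),
        ``patient_id`` and any clinical covariates.
    probesets : DataFrame
        index ``probeset_id``; columns :data:`ANNOTATION_COLUMNS`, with
        ``isoform_ids`` holding frozensets of isoform accessions.
    genes : DataFrame
        index ``gene_id``; columns ``symbol``, ``aliases`` (tuple),
        ``chrom``, ``start``, ``stop``, ``strand``, ``pathway_ids`` and
        ``go_ids`` (frozensets).
    gene_sets : DataFrame or None
        long-format membership table, columns ``set_id``, ``gene_id``,
        ``kind`` (``pathway`` or ``go``).
    covariate_kinds : dict
        covariate name -> ``numeric`` | ``categorical``, inferred at load
        time and fixed thereafter.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    probesets: pd.DataFrame
    genes: pd.DataFrame
    dabg: pd.DataFrame | None = None
    gene_sets: pd.DataFrame | None = None
    covariate_kinds: dict[str, str] = field(default_factory=dict)

    @property
    def condition(self) -> pd.Series:
        """Sample -> condition labels aligned to the expression columns."""
        return self.samples.loc[self.expression.columns, "condition"]

    def covariate_table(self, include_condition: bool = True) -> pd.DataFrame:
        """Clinical covariates for tree analysis, one row per sample.

        Numeric covariates are coerced to float (missing -> NaN);
        categorical ones keep missing values as NaN objects.
        """
        cols: dict[str, pd.Series] = {}
        if include_condition:
            cols["condition"] = self.samples["condition"]
        for name, kind in self.covariate_kinds.items():
            col = self.samples[name]
            if kind == "numeric":
                cols[name] = pd.to_numeric(col, errors="coerce")
            else:
                cols[name] = col.where(col.notna() & (col.astype(str).str.strip() != ""))
        return pd.DataFrame(cols, index=self.samples.index).loc[self.expression.columns]

    def validate(self) -> "Dataset":
        """Check referential integrity across all components.

        Raises
        ------
        ValidationError
            naming the first offending id found.
        """
        expr = self.expression
        if expr.index.has_duplicates:
            dup = expr.index[expr.index.duplicated()][0]
            raise ValidationError(f"duplicate probeset id in expression matrix: {dup!r}")
        if expr.columns.has_duplicates:
            dup = expr.columns[expr.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id in expression matrix: {dup!r}")
        values = expr.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite expression value for probeset {expr.index[i]!r} "
                f"in sample {expr.columns[j]!r}"
            )
        missing_ps = expr.index.difference(self.probesets.index)
        if len(missing_ps):
            raise ValidationError(
                f"probeset {missing_ps[0]!r} in expression matrix is absent from annotation"
            )
        missing_smp = expr.columns.difference(self.samples.index)
        if len(missing_smp):
            raise ValidationError(
                f"sample {missing_smp[0]!r} in expression matrix is absent from metadata"
            )
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id in metadata: {dup!r}")
        if "condition" not in self.samples.columns:
            raise ValidationError("condition required: metadata lacks a 'condition' column")
        bad_cond = self.samples.loc[~self.samples["condition"].isin(CONDITIONS)]
        if len(bad_cond):
            raise ValidationError(
                f"sample {bad_cond.index[0]!r} has condition "
                f"{bad_cond['condition'].iloc[0]!r}; expected one of {CONDITIONS}"
            )
        ann = self.probesets
        bad_coord = ann.loc[ann["start"] > ann["stop"]]
        if len(bad_coord):
            raise ValidationError(
                f"probeset {bad_coord.index[0]!r} has start > stop"
            )
        bad_strand = ann.loc[~ann["strand"].isin(["+", "-"])]
        if len(bad_strand):
            raise ValidationError(
                f"probeset {bad_strand.index[0]!r} has invalid strand "
                f"{bad_strand['strand'].iloc[0]!r}"
            )
        missing_gene = ann.index[~ann["gene_id"].isin(self.genes.index)]
        if len(missing_gene):
            raise ValidationError(
                f"probeset {missing_gene[0]!r} references unknown gene "
                f"{ann.loc[missing_gene[0], 'gene_id']!r}"
            )
        if self.dabg is not None:
            if not self.dabg.index.equals(expr.index) or not self.dabg.columns.equals(
                expr.columns
            ):
                raise ValidationError(
                    "DABG matrix row/column ids differ from the expression matrix"
                )
            dv = self.dabg.to_numpy(dtype=float, copy=False)
            out = ~((dv >= 0.0) & (dv <= 1.0))
            if out.any():
                i, j = np.argwhere(out)[0]
                raise ValidationError(
                    f"DABG value outside [0,1] for probeset {self.dabg.index[i]!r} "
                    f"in sample {self.dabg.columns[j]!r}"
                )
        if self.gene_sets is not None:
            unknown = self.gene_sets.loc[~self.gene_sets["gene_id"].isin(self.genes.index)]
            if len(unknown):
                raise ValidationError(
                    f"gene set {unknown['set_id'].iloc[0]!r} references unknown gene "
                    f"{unknown['gene_id'].iloc[0]!r}"
                )
        return self
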