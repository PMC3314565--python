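"""Readers and writers for the flat-file interchange formats.

Four tables describe a case study:

* expression (TSV): first column ``probeset_id``, remaining columns one
  per sample, log2 intensities;
* DABG (TSV, optional): same layout, detection p-values in [0, 1];
* sample metadata (CSV): ``sample_id,condition,patient_id,gender,age,
  stage,...`` — any further columns are free-form clinical covariates
  whose kind (numeric vs categorical) is inferred at load time;
* probeset annotation (TSV): ``probeset_id, transcript_cluster_id,
  gene_id, chrom, start, stop, strand, exon_index, isoform_ids`` with
  isoform ids semicolon-separated; optional ``gene_symbol`` and
  ``gene_aliases`` columns carry gene naming (aliases semicolon
  separated).

Gene-set membership (pathways / GO terms) is a fourth optional TSV with
columns ``set_id``, ``gene_id``, ``kind`` in {pathway, go}.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    ANNOTATION_COLUMNS,
    RESERVED_METADATA_COLUMNS,
    Dataset,
    ValidationError,
    infer_covariate_kind,
)

__all__ = ["load_dataset", "write_table", "read_table"]


def _read_matrix(path: str | os.PathLike, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = "probeset_id"
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{what} matrix {path}: non-numeric entry ({exc})") from exc
    return df


def _parse_id_set(raw: object) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return frozenset()
    text = str(raw).strip()
    if not text:
        return frozenset()
    return frozenset(part for part in text.split(";") if part)


def _load_annotation(path: str | os.PathLike) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["probeset_id"] + ANNOTATION_COLUMNS
    missing = [c for c in required if c not in ann.columns and c != "isoform_ids"]
    if "isoform_ids" not in ann.columns:
        ann["isoform_ids"] = ""
    if missing:
        raise ValidationError(f"annotation {path}: missing columns {missing}")
    if ann["probeset_id"].duplicated().any():
        dup = ann.loc[ann["probeset_id"].duplicated(), "probeset_id"].iloc[0]
        raise ValidationError(f"annotation {path}: duplicate probeset id {dup!r}")
    ann = ann.set_index("probeset_id")
    for col in ("start", "stop", "exon_index"):
        try:
            ann[col] = ann[col].astype(int)
        except ValueError as exc:
            raise ValidationError(f"annotation {path}: non-integer {col} ({exc})") from exc
    ann["isoform_ids"] = ann["isoform_ids"].map(_parse_id_set)
    return ann


def _genes_from_annotation(ann: pd.DataFrame, gene_sets: pd.DataFrame | None) -> pd.DataFrame:
    """Derive the gene table from probeset annotation plus set membership."""
    rows = []
    for gene_id, sub in ann.groupby("gene_id", sort=True):
        symbol = gene_id
        aliases: tuple[str, ...] = ()
        if "gene_symbol" in sub.columns:
            syms = [s for s in sub["gene_symbol"].unique() if s]
            if syms:
                symbol = syms[0]
        if "gene_aliases" in sub.columns:
            alias_sets = {a for raw in sub["gene_aliases"] for a in _parse_id_set(raw)}
            aliases = tuple(sorted(alias_sets))
        rows.append(
            {
                "gene_id": gene_id,
                "symbol": symbol,
                "aliases": aliases,
                "chrom": sub["chrom"].iloc[0],
                "start": int(sub["start"].min()),
                "stop": int(sub["stop"].max()),
                "strand": sub["strand"].iloc[0],
            }
        )
    genes = pd.DataFrame(rows).set_index("gene_id")
    pathway: dict[str, set[str]] = {}
    go: dict[str, set[str]] = {}
    if gene_sets is not None:
        for _, rec in gene_sets.iterrows():
            target = pathway if rec["kind"] == "pathway" else go
            target.setdefault(rec["gene_id"], set()).add(rec["set_id"])
    genes["pathway_ids"] = [frozenset(pathway.get(g, ())) for g in genes.index]
    genes["go_ids"] = [frozenset(go.get(g, ())) for g in genes.index]
    return genes


def _load_metadata(path: str | os.PathLike) -> tuple[pd.DataFrame, dict[str, str]]:
    meta = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "sample_id" not in meta.columns:
        raise ValidationError(f"metadata {path}: missing 'sample_id' column")
    if "condition" not in meta.columns:
        raise ValidationError(f"metadata {path}: condition required")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"metadata {path}: duplicate sample id {dup!r}")
    meta = meta.set_index("sample_id")
    # empty strings are missing values, never zeros
    meta = meta.where(meta.apply(lambda col: col.str.strip() != ""))
    kinds: dict[str, str] = {}
    for col in meta.columns:
        if col in RESERVED_METADATA_COLUMNS:
            continue
        kinds[col] = infer_covariate_kind(meta[col])
        if kinds[col] == "numeric":
            meta[col] = pd.to_numeric(meta[col])
    return meta, kinds


def load_dataset(
    expression_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
    dabg_path: str | os.PathLike | None = None,
    gene_sets_path: str | os.PathLike | None = None,
) -> Dataset:
    """Load and cross-validate a case study from its flat files.

    Returns a :class:`~exonflow.datamodel.Dataset` with row/column order
    preserved from the input files.  Any structural defect (duplicate
    ids, non-finite expression, DABG outside [0, 1], dangling references)
    raises :class:`~exonflow.datamodel.ValidationError` naming the
    offending record.
    """
    for p in (expression_path, metadata_path, annotation_path, dabg_path, gene_sets_path):
        if p is not None and not os.path.exists(p):
            raise FileNotFoundError(p)
    expression = _read_matrix(expression_path, "expression")
    samples, kinds = _load_metadata(metadata_path)
    probesets = _load_annotation(annotation_path)
    gene_sets = None
    if gene_sets_path is not None:
        gene_sets = pd.read_csv(
            gene_sets_path, sep="\t", dtype=str, names=["set_id", "gene_id", "kind"],
            header=0,
        )
        bad = gene_sets.loc[~gene_sets["kind"].isin(["pathway", "go"])]
        if len(bad):
            raise ValidationError(
                f"gene sets {gene_sets_path}: unknown kind {bad['kind'].iloc[0]!r}"
            )
    genes = _genes_from_annotation(probesets, gene_sets)
    dabg = _read_matrix(dabg_path, "DABG") if dabg_path is not None else None
    ds = Dataset(
        expression=expression,
        samples=samples,
        probesets=probesets,
        genes=genes,
        dabg=dabg,
        gene_sets=gene_sets,
        covariate_kinds=kinds,
    )
    return ds.validate()


def write_table(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a statistics table as TSV with stable column order.

    The index (probeset or gene id) becomes the first column; floats are
    rendered with 6 significant digits so a read-back reproduces values
    to rendering precision.  An empty table yields a header-only file.
    """
    records.to_csv(path, sep="\t", float_format="%.6g")


def read_table(path: str | os.PathLike, index_col: int | str = 0) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", index_col=index_col)
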