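"""Readers and writers for the pipeline's file formats.

Formats handled:

* GCT v1.2 — the distribution format of transcript-level TPM releases
  (version line ``#1.2``, a dimensions line, then a header with ``Name``,
  ``Description`` and one column per sample).  Read and write.
* Sample-attribute TSV — maps sample ids to tissue subtype labels
  (``SAMPID`` / ``SMTSD`` dialect).  Read.
* Annotation TSV — one row per transcript with gene membership, biotypes and
  transcript/ORF lengths.  Read and write.
* GENCODE-style GTF — annotation derived from exon, CDS and stop_codon
  features.  Read only.

Coordinates in GTF are 1-based inclusive; feature length is end - start + 1.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    DimensionError,
    GctFormatError,
    SchemaError,
)
from .model import ANNOTATION_COLUMNS, ExpressionMatrix, TissueMatrix, validate_annotation

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GCT v1.2
# ---------------------------------------------------------------------------

def read_gct(path, na_as_zero: bool = False, strip_versions: bool = False) -> ExpressionMatrix:
    """Read a GCT v1.2 matrix into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    path
        GCT file.  The first line must be a version tag (``#1.2``), the
        second ``<n_rows>\\t<n_cols>``.
    na_as_zero
        Replace NA cells with 0 (logged); by default NA cells are an error
        because the pipeline assumes complete TPM matrices.
    strip_versions
        Drop ``.N`` version suffixes from row identifiers.
    """
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#"):
            raise GctFormatError(f"{path}: first line {version!r} is not a GCT version tag")
        dims_line = fh.readline().strip()
        parts = dims_line.split("\t")
        if len(parts) < 2:
            raise GctFormatError(f"{path}: malformed dimensions line {dims_line!r}")
        try:
            n_rows, n_cols = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise GctFormatError(f"{path}: non-integer dimensions {dims_line!r}") from exc
        table = pd.read_csv(fh, sep="\t", header=0, index_col=0, dtype=str)

    has_description = len(table.columns) and table.columns[0].lower() == "description"
    description = None
    if has_description:
        description = table.iloc[:, 0]
        values = table.iloc[:, 1:]
    else:
        values = table

    if values.shape != (n_rows, n_cols):
        raise DimensionError(
            f"{path}: declared {n_rows}x{n_cols} but parsed {values.shape[0]}x{values.shape[1]}"
        )

    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise GctFormatError(
            f"{path}: non-numeric value {values.iat[i, j]!r} at row "
            f"{values.index[i]!r}, column {values.columns[j]!r}"
        )
    if numeric.isna().any().any():
        if not na_as_zero:
            n_na = int(numeric.isna().sum().sum())
            raise GctFormatError(
                f"{path}: {n_na} missing cells; pass na_as_zero=True to convert them to 0"
            )
        n_na = int(numeric.isna().sum().sum())
        logger.warning("%s: converted %d NA cells to 0", path, n_na)
        numeric = numeric.fillna(0.0)

    numeric = numeric.astype(float)
    numeric.index.name = "Name"
    if strip_versions:
        numeric.index = numeric.index.str.replace(r"\.\d+$", "", regex=True)
        if description is not None:
            description.index = numeric.index
    return ExpressionMatrix(tpm=numeric, description=description)


def write_gct(matrix: ExpressionMatrix, path, float_format: str = "%.6g") -> None:
    """Write an :class:`ExpressionMatrix` as GCT v1.2.

    A missing Description column is emitted as the transcript id (the
    convention of TPM releases without separate descriptions), so a
    write -> read round trip preserves the matrix.
    """
    desc = matrix.description
    if desc is None:
        desc = pd.Series(matrix.tpm.index, index=matrix.tpm.index)
    out = matrix.tpm.copy()
    out.insert(0, "Description", desc)
    out.index.name = "Name"
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_transcripts}\t{matrix.n_samples}\n")
        out.to_csv(fh, sep="\t", float_format=float_format)


# ---------------------------------------------------------------------------
# Sample attributes
# ---------------------------------------------------------------------------

def read_sample_attributes(
    path, id_column: str = "SAMPID", tissue_column: str = "SMTSD"
) -> pd.Series:
    """Read a sample-attribute TSV into a sample_id -> tissue Series.

    Extra columns are ignored.  Duplicate sample rows are tolerated only if
    they agree on the tissue; an empty tissue label is an error.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in (id_column, tissue_column):
        if col not in table.columns:
            raise SchemaError(f"{path}: missing column {col!r} (have {list(table.columns)})")
    sub = table[[id_column, tissue_column]]
    if sub[tissue_column].isna().any() or (sub[tissue_column].str.strip() == "").any():
        bad = sub[sub[tissue_column].isna() | (sub[tissue_column].str.strip() == "")]
        raise SchemaError(f"{path}: empty tissue label for samples {bad[id_column].tolist()[:5]}")
    grouped = sub.groupby(id_column)[tissue_column].nunique()
    conflicts = grouped[grouped > 1]
    if len(conflicts):
        raise SchemaError(
            f"{path}: conflicting tissue labels for samples {conflicts.index.tolist()[:5]}"
        )
    dedup = sub.drop_duplicates(subset=id_column)
    return pd.Series(
        dedup[tissue_column].to_numpy(), index=dedup[id_column].to_numpy(), name="tissue"
    )


# ---------------------------------------------------------------------------
# Annotation: TSV and GTF
# ---------------------------------------------------------------------------

def read_annotation_tsv(path) -> pd.DataFrame:
    """Read a transcript annotation TSV (transcript_id + the six fields)."""
    table = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    if "transcript_id" not in table.columns:
        raise SchemaError(f"{path}: missing column 'transcript_id'")
    table = table.set_index("transcript_id")
    return validate_annotation(table[ANNOTATION_COLUMNS])


def write_annotation_tsv(table: pd.DataFrame, path) -> None:
    table[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index_label="transcript_id")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict:
    return dict(_ATTR_RE.findall(attr_field))


def read_annotation_gtf(path) -> pd.DataFrame:
    """Derive an annotation table from a GENCODE-style GTF.

    transcript_length is the summed exon length of the transcript;
    orf_length sums CDS features plus stop_codon features (GENCODE CDS
    records exclude the stop codon), and is 0 for non-coding transcripts.
    Accepts both ``gene_type`` (GENCODE) and ``gene_biotype`` (Ensembl)
    attribute spellings.
    """
    exon_len: dict[str, int] = {}
    cds_len: dict[str, int] = {}
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"{path}:{line_no}: expected 9 GTF columns")
            feature, start, end, attrs_raw = fields[2], fields[3], fields[4], fields[8]
            if feature not in ("exon", "CDS", "stop_codon", "transcript"):
                continue
            attrs = _parse_attributes(attrs_raw)
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            if tid not in meta:
                meta[tid] = {
                    "gene_id": attrs.get("gene_id", ""),
                    "gene_name": attrs.get("gene_name", attrs.get("gene_id", "")),
                    "gene_biotype": attrs.get("gene_type", attrs.get("gene_biotype", "")),
                    "transcript_biotype": attrs.get(
                        "transcript_type", attrs.get("transcript_biotype", "")
                    ),
                }
            elif feature == "transcript" and (tid in exon_len or tid in cds_len):
                raise AnnotationError(f"{path}:{line_no}: duplicate transcript record {tid!r}")
            if feature == "transcript":
                continue
            length = int(end) - int(start) + 1  # 1-based inclusive
            if length <= 0:
                raise AnnotationError(f"{path}:{line_no}: non-positive feature length")
            if feature == "exon":
                exon_len[tid] = exon_len.get(tid, 0) + length
            else:  # CDS or stop_codon
                cds_len[tid] = cds_len.get(tid, 0) + length

    coding_no_exon = set(cds_len) - set(exon_len)
    if coding_no_exon:
        raise AnnotationError(
            f"{path}: transcripts with CDS but no exon features: {sorted(coding_no_exon)[:5]}"
        )
    rows = []
    for tid, info in meta.items():
        if tid not in exon_len:
            continue  # transcript line without exons: skip (no length derivable)
        rows.append(
            {
                "transcript_id": tid,
                **info,
                "transcript_length": exon_len[tid],
                "orf_length": cds_len.get(tid, 0),
            }
        )
    table = pd.DataFrame(rows).set_index("transcript_id")
    return validate_annotation(table[ANNOTATION_COLUMNS])


# ---------------------------------------------------------------------------
# Tissue-level matrices
# ---------------------------------------------------------------------------

def write_tissue_matrix(tm: TissueMatrix, values_path, n_samples_path) -> None:
    """Serialize a TissueMatrix as two TSVs (means, and per-tissue counts)."""
    tm.values.to_csv(values_path, sep="\t", index_label="transcript_id")
    tm.n_samples.rename("n_samples").to_csv(n_samples_path, sep="\t", index_label="tissue")


def read_tissue_matrix(values_path, n_samples_path) -> TissueMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="transcript_id")
    n_samples = pd.read_csv(n_samples_path, sep="\t", index_col="tissue")["n_samples"]
    return TissueMatrix(values=values, n_samples=n_samples)
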