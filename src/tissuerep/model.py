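"""In-memory data model: expression matrices, annotation, tissue summaries, profiles.

All containers are thin dataclasses around pandas objects.  Transcripts are
rows everywhere; sample or tissue labels are columns.  Identifiers are kept
verbatim (GENCODE version suffixes like ``.5`` included) and matching between
tables is exact-string unless versions are stripped explicitly at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnnotationError, ConfigurationError, SchemaError

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "gene_id",
    "gene_name",
    "gene_biotype",
    "transcript_biotype",
    "transcript_length",
    "orf_length",
]


@dataclass
class ExpressionMatrix:
    """Transcript x sample TPM matrix with an optional sample -> tissue map.

    Parameters
    ----------
    tpm
        Dense non-negative TPM values, transcripts as the index, sample ids
        as columns.  NA cells are rejected; convert them upstream if needed.
    sample_tissue
        Series mapping every sample id (index) to a tissue label.  Attached
        after load via :meth:`attach_sample_tissue`; ``None`` until then.
    description
        Optional GCT "Description" column, preserved verbatim for round-trips.
    """

    tpm: pd.DataFrame
    sample_tissue: pd.Series | None = None
    description: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.tpm.index.is_unique:
            dupes = self.tpm.index[self.tpm.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate transcript ids: {dupes[:5]}")
        if not self.tpm.columns.is_unique:
            raise SchemaError("duplicate sample ids in expression matrix")
        if self.tpm.isna().any().any():
            raise SchemaError("missing (NA) TPM values are not permitted")
        if (self.tpm.to_numpy() < 0).any():
            raise SchemaError("negative TPM values are not permitted")
        if self.sample_tissue is not None:
            self._check_tissue_map(self.sample_tissue)

    def _check_tissue_map(self, mapping: pd.Series) -> None:
        missing = self.tpm.columns.difference(mapping.index)
        if len(missing):
            raise SchemaError(
                f"{len(missing)} samples lack a tissue label, e.g. {list(missing[:3])}"
            )
        if mapping.loc[self.tpm.columns].isna().any():
            raise SchemaError("empty tissue label for at least one sample")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.tpm.columns

    @property
    def n_transcripts(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_samples(self) -> int:
        return self.tpm.shape[1]

    def attach_sample_tissue(self, mapping: pd.Series | dict) -> "ExpressionMatrix":
        """Join a sample -> tissue map; drop (with a warning) unmapped samples.

        Attribute rows for samples absent from the matrix are ignored; matrix
        samples absent from the attributes are dropped rather than silently
        mis-assigned.  Both unmatched counts are logged.
        """
        mapping = pd.Series(dict(mapping)) if not isinstance(mapping, pd.Series) else mapping
        in_both = self.tpm.columns.intersection(mapping.index)
        only_expr = self.tpm.columns.difference(mapping.index)
        only_attr = mapping.index.difference(self.tpm.columns)
        if len(only_expr):
            logger.warning(
                "dropping %d expression samples without tissue attributes", len(only_expr)
            )
        if len(only_attr):
            logger.info("%d attribute rows not present in the expression matrix", len(only_attr))
        if not len(in_both):
            raise ConfigurationError("no samples shared between expression matrix and attributes")
        tpm = self.tpm.loc[:, in_both]
        return ExpressionMatrix(
            tpm=tpm, sample_tissue=mapping.loc[in_both], description=self.description
        )

    def subset_transcripts(self, ids: pd.Index | list) -> "ExpressionMatrix":
        desc = self.description.loc[ids] if self.description is not None else None
        return ExpressionMatrix(
            tpm=self.tpm.loc[ids], sample_tissue=self.sample_tissue, description=desc
        )


def validate_annotation(table: pd.DataFrame) -> pd.DataFrame:
    """Check an AnnotationTable DataFrame (indexed by transcript_id).

    Enforces: unique transcript ids, orf_length <= transcript_length,
    transcripts of a gene share gene_name and gene_biotype.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"annotation table missing columns: {missing}")
    if not table.index.is_unique:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise AnnotationError(f"duplicate transcript ids in annotation: {dupes[:5]}")
    if (table["transcript_length"] <= 0).any():
        raise AnnotationError("transcript_length must be a positive integer")
    if (table["orf_length"] < 0).any():
        raise AnnotationError("orf_length must be non-negative")
    bad = table[table["orf_length"] > table["transcript_length"]]
    if len(bad):
        raise AnnotationError(
            f"orf_length exceeds transcript_length for: {bad.index.tolist()[:5]}"
        )
    per_gene = table.groupby("gene_id")[["gene_name", "gene_biotype"]].nunique()
    inconsistent = per_gene[(per_gene > 1).any(axis=1)]
    if len(inconsistent):
        raise AnnotationError(
            f"genes with inconsistent name/biotype across transcripts: "
            f"{inconsistent.index.tolist()[:5]}"
        )
    return table


@dataclass
class TissueMatrix:
    """Transcript x tissue matrix of mean TPM, with per-tissue sample counts."""

    values: pd.DataFrame          # transcripts x tissues, arithmetic means of sample TPM
    n_samples: pd.Series          # tissue -> number of samples averaged

    def __post_init__(self) -> None:
        if (self.n_samples < 1).any():
            raise ConfigurationError("every tissue needs at least one sample")
        if list(self.values.columns) != list(self.n_samples.index):
            raise ConfigurationError("tissue order mismatch between values and n_samples")

    @property
    def tissues(self) -> pd.Index:
        return self.values.columns

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneTissueMatrix:
    """Gene-level TPM (sum of transcript tissue means) and per-transcript shares.

    ``shares`` holds the "Rank TPM%" quantity: 100 * x_ij / g_gj where g is
    the transcript's gene.  Where a gene's TPM is exactly 0 in a tissue, all
    of its transcripts' shares are defined as 0.
    """

    gene_tpm: pd.DataFrame        # genes x tissues
    shares: pd.DataFrame          # transcripts x tissues, percent of gene TPM
    gene_of: pd.Series            # transcript_id -> gene_id


@dataclass
class TranscriptProfiles:
    """Per-transcript results of the ranking / Z-score / classification stage.

    ``table`` is indexed by transcript_id with columns: gene_id, gene_name,
    rank, overall_mean_tpm, mu, sigma, cv, category, representative_tissues
    (comma-joined, lexicographic tissue order).  ``z`` is the transcript x
    tissue Z-score matrix the classification was derived from.
    """

    table: pd.DataFrame
    z: pd.DataFrame
    tau: float = 3.0
    sd_mode: str = "population"

    def representative_sets(self) -> pd.Series:
        """Series of frozensets of representative tissues per transcript."""
        rep = self.z.ge(self.tau)
        cols = np.asarray(self.z.columns)
        return pd.Series(
            [frozenset(cols[row]) for row in rep.to_numpy()],
            index=self.z.index,
            name="representative_tissues",
        )
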