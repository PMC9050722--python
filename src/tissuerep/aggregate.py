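"""Aggregation from sample-level TPM to tissue-level summaries.

Samples are collapsed to per-tissue arithmetic means first (tissues carry
very unequal donor counts, so all cross-tissue statistics operate on the
tissue-level vector), then to a per-transcript overall mean across tissues.
Gene-level TPM is the sum of the gene's transcript tissue means, and each
transcript's "Rank TPM%" is its percentage share of that sum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import ExpressionMatrix, GeneTissueMatrix, TissueMatrix


def tissue_means(matrix: ExpressionMatrix) -> TissueMatrix:
    """Average sample TPM within each tissue; tissues ordered lexicographically."""
    if matrix.sample_tissue is None:
        raise ConfigurationError("expression matrix has no sample -> tissue assignment")
    tissues = matrix.sample_tissue.loc[matrix.sample_ids]
    means = matrix.tpm.T.groupby(tissues.to_numpy()).mean().T
    means = means.sort_index(axis=1)
    counts = tissues.value_counts().sort_index()
    counts.index.name = "tissue"
    if (counts < 1).any():
        raise ConfigurationError("a tissue label ended up with zero samples")
    return TissueMatrix(values=means, n_samples=counts)


def overall_mean(tm: TissueMatrix, donor_weighted: bool = False) -> pd.Series:
    """Per-transcript overall average TPM.

    By default the unweighted mean of tissue means (each tissue contributes
    equally regardless of donor count).  ``donor_weighted=True`` weights
    tissues by their sample counts instead, recovering the grand mean over
    samples; offered for sensitivity analysis.
    """
    if donor_weighted:
        w = tm.n_samples.to_numpy(dtype=float)
        vals = tm.values.to_numpy() @ w / w.sum()
        return pd.Series(vals, index=tm.transcript_ids, name="overall_mean_tpm")
    return tm.values.mean(axis=1).rename("overall_mean_tpm")


def gene_tpm_and_shares(tm: TissueMatrix, annotation: pd.DataFrame) -> GeneTissueMatrix:
    """Gene TPM per tissue (sum over the gene's transcripts) and percent shares.

    Shares are 100 * x_ij / g_gj; where the gene TPM is 0 in a tissue every
    share of that gene is defined as 0.
    """
    missing = tm.transcript_ids.difference(annotation.index)
    if len(missing):
        raise KeyError(
            f"{len(missing)} transcripts lack annotation, e.g. {list(missing[:5])}"
        )
    gene_of = annotation.loc[tm.transcript_ids, "gene_id"]
    gene_tpm = tm.values.groupby(gene_of.to_numpy()).sum()
    gene_tpm.index.name = "gene_id"
    denom = gene_tpm.loc[gene_of.to_numpy()].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        shares = np.where(denom > 0, 100.0 * tm.values.to_numpy() / denom, 0.0)
    shares = pd.DataFrame(shares, index=tm.transcript_ids, columns=tm.tissues)
    return GeneTissueMatrix(gene_tpm=gene_tpm, shares=shares, gene_of=gene_of)
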