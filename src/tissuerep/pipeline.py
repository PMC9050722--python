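"""End-to-end orchestration: filter -> aggregate -> rank -> Z-score -> classify.

The stage order is fixed: restrict to transcripts of protein-coding genes,
then drop transcripts with zero TPM in every sample, then aggregate to
tissue means and classify.  Counts at every stage are kept on the result so
a run on real data can be audited line by line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import aggregate, rank_classify
from .model import ExpressionMatrix, GeneTissueMatrix, TissueMatrix, TranscriptProfiles


@dataclass
class PipelineResult:
    profiles: TranscriptProfiles
    tissue_matrix: TissueMatrix
    gene_matrix: GeneTissueMatrix
    counts: dict = field(default_factory=dict)


def run_pipeline(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    tau: float = 3.0,
    sd_mode: str = "population",
    donor_weighted: bool = False,
) -> PipelineResult:
    """Run the full classification pipeline on a sample-level matrix."""
    counts = {"total_records": matrix.n_transcripts}
    pc = rank_classify.filter_protein_coding(matrix, annotation)
    counts["protein_coding_gene_transcripts"] = pc.n_transcripts
    expressed, n_removed = rank_classify.drop_unexpressed(pc)
    counts["removed_unexpressed"] = n_removed
    counts["analyzed_transcripts"] = expressed.n_transcripts
    tm = aggregate.tissue_means(expressed)
    gm = aggregate.gene_tpm_and_shares(tm, annotation)
    profiles = rank_classify.build_profiles(
        tm, annotation, tau=tau, sd_mode=sd_mode, donor_weighted=donor_weighted
    )
    counts["classified_ge1_tissue"] = int((profiles.table["category"] >= 1).sum())
    counts["n_genes"] = int(profiles.table["gene_id"].nunique())
    return PipelineResult(profiles=profiles, tissue_matrix=tm, gene_matrix=gm, counts=counts)
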