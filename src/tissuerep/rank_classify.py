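"""Analytical core: expression filtering, within-gene ranking, cross-tissue
Z-scores, CV, and representative-tissue classification.

A transcript is called *representative* of a tissue when its mean TPM there
exceeds its own cross-tissue mean by at least ``tau`` standard deviations:

    z_ij = (x_ij - mu_i) / sigma_i,    representative  <=>  z_ij >= tau

with x_ij the tissue-mean TPM of transcript i in tissue j, and mu_i / sigma_i
the mean and SD of that transcript's tissue vector.  The default cutoff
tau = 3 corresponds to a one-sided normal tail probability of 0.00135.  The
*category* of a transcript is the number of tissues it represents; with a
population SD, sum z^2 = n_tissues forces category <= floor(n_tissues / tau^2)
(6 for 54 tissues at tau = 3).

Transcripts are ranked within their gene by overall mean TPM (descending);
ties fall back to ORF length, then transcript length (both descending), then
transcript id (ascending) so that identical inputs always yield identical
ranks.  Rank 1 is the gene's dominantly expressed transcript.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .model import ExpressionMatrix, TissueMatrix, TranscriptProfiles

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_protein_coding(
    matrix: ExpressionMatrix, annotation: pd.DataFrame
) -> ExpressionMatrix:
    """Keep transcripts whose *gene* biotype is protein_coding.

    The transcript biotype is deliberately not restricted: non-coding
    isoforms of coding genes (retained_intron, processed_transcript,
    nonsense_mediated_decay, ...) stay in the analysis.
    """
    missing = matrix.transcript_ids.difference(annotation.index)
    if len(missing):
        raise KeyError(
            f"{len(missing)} transcripts lack annotation, e.g. {list(missing[:5])}"
        )
    biotype = annotation.loc[matrix.transcript_ids, "gene_biotype"]
    keep = matrix.transcript_ids[(biotype == "protein_coding").to_numpy()]
    if not len(keep):
        logger.warning("no protein-coding-gene transcripts retained")
    logger.info(
        "protein-coding-gene filter: %d -> %d transcripts",
        matrix.n_transcripts,
        len(keep),
    )
    return matrix.subset_transcripts(keep)


def drop_unexpressed(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, int]:
    """Remove transcripts with zero TPM in every sample; return (matrix, n_removed)."""
    expressed = (matrix.tpm.to_numpy() > 0).any(axis=1)
    n_removed = int((~expressed).sum())
    logger.info(
        "zero-expression filter: removed %d of %d transcripts",
        n_removed,
        matrix.n_transcripts,
    )
    return matrix.subset_transcripts(matrix.transcript_ids[expressed]), n_removed


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_transcripts(overall_means: pd.Series, annotation: pd.DataFrame) -> pd.Series:
    """Assign within-gene ranks 1..T_g (1 = most expressed).

    Sort key per gene: overall mean TPM desc, ORF length desc, transcript
    length desc, transcript id asc.
    """
    ann = annotation.loc[overall_means.index]
    key = pd.DataFrame(
        {
            "gene_id": ann["gene_id"],
            "m": overall_means,
            "orf": ann["orf_length"],
            "tlen": ann["transcript_length"],
        },
        index=overall_means.index,
    )
    key = key.rename_axis("transcript_id").reset_index()
    key = key.sort_values(
        by=["gene_id", "m", "orf", "tlen", "transcript_id"],
        ascending=[True, False, False, False, True],
        kind="mergesort",
    )
    key["rank"] = key.groupby("gene_id").cumcount() + 1
    return key.set_index("transcript_id")["rank"].loc[overall_means.index]


# ---------------------------------------------------------------------------
# Z-scores, CV, classification
# ---------------------------------------------------------------------------

def zscores(
    tm: TissueMatrix, sd_mode: str = "population"
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Cross-tissue Z-scores per transcript; returns (z, mu, sigma).

    ``sd_mode`` selects the population SD (divide by n, default) or the
    sample SD (divide by n - 1).  A transcript with sigma = 0 (exactly
    constant tissue vector) gets z = 0 in every tissue, i.e. it is commonly
    expressed and never representative.
    """
    if tm.n_tissues < 2:
        raise ConfigurationError("Z-scores need at least 2 tissues")
    if sd_mode not in ("population", "sample"):
        raise ConfigurationError(f"unknown sd_mode {sd_mode!r}")
    ddof = 0 if sd_mode == "population" else 1
    x = tm.values.to_numpy(dtype=float)
    mu = x.mean(axis=1)
    sigma = x.std(axis=1, ddof=ddof)
    # A vector that is constant up to float rounding (e.g. identical samples
    # averaged over different donor counts) must count as sigma = 0, or the
    # rounding jitter alone would produce huge z-scores.
    degenerate = sigma <= 1e-12 * np.abs(mu)
    sigma = np.where(degenerate, 0.0, sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma[:, None] > 0, (x - mu[:, None]) / sigma[:, None], 0.0)
    z = pd.DataFrame(z, index=tm.transcript_ids, columns=tm.tissues)
    return (
        z,
        pd.Series(mu, index=tm.transcript_ids, name="mu"),
        pd.Series(sigma, index=tm.transcript_ids, name="sigma"),
    )


def classify_representative(z: pd.DataFrame, tau: float = 3.0) -> tuple[pd.Series, pd.Series]:
    """Representative tissue sets {j : z_ij >= tau} (inclusive) and categories.

    Returns (representative_tissues as comma-joined strings in lexicographic
    tissue order, category = set size).
    """
    rep = z.ge(tau)
    cols = np.asarray(z.columns)
    order = np.argsort(cols, kind="stable")
    joined = [
        ",".join(cols[order][rep.to_numpy()[i][order]]) for i in range(rep.shape[0])
    ]
    sets = pd.Series(joined, index=z.index, name="representative_tissues")
    category = rep.sum(axis=1).rename("category")
    return sets, category


def coefficient_of_variation(mu: pd.Series, sigma: pd.Series) -> pd.Series:
    """CV = sigma / mu; defined as 0 where mu = 0 (all-zero transcripts)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu.to_numpy() > 0, sigma.to_numpy() / mu.to_numpy(), 0.0)
    return pd.Series(cv, index=mu.index, name="cv")


def tail_probability(tau: float) -> float:
    """One-sided standard-normal tail 1 - Phi(tau) implied by the Z cutoff."""
    return float(stats.norm.sf(tau))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def build_profiles(
    tm: TissueMatrix,
    annotation: pd.DataFrame,
    tau: float = 3.0,
    sd_mode: str = "population",
    donor_weighted: bool = False,
) -> TranscriptProfiles:
    """Compute the full per-transcript profile table from a TissueMatrix."""
    from .aggregate import overall_mean  # local import to avoid a cycle

    if tau <= 0:
        raise ConfigurationError("tau must be positive")
    m = overall_mean(tm, donor_weighted=donor_weighted)
    rank = rank_transcripts(m, annotation)
    z, mu, sigma = zscores(tm, sd_mode=sd_mode)
    rep_sets, category = classify_representative(z, tau=tau)
    cv = coefficient_of_variation(mu, sigma)
    ann = annotation.loc[tm.transcript_ids]
    table = pd.DataFrame(
        {
            "gene_id": ann["gene_id"],
            "gene_name": ann["gene_name"],
            "rank": rank,
            "overall_mean_tpm": m,
            "mu": mu,
            "sigma": sigma,
            "cv": cv,
            "category": category,
            "representative_tissues": rep_sets,
        },
        index=tm.transcript_ids,
    )
    table.index.name = "transcript_id"
    return TranscriptProfiles(table=table, z=z, tau=tau, sd_mode=sd_mode)


def write_profiles(profiles: TranscriptProfiles, path, include_z: bool = False) -> None:
    """Serialize profiles to TSV; optionally append one Z column per tissue."""
    out = profiles.table.copy()
    if include_z:
        zcols = profiles.z.add_prefix("z:")
        out = out.join(zcols)
    out.to_csv(path, sep="\t", index_label="transcript_id")


def read_profiles(path) -> TranscriptProfiles:
    """Load a profiles TSV written with ``include_z=True``."""
    table = pd.read_csv(path, sep="\t", index_col="transcript_id")
    zcols = [c for c in table.columns if c.startswith("z:")]
    if not zcols:
        raise ConfigurationError(
            f"{path}: no z: columns; write profiles with include_z=True to reload them"
        )
    z = table[zcols].rename(columns=lambda c: c[2:])
    base = table.drop(columns=zcols)
    base["representative_tissues"] = base["representative_tissues"].fillna("")
    return TranscriptProfiles(table=base, z=z)
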