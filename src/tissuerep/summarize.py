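"""Summary tables over classified transcript profiles.

Four report families:

* category table — transcripts cross-tabulated by tissue-count category
  (0..4, overflow row if any) and TPM thresholds (>= 1, 10, 100);
* tissue report — per-tissue counts and mean TPM of the transcripts
  representative there;
* rank table — per within-gene rank: totals, representative counts, and mean
  TPM per category;
* switch events — genes whose classified transcripts occupy disjoint tissue
  sets (isoform switches between tissues).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import TissueMatrix, TranscriptProfiles

CATEGORY_ROWS = [0, 1, 2, 3, 4]


def category_table(
    profiles: TranscriptProfiles,
    thresholds: tuple[float, ...] = (1.0, 10.0, 100.0),
    tpm_basis: str = "overall_mean",
) -> pd.DataFrame:
    """Counts of transcripts by category and TPM threshold.

    ``tpm_basis`` picks the TPM value m compared against the thresholds:
    ``overall_mean`` (default) uses the cross-tissue mean; ``representative_max``
    uses the maximum tissue-mean TPM over the transcript's representative
    tissues (0 for category-0 transcripts).  Rows are categories 0..4 plus a
    ``>=5`` overflow row when present, and a totals row whose percentage
    columns give each threshold count as a share of all transcripts.
    """
    t = profiles.table
    if tpm_basis == "overall_mean":
        m = t["overall_mean_tpm"]
    elif tpm_basis == "representative_max":
        rep = profiles.z.ge(profiles.tau)
        # mu + z*sigma reconstructs the tissue-mean TPM scale of the z matrix
        x = profiles.z.mul(t["sigma"], axis=0).add(t["mu"], axis=0)
        m = x.where(rep).max(axis=1).fillna(0.0)
    else:
        raise ValueError(f"unknown tpm_basis {tpm_basis!r}")

    cat = t["category"].copy()
    overflow = cat > max(CATEGORY_ROWS)
    rows = CATEGORY_ROWS + ([">=5"] if overflow.any() else [])
    labels = cat.where(~overflow, ">=5").astype(object)

    data = {}
    data["n_transcripts"] = labels.value_counts()
    for thr in thresholds:
        data[f"n_tpm_ge_{thr:g}"] = labels[m >= thr].value_counts()
    table = pd.DataFrame(data).reindex(rows).fillna(0).astype(int)
    table.index.name = "category"
    total = table.sum(axis=0)
    table.loc["total"] = total
    pct = 100.0 * total / max(total["n_transcripts"], 1)
    table.attrs["total_pct"] = {k: round(float(v), 1) for k, v in pct.items()}
    table.attrs["tpm_basis"] = tpm_basis
    return table


def tissue_report(
    profiles: TranscriptProfiles, tissue_matrix: TissueMatrix | None = None
) -> pd.DataFrame:
    """Per-tissue counts and mean TPM of representative transcripts.

    Columns: n_representative; mean_overall_tpm (cross-tissue mean of those
    transcripts); mean_in_tissue_tpm (their mean TPM within that tissue,
    when a TissueMatrix is supplied); top gene/transcript; empty flag.
    Tissues with no representative transcript report means of 0 and
    ``empty = True`` rather than NaN.
    """
    rep = profiles.z.ge(profiles.tau)
    t = profiles.table
    tissues = sorted(profiles.z.columns)
    rows = []
    for tissue in tissues:
        mask = rep[tissue]
        ids = rep.index[mask.to_numpy()]
        n = len(ids)
        row = {"tissue": tissue, "n_representative": n, "empty": n == 0}
        if n:
            sub = t.loc[ids]
            row["mean_overall_tpm"] = float(sub["overall_mean_tpm"].mean())
            if tissue_matrix is not None:
                in_tissue = tissue_matrix.values.loc[ids, tissue]
                row["mean_in_tissue_tpm"] = float(in_tissue.mean())
                top = in_tissue.idxmax()
            else:
                row["mean_in_tissue_tpm"] = np.nan
                top = sub["overall_mean_tpm"].idxmax()
            row["top_transcript"] = top
            row["top_gene"] = t.at[top, "gene_name"] or t.at[top, "gene_id"]
        else:
            row.update(
                mean_overall_tpm=0.0, mean_in_tissue_tpm=0.0, top_transcript="", top_gene=""
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("tissue")


def rank_table(profiles: TranscriptProfiles, max_rank: int = 10) -> pd.DataFrame:
    """Per-rank totals, representative counts, and mean TPM per category.

    For rank r in 1..max_rank: n_total transcripts with that rank,
    n_representative with category >= 1, and mean overall TPM within each
    category bucket 0..4 (NaN where the bucket is empty).
    """
    t = profiles.table
    rows = []
    for r in range(1, max_rank + 1):
        sub = t[t["rank"] == r]
        row = {
            "rank": r,
            "n_total": len(sub),
            "n_representative": int((sub["category"] >= 1).sum()),
        }
        for c in CATEGORY_ROWS:
            bucket = sub[sub["category"] == c]
            row[f"mean_tpm_cat{c}"] = (
                float(bucket["overall_mean_tpm"].mean()) if len(bucket) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("rank")


def switch_events(profiles: TranscriptProfiles) -> pd.DataFrame:
    """Genes whose classified transcripts are representative in disjoint tissues.

    A gene is flagged when at least two of its transcripts have category >= 1
    and some pair of them has disjoint representative-tissue sets — the
    hallmark of a tissue isoform switch (e.g. a cerebellum transcript and a
    testis transcript of the same gene).  Returns one row per flagged gene
    with the per-transcript tissue sets for display.
    """
    t = profiles.table
    classified = t[t["category"] >= 1]
    sets = profiles.representative_sets().loc[classified.index]
    rows = []
    for gene_id, sub in classified.groupby("gene_id", sort=True):
        if len(sub) < 2:
            continue
        ids = list(sub.index)
        pairs = [
            (a, b)
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
            if sets[a].isdisjoint(sets[b])
        ]
        if not pairs:
            continue
        rows.append(
            {
                "gene_id": gene_id,
                "gene_name": sub["gene_name"].iloc[0],
                "n_transcripts": len(ids),
                "transcripts": ";".join(ids),
                "tissue_sets": ";".join(
                    ",".join(sorted(sets[i])) for i in ids
                ),
                "n_disjoint_pairs": len(pairs),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "gene_name",
            "n_transcripts",
            "transcripts",
            "tissue_sets",
            "n_disjoint_pairs",
        ],
    )
    return out.set_index("gene_id")


def top_genes_export(
    profiles: TranscriptProfiles,
    tissue_matrix: TissueMatrix,
    tissue: str,
    n: int = 100,
    rank_filter: int = 1,
) -> pd.DataFrame:
    """Top-n genes whose rank-``rank_filter`` transcript represents ``tissue``.

    Sorted by the transcript's mean TPM in that tissue, descending; ties
    broken by gene id ascending.  The output feeds external enrichment tools.
    """
    if tissue not in profiles.z.columns:
        raise KeyError(f"unknown tissue {tissue!r}")
    t = profiles.table
    rep = profiles.z[tissue].ge(profiles.tau)
    mask = rep & (t["rank"] == rank_filter)
    sub = t[mask].copy()
    sub["tissue_tpm"] = tissue_matrix.values.loc[sub.index, tissue]
    sub = sub.rename_axis("transcript_id").reset_index()
    sub = sub.sort_values(
        by=["tissue_tpm", "gene_id"], ascending=[False, True], kind="mergesort"
    ).head(n)
    return sub[["gene_id", "gene_name", "transcript_id", "tissue_tpm"]].reset_index(drop=True)
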