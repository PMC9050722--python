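import numpy as np
import pandas as pd
import pytest

from tissuerep import run_pipeline
from tissuerep.model import TissueMatrix
from tissuerep.synthetic_data import GTEX_TISSUES, SimConfig, simulate


def make_annotation(rows):
    """Build an annotation DataFrame from (tid, gene, gene_biotype, tx_biotype, orf, tlen)."""
    return pd.DataFrame(
        [
            {
                "transcript_id": tid,
                "gene_id": gene,
                "gene_name": f"NAME_{gene}",
                "gene_biotype": gb,
                "transcript_biotype": tb,
                "transcript_length": tlen,
                "orf_length": orf,
            }
            for tid, gene, gb, tb, orf, tlen in rows
        ]
    ).set_index("transcript_id")


def make_tissue_matrix(values, transcript_ids=None, tissues=None, n_samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_tx, n_tis = values.shape
    if transcript_ids is None:
        transcript_ids = [f"T{i}" for i in range(1, n_tx + 1)]
    if tissues is None:
        tissues = (
            list(GTEX_TISSUES[:n_tis])
            if n_tis <= len(GTEX_TISSUES)
            else [f"tissue_{j:03d}" for j in range(n_tis)]
        )
    if n_samples is None:
        n_samples = pd.Series(1, index=pd.Index(tissues, name="tissue"))
    df = pd.DataFrame(values, index=transcript_ids, columns=tissues)
    return TissueMatrix(values=df, n_samples=n_samples)


@pytest.fixture(scope="session")
def sim_bundle():
    """A moderate simulated study plus its pipeline result, shared read-only."""
    config = SimConfig(n_genes=150, seed=11)
    result = simulate(config)
    pipeline = run_pipeline(result.expression, result.annotation)
    return config, result, pipeline
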