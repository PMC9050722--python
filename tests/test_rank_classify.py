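"""Filtering, ranking with tie-breaks, Z-scores, CV and classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tissuerep import (
    classify_representative,
    coefficient_of_variation,
    drop_unexpressed,
    filter_protein_coding,
    rank_transcripts,
    tail_probability,
    zscores,
)
from tissuerep.errors import ConfigurationError
from tissuerep.model import ExpressionMatrix

from conftest import make_annotation, make_tissue_matrix


def brute_force_zscores(values, ddof=0):
    """Independent per-row loop implementation of the Z-score definition."""
    values = np.atleast_2d(values)
    out = np.zeros_like(values, dtype=float)
    for i in range(values.shape[0]):
        row = values[i]
        mu = sum(row) / len(row)
        var = sum((v - mu) ** 2 for v in row) / (len(row) - ddof)
        sd = math.sqrt(var)
        if sd > 0:
            out[i] = [(v - mu) / sd for v in row]
    return out


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

class TestFilters:
    def _em(self, n_tx, values=None):
        ids = [f"T{i}" for i in range(1, n_tx + 1)]
        if values is None:
            values = np.arange(1, n_tx * 2 + 1, dtype=float).reshape(n_tx, 2)
        return ExpressionMatrix(tpm=pd.DataFrame(values, index=ids, columns=["S1", "S2"]))

    def test_keeps_only_protein_coding_genes(self):
        em = self._em(3)
        ann = make_annotation(
            [
                ("T1", "G1", "protein_coding", "protein_coding", 30, 100),
                ("T2", "G2", "lincRNA", "lincRNA", 0, 100),
                ("T3", "G3", "protein_coding", "protein_coding", 30, 100),
            ]
        )
        out = filter_protein_coding(em, ann)
        assert list(out.transcript_ids) == ["T1", "T3"]

    def test_noncoding_isoform_of_coding_gene_retained(self):
        em = self._em(2)
        ann = make_annotation(
            [
                ("T1", "G1", "protein_coding", "protein_coding", 30, 100),
                ("T2", "G1", "protein_coding", "retained_intron", 0, 100),
            ]
        )
        out = filter_protein_coding(em, ann)
        assert list(out.transcript_ids) == ["T1", "T2"]

    def test_all_noncoding_gives_empty_matrix(self):
        em = self._em(1)
        ann = make_annotation([("T1", "G1", "snoRNA", "snoRNA", 0, 100)])
        out = filter_protein_coding(em, ann)
        assert out.n_transcripts == 0

    def test_drop_unexpressed(self):
        values = np.array([[0.0] * 10, [0.0] * 9 + [0.01]])
        tpm = pd.DataFrame(values, index=["T1", "T2"], columns=[f"S{i}" for i in range(10)])
        out, n_removed = drop_unexpressed(ExpressionMatrix(tpm=tpm))
        assert n_removed == 1
        assert list(out.transcript_ids) == ["T2"]


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

class TestRanking:
    def test_single_transcript_gene(self):
        ann = make_annotation([("T1", "G1", "protein_coding", "protein_coding", 30, 100)])
        ranks = rank_transcripts(pd.Series({"T1": 5.0}), ann)
        assert ranks.loc["T1"] == 1

    def test_tpm_tie_broken_by_orf_length(self):
        ann = make_annotation(
            [
                ("T1", "G1", "protein_coding", "protein_coding", 300, 1000),
                ("T2", "G1", "protein_coding", "protein_coding", 150, 1000),
            ]
        )
        ranks = rank_transcripts(pd.Series({"T1": 5.0, "T2": 5.0}), ann)
        assert (ranks.loc["T1"], ranks.loc["T2"]) == (1, 2)

    def test_orf_tie_broken_by_transcript_length(self):
        ann = make_annotation(
            [
                ("T1", "G1", "protein_coding", "protein_coding", 300, 1000),
                ("T2", "G1", "protein_coding", "protein_coding", 300, 2000),
            ]
        )
        ranks = rank_transcripts(pd.Series({"T1": 5.0, "T2": 5.0}), ann)
        assert (ranks.loc["T1"], ranks.loc["T2"]) == (2, 1)

    def test_full_tie_broken_by_transcript_id(self):
        ann = make_annotation(
            [
                ("T2", "G1", "protein_coding", "protein_coding", 300, 1000),
                ("T1", "G1", "protein_coding", "protein_coding", 300, 1000),
            ]
        )
        ranks = rank_transcripts(pd.Series({"T2": 5.0, "T1": 5.0}), ann)
        assert (ranks.loc["T1"], ranks.loc["T2"]) == (1, 2)

    def test_matches_brute_force_comparator(self):
        rng = np.random.default_rng(3)
        n = 40
        ids = [f"T{i:02d}" for i in range(n)]
        genes = [f"G{rng.integers(8)}" for _ in range(n)]
        m = pd.Series(rng.choice([0.0, 1.0, 5.0, 5.0, 9.0], size=n), index=ids)
        rows = [
            (ids[i], genes[i], "protein_coding", "protein_coding",
             int(rng.choice([100, 200, 300])), int(rng.choice([500, 1000])))
            for i in range(n)
        ]
        # make orf <= length
        rows = [(t, g, gb, tb, min(orf, ln), ln) for t, g, gb, tb, orf, ln in rows]
        ann = make_annotation(rows)
        ranks = rank_transcripts(m, ann)
        for gene in set(genes):
            members = [i for i in range(n) if genes[i] == gene]
            key = lambda i: (
                -m[ids[i]], -ann.loc[ids[i], "orf_length"],
                -ann.loc[ids[i], "transcript_length"], ids[i],
            )
            expected = {ids[i]: r + 1 for r, i in enumerate(sorted(members, key=key))}
            for tid, r in expected.items():
                assert ranks.loc[tid] == r
        # ranks are a permutation of 1..T_g within each gene
        for gene in set(genes):
            got = sorted(ranks[pd.Index(genes, name="g") == gene].tolist())
            assert got == list(range(1, len(got) + 1))


# ---------------------------------------------------------------------------
# Z-scores / CV / classification
# ---------------------------------------------------------------------------

class TestZscores:
    def test_constant_vector_all_zero(self):
        tm = make_tissue_matrix([[4.2] * 54])
        z, mu, sigma = zscores(tm)
        assert (z.to_numpy() == 0).all()
        assert sigma.loc["T1"] == 0.0

    def test_one_hot_closed_form(self):
        x = np.zeros((1, 54))
        x[0, 7] = 13.0
        tm = make_tissue_matrix(x)
        z, _, _ = zscores(tm)
        hot = tm.tissues[7]
        assert z.at["T1", hot] == pytest.approx(math.sqrt(53), rel=1e-12)
        cold = z.loc["T1"].drop(hot)
        assert np.allclose(cold, -1 / math.sqrt(53), rtol=1e-12)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(12)
        values = rng.uniform(0, 1000, size=(100, 54))
        tm = make_tissue_matrix(values)
        for mode, ddof in [("population", 0), ("sample", 1)]:
            z, _, _ = zscores(tm, sd_mode=mode)
            assert np.abs(z.to_numpy() - brute_force_zscores(values, ddof)).max() < 1e-12

    def test_single_tissue_rejected(self):
        tm = make_tissue_matrix([[1.0]])
        with pytest.raises(ConfigurationError):
            zscores(tm)

    def test_unknown_sd_mode_rejected(self):
        tm = make_tissue_matrix([[1.0, 2.0]])
        with pytest.raises(ConfigurationError):
            zscores(tm, sd_mode="robust")

    @given(
        arrays(
            np.float64,
            (5, 54),
            elements=st.floats(0, 1e6, allow_nan=False, width=64),
        )
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_normalization_property(self, values):
        tm = make_tissue_matrix(values)
        z, _, sigma = zscores(tm)
        zv = z.to_numpy()
        mu = values.mean(axis=1)
        for i in range(5):
            if sigma.iloc[i] > 0:
                # kappa bounds the rounding amplification for near-constant rows
                kappa = max(1.0, abs(mu[i]) / sigma.iloc[i])
                assert abs(zv[i].sum()) < 1e-10 * 54 * kappa
                assert zv[i] @ zv[i] == pytest.approx(54, rel=1e-12 * kappa + 1e-9)
            else:
                assert (zv[i] == 0).all()


class TestClassification:
    def test_constant_transcript_is_category_zero(self):
        tm = make_tissue_matrix([[1.0] * 54])
        z, _, _ = zscores(tm)
        sets, category = classify_representative(z)
        assert category.loc["T1"] == 0
        assert sets.loc["T1"] == ""

    def test_one_hot_category_one(self):
        x = np.zeros((1, 54))
        x[0, 11] = 5.0
        tm = make_tissue_matrix(x)
        z, _, _ = zscores(tm)
        sets, category = classify_representative(z)
        assert category.loc["T1"] == 1
        assert sets.loc["T1"] == tm.tissues[11]

    def test_two_hot_category_two(self):
        x = np.zeros((1, 54))
        x[0, 3] = x[0, 40] = 9.0
        tm = make_tissue_matrix(x)
        z, _, _ = zscores(tm)
        hot = z.loc["T1"].iloc[[3, 40]]
        assert np.allclose(hot, math.sqrt(26), rtol=1e-12)  # ~5.099
        _, category = classify_representative(z)
        assert category.loc["T1"] == 2

    def test_cutoff_is_inclusive(self):
        z = pd.DataFrame([[3.0, -1.0]], index=["T1"], columns=["a", "b"])
        sets, category = classify_representative(z, tau=3.0)
        assert category.loc["T1"] == 1 and sets.loc["T1"] == "a"

    @given(
        arrays(
            np.float64,
            (8, 54),
            elements=st.floats(0, 1e9, allow_nan=False, width=64),
        )
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_category_bound_six_at_tau_three(self, values):
        tm = make_tissue_matrix(values)
        z, _, _ = zscores(tm)
        _, category = classify_representative(z, tau=3.0)
        assert (category <= 54 // 9).all()


class TestCv:
    def test_constant_positive_vector(self):
        tm = make_tissue_matrix([[3.3] * 54])
        _, mu, sigma = zscores(tm)
        assert coefficient_of_variation(mu, sigma).loc["T1"] == 0.0

    def test_one_hot_closed_form(self):
        x = np.zeros((1, 54))
        x[0, 0] = 7.0
        tm = make_tissue_matrix(x)
        _, mu, sigma = zscores(tm)
        assert coefficient_of_variation(mu, sigma).loc["T1"] == pytest.approx(
            math.sqrt(53), rel=1e-12
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 10, size=(1, 54))
        for c in (0.01, 1.0, 250.0):
            _, mu, sigma = zscores(make_tissue_matrix(values * c))
            cv = coefficient_of_variation(mu, sigma)
            _, mu0, sigma0 = zscores(make_tissue_matrix(values))
            assert cv.loc["T1"] == pytest.approx(
                coefficient_of_variation(mu0, sigma0).loc["T1"], rel=1e-9
            )

    def test_zero_mean_defined_as_zero(self):
        mu = pd.Series({"T1": 0.0})
        sigma = pd.Series({"T1": 0.0})
        assert coefficient_of_variation(mu, sigma).loc["T1"] == 0.0


class TestTailProbability:
    def test_values(self):
        assert tail_probability(0.0) == pytest.approx(0.5)
        assert tail_probability(3.0) == pytest.approx(0.00135, abs=5e-6)
        assert tail_probability(-np.inf) == 1.0
        assert tail_probability(np.inf) == 0.0
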