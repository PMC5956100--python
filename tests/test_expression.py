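"""Normalization, BH adjustment, the Welch DE filter, PCA and SDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from devcoexpr.expression import (
    benjamini_hochberg,
    compute_sdr,
    consecutive_stage_de,
    normalize_log2_cpm,
    pca_scores,
    stage_mean_sdr,
)
from devcoexpr.simulate import DEBlock, SimConfig, simulate_dataset
from devcoexpr.types import CountMatrix, SampleMetadata, ValidationError


def bh_stepup_oracle(pvalues):
    """Brute-force BH step-up: q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


class TestNormalize:
    def test_direct_arithmetic(self):
        # sample s1 has total exactly 1e6, so CPM equals the raw count
        df = pd.DataFrame(
            {"s1": [1024, 1_000_000 - 1024 - 0, 0], "s2": [10, 10, 10]},
            index=["g1", "g2", "g3"],
        )
        norm = normalize_log2_cpm(CountMatrix(df), pseudocount=1.0)
        assert norm.loc["g1", "s1"] == pytest.approx(np.log2(1025))
        assert norm.loc["g3", "s1"] == 0.0  # log2(0 + 1)

    def test_scale_invariance(self, small_counts):
        norm1 = normalize_log2_cpm(small_counts)
        doubled = CountMatrix(small_counts.counts * 2)
        norm2 = normalize_log2_cpm(doubled)
        pd.testing.assert_frame_equal(norm1, norm2)

    def test_zero_total_sample_named(self):
        df = pd.DataFrame({"ok": [1, 2], "dead": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValidationError, match="dead"):
            normalize_log2_cpm(CountMatrix(df))


class TestBenjaminiHochberg:
    def test_hand_evaluated_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.2])

    @given(
        arrays(float, st.integers(1, 60),
               elements=st.floats(0, 1, allow_nan=False))
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_oracle_and_dominates_p(self, p):
        q = benjamini_hochberg(p)
        np.testing.assert_allclose(q, bh_stepup_oracle(p), atol=1e-12)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestConsecutiveStageDE:
    def test_planted_block_recovered(self, rng):
        cfg = SimConfig(
            n_genes=500,
            stage_order=("E11", "E12"),
            replicates=(6, 7),
            de_blocks=(DEBlock(50, ("E12",), 2.0),),
            dispersion=0.05,
            seed=5,
        )
        counts, meta, truth = simulate_dataset(cfg)
        norm = normalize_log2_cpm(counts)
        res = consecutive_stage_de(norm, meta)
        planted = set(truth[truth.is_de].gene)
        sens = len(planted & set(res.de_genes)) / len(planted)
        assert sens >= 0.9

    def test_identical_stages_not_de(self, two_stage_meta):
        norm = pd.DataFrame(
            [[5.0, 6.0, 5.0, 6.0], [1.0, 2.0, 1.0, 2.0]],
            index=["g1", "g2"],
            columns=["s1", "s2", "s3", "s4"],
        )
        res = consecutive_stage_de(norm, two_stage_meta)
        table = res.tables[("A", "B")]
        np.testing.assert_allclose(table.log2fc, 0.0)
        assert res.de_genes == []

    def test_fold_change_filter_excludes_small_significant_shift(self):
        """A noise-free shift of log2(1.4) has p ~ 0 but fails the 1.5-fold filter."""
        meta = SampleMetadata(
            {f"s{i}": ("A" if i < 10 else "B") for i in range(20)},
            ("A", "B"),
        )
        rng = np.random.default_rng(0)
        base = rng.normal(5, 0.001, (5, 20))
        base[:, 10:] += np.log2(1.4)
        norm = pd.DataFrame(base, index=[f"g{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(20)])
        res = consecutive_stage_de(norm, meta, fc_min=1.5, q_max=0.05)
        assert (res.tables[("A", "B")].q < 1e-6).all()
        assert res.de_genes == []

    def test_q_dominates_p(self, study_meta, rng):
        norm = pd.DataFrame(
            rng.normal(5, 1, (40, 28)),
            index=[f"g{i}" for i in range(40)],
            columns=study_meta.sample_ids,
        )
        for table in consecutive_stage_de(norm, study_meta).tables.values():
            assert (table.q >= table.p - 1e-15).all()


class TestPCA:
    def test_rank_one_data(self, rng):
        direction = rng.normal(size=50)
        weights = rng.normal(size=12)
        data = np.outer(direction, weights) + rng.normal(0, 1e-4, (50, 12))
        norm = pd.DataFrame(data, index=[f"g{i}" for i in range(50)],
                            columns=[f"s{i}" for i in range(12)])
        _, varfrac = pca_scores(norm, 3)
        assert varfrac[0] >= 0.99

    def test_scores_orthogonal(self, rng):
        norm = pd.DataFrame(rng.normal(size=(30, 10)))
        scores, _ = pca_scores(norm, 4)
        gram = scores.to_numpy().T @ scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_out_of_range_components_rejected(self, rng):
        norm = pd.DataFrame(rng.normal(size=(30, 10)))
        with pytest.raises(ValidationError):
            pca_scores(norm, 11)

    def test_stage_trajectory_clusters(self):
        """Samples from the default synthetic design cluster by stage."""
        from devcoexpr.simulate import default_study_config

        counts, meta, _ = simulate_dataset(default_study_config())
        norm = normalize_log2_cpm(counts)
        scores, _ = pca_scores(norm, 2)
        x = scores.to_numpy()
        stages = np.array([meta.stage_of[s] for s in scores.index])
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        same = stages[:, None] == stages[None, :]
        iu = np.triu_indices(len(x), 1)
        assert d[iu][same[iu]].mean() < d[iu][~same[iu]].mean()


class TestSDR:
    def test_hand_evaluated_example(self):
        norm = pd.DataFrame([[2.0, 2.0, 4.0, 4.0]], index=["g"],
                            columns=list("abcd"))
        np.testing.assert_allclose(compute_sdr(norm).loc["g"], [-1, -1, 1, 1])

    def test_constant_gene_all_zero(self):
        norm = pd.DataFrame([[3.0, 3.0, 3.0]], index=["g"], columns=list("abc"))
        np.testing.assert_allclose(compute_sdr(norm).loc["g"], 0.0)

    @given(
        arrays(float, st.tuples(st.integers(1, 8), st.integers(2, 10)),
               elements=st.floats(-50, 50, allow_nan=False))
    )
    @settings(max_examples=150, deadline=None)
    def test_centering_and_unit_scale(self, values):
        sdr = compute_sdr(pd.DataFrame(values)).to_numpy()
        assert np.all(np.abs(sdr) <= 1 + 1e-12)
        centered = values - values.mean(axis=1, keepdims=True)
        nonconstant = np.abs(centered).max(axis=1) > 1e-9
        # centered values sum to zero, and non-constant genes reach |sdr|=1
        scaled_sum = np.abs(sdr.sum(axis=1))
        assert np.all(scaled_sum[nonconstant] < 1e-6)
        assert np.allclose(np.abs(sdr[nonconstant]).max(axis=1), 1.0)

    def test_stage_means(self, two_stage_meta):
        sdr = pd.DataFrame([[-1.0, -1.0, 1.0, 1.0], [0, 0, 0, 0]],
                           index=["g1", "g2"], columns=["s1", "s2", "s3", "s4"])
        prof = stage_mean_sdr(sdr, two_stage_meta)
        assert prof.loc["g1", "A"] == -1.0
        assert prof.loc["g1", "B"] == 1.0
        assert (prof.loc["g2"] == 0).all()

    @given(
        arrays(float, st.tuples(st.integers(1, 6), st.just(4)),
               elements=st.floats(-1, 1, allow_nan=False))
    )
    @settings(max_examples=100, deadline=None)
    def test_stage_mean_within_sample_range(self, values):
        sdr = pd.DataFrame(values, columns=["s1", "s2", "s3", "s4"])
        meta = SampleMetadata(
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}, ("A", "B")
        )
        prof = stage_mean_sdr(sdr, meta)
        for gene in sdr.index:
            assert sdr.loc[gene].min() - 1e-12 <= prof.loc[gene].min()
            assert prof.loc[gene].max() <= sdr.loc[gene].max() + 1e-12


class TestDETypeIControl:
    def test_null_de_fraction_bounded(self):
        """On 20 null simulations the DE fraction stays within binomial
        error of the nominal FDR level."""
        total_genes = 0
        total_called = 0
        for seed in range(20):
            cfg = SimConfig(n_genes=250, dispersion=0.05, seed=1000 + seed)
            counts, meta, _ = simulate_dataset(cfg)
            norm = normalize_log2_cpm(counts)
            res = consecutive_stage_de(norm, meta)
            total_genes += cfg.n_genes
            total_called += len(res.de_genes)
        frac = total_called / total_genes
        bound = 0.05 + 2 * np.sqrt(0.05 * 0.95 / total_genes)
        assert frac <= bound
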