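"""Expression normalization, nsNMF factorization and kinetic-class calls."""

import numpy as np
import pandas as pd
import pytest

from virokin.kinetic_classes import (
    ExpressionMatrix,
    assign_classes,
    de_threshold,
    length_standardize,
    min_shift,
    nsnmf_factorize,
    replicate_concordance,
    size_factors,
    timepoint_profiles,
)


def make_em(counts: pd.DataFrame, timepoints, conditions=None, replicates=None):
    meta = pd.DataFrame(
        {
            "timepoint_h": timepoints,
            "condition": conditions or ["single"] * len(counts.columns),
            "replicate": replicates or ["1"] * len(counts.columns),
        },
        index=counts.columns,
    )
    lengths = pd.Series(1000.0, index=counts.index)
    return ExpressionMatrix(counts, lengths, meta)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [3, 5, 9], "s2": [3, 5, 9], "s3": [3, 5, 9]})
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_doubled_column_equivariance(self, rng):
        """Factors are defined up to a common scale; doubling one sample's
        counts doubles its factor relative to every other sample's."""
        base = pd.DataFrame(rng.integers(1, 200, (50, 4)).astype(float))
        doubled = base.copy()
        doubled[0] = base[0] * 2.0
        rel0 = size_factors(base).to_numpy()
        rel1 = size_factors(doubled).to_numpy()
        np.testing.assert_allclose(
            (rel1[0] / rel1[1:]), 2 * (rel0[0] / rel0[1:]), rtol=1e-12
        )

    def test_matches_deseq2_reference_implementation(self, rng):
        """Independent cross-check against pydeseq2's size-factor routine."""
        from pydeseq2.preprocessing import deseq2_norm

        counts = pd.DataFrame(
            rng.integers(1, 500, (40, 6)).astype(float),
            columns=[f"s{i}" for i in range(6)],
        )
        ours = size_factors(counts)
        _, ref = deseq2_norm(counts.T)  # pydeseq2 uses samples x genes
        np.testing.assert_allclose(ours.to_numpy(), np.asarray(ref), rtol=1e-10)

    def test_hand_computed_medians_of_ratios(self):
        counts = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [2.0, 4.0, 6.0], "s3": [4.0, 8.0, 12.0]}
        )
        # every gene's geometric mean doubles down the column pattern:
        # ratios are 0.5, 1, 2 for all genes
        np.testing.assert_allclose(size_factors(counts), [0.5, 1.0, 2.0], rtol=1e-12)

    def test_all_zero_gene_matrix_rejected(self):
        counts = pd.DataFrame({"s1": [0, 1], "s2": [1, 0]})
        with pytest.raises(ValueError, match="no gene"):
            size_factors(counts)


class TestLengthStandardize:
    def test_uniform_length_is_uniform_scaling(self):
        m = pd.DataFrame({"s1": [10.0, 20.0]}, index=["g1", "g2"])
        out = length_standardize(m, pd.Series(1000.0, index=["g1", "g2"]))
        np.testing.assert_allclose(out["s1"], [0.01, 0.02])

    def test_doubling_length_halves_value_cellwise(self):
        m = pd.DataFrame(
            {"s1": [10.0, 10.0], "s2": [6.0, 6.0]}, index=["g1", "g2"]
        )
        out = length_standardize(m, pd.Series([500.0, 1000.0], index=["g1", "g2"]))
        np.testing.assert_allclose(out.loc["g1"], 2 * out.loc["g2"])
        np.testing.assert_allclose(
            out.to_numpy(), [[0.02, 0.012], [0.01, 0.006]]
        )

    def test_missing_length_rejected(self):
        m = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="missing length"):
            length_standardize(m, pd.Series([100.0], index=["other"]))


class TestTimepointProfiles:
    def test_replicate_mean_then_z_score_with_sample_sd(self):
        counts = pd.DataFrame(
            {"a": [2.0], "b": [4.0], "c": [2.0], "d": [2.0]}, index=["g"]
        )
        meta = pd.DataFrame(
            {
                "timepoint_h": [0.0, 0.0, 6.0, 12.0],
                "condition": ["single"] * 4,
                "replicate": ["1", "2", "1", "1"],
            },
            index=list("abcd"),
        )
        prof, flat = timepoint_profiles(counts, meta)
        # replicates {2, 4} at t0 average to 3; profile [3, 2, 2] is z-scored
        np.testing.assert_allclose(
            prof.loc["g"], ((np.array([3.0, 2.0, 2.0]) - 7 / 3) / np.std([3, 2, 2], ddof=1))
        )
        assert len(flat) == 0

    def test_linear_profile_z_scores_to_unit_steps(self):
        counts = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=["g"])
        meta = pd.DataFrame(
            {
                "timepoint_h": [0.0, 6.0, 12.0],
                "condition": ["single"] * 3,
                "replicate": ["1"] * 3,
            },
            index=list("abc"),
        )
        prof, _ = timepoint_profiles(counts, meta)  # sample sd (ddof=1)
        np.testing.assert_allclose(prof.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_gene_flagged_and_zeroed(self):
        counts = pd.DataFrame(
            {"a": [5.0, 1.0], "b": [5.0, 2.0], "c": [5.0, 3.0]},
            index=["flat", "rising"],
        )
        meta = pd.DataFrame(
            {
                "timepoint_h": [0.0, 6.0, 12.0],
                "condition": ["single"] * 3,
                "replicate": ["1"] * 3,
            },
            index=list("abc"),
        )
        prof, flat = timepoint_profiles(counts, meta)
        assert list(flat) == ["flat"]
        np.testing.assert_array_equal(prof.loc["flat"], 0.0)


class TestNsNmf:
    def test_exact_rank_one_matrix_reconstructed(self, rng):
        v = np.outer(rng.uniform(1, 2, 20), rng.uniform(1, 2, 6))
        f = nsnmf_factorize(v, rank=1, theta=0.0, seed=0, n_restarts=5)
        rel = f.reconstruction_error / np.linalg.norm(v, "fro")
        assert rel < 1e-6

    def test_objective_monotone_nonincreasing(self, rng):
        for _ in range(50):
            v = rng.uniform(0, 1, (15, 7))
            f = nsnmf_factorize(
                v, rank=3, theta=0.5, seed=int(rng.integers(2**31)), n_restarts=1
            )
            assert np.all(np.diff(f.objective_history) <= 1e-10)

    def test_theta_zero_matches_plain_nmf_oracle(self, rng):
        """With theta = 0 the factorization solves the standard NMF problem;
        scikit-learn's multiplicative-update NMF is the independent oracle."""
        from sklearn.decomposition import NMF

        v = np.abs(rng.normal(1, 0.3, (30, 8)))
        ours = nsnmf_factorize(v, rank=3, theta=0.0, seed=0, n_restarts=10)
        sk = NMF(
            n_components=3, init="random", solver="mu", beta_loss="frobenius",
            max_iter=2000, random_state=0, tol=1e-6,
        )
        w = sk.fit_transform(v)
        sk_err = np.linalg.norm(v - w @ sk.components_, "fro")
        assert ours.reconstruction_error <= sk_err * 1.05

    def test_smoothing_matrix_definition(self):
        f = nsnmf_factorize(np.ones((4, 4)) + np.eye(4), rank=2, theta=0.5,
                            seed=0, n_restarts=1, max_iter=50)
        s = f.smoothing_matrix()
        np.testing.assert_allclose(s, 0.5 * np.eye(2) + 0.25 * np.ones((2, 2)))
        np.testing.assert_allclose(s.sum(axis=0), 1.0)  # column-stochastic

    def test_deterministic_given_seed(self, rng):
        v = rng.uniform(0, 1, (12, 5))
        f1 = nsnmf_factorize(v, rank=2, theta=0.5, seed=42, n_restarts=3)
        f2 = nsnmf_factorize(v, rank=2, theta=0.5, seed=42, n_restarts=3)
        np.testing.assert_array_equal(f1.basis, f2.basis)
        np.testing.assert_array_equal(f1.coeff, f2.coeff)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            nsnmf_factorize(np.array([[1.0, -1.0]]), rank=1)
        with pytest.raises(ValueError, match="rank"):
            nsnmf_factorize(np.ones((3, 3)), rank=5)


class TestClassAssignment:
    @staticmethod
    def planted_profiles(n_per_class=10):
        timepoints = [0.0, 12.0, 24.0]
        blocks = []
        names = []
        for i, peak in enumerate(timepoints):
            block = np.full((n_per_class, 3), 0.1)
            block[:, i] = 1.0
            blocks.append(block)
            names += [f"c{i}_g{j}" for j in range(n_per_class)]
        return pd.DataFrame(np.vstack(blocks), index=names, columns=timepoints)

    def test_noiseless_three_class_labels_follow_peak_time(self):
        prof = self.planted_profiles()
        z = prof.sub(prof.mean(axis=1), axis=0).div(prof.std(axis=1, ddof=1), axis=0)
        fact = nsnmf_factorize(min_shift(z).to_numpy(), rank=3, theta=0.5, seed=0,
                               n_restarts=10)
        asg = assign_classes(fact, z)
        assert asg.class_order == ["early", "mid", "late"]
        for gene, label in asg.labels.items():
            expected = {"c0": "early", "c1": "mid", "c2": "late"}[gene.split("_")[0]]
            assert label == expected
        assert asg.class_peak_time["early"] < asg.class_peak_time["late"]

    def test_single_component_puts_all_genes_in_one_class(self):
        prof = self.planted_profiles(n_per_class=4).iloc[:4]
        fact = nsnmf_factorize(prof.to_numpy(), rank=1, theta=0.0, seed=0,
                               n_restarts=2)
        asg = assign_classes(fact, prof)
        assert set(asg.labels) == {"class_1"}

    def test_gene_order_permutation_invariance(self, rng):
        prof = self.planted_profiles()
        z = prof.sub(prof.mean(axis=1), axis=0).div(prof.std(axis=1, ddof=1), axis=0)
        perm = rng.permutation(len(z))
        zp = z.iloc[perm]
        a1 = assign_classes(
            nsnmf_factorize(min_shift(z).to_numpy(), 3, 0.5, seed=0, n_restarts=5), z
        )
        a2 = assign_classes(
            nsnmf_factorize(min_shift(zp).to_numpy(), 3, 0.5, seed=0, n_restarts=5), zp
        )
        common = a1.labels.index
        assert (a2.labels.loc[common] == a1.labels.loc[common]).all()


class TestReplicateConcordance:
    @staticmethod
    def planted_em(rng, shuffle_sample=None):
        timepoints = [0.0, 12.0, 24.0]
        genes = [f"g{i}" for i in range(30)]
        cols, meta_tp, meta_rep = [], [], []
        data = {}
        base = rng.uniform(50, 500, size=(30, 3))
        peaked = base.copy()
        for i in range(3):
            peaked[10 * i : 10 * (i + 1), i] *= 20  # block structure
        for i, tp in enumerate(timepoints):
            for rep in ("1", "2"):
                col = f"T{int(tp)}_r{rep}"
                noise = rng.normal(1, 0.02, 30)
                data[col] = np.round(peaked[:, i] * noise).clip(1)
                cols.append(col)
                meta_tp.append(tp)
                meta_rep.append(rep)
        counts = pd.DataFrame(data, index=genes)
        if shuffle_sample:
            counts[shuffle_sample] = rng.permutation(
                counts[shuffle_sample].to_numpy()
            )
        meta = pd.DataFrame(
            {"timepoint_h": meta_tp, "condition": "single", "replicate": meta_rep},
            index=cols,
        )
        return ExpressionMatrix(counts, pd.Series(1000.0, index=genes), meta)

    def test_duplicated_replicates_pass(self, rng):
        em = self.planted_em(rng)
        verdict, table = replicate_concordance(em, rank=3, seed=0)
        assert verdict
        assert table["cluster"].nunique() == 3

    def test_shuffled_replicate_fails_and_is_named(self, rng):
        em = self.planted_em(rng, shuffle_sample="T12_r2")
        verdict, table = replicate_concordance(em, rank=3, seed=0)
        assert not verdict
        assert not table.loc["T12_r2", "concordant"]


class TestDeThreshold:
    def test_threshold_rule_examples(self):
        table = pd.DataFrame(
            {
                "log2fc": [0.0, 2.5, -2.5, 2.5, 2.0],
                "padj": [1e-4, 1e-4, 1e-4, 0.01, 1e-4],
            },
            index=["flat", "up", "down", "weak_p", "boundary"],
        )
        out = de_threshold(table)
        # strict inequalities: |lfc| must exceed 2 and padj be below 1e-3
        assert sorted(out.index) == ["down", "up"]
        assert out.loc["up", "direction"] == "up"
        assert out.loc["down", "direction"] == "down"

    def test_five_row_enumeration(self):
        table = pd.DataFrame(
            {
                "log2fc": [3.0, -4.0, 1.0, 2.1, -2.2],
                "padj": [1e-5, 1e-6, 1e-9, 0.5, 9e-4],
            },
            index=list("abcde"),
        )
        assert sorted(de_threshold(table).index) == ["a", "b", "e"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="padj"):
            de_threshold(pd.DataFrame({"log2fc": [1.0]}))
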