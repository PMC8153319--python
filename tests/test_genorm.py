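import numpy as np
import pandas as pd
import pytest

from refstab import to_quantities
from refstab.genorm import (
    genorm,
    m_values,
    m_values_from_pairwise,
    normalization_factor,
    optimal_gene_count,
    pairwise_variation,
    pairwise_variation_matrix,
    rank_genes,
)
from tests.conftest import random_ct_matrix


def q_from_log2(x: pd.DataFrame):
    ct = 25.0 - x  # arbitrary anchor; quantities renormalize per gene
    return to_quantities(ct)


def brute_force_m(x: pd.DataFrame) -> pd.Series:
    """Independent double-loop M values from a log2-quantity matrix."""
    genes = list(x.index)
    out = {}
    for j in genes:
        vs = []
        for k in genes:
            if k == j:
                continue
            ratios = x.loc[j] - x.loc[k]
            vs.append(np.std(ratios.to_numpy(), ddof=1))
        out[j] = np.mean(vs)
    return pd.Series(out)


class TestPairwiseVariation:
    def test_identical_genes_zero(self):
        x = pd.DataFrame([[0, -1, -2.0]] * 2, index=["a", "b"])
        assert pairwise_variation(q_from_log2(x), "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_constant_ratio_zero(self):
        x = pd.DataFrame([[0, -1, -2.0], [-3, -4, -5.0]], index=["a", "b"])
        assert pairwise_variation(q_from_log2(x), "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_value(self):
        # log2 ratios {0, -1}: sample SD = sqrt(0.5) = 0.7071
        x = pd.DataFrame([[0.0, -1.0], [0.0, 0.0]], index=["a", "b"])
        v = pairwise_variation(q_from_log2(x), "a", "b")
        assert v == pytest.approx(0.70710678, abs=1e-6)

    def test_symmetry(self, rng):
        mat = random_ct_matrix(rng)
        v = pairwise_variation_matrix(to_quantities(mat))
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)


class TestMValues:
    def test_arithmetic_from_pairwise(self):
        v = pd.DataFrame(
            [[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]],
            index=list("abc"),
            columns=list("abc"),
        )
        m = m_values_from_pairwise(v)
        assert m["a"] == pytest.approx(0.3)
        assert m["b"] == pytest.approx(0.4)
        assert m["c"] == pytest.approx(0.5)

    def test_duplicated_pair_zero(self):
        x = pd.DataFrame([[0, -1, -2.0]] * 2, index=["a", "b"])
        m = m_values(q_from_log2(x))
        assert np.allclose(m, 0.0)

    def test_brute_force_oracle(self, rng):
        for _ in range(10):
            mat = random_ct_matrix(rng, n_genes=5, n_samples=6)
            q = to_quantities(mat)
            engine = m_values(q)
            oracle = brute_force_m(np.log2(q.q))
            assert np.abs(engine - oracle).max() < 1e-12

    def test_survey_survivors(self, schima_q):
        res = rank_genes(schima_q)
        assert set(res.ranking[:2]) == {"SsuTUA1", "SsuRIB"}


class TestRanking:
    def test_survey_ranks_match_published(self, schima_q, published_consensus):
        res = rank_genes(schima_q)
        for gene, rank in published_consensus["genorm"].items():
            assert res.rank_of[gene] == rank
        assert res.rank_of["SsuCas"] == 18
        assert res.rank_of["SsuUDP"] == 17

    def test_dense_ranks_two_at_one(self, schima_q):
        res = rank_genes(schima_q)
        ranks = sorted(res.rank_of.values())
        assert ranks.count(1) == 2
        assert ranks == [1] + list(range(1, 19))

    def test_identical_pair_survives(self):
        x = pd.DataFrame(
            [[0, -1, -2, -0.5], [0, -1, -2, -0.5], [0, -3, -1, -2.2]],
            index=["a", "b", "noisy"],
        )
        res = rank_genes(q_from_log2(x))
        assert set(res.ranking[:2]) == {"a", "b"}
        assert res.rank_of["noisy"] == 2

    def test_double_noise_gene_excluded_first_majority(self):
        hits = 0
        for seed in range(200):
            rs = np.random.default_rng(seed)
            x = pd.DataFrame(
                np.vstack(
                    [rs.normal(0, 0.3, 6), rs.normal(0, 0.3, 6), rs.normal(0, 0.6, 6)]
                ),
                index=["A", "B", "C"],
            )
            hits += rank_genes(q_from_log2(x)).ranking[-1] == "C"
        assert hits / 200 > 0.5

    def test_invariance_to_scaling_and_sample_order(self, rng):
        mat = random_ct_matrix(rng, n_genes=6)
        q = to_quantities(mat)
        base = rank_genes(q).ranking
        shifted = rank_genes(to_quantities(mat + rng.normal(0, 2, (6, 1)))).ranking
        assert shifted == base
        perm = list(rng.permutation(mat.columns))
        assert rank_genes(to_quantities(mat[perm])).ranking == base


class TestNormalizationFactor:
    def test_two_gene_geometric_mean(self):
        q = to_quantities(pd.DataFrame([[20.0, 22.0], [20.0, 20.0]], index=["a", "b"]))
        nf = normalization_factor(q, ["a", "b"])
        assert np.allclose(nf, [1.0, 0.5])

    def test_equal_genes_identity(self):
        q = to_quantities(pd.DataFrame([[20.0, 21.0]] * 3, index=list("abc")))
        nf = normalization_factor(q, list("abc"))
        assert np.allclose(nf, [1.0, 0.5])

    def test_three_gene_example(self):
        ct = pd.DataFrame(
            [[20.0, 20.0], [20.0, 21.0], [20.0, 22.0]], index=list("abc")
        )
        nf = normalization_factor(to_quantities(ct), list("abc"))
        # (1 * 0.5 * 0.25)^(1/3) = 0.5
        assert np.allclose(nf, [1.0, 0.5])


class TestOptimalCount:
    def test_survey_optimal_two(self, schima_q):
        res = genorm(schima_q)
        assert res.optimal_n == 2
        assert res.threshold_met
        # the last pairwise variation (adding the worst gene) exceeds 0.15
        assert res.v_series.iloc[-1] > 0.15
        assert (res.v_series.iloc[:-1] < 0.15).all()

    def test_proportional_genes_all_zero(self):
        x = pd.DataFrame(
            [[0.0, -1, -2, -3]] * 4 + [[-1.0, -2, -3, -4]],
            index=list("abcde"),
        )
        v_series, optimal_n, met = optimal_gene_count(q_from_log2(x))
        assert np.allclose(v_series, 0.0)
        assert optimal_n == 2 and met

    def test_constructed_three_gene_optimum(self):
        # four genes with mutually orthogonal, equal-strength noise vectors:
        # V(2/3) = sigma/sqrt(6) and V(3/4) = sigma/sqrt(12) exactly, so
        # sigma = 0.45 puts the first below 0.15 only at n = 3.
        sigma = 0.45
        a = sigma * np.sqrt(7 / 8)
        h = np.array(
            [
                [1, -1, 1, -1, 1, -1, 1, -1],
                [1, 1, -1, -1, 1, 1, -1, -1],
                [1, -1, -1, 1, 1, -1, -1, 1],
                [1, 1, 1, 1, -1, -1, -1, -1],
            ],
            dtype=float,
        )
        x = pd.DataFrame(a * h, index=list("abcd"))
        q = q_from_log2(x)
        v_series, optimal_n, met = optimal_gene_count(q, ranking=list("abcd"))
        # oracle: direct NF computation from geometric means
        logq = np.log2(q.q)
        for n in (2, 3):
            nf_n = logq.iloc[:n].mean(axis=0)
            nf_n1 = logq.iloc[: n + 1].mean(axis=0)
            assert v_series[n] == pytest.approx(np.std(nf_n - nf_n1, ddof=1), abs=1e-12)
        assert v_series[2] == pytest.approx(sigma / np.sqrt(6), abs=1e-9)
        assert v_series[3] == pytest.approx(sigma / np.sqrt(12), abs=1e-9)
        assert optimal_n == 3 and met

    def test_no_v_below_threshold_flags(self, rng):
        x = pd.DataFrame(rng.normal(0, 3.0, (4, 6)), index=list("abcd"))
        v_series, optimal_n, met = optimal_gene_count(q_from_log2(x), threshold=1e-6)
        assert not met and optimal_n == 4
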