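"""TPM conversion, detection filtering, ranking, Spearman, background null."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from neighborcorr.expression_corr import (
    ExpressionMatrix,
    background_correlation,
    detection_filter,
    pair_correlations,
    rank_by_experiment,
    tpm_from_counts,
)
from neighborcorr.genome_pairs import GeneTable, PairTable, neighbor_pairs


def _matrix(values, genes=None, exps=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    exps = exps or [f"e{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=exps))


def _pair_table(pairs):
    df = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
    df["chromosome"] = "chr1"
    df["distance_bp"] = 1000
    df["rank_separation"] = 1
    df["orientation"] = "parallel"
    df["is_operon_pair"] = False
    df["is_duplicate_pair"] = False
    return PairTable(df, k=1)


class TestTPM:
    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = pd.DataFrame({"e1": [10, 10]}, index=["g1", "g2"])
        tpm = tpm_from_counts(counts, np.array([500.0, 500.0]))
        assert np.allclose(tpm.df["e1"], [500_000, 500_000])

    def test_length_normalization_hand_computed(self):
        counts = pd.DataFrame({"e1": [10, 10]}, index=["g1", "g2"])
        tpm = tpm_from_counts(counts, np.array([1000.0, 2000.0]))
        assert np.allclose(tpm.df["e1"], [666_666.6667, 333_333.3333], atol=0.01)

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(30, 5)).astype(float))
        counts.index = [f"g{i}" for i in range(30)]
        tpm = tpm_from_counts(counts, rng.uniform(200, 5000, 30))
        assert np.allclose(tpm.df.sum(axis=0), 1e6, rtol=1e-6)

    def test_all_zero_experiment_named_in_error(self):
        counts = pd.DataFrame({"ok": [5, 5], "dead": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="dead"):
            tpm_from_counts(counts, np.array([100.0, 100.0]))

    def test_nonpositive_length_rejected(self):
        counts = pd.DataFrame({"e1": [5, 5]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="length"):
            tpm_from_counts(counts, np.array([100.0, 0.0]))


class TestDetectionFilter:
    def test_boundary_inclusive(self):
        row_kept = [1.0] * 8 + [0.0] * 2  # 8/10 detected
        row_dropped = [1.0] * 7 + [0.0] * 3  # 7/10 detected
        m = _matrix([row_kept, row_dropped])
        out = detection_filter(m, min_frac=0.8)
        assert list(out.df.index) == ["g0"]

    def test_zero_inflated_matrix_matches_counting_oracle(self, rng):
        vals = rng.uniform(0, 10, size=(100, 20))
        vals[rng.random(vals.shape) < 0.4] = 0.0
        m = _matrix(vals)
        out = detection_filter(m, min_frac=0.8)
        oracle = {f"g{i}" for i in range(100) if (vals[i] > 0).sum() >= 16}
        assert set(out.df.index) == oracle

    def test_missing_does_not_count_as_detected(self):
        vals = np.ones((2, 10))
        vals[0, :3] = np.nan
        m = _matrix(vals)
        out = detection_filter(m, min_frac=0.8)
        assert list(out.df.index) == ["g1"]

    def test_empty_result_errors(self):
        m = _matrix(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="every gene"):
            detection_filter(m)


def naive_average_ranks(col: np.ndarray) -> np.ndarray:
    """Independent tie-averaged ranking oracle via double argsort."""
    order = np.argsort(col, kind="stable")
    ranks = np.empty(len(col), dtype=float)
    i = 0
    while i < len(col):
        j = i
        while j + 1 < len(col) and col[order[j + 1]] == col[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


class TestRanking:
    def test_strict_ordering(self):
        r = rank_by_experiment(_matrix([[3.0], [1.0], [2.0]]))
        assert list(r.df["e0"]) == [3, 1, 2]

    def test_ties_get_average_ranks(self):
        r = rank_by_experiment(_matrix([[5.0], [5.0], [1.0]]))
        assert list(r.df["e0"]) == [2.5, 2.5, 1.0]

    def test_random_matrix_matches_sort_oracle(self, rng):
        vals = np.round(rng.uniform(0, 10, size=(50, 5)), 1)  # induce ties
        r = rank_by_experiment(_matrix(vals))
        for j in range(5):
            assert np.allclose(r.df.iloc[:, j], naive_average_ranks(vals[:, j]))

    def test_missing_entries_stay_missing(self):
        vals = np.array([[1.0, 2.0], [np.nan, 1.0], [3.0, 3.0]])
        r = rank_by_experiment(_matrix(vals))
        assert np.isnan(r.df.iloc[1, 0])
        assert list(r.df.iloc[:, 0].dropna()) == [1.0, 2.0]

    def test_degenerate_experiment_excluded(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, 5.0]])
        r = rank_by_experiment(_matrix(vals))
        assert list(r.df.columns) == ["e0"]


class TestPairCorrelations:
    def _ranked(self, vals):
        return rank_by_experiment(_matrix(vals))

    def test_identical_expression_gives_rho_one(self, rng):
        # two identical genes plus a third to keep their ranks non-constant
        x = np.array([1.0, 5.0, 2.0, 9.0, 3.0, 4.0, 8.0, 7.0, 6.0, 10.0])
        vals = np.vstack([x, x, rng.uniform(0, 20, 10)])
        r = self._ranked(vals)
        out = pair_correlations(r, _pair_table([("g0", "g1")]), min_obs=3)
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self, rng):
        x = rng.uniform(1, 10, 10)
        vals = np.vstack([x, x.max() + 1 - x])
        out = pair_correlations(self._ranked(vals), _pair_table([("g0", "g1")]), min_obs=3)
        assert out["rho"].iloc[0] == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        # ranks x=(1,2,3), y=(2,1,3): cov=1/3, var=2/3 each -> rho=0.5
        from neighborcorr.expression_corr import _masked_pearson

        rho, n = _masked_pearson(
            np.array([[1.0, 2.0, 3.0]]), np.array([[2.0, 1.0, 3.0]])
        )
        assert n[0] == 3
        assert rho[0] == pytest.approx(0.5, abs=1e-15)

    def test_matches_naive_rank_pearson(self, rng):
        # oracle: rank each experiment with the independent naive ranker,
        # then plain numpy Pearson of the two rank trajectories
        n_genes, n_exp = 40, 25
        vals = rng.uniform(0.1, 100, size=(n_genes, n_exp))
        r = self._ranked(vals)
        pairs = _pair_table([(f"g{i}", f"g{i+1}") for i in range(n_genes - 1)])
        out = pair_correlations(r, pairs, min_obs=3)
        ranks = np.column_stack([naive_average_ranks(vals[:, j]) for j in range(n_exp)])
        for i in range(n_genes - 1):
            expected = np.corrcoef(ranks[i], ranks[i + 1])[0, 1]
            assert out["rho"].iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_spearman_identity_matches_scipy(self, rng):
        from neighborcorr.expression_corr import spearman

        for _ in range(100):
            x = rng.uniform(0, 100, 40)
            y = rng.uniform(0, 100, 40)
            assert spearman(x, y) == pytest.approx(
                scipy.stats.spearmanr(x, y).statistic, abs=1e-12
            )

    def test_symmetric_in_gene_order(self, rng):
        vals = rng.uniform(0, 10, size=(4, 15))
        r = self._ranked(vals)
        fwd = pair_correlations(r, _pair_table([("g0", "g1")]), min_obs=3)
        rev = pair_correlations(r, _pair_table([("g1", "g0")]), min_obs=3)
        assert fwd["rho"].iloc[0] == pytest.approx(rev["rho"].iloc[0], abs=1e-15)

    def test_monotone_transform_invariance(self, rng):
        vals = rng.lognormal(1, 1, size=(30, 20))
        pairs = _pair_table([(f"g{i}", f"g{i+1}") for i in range(29)])
        base = pair_correlations(self._ranked(vals), pairs, min_obs=3)
        for fn in (np.log1p, lambda x: x**3):
            alt = pair_correlations(self._ranked(fn(vals)), pairs, min_obs=3)
            assert np.max(np.abs(base["rho"] - alt["rho"])) <= 1e-12

    def test_min_obs_floor_omits_sparse_pairs(self, rng):
        vals = rng.uniform(1, 10, size=(3, 12))
        vals[0, :8] = np.nan  # only 4 joint observations with anyone
        out = pair_correlations(
            self._ranked(vals), _pair_table([("g0", "g1"), ("g1", "g2")]), min_obs=10
        )
        assert list(zip(out["gene_a"], out["gene_b"])) == [("g1", "g2")]

    def test_constant_rank_gene_omitted(self, rng):
        # g0 is always the top-expressed gene, so its rank vector is constant
        vals = np.vstack(
            [np.full(12, 100.0), rng.uniform(0, 10, 12), rng.uniform(0, 10, 12)]
        )
        out = pair_correlations(
            self._ranked(vals), _pair_table([("g0", "g1"), ("g1", "g2")]), min_obs=3
        )
        assert ("g0", "g1") not in set(zip(out["gene_a"], out["gene_b"]))
        assert ("g1", "g2") in set(zip(out["gene_a"], out["gene_b"]))

    def test_pairwise_complete_matches_naive_loop(self, rng):
        vals = rng.uniform(1, 10, size=(20, 30))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        r = self._ranked(vals)
        pairs = _pair_table([(f"g{i}", f"g{i+1}") for i in range(19)])
        out = pair_correlations(r, pairs, min_obs=3).set_index(["gene_a", "gene_b"])
        R = r.df.to_numpy()
        for i in range(19):
            both = ~(np.isnan(R[i]) | np.isnan(R[i + 1]))
            if both.sum() < 3:
                continue
            expected = scipy.stats.pearsonr(R[i][both], R[i + 1][both]).statistic
            got = out.loc[(f"g{i}", f"g{i+1}"), "rho"]
            assert got == pytest.approx(expected, abs=1e-10)


def _null_ranked(rng, n_genes=60, n_exp=50):
    vals = rng.uniform(0.5, 100, size=(n_genes, n_exp))
    return rank_by_experiment(_matrix(vals))


def _grid_genes(n_genes, n_chrom=3):
    per = n_genes // n_chrom
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chromosome": [f"chr{i // per + 1}" for i in range(n_genes)],
            "start": [1000 * (i % per) + 1 for i in range(n_genes)],
            "strand": "+",
            "biotype": "protein_coding",
        }
    )
    df["end"] = df["start"] + 100
    df["tss"] = df["start"]
    return GeneTable(df)


class TestBackground:
    def test_deterministic_under_seed(self, rng):
        r = _null_ranked(rng)
        genes = _grid_genes(60)
        a = background_correlation(r, genes, n_per_gene=5, n_boot=200, seed=9)
        b = background_correlation(r, genes, n_per_gene=5, n_boot=200, seed=9)
        assert a == b

    def test_pair_count_is_n_per_gene_times_genes(self, rng):
        r = _null_ranked(rng, n_genes=100)
        genes = _grid_genes(100, n_chrom=4)
        est = background_correlation(r, genes, n_per_gene=20, n_boot=100, seed=1)
        assert est.n_pairs == 2000

    def test_single_chromosome_rejected(self, rng):
        r = _null_ranked(rng, n_genes=20)
        genes = _grid_genes(20, n_chrom=1)
        with pytest.raises(ValueError, match="chromosome"):
            background_correlation(r, genes, seed=0)

    def test_null_ci_contains_theoretical_median(self, rng):
        # within-experiment ranks sum to a constant, so the exact null level
        # of the pairwise rank correlation is -1/(n_genes - 1), not 0
        n_genes = 90
        r = _null_ranked(rng, n_genes=n_genes, n_exp=60)
        genes = _grid_genes(n_genes)
        est = background_correlation(r, genes, n_per_gene=20, n_boot=1000, seed=3)
        assert est.ci_low <= -1 / (n_genes - 1) <= est.ci_high
        assert est.ci_low <= est.median_rho <= est.ci_high

    def test_ci_width_shrinks_with_more_pairs(self):
        rng = np.random.default_rng(77)
        widths = []
        for n_genes, n_per in [(30, 4), (60, 17), (200, 50)]:
            r = _null_ranked(rng, n_genes=n_genes, n_exp=40)
            genes = _grid_genes(n_genes if n_genes % 3 == 0 else n_genes, 2)
            est = background_correlation(r, genes, n_per_gene=n_per, n_boot=500, seed=5)
            widths.append(est.ci_high - est.ci_low)
        assert widths[0] > widths[1] > widths[2]
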