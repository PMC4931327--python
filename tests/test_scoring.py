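import numpy as np
import pandas as pd
import pytest

import statepath as sp
from statepath.io import ExpressionMatrix
from statepath.scoring import (
    CommitmentScore,
    CoverageError,
    _ks_enrichment,
    rank_genes,
    scores_to_frame,
)

from conftest import matrix_from_array


def ranking(genes: list[str]) -> pd.Index:
    return pd.Index(genes)


class TestCmapScore:
    def test_hand_enumerated_ks_maxima(self):
        """n=10, up at ranked positions {1,2}, down at {9,10}.

        ks_up: a = max(1/2-1/10, 1-2/10) = 0.8 beats b = 0.1.
        ks_down: b = max(9/10, 1-1/2) = 0.9 beats a = 0 -> -0.9.
        Opposite signs: raw = 0.8 + 0.9 = 1.7.
        """
        genes = [f"g{i}" for i in range(10)]
        sig = sp.GeneSetPair({"g0", "g1"}, {"g8", "g9"})
        assert sp.cmap_score(ranking(genes), sig) == pytest.approx(1.7)

    def test_extreme_concordance_attains_maximum(self):
        n, s = 20, 3
        genes = [f"g{i:02d}" for i in range(n)]
        sig = sp.GeneSetPair(set(genes[:s]), set(genes[-s:]))
        expected = (1 - s / n) + (n - s + 1) / n
        assert sp.cmap_score(ranking(genes), sig) == pytest.approx(expected)

    def test_antisymmetric_under_up_down_swap(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i:02d}" for i in range(30)]
        for _ in range(20):
            perm = list(rng.permutation(genes))
            up = set(rng.choice(genes, 4, replace=False))
            down = set(rng.choice([g for g in genes if g not in up], 4, replace=False))
            fwd = sp.cmap_score(ranking(perm), sp.GeneSetPair(up, down))
            rev = sp.cmap_score(ranking(perm), sp.GeneSetPair(down, up))
            assert fwd == pytest.approx(-rev)

    def test_zero_when_enrichments_share_sign(self):
        # both halves at the top: both KS stats positive -> score 0
        genes = [f"g{i}" for i in range(10)]
        sig = sp.GeneSetPair({"g0", "g1"}, {"g2", "g3"})
        assert sp.cmap_score(ranking(genes), sig) == 0.0

    def test_coverage_error_when_signature_absent(self):
        genes = [f"g{i}" for i in range(10)]
        sig = sp.GeneSetPair({"x1"}, {"x2"})
        with pytest.raises(CoverageError):
            sp.cmap_score(ranking(genes), sig)

    def test_rank_genes_descending_with_name_ties(self):
        values = pd.Series({"b": 5.0, "a": 5.0, "c": 9.0})
        assert list(rank_genes(values)) == ["c", "a", "b"]


class TestKsEnrichment:
    def test_top_positions_positive(self):
        assert _ks_enrichment(np.array([1, 2]), 10) == pytest.approx(0.8)

    def test_bottom_positions_negative(self):
        assert _ks_enrichment(np.array([9, 10]), 10) == pytest.approx(-0.9)


class TestPermutationTest:
    def _shifted_matrix(self, seed=0, n_cells=40, shift=3.0):
        """Half the cells have up-genes shifted +shift, down-genes -shift."""
        rng = np.random.default_rng(seed)
        n_genes = 60
        Y = rng.normal(5.0, 1.0, size=(n_genes, n_cells))
        up, down = np.arange(0, 8), np.arange(8, 16)
        half = n_cells // 2
        Y[np.ix_(up, np.arange(half))] += shift
        Y[np.ix_(down, np.arange(half))] -= shift
        cells = [f"c{i:02d}" for i in range(n_cells)]
        m = matrix_from_array(Y, cells)
        sig = sp.GeneSetPair(
            {f"g{i:05d}" for i in up}, {f"g{i:05d}" for i in down}
        )
        return m, sig, cells[:half], cells[half:]

    def test_shifted_cells_labeled_positive_committed(self):
        m, sig, shifted, rest = self._shifted_matrix()
        scores = sp.cmap_permutation_test(m, sig, n_perm=200, seed=1)
        by_cell = {s.cell_id: s for s in scores}
        frac = np.mean([by_cell[c].label == "positive-committed" for c in shifted])
        assert frac >= 0.95

    def test_minimal_p_is_add_one_bound(self):
        m, sig, shifted, _ = self._shifted_matrix()
        n_perm = 200
        scores = sp.cmap_permutation_test(m, sig, n_perm=n_perm, seed=2)
        pmin = min(s.p_value for s in scores)
        assert pmin >= 1 / (1 + n_perm)

    def test_scaled_scores_attain_unit_magnitude(self):
        m, sig, *_ = self._shifted_matrix()
        scores = sp.cmap_permutation_test(m, sig, n_perm=100, seed=3)
        assert max(abs(s.scaled) for s in scores) == pytest.approx(1.0)
        assert all(abs(s.scaled) <= 1.0 for s in scores)

    def test_zero_raw_score_uncommitted(self):
        # constant expression: every gene ties, ranking from names only;
        # identical rankings give identical (deterministic) raw scores
        Y = np.full((30, 5), 2.0)
        m = matrix_from_array(Y, [f"c{i}" for i in range(5)])
        sig = sp.GeneSetPair({"g00000", "g00001"}, {"g00010", "g00011"})
        scores = sp.cmap_permutation_test(m, sig, n_perm=100, seed=4)
        for s in scores:
            if s.raw == 0.0:
                assert s.label == "uncommitted"

    def test_seed_reproducibility(self):
        m, sig, *_ = self._shifted_matrix()
        a = sp.cmap_permutation_test(m, sig, n_perm=100, seed=9)
        b = sp.cmap_permutation_test(m, sig, n_perm=100, seed=9)
        assert [s.p_value for s in a] == [s.p_value for s in b]

    def test_missing_seed_rejected(self):
        m, sig, *_ = self._shifted_matrix()
        with pytest.raises(ValueError):
            sp.cmap_permutation_test(m, sig, n_perm=100)


class TestCommitmentByLandmark:
    def test_counting_proportions(self):
        scores = (
            [CommitmentScore(f"p{i}", 1, 1, 0.01, "positive-committed") for i in range(3)]
            + [CommitmentScore(f"n{i}", -1, -1, 0.01, "negative-committed") for i in range(2)]
            + [CommitmentScore(f"u{i}", 0, 0, 1.0, "uncommitted") for i in range(5)]
        )
        membership = pd.Series(
            {s.cell_id: "LM" for s in scores}
        )
        props = sp.commitment_by_landmark(scores, membership)
        assert props.loc["LM", "positive-committed"] == pytest.approx(0.3)
        assert props.loc["LM", "negative-committed"] == pytest.approx(0.2)
        assert props.loc["LM", "uncommitted"] == pytest.approx(0.5)

    def test_rows_sum_to_one(self, y_dataset, y_trajectory):
        m, ls, nn, stn = y_trajectory
        sig = sp.attach_signatures(y_dataset, "C", "D")
        scores = sp.cmap_permutation_test(m, sig, n_perm=100, seed=5)
        props = sp.commitment_by_landmark(scores, ls.membership)
        np.testing.assert_allclose(props.sum(axis=1).values, 1.0)


class TestMarkerOverlay:
    def _landmarks(self):
        from statepath.landmarks import LandmarkSet

        data = pd.DataFrame(
            [[4.0, 4.0, 8.0, 8.0], [2.0, 2.0, 2.0, 2.0]],
            index=["hi", "flat"], columns=["c1", "c2", "c3", "c4"],
        )
        m = ExpressionMatrix(data, scale="log2")
        ls = LandmarkSet(
            centroids=pd.DataFrame(
                {"L1": [4.0, 2.0], "L2": [8.0, 2.0]}, index=["hi", "flat"]
            ),
            membership=pd.Series({"c1": "L1", "c2": "L1", "c3": "L2", "c4": "L2"}),
        )
        return m, ls

    def test_min_max_scaling(self):
        m, ls = self._landmarks()
        vals = sp.marker_overlay(m, ls, "hi")
        assert vals["L1"] == 0.0
        assert vals["L2"] == 1.0

    def test_constant_gene_all_zero_with_warning(self):
        m, ls = self._landmarks()
        with pytest.warns(UserWarning, match="constant"):
            vals = sp.marker_overlay(m, ls, "flat")
        assert (vals == 0.0).all()

    def test_absent_gene_rejected(self):
        m, ls = self._landmarks()
        with pytest.raises(Exception):
            sp.marker_overlay(m, ls, "nope")


class TestGroupAnova:
    def test_constant_gene_f_zero_p_one(self):
        Y = np.vstack([np.full(12, 3.0), np.random.default_rng(0).normal(size=12)])
        cells = [f"c{i}" for i in range(12)]
        m = matrix_from_array(Y, cells)
        ann = pd.Series(["A"] * 6 + ["B"] * 6, index=cells)
        table = sp.group_anova(m, ann, tukey=False)
        assert table.loc["g00000", "F"] == 0.0
        assert table.loc["g00000", "p"] == 1.0

    def test_f_matches_from_scratch_sums_of_squares(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(5, 18))
        cells = [f"c{i}" for i in range(18)]
        m = matrix_from_array(Y, cells)
        ann = pd.Series(["A"] * 6 + ["B"] * 6 + ["C"] * 6, index=cells)
        table = sp.group_anova(m, ann, tukey=False)
        for gi in range(5):
            y = Y[gi]
            grand = y.mean()
            groups = [y[:6], y[6:12], y[12:]]
            ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
            f_expect = (ss_between / 2) / (ss_within / 15)
            assert table["F"].iloc[gi] == pytest.approx(f_expect, rel=1e-10)

    def test_power_for_large_shift(self):
        rng = np.random.default_rng(8)
        hits = 0
        for rep in range(20):
            Y = rng.normal(0.0, 1.0, size=(1, 60))
            Y[0, 30:] += 5.0  # 5 noise-sd shift, n = 30 per group
            cells = [f"c{i}" for i in range(60)]
            m = matrix_from_array(Y, cells)
            ann = pd.Series(["A"] * 30 + ["B"] * 30, index=cells)
            table = sp.group_anova(m, ann, tukey=False)
            hits += table["adj_p"].iloc[0] < 0.05
        assert hits == 20

    def test_null_type_i_error_near_nominal(self):
        rng = np.random.default_rng(12)
        Y = rng.normal(size=(1000, 30))
        cells = [f"c{i}" for i in range(30)]
        m = matrix_from_array(Y, cells)
        ann = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=cells)
        table = sp.group_anova(m, ann, tukey=False)
        frac = (table["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07  # binomial 99% band around 0.05

    def test_bh_adjustment_monotone_and_not_smaller(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(50, 20))
        Y[:10, 10:] += 3.0
        cells = [f"c{i}" for i in range(20)]
        m = matrix_from_array(Y, cells)
        ann = pd.Series(["A"] * 10 + ["B"] * 10, index=cells)
        table = sp.group_anova(m, ann, tukey=False).sort_values("p")
        assert (table["adj_p"].values >= table["p"].values - 1e-15).all()
        assert (np.diff(table["adj_p"].values) >= -1e-12).all()

    def test_tukey_pairwise_filled_for_significant_genes(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(3, 30))
        Y[0, 20:] += 6.0
        cells = [f"c{i}" for i in range(30)]
        m = matrix_from_array(Y, cells)
        ann = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=cells)
        table = sp.group_anova(m, ann)
        sig_gene = table.index[table["adj_p"] < 0.05][0]
        tukey_cols = [c for c in table.columns if c.startswith("tukey_p_")]
        assert len(tukey_cols) == 3
        assert table.loc[sig_gene, tukey_cols].notna().all()

    def test_small_group_rejected(self):
        Y = np.zeros((2, 3))
        cells = ["c1", "c2", "c3"]
        m = matrix_from_array(Y, cells)
        ann = pd.Series(["A", "A", "B"], index=cells)
        with pytest.raises(ValueError):
            sp.group_anova(m, ann)


class TestScoresFrame:
    def test_tsv_columns(self, tmp_path):
        scores = [CommitmentScore("c1", 0.5, 1.0, 0.01, "positive-committed")]
        df = scores_to_frame(scores)
        assert list(df.columns) == ["raw", "scaled", "p", "label"]
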