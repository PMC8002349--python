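import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinflux.itd import (
    classify_genus,
    compute_itd,
    extract_susceptible,
    grand_md,
    mean_itdx,
    standardize,
    welch_test,
)
from twinflux.tables import PairMap, TwinfluxError, taxon_index

from conftest import make_counts


def _std_frame(mat, samples=None):
    mat = np.asarray(mat, dtype=float)
    taxa = [("Fam", f"g{i}") for i in range(mat.shape[0])]
    if samples is None:
        samples = [f"S{j}" for j in range(mat.shape[1])]
    return pd.DataFrame(mat, index=taxon_index(taxa), columns=samples)


class TestStandardize:
    def test_simple_triplet(self):
        std = standardize(_std_frame([[1, 2, 3]]))
        np.testing.assert_allclose(std.q_values.to_numpy()[0], [-1, 0, 1])

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 10))
        a = standardize(_std_frame(x))
        b = standardize(_std_frame(3.7 * x + 11.0))
        np.testing.assert_allclose(
            a.q_values.to_numpy(), b.q_values.to_numpy(), atol=1e-12
        )

    def test_random_table_moments(self):
        rng = np.random.default_rng(1)
        std = standardize(_std_frame(rng.normal(size=(133, 56))))
        q = std.q_values.to_numpy()
        np.testing.assert_allclose(q.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(q.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        std = standardize(_std_frame(rng.normal(size=(5, 9))))
        again = standardize(std.q_values)
        np.testing.assert_allclose(
            std.q_values.to_numpy(), again.q_values.to_numpy(), atol=1e-9
        )

    def test_zero_sd_taxon_lists_offender(self):
        with pytest.raises(TwinfluxError, match="g1"):
            standardize(_std_frame([[1, 2, 3], [4, 4, 4]]))


PAIRS = PairMap((("P1", "S0", "S1"), ("P2", "S2", "S3")))


class TestITD:
    def test_simple_difference(self):
        from twinflux.tables import StandardizedTable

        q = _std_frame([[0.5, -0.5, 1.0, -1.0]])
        itd = compute_itd(StandardizedTable(q_values=q), PAIRS)
        np.testing.assert_allclose(itd.itd.to_numpy()[:, 0], [1.0, 2.0])
        assert (itd.ordering.to_numpy()[:, 0] == [1, 1]).all()

    def test_matrix_equals_absolute_q_difference(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(7, 4))
        std = standardize(_std_frame(mat))
        itd = compute_itd(std, PAIRS)
        q = std.q_values.to_numpy()
        expected = np.abs(q[:, [0, 2]] - q[:, [1, 3]]).T
        np.testing.assert_allclose(itd.itd.to_numpy(), expected, atol=1e-12)

    def test_tie_gives_zero_and_tie_code(self):
        q = _std_frame([[0.3, 0.3, -0.3, -0.3]])
        from twinflux.tables import StandardizedTable

        itd = compute_itd(StandardizedTable(q_values=q), PAIRS)
        assert (itd.itd.to_numpy() == 0).all()
        assert (itd.ordering.to_numpy() == 0).all()

    def test_member_relabeling_preserves_itd_flips_ordering(self):
        rng = np.random.default_rng(4)
        std = standardize(_std_frame(rng.normal(size=(5, 4))))
        swapped = PairMap((("P1", "S1", "S0"), ("P2", "S2", "S3")))
        a = compute_itd(std, PAIRS)
        b = compute_itd(std, swapped)
        np.testing.assert_allclose(a.itd.to_numpy(), b.itd.to_numpy(), atol=1e-12)
        assert (a.ordering.to_numpy()[0] == -b.ordering.to_numpy()[0]).all()

    def test_incomplete_pair_partition_rejected(self):
        std = standardize(_std_frame(np.random.default_rng(5).normal(size=(2, 4))))
        bad = PairMap((("P1", "S0", "S1"), ("P2", "S2", "S9")))
        with pytest.raises(TwinfluxError, match="S9"):
            compute_itd(std, bad)


class TestMeans:
    def _itd(self, mat):
        from twinflux.tables import ITDMatrix

        mat = np.asarray(mat, dtype=float)
        idx = pd.Index([f"P{i}" for i in range(mat.shape[0])], name="pair_id")
        cols = taxon_index([("Fam", f"g{j}") for j in range(mat.shape[1])])
        return ITDMatrix(
            itd=pd.DataFrame(mat, index=idx, columns=cols),
            ordering=pd.DataFrame(
                np.where(mat > 0, 1, 0).astype(np.int8), index=idx, columns=cols
            ),
            pair_map=PairMap(tuple((f"P{i}", f"S{i}A", f"S{i}B") for i in range(mat.shape[0]))),
        )

    def test_single_pair_mean_is_row(self):
        itd = self._itd([[1.0, 2.0, 0.5]])
        np.testing.assert_allclose(mean_itdx(itd).to_numpy(), [1.0, 2.0, 0.5])

    def test_all_zero(self):
        itd = self._itd(np.zeros((3, 2)))
        assert (mean_itdx(itd) == 0).all()
        assert grand_md(itd) == 0.0

    def test_grand_mean_2x2(self):
        assert grand_md(self._itd([[1, 3], [2, 2]])) == 2.0

    def test_grand_mean_equals_mean_of_taxon_means(self):
        rng = np.random.default_rng(6)
        itd = self._itd(np.abs(rng.normal(size=(28, 13))))
        assert grand_md(itd) == pytest.approx(mean_itdx(itd).mean(), abs=1e-12)


class TestWelch:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = welch_test(x, x)
        assert t == 0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        t, df, p = welch_test(np.array([1, 2, 3]), np.array([4, 5, 6, 7]))
        assert t == pytest.approx(-4.0415, abs=1e-4)
        assert df == pytest.approx(4.96, abs=0.01)

    def test_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=8), rng.normal(1, 2, size=5)
        t1, df1, p1 = welch_test(x, y)
        t2, df2, p2 = welch_test(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2) and df1 == pytest.approx(df2)

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 30))
            y = rng.normal(rng.normal(), rng.uniform(0.5, 3), size=rng.integers(3, 30))
            t, df, p = welch_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert df == pytest.approx(ref.df, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_variance_both_is_error(self):
        with pytest.raises(TwinfluxError, match="zero variance"):
            welch_test(np.array([1.0, 1.0]), np.array([2.0, 2.0]))


class TestClassify:
    @pytest.mark.parametrize(
        "mean,md,p,expected",
        [
            (1.338, 0.668, 0.000, "environment_susceptible"),
            (0.380, 0.668, 0.015, "genetic_susceptible"),
            (0.700, 0.668, 0.500, "indeterminate"),
        ],
    )
    def test_decision_rule(self, mean, md, p, expected):
        assert classify_genus(mean, md, p) == expected

    def test_p_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_genus(1.0, 0.5, 1.5)


class TestExtract:
    def _itd_from_latent(self, r, n_pairs, n_taxa, seed):
        rng = np.random.default_rng(seed)
        r = np.broadcast_to(np.asarray(r, float), (n_taxa,))
        G = rng.standard_normal((n_taxa, n_pairs)) * np.sqrt(r)[:, None]
        E = rng.standard_normal((n_taxa, n_pairs, 2)) * np.sqrt(1 - r)[:, None, None]
        L = (G[:, :, None] + E).reshape(n_taxa, -1)
        samples = [f"P{i}{m}" for i in range(n_pairs) for m in "AB"]
        std = standardize(_std_frame(L, samples=samples))
        pairs = PairMap(tuple((f"P{i}", f"P{i}A", f"P{i}B") for i in range(n_pairs)))
        return compute_itd(std, pairs)

    def test_planted_low_r_taxa_flagged_environmental(self):
        r = np.full(60, 0.8)
        r[:6] = 0.05
        itd = self._itd_from_latent(r, 28, 60, seed=11)
        susc = extract_susceptible(itd)
        env = set(susc.environment_susceptible)
        planted = set(itd.taxa[:6])
        assert len(env & planted) >= 5

    def test_planted_high_r_taxon_flagged_genetic(self):
        r = np.full(60, 0.5)
        r[0] = 0.99
        itd = self._itd_from_latent(r, 28, 60, seed=12)
        susc = extract_susceptible(itd)
        assert itd.taxa[0] in susc.genetic_susceptible

    def test_population_sd_rescaling_leaves_classification_unchanged(self):
        """Using the population (n) instead of sample (n-1) SD rescales every
        taxon's Q by the same constant, so t-statistics and classifications
        are identical."""
        itd = self._itd_from_latent(np.full(20, 0.5), 20, 20, seed=13)
        scaled = type(itd)(
            itd=itd.itd * np.sqrt(40 / 39), ordering=itd.ordering, pair_map=itd.pair_map
        )
        a = extract_susceptible(itd)
        b = extract_susceptible(scaled)
        np.testing.assert_allclose(a.table["t"], b.table["t"], atol=1e-9)
        assert (a.table["classification"] == b.table["classification"]).all()

    def test_exclude_focal_variant_differs(self):
        itd = self._itd_from_latent(np.full(10, 0.3), 15, 10, seed=14)
        inc = extract_susceptible(itd, exclude_focal=False)
        exc = extract_susceptible(itd, exclude_focal=True)
        assert not np.allclose(inc.table["t"], exc.table["t"])

    def test_all_tied_cohort_degenerates_gracefully(self):
        from twinflux.tables import ITDMatrix

        idx = pd.Index(["P1", "P2", "P3"], name="pair_id")
        cols = taxon_index([("F", "g0"), ("F", "g1")])
        itd = ITDMatrix(
            itd=pd.DataFrame(np.zeros((3, 2)), index=idx, columns=cols),
            ordering=pd.DataFrame(np.zeros((3, 2), dtype=np.int8), index=idx, columns=cols),
            pair_map=PairMap((("P1", "a1", "b1"), ("P2", "a2", "b2"), ("P3", "a3", "b3"))),
        )
        susc = extract_susceptible(itd)
        assert susc.md == 0.0
        assert len(susc.environment_susceptible) == 0
        assert (susc.table["classification"] == "indeterminate").all()
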