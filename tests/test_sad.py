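import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stygodiv import (
    CommunityVector,
    RankAbundance,
    expected_broken_stick,
    expected_geometric,
    expected_zipf,
    fit_broken_stick,
    fit_geometric,
    fit_lognormal,
    fit_zipf,
    generate_community,
    rank_abundances,
    select_model,
)
from stygodiv.sad import normal_order_scores, poisson_loglik


def ra_from_counts(*counts, ids=None):
    ids = ids or [chr(ord("a") + i) for i in range(len(counts))]
    return rank_abundances(
        CommunityVector(np.array(ids, dtype=object), np.array(counts))
    )


class TestRankAbundance:
    def test_descending_sort(self):
        ra = ra_from_counts(5, 9, 1)
        assert list(ra.abundances) == [9, 5, 1]
        assert list(ra.ranks) == [1, 2, 3]

    def test_tie_broken_by_species_id(self):
        ra = ra_from_counts(4, 4, ids=["b", "a"])
        assert list(ra.species_ids) == ["a", "b"]

    def test_normal_scores_are_midpoint_quantiles(self):
        phi = normal_order_scores(4)
        expected = stats.norm.ppf([0.875, 0.625, 0.375, 0.125])
        np.testing.assert_allclose(phi, expected)
        assert np.all(np.diff(phi) < 0)  # rank 1 gets the largest deviate


class TestExpectedAbundances:
    def test_geometric_direct_values(self):
        np.testing.assert_allclose(
            expected_geometric(100, 3, 0.5), [50.0, 25.0, 12.5]
        )

    @given(
        j=st.integers(min_value=10, max_value=10000),
        s=st.integers(min_value=1, max_value=40),
        alpha=st.floats(min_value=0.01, max_value=0.95),
    )
    @settings(max_examples=50, deadline=None)
    def test_geometric_sum_identity(self, j, s, alpha):
        total = expected_geometric(j, s, alpha).sum()
        assert total == pytest.approx(j * (1 - (1 - alpha) ** s))

    def test_geometric_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            expected_geometric(10, 3, 1.2)

    def test_broken_stick_direct_values(self):
        np.testing.assert_allclose(
            expected_broken_stick(6, 3), [11 / 3, 5 / 3, 2 / 3], atol=1e-12
        )
        np.testing.assert_allclose(expected_broken_stick(10, 2), [7.5, 2.5])

    @given(
        j=st.integers(min_value=1, max_value=100000),
        s=st.integers(min_value=1, max_value=60),
    )
    @settings(max_examples=50, deadline=None)
    def test_broken_stick_sums_to_j_exactly(self, j, s):
        assert expected_broken_stick(j, s).sum() == pytest.approx(j, rel=1e-12)

    def test_zipf_rank_one_identity(self):
        assert expected_zipf(200, 0.4, -1.2, r=1) == pytest.approx(200 * 0.4)


def grid_search_alpha(ra, grid=None):
    grid = grid if grid is not None else np.linspace(0.001, 0.999, 9981)
    lls = [
        poisson_loglik(ra.abundances, expected_geometric(ra.J, ra.S, a))
        for a in grid
    ]
    return float(grid[int(np.argmax(lls))])


class TestGeometricFit:
    @pytest.mark.parametrize(
        "counts",
        [(7, 3), (12, 5, 2), (30, 14, 8, 3, 1), (40, 22, 11, 6, 3, 2)],
    )
    def test_matches_grid_search_oracle(self, counts):
        ra = ra_from_counts(*counts)
        fit = fit_geometric(ra)
        assert fit.params["alpha"] == pytest.approx(
            grid_search_alpha(ra), abs=1e-3
        )

    def test_noiseless_self_consistency(self):
        exp = np.round(expected_geometric(1000, 12, 0.3)).astype(int)
        ra = ra_from_counts(*exp)
        assert fit_geometric(ra).params["alpha"] == pytest.approx(0.3, abs=0.02)

    def test_requires_two_species(self):
        with pytest.raises(ValueError):
            fit_geometric(ra_from_counts(5))

    def test_aic_beats_alpha_fixed_version(self):
        # maximising over alpha can never have lower logL than fixing it
        ra = ra_from_counts(33, 18, 9, 4, 2)
        fit = fit_geometric(ra)
        for alpha in (0.2, 0.4, 0.6):
            fixed_ll = poisson_loglik(
                ra.abundances, expected_geometric(ra.J, ra.S, alpha)
            )
            assert fit.loglik >= fixed_ll - 1e-9


class TestBrokenStickFit:
    def test_aic_is_minus_two_loglik(self):
        ra = ra_from_counts(8, 5, 3, 1)
        fit = fit_broken_stick(ra)
        assert fit.k == 0
        assert fit.aic == pytest.approx(-2 * fit.loglik)
        assert fit.loglik == pytest.approx(
            poisson_loglik(ra.abundances, expected_broken_stick(ra.J, ra.S))
        )

    def test_single_species_undefined(self):
        with pytest.raises(ValueError):
            fit_broken_stick(ra_from_counts(9))

    def test_prefers_even_communities(self):
        even = np.round(expected_broken_stick(600, 10)).astype(int)
        steep = np.round(expected_geometric(600, 10, 0.6)).astype(int)
        steep[steep == 0] = 1
        aic_even = fit_broken_stick(ra_from_counts(*even)).aic
        aic_steep = fit_broken_stick(ra_from_counts(*steep)).aic
        assert aic_even < aic_steep


class TestGlmFits:
    def test_lognormal_noiseless_recovery(self):
        phi = normal_order_scores(15)
        counts = np.round(np.exp(3.0 + 1.2 * phi)).astype(int)
        fit = fit_lognormal(ra_from_counts(*counts))
        assert fit.params["mu"] == pytest.approx(3.0, abs=0.1)
        assert fit.params["sigma"] == pytest.approx(1.2, abs=0.1)
        assert fit.k == 2

    def test_lognormal_intercept_only_limit(self):
        fit = fit_lognormal(ra_from_counts(7, 7, 7, 7, 7))
        assert fit.params["sigma"] == pytest.approx(0.0, abs=1e-6)
        assert fit.params["mu"] == pytest.approx(np.log(7.0), abs=1e-6)

    def test_zipf_noiseless_recovery(self):
        r = np.arange(1, 13)
        counts = np.round(100.0 * r ** -1.3).astype(int)
        counts[counts == 0] = 1
        fit = fit_zipf(ra_from_counts(*counts))
        assert fit.params["gamma"] == pytest.approx(-1.3, abs=0.05)

    def test_zipf_rank_one_fitted_value(self):
        ra = ra_from_counts(50, 20, 11, 6, 4, 2)
        fit = fit_zipf(ra)
        assert fit.fitted[0] == pytest.approx(ra.J * fit.params["p1"])

    def test_zipf_steeper_for_more_dominated_input(self):
        shallow = np.round(expected_geometric(800, 12, 0.2)).astype(int)
        steep = np.round(expected_geometric(800, 12, 0.5)).astype(int)
        steep[steep == 0] = 1
        g_shallow = fit_zipf(ra_from_counts(*shallow)).params["gamma"]
        g_steep = fit_zipf(ra_from_counts(*steep)).params["gamma"]
        assert g_steep < g_shallow


class TestVeganAgreement:
    """Frozen reference values from R vegan 2.7 (vegdist/radfit) on a
    15-species fixture: an independent implementation of the same fits."""

    COUNTS = (334, 120, 86, 62, 44, 32, 23, 16, 12, 8, 6, 4, 3, 2, 1)

    def test_all_models_match_reference(self):
        ra = ra_from_counts(*self.COUNTS)
        g = fit_geometric(ra)
        assert g.params["alpha"] == pytest.approx(0.3446283, abs=1e-6)
        assert g.aic == pytest.approx(122.3764, abs=1e-3)
        l = fit_lognormal(ra)
        assert l.params["mu"] == pytest.approx(2.827287, abs=1e-5)
        assert l.params["sigma"] == pytest.approx(1.623386, abs=1e-5)
        assert l.aic == pytest.approx(78.58141, abs=1e-3)
        z = fit_zipf(ra)
        assert z.params["p1"] == pytest.approx(0.4690077, abs=1e-6)
        assert z.params["gamma"] == pytest.approx(-1.482082, abs=1e-5)
        assert z.aic == pytest.approx(113.5444, abs=1e-3)
        assert fit_broken_stick(ra).aic == pytest.approx(312.1298, abs=1e-3)


class TestModelSelection:
    def test_sorted_by_aic_with_delta(self):
        ra = ra_from_counts(*TestVeganAgreement.COUNTS)
        sel = select_model(ra)
        aics = [f.aic for f in sel.fits]
        assert aics == sorted(aics)
        assert sel.delta_aic[0] == 0.0
        assert sel.verdict == "lognormal"

    def test_tie_verdict_straddles_the_threshold(self):
        ra = ra_from_counts(40, 21, 10, 5, 3, 1)
        base = select_model(ra)
        gap = base.delta_aic[1]
        assert gap > 0
        # the same fits read as a tie iff the threshold exceeds the gap
        assert select_model(ra, tie_threshold=gap * 1.01).verdict == "tie"
        assert (
            select_model(ra, tie_threshold=gap * 0.99).verdict
            == base.fits[0].model
        )

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            select_model(ra_from_counts(3, 2, 1), models=("geometric", "gamma"))

    def test_deterministic_pipeline(self):
        c = generate_community(18, 800, params={"alpha": 0.35}, seed=77)
        a1 = select_model(rank_abundances(c)).best.aic
        a2 = select_model(rank_abundances(c)).best.aic
        assert a1 == a2

    @pytest.mark.parametrize("model", ["geometric", "broken_stick", "zipf", "lognormal"])
    def test_fitted_curves_positive_and_decreasing(self, model):
        ra = ra_from_counts(55, 30, 17, 9, 5, 2, 1)
        sel = select_model(ra, models=(model,))
        fitted = sel.best.fitted
        assert np.all(fitted > 0)
        assert np.all(np.diff(fitted) <= 1e-9)
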