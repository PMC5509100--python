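import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from deltabind.diff_mixture import (
    DiffEMConfig,
    DiffMixtureModel,
    WindowConfig,
    WindowParams,
    fit_diff_mixture,
    fit_three_component,
    posterior_B,
    posterior_categories,
)
from deltabind.rank_transform import RankTable


def rank_table_from_diffs(d, mean_bound=None):
    """Build a minimal rank table with prescribed mean-rank differences."""
    n = len(d)
    mb = np.arange(1.0, n + 1) if mean_bound is None else np.asarray(mean_bound, float)
    ranks = pd.DataFrame(
        {
            "rank_K1": mb,
            "rank_K2": mb,
            "meanrank_K": mb,
            "rank_G1": mb - d,
            "meanrank_G": mb - d,
        }
    )
    ids = pd.Series([f"s{i:06d}" for i in range(n)])
    return RankTable(ids, ranks, "K", "G", n)


@pytest.fixture(scope="module")
def planted_d():
    rng = np.random.default_rng(3)
    n = 10_000
    comp = rng.choice(3, size=n, p=[0.9, 0.05, 0.05])
    d = np.where(
        comp == 0,
        rng.normal(0, 50, n),
        np.where(comp == 1, rng.normal(400, 80, n), rng.normal(-400, 80, n)),
    )
    return d, comp


class TestThreeComponentEM:
    def test_recovers_planted_mixture(self, planted_d):
        d, _ = planted_d
        pis, delta, s0, s1, trace = fit_three_component(d)
        assert pis[0] == pytest.approx(0.90, abs=0.02)
        assert pis[1] == pytest.approx(0.05, abs=0.02)
        assert pis[2] == pytest.approx(0.05, abs=0.02)
        assert delta == pytest.approx(400, abs=40)
        trace = np.asarray(trace)
        assert np.all(np.diff(trace) >= -1e-7 * np.abs(trace[:-1]))

    def test_mirroring_swaps_directional_weights_exactly(self, planted_d):
        d, _ = planted_d
        pis, delta, s0, s1, _ = fit_three_component(d)
        pis_m, delta_m, s0_m, s1_m, _ = fit_three_component(-d)
        assert pis_m == (pis[0], pis[2], pis[1])
        assert (delta_m, s0_m, s1_m) == (delta, s0, s1)

    def test_all_zero_differences_collapse_to_null_category(self):
        pis, delta, s0, s1, _ = fit_three_component(np.zeros(500))
        em = DiffEMConfig()
        assert pis[0] == pytest.approx(1.0, abs=1e-4)
        assert s0 == em.sigma_floor  # degenerate-spread guard

    def test_case_weights_deweight_contaminating_sites(self):
        # a contaminating far-shifted block with zero case weight must not
        # pull the shifted component out to it, while at full weight it does
        rng = np.random.default_rng(8)
        d = np.concatenate([rng.normal(0, 10, 2000), rng.normal(500, 10, 500)])
        w = np.concatenate([np.ones(2000), np.zeros(500)])
        _, delta_deweighted, *_ = fit_three_component(d, w)
        _, delta_full, *_ = fit_three_component(d)
        assert delta_deweighted < 50 < delta_full


class TestFitDiffMixture:
    def test_single_window_matches_flat_fit(self, planted_d):
        d, _ = planted_d
        rt = rank_table_from_diffs(d)
        model = fit_diff_mixture(
            rt,
            np.ones(len(d)),
            window=WindowConfig(n_windows=1, window_frac=1.0),
        )
        assert len(model.windows) == 1
        pis_flat, delta_flat, *_ = fit_three_component(d)
        w = model.windows[0]
        assert w.weights == pytest.approx(pis_flat, abs=1e-9)
        assert w.delta == pytest.approx(delta_flat, abs=1e-6)

    def test_low_weight_windows_borrow_from_neighbours(self, planted_d):
        d, _ = planted_d
        rt = rank_table_from_diffs(d)
        # only the top half of sites carry weight; bottom windows must borrow
        weights = (np.arange(len(d)) > len(d) / 2).astype(float)
        with pytest.warns(UserWarning, match="borrowed"):
            model = fit_diff_mixture(rt, weights)
        assert any(w.borrowed for w in model.windows)
        assert any(not w.borrowed for w in model.windows)

    def test_adjacent_window_shifts_vary_smoothly(self, small_result):
        model = small_result.diff_model
        deltas = np.array(
            [w.delta for w in model.windows if not w.borrowed and w.weights[1] > 0.01]
        )
        rel = np.abs(np.diff(deltas)) / deltas[:-1]
        assert np.all(rel < 0.25)

    def test_posterior_length_mismatch_rejected(self, planted_d):
        d, _ = planted_d
        rt = rank_table_from_diffs(d)
        with pytest.raises(ValueError, match="length"):
            fit_diff_mixture(rt, np.ones(10))


class TestPosterior:
    def _model(self, weights=(0.9, 0.05, 0.05), delta=100.0, s0=50.0, s1=50.0):
        return DiffMixtureModel(
            windows=[WindowParams(500.0, weights, delta, s0, s1, 1000.0)]
        )

    def test_large_positive_shift_is_near_certain(self):
        model = self._model()
        rt = rank_table_from_diffs(np.array([400.0, 0.0]), mean_bound=[500.0, 500.0])
        pb = posterior_B(model, rt)
        assert pb[0] > 0.95
        # independent density-ratio oracle
        w, dl, s0, s1 = (0.9, 0.05, 0.05), 100.0, 50.0, 50.0
        f = (
            w[0] * norm.pdf(400, 0, s0),
            w[1] * norm.pdf(400, dl, s1),
            w[2] * norm.pdf(400, -dl, s1),
        )
        assert pb[0] == pytest.approx(f[1] / sum(f), abs=1e-12)

    def test_zero_difference_is_direction_symmetric(self):
        model = self._model()
        rt = rank_table_from_diffs(np.array([0.0]), mean_bound=[500.0])
        post = posterior_categories(model, rt)[0]
        assert post[1] == pytest.approx(post[2], abs=1e-12)

    def test_zero_weight_category_never_called(self):
        model = self._model(weights=(0.95, 0.0, 0.05))
        rt = rank_table_from_diffs(np.array([300.0, -300.0, 0.0]))
        np.testing.assert_array_equal(posterior_B(model, rt), 0.0)

    def test_category_posteriors_sum_to_one(self, small_result):
        post = posterior_categories(
            small_result.diff_model, small_result.rank_table
        )
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_monotone_in_difference_within_window(self):
        model = self._model()
        grid = np.linspace(-400, 400, 81)
        rt = rank_table_from_diffs(grid, mean_bound=np.full(81, 500.0))
        pb = posterior_B(model, rt)
        assert np.all(np.diff(pb) >= -1e-12)

    def test_blending_interpolates_between_window_centers(self):
        lo = WindowParams(100.0, (0.8, 0.2, 0.0), 50.0, 20.0, 20.0, 500.0)
        hi = WindowParams(300.0, (0.6, 0.4, 0.0), 50.0, 20.0, 20.0, 500.0)
        model = DiffMixtureModel(windows=[lo, hi])
        d = np.array([60.0, 60.0, 60.0])
        rt = rank_table_from_diffs(d, mean_bound=[100.0, 200.0, 300.0])
        pb = posterior_B(model, rt)
        assert pb[0] < pb[1] < pb[2]
        assert pb[1] == pytest.approx(0.5 * (pb[0] + pb[2]), abs=1e-12)


def test_single_unbound_replicate_runs_end_to_end():
    from deltabind.caller import fit_and_call
    from deltabind.synthetic import SimConfig, simulate_scores

    cfg = SimConfig(n_sites=5000, seed=3, n_replicates_unbound=1)
    table, labels, _ = simulate_scores(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = fit_and_call(table)
    scores = result.calls.scores
    assert np.isfinite(scores).all()
    assert ((scores >= 0) & (scores <= 1)).all()
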