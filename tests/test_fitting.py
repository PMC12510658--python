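"""Cost function, AICc, Latin hypercube sampling, local fits, ranking."""

import numpy as np
import pandas as pd
import pytest

import ppiflux as px
from ppiflux.fitting import (
    FitEnsemble,
    FitResult,
    PriorBounds,
    _species_scales,
    aicc,
    fit_once,
    lhs_sample,
    multistart_fit,
    normalised_sse,
    rank_models,
    sse,
    uncertainty_ranges,
)
from ppiflux.models import build_model
from ppiflux.simulate import DEFAULT_SETTINGS
from ppiflux.synthetic import NoiseModel, simulate_dataset

A0 = build_model("A0")

#: a well-behaved generating parameter set used across fitting tests
TRUTH = {n: v for n, v in zip(A0.free_parameter_names, [
    0.03, 0.8, 0.5, 0.09, 0.4, 1e-3, 5e-4, 2e-3, 1e-3, 0.05,
    1e-3, 5e-3, 1e-3, 2e-3, 0.2,
])}


@pytest.fixture(scope="module")
def clean_dataset():
    return simulate_dataset(A0, TRUTH, noise=NoiseModel(cv=0.0))


class TestLhsSample:
    def test_single_point_inside_box(self):
        b = PriorBounds.default(A0)
        pts = lhs_sample(b, 1, seed=0)
        assert pts.shape == (1, 15)
        assert np.all(pts >= -4) and np.all(pts <= 2)

    def test_one_point_per_marginal_bin(self):
        b = PriorBounds.default(A0)
        pts = lhs_sample(b, 10, seed=1)
        edges = np.linspace(-4, 2, 11)
        for d in range(pts.shape[1]):
            counts, _ = np.histogram(pts[:, d], bins=edges)
            assert np.all(counts == 1), f"dimension {d} not stratified"

    def test_seed_reproducibility(self):
        b = PriorBounds.default(A0)
        np.testing.assert_array_equal(lhs_sample(b, 25, 7), lhs_sample(b, 25, 7))
        assert not np.array_equal(lhs_sample(b, 25, 7), lhs_sample(b, 25, 8))

    def test_invalid_inputs(self):
        b = PriorBounds.default(A0)
        with pytest.raises(ValueError):
            lhs_sample(b, 0, seed=0)
        with pytest.raises(ValueError, match="strictly below"):
            PriorBounds(("r1",), np.array([2.0]), np.array([-4.0]))
        with pytest.raises(ValueError, match="fixed parameter"):
            PriorBounds(("theta1",), np.array([-4.0]), np.array([2.0]))


class TestAicc:
    def test_unit_variance_no_parameters(self):
        assert aicc(42.0, 42, 0) == pytest.approx(0.0)

    def test_fifteen_parameter_penalty(self):
        # n ln(1) + 2*15 + 2*15*16/26
        assert aicc(42.0, 42, 15) == pytest.approx(30 + 480 / 26)

    def test_low_sse_regime(self):
        assert aicc(0.054 * 42, 42, 15) == pytest.approx(-74.1, abs=0.05)

    def test_correction_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(1.0, 16, 15)
        with pytest.raises(ValueError):
            aicc(0.0, 42, 15)

    def test_matches_independent_transcription(self, rng):
        """Oracle: 1000 random inputs against a literal reimplementation."""
        for _ in range(1000):
            s = float(rng.uniform(1e-6, 1e3))
            n = int(rng.integers(20, 200))
            K = int(rng.integers(0, min(15, n - 2) + 1))
            expected = n * np.log(s / n) + 2 * K + (2 * K * (K + 1)) / (n - K - 1)
            assert abs(aicc(s, n, K) - expected) <= 1e-12 * max(1.0, abs(expected))

    def test_penalty_strictly_increases_with_K(self):
        vals = [aicc(10.0, 42, K) for K in range(0, 20)]
        assert np.all(np.diff(vals) > 0)


class TestSse:
    def test_perfect_prediction_scores_zero(self, clean_dataset):
        val = sse(A0, A0.full_parameters(TRUTH), clean_dataset,
                  settings=DEFAULT_SETTINGS)
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_single_cell_discrepancy_hand_value(self):
        data = np.array([[4.0, 10.0], [2.0, 10.0]])
        pred = np.array([[1.0, 10.0], [2.0, 10.0]])
        scales = data.max(axis=0)
        assert normalised_sse(pred, data, scales) == pytest.approx((3 / 4) ** 2)

    def test_matches_brute_force_double_loop(self, rng):
        """Oracle: cell-by-cell accumulation over random 7x6 matrices."""
        for _ in range(200):
            data = rng.uniform(1.0, 1e6, size=(7, 6))
            pred = rng.uniform(0.0, 1e6, size=(7, 6))
            scales = data.max(axis=0)
            total = 0.0
            for i in range(7):
                for j in range(6):
                    total += ((pred[i, j] - data[i, j]) / scales[j]) ** 2
            got = normalised_sse(pred, data, scales)
            assert got == pytest.approx(total, rel=1e-12)

    def test_invariant_to_species_unit_rescaling(self, rng):
        data = rng.uniform(1.0, 1e5, size=(7, 6))
        pred = rng.uniform(0.0, 1e5, size=(7, 6))
        ref = normalised_sse(pred, data, data.max(axis=0))
        data2, pred2 = data.copy(), pred.copy()
        data2[:, 2] *= 1e3
        pred2[:, 2] *= 1e3
        assert normalised_sse(pred2, data2, data2.max(axis=0)) == pytest.approx(
            ref, rel=1e-12)

    def test_solver_failure_scores_inf(self, clean_dataset):
        params = {n: 1e12 for n in A0.free_parameter_names}  # out of any prior
        with pytest.raises(ValueError):
            # absurd rates are rejected before integration is attempted
            px.integrate(A0, {**params, "r1": -1.0})
        bad = {n: 100.0 for n in A0.free_parameter_names}
        val = sse(A0, bad, clean_dataset)
        assert np.isfinite(val) or val == np.inf  # never NaN


class TestFitOnce:
    def test_start_at_truth_stays_at_truth(self, clean_dataset):
        fit = fit_once(A0, TRUTH, clean_dataset)
        assert fit.sse <= sse(A0, A0.full_parameters(TRUTH), clean_dataset) + 1e-9
        assert fit.sse < 1e-6
        assert fit.converged

    def test_fixed_parameters_untouched(self, clean_dataset):
        fit = fit_once(A0, TRUTH, clean_dataset)
        assert fit.params["theta1"] == 0.04
        assert fit.params["r3"] == 0.0002
        assert "theta1" not in fit.free_names

    def test_result_consistency(self, clean_dataset):
        b = PriorBounds.default(A0)
        start = lhs_sample(b, 1, seed=3)[0]
        fit = fit_once(A0, start, clean_dataset, b, max_nfev=60)
        assert fit.K == 15 and fit.n == 42
        assert np.all(fit.free_log10 >= b.lo) and np.all(fit.free_log10 <= b.hi)
        if np.isfinite(fit.sse) and fit.sse > 0:
            assert fit.aicc == pytest.approx(aicc(fit.sse, 42, 15))

    def test_optimiser_never_increases_cost(self, clean_dataset):
        b = PriorBounds.default(A0)
        start = lhs_sample(b, 1, seed=5)[0]
        start_params = {n: 10.0 ** v for n, v in zip(b.parameter_names, start)}
        initial = sse(A0, start_params, clean_dataset)
        fit = fit_once(A0, start, clean_dataset, b, max_nfev=60)
        assert fit.sse <= initial + 1e-9


class TestMultistart:
    def test_single_start_reduces_to_fit_once(self, clean_dataset):
        b = PriorBounds.default(A0)
        ens = multistart_fit(A0, clean_dataset, b, n_starts=1, seed=2,
                             max_nfev=40)
        direct = fit_once(A0, lhs_sample(b, 1, 2)[0], clean_dataset, b,
                          max_nfev=40)
        assert ens.best.sse == pytest.approx(direct.sse)

    def test_best_sse_non_increasing_under_more_starts(self, clean_dataset):
        b = PriorBounds.default(A0)
        starts = lhs_sample(b, 4, seed=9)
        fits = [fit_once(A0, s, clean_dataset, b, max_nfev=30) for s in starts]
        best2 = min(f.sse for f in fits[:2])
        best4 = min(f.sse for f in fits)
        assert best4 <= best2


def _fake_ensemble(variant_id, sses, dataset, K=15):
    spec = build_model(variant_id)
    fits = []
    for i, s in enumerate(sses):
        fits.append(FitResult(
            variant_id=variant_id, params={}, free_log10=np.zeros(K),
            free_names=spec.free_parameter_names[:K], sse=s, n=42, K=K,
            aicc=aicc(s, 42, K), converged=True, start_index=i))
    return FitEnsemble(variant_id, fits, dataset, n_starts=len(sses))


class TestUncertaintyRanges:
    def test_identical_fits_give_zero_width_bands(self, clean_dataset):
        ens = _fake_ensemble("A0", [1.0] * 20, clean_dataset)
        ranges = uncertainty_ranges(ens, top_k=10)
        assert (ranges["q95"] - ranges["q05"]).max() == 0.0
        assert (ranges["median"] == 0.0).all()

    def test_bands_nested(self, clean_dataset, rng):
        spec = build_model("A0")
        fits = []
        for i in range(50):
            x = rng.uniform(-4, 2, size=15)
            fits.append(FitResult("A0", {}, x, spec.free_parameter_names,
                                  float(i + 1), 42, 15, aicc(float(i + 1), 42, 15),
                                  True, i))
        ranges = uncertainty_ranges(FitEnsemble("A0", fits, clean_dataset, 50),
                                    top_k=50)
        assert (ranges["q45"] >= ranges["q25"]).all()
        assert (ranges["q55"] <= ranges["q75"]).all()
        assert (ranges["q25"] >= ranges["q05"]).all()
        assert (ranges["q75"] <= ranges["q95"]).all()

    def test_prior_wide_band_flagged_non_identifiable(self, clean_dataset, rng):
        spec = build_model("A0")
        fits = []
        for i in range(100):
            x = np.full(15, 0.0)
            x[0] = -4.0 + 6.0 * (i / 99)  # r1 spread across the whole prior
            fits.append(FitResult("A0", {}, x, spec.free_parameter_names, 1.0,
                                  42, 15, aicc(1.0, 42, 15), True, i))
        ranges = uncertainty_ranges(FitEnsemble("A0", fits, clean_dataset, 100))
        assert bool(ranges.loc["r1", "non_identifiable"])
        assert not bool(ranges.loc["r2", "non_identifiable"])

    def test_empty_ensemble_rejected(self, clean_dataset):
        with pytest.raises(ValueError, match="empty"):
            uncertainty_ranges(FitEnsemble("A0", [], clean_dataset, 0))


class TestRankModels:
    def test_equal_sse_smaller_K_ranks_first(self, clean_dataset):
        e15 = _fake_ensemble("A0", [2.0, 3.0], clean_dataset, K=15)
        e16 = _fake_ensemble("A09", [2.0, 3.0], clean_dataset, K=16)
        comp = rank_models([e16, e15])
        assert comp.ranking == ["A0", "A09"]

    def test_order_invariance(self, clean_dataset):
        a = _fake_ensemble("A0", [2.0], clean_dataset, 15)
        b = _fake_ensemble("A09", [1.0], clean_dataset, 16)
        c = _fake_ensemble("A10", [3.0], clean_dataset, 16)
        r1 = rank_models([a, b, c]).ranking
        r2 = rank_models([c, a, b]).ranking
        assert r1 == r2

    def test_mismatched_datasets_rejected(self, clean_dataset):
        other = simulate_dataset(A0, TRUTH, noise=NoiseModel(cv=0.3, seed=5))
        e1 = _fake_ensemble("A0", [1.0], clean_dataset)
        e2 = _fake_ensemble("A09", [1.0], other, K=16)
        with pytest.raises(ValueError, match="different datasets"):
            rank_models([e1, e2])

    def test_requires_two_variants(self, clean_dataset):
        with pytest.raises(ValueError, match="at least two"):
            rank_models([_fake_ensemble("A0", [1.0], clean_dataset)])

    def test_table_columns(self, clean_dataset):
        comp = rank_models([
            _fake_ensemble("A0", [2.0, 4.0, 6.0], clean_dataset, 15),
            _fake_ensemble("A09", [2.5], clean_dataset, 16),
        ])
        t = comp.table
        assert list(t.columns) == ["min_sse_n", "median_sse_n", "min_aicc", "K",
                                   "rank"]
        assert t.loc["A0", "min_sse_n"] == pytest.approx(2.0 / 42)
        assert t.loc["A0", "median_sse_n"] == pytest.approx(4.0 / 42)
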