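"""Sigmoid melting model, Tm extraction, quality filtering and ΔTm."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from tppkit.melting import (
    InputError,
    MeltProfile,
    NormalizationError,
    StatisticsError,
    compute_tm,
    curve_quality_filter,
    delta_tm,
    fit_all_profiles,
    fit_melting_curve,
    normalize_to_reference,
    replicate_tm_correlation,
    sigmoid_model,
)
from tppkit.simulate import SimulationConfig, simulate_dataset

GRID = np.linspace(37.0, 67.0, 10)


def make_profile(a, b, plateau, noise=None, rng=None, **kw):
    y = sigmoid_model(GRID, a, b, plateau)
    if noise:
        y = y * (1 + rng.normal(0, noise, GRID.size))
    defaults = dict(protein_id="P0", condition="vehicle", replicate=1)
    defaults.update(kw)
    return MeltProfile(temperatures_c=GRID, rel_abundance=np.maximum(y, 0), **defaults)


class TestSigmoidModel:
    def test_closed_form_values(self):
        # midpoint of the plain logistic
        assert sigmoid_model(55.0, 550.0, 10.0, 0.0) == pytest.approx(0.5)
        # exp(b - a/T) = 1 at T = 55 => (1 - 0.2)/2 + 0.2
        assert sigmoid_model(55.0, 550.0, 10.0, 0.2) == pytest.approx(0.6)

    def test_high_temperature_limit_is_plateau(self):
        assert sigmoid_model(1e6, 550.0, 10.0, 0.15) == pytest.approx(0.15, abs=1e-4)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(InputError):
            sigmoid_model(-1.0, 550.0, 10.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(100.0, 1500.0),
        b=st.floats(2.0, 25.0),
        plateau=st.floats(0.0, 0.45),
    )
    def test_strictly_decreasing_in_temperature(self, a, b, plateau):
        t = np.linspace(30.0, 90.0, 60)
        y = sigmoid_model(t, a, b, plateau)
        assert np.all(np.diff(y) <= 0)
        # strictly decreasing wherever the curve is away from float saturation
        interior = (y[:-1] < 1.0 - 1e-9) & (y[1:] > plateau + 1e-9)
        assert np.all(np.diff(y)[interior] < 0)


class TestNormalize:
    def test_divides_by_reference(self):
        p = MeltProfile("P", "vehicle", 1, np.array([37.0, 50.0]), np.array([2.0, 1.0]))
        out = normalize_to_reference(p)
        np.testing.assert_allclose(out.rel_abundance, [1.0, 0.5])

    def test_idempotent(self):
        p = make_profile(550, 10, 0.1)
        once = normalize_to_reference(p)
        twice = normalize_to_reference(once)
        np.testing.assert_allclose(once.rel_abundance, twice.rel_abundance)
        assert once.rel_abundance[0] == 1.0

    def test_zero_reference_abundance_is_error(self):
        p = MeltProfile("P", "vehicle", 1, np.array([37.0, 50.0]), np.array([0.0, 0.5]))
        with pytest.raises(NormalizationError):
            normalize_to_reference(p)

    def test_missing_reference_temperature_is_error(self):
        p = make_profile(550, 10, 0.0)
        with pytest.raises(NormalizationError):
            normalize_to_reference(p, reference_temp_c=25.0)


class TestComputeTm:
    def test_closed_form(self):
        assert compute_tm(550.0, 10.0, 0.0) == pytest.approx(55.0)
        assert compute_tm(550.0, 10.0, 0.2) == pytest.approx(550.0 / (10.0 - math.log(5.0 / 3.0)))

    def test_high_plateau_undefined(self):
        assert compute_tm(550.0, 10.0, 0.6) is None

    def test_outside_window_undefined(self):
        assert compute_tm(550.0, 10.0, 0.0, window=(37.0 - 5, 50.0)) is None

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.floats(200.0, 1200.0),
        b=st.floats(4.0, 20.0),
        plateau=st.floats(0.0, 0.45),
    )
    def test_agrees_with_bisection_oracle(self, a, b, plateau):
        tm = compute_tm(a, b, plateau)
        if tm is None or not (1.0 < tm < 1e4):
            return
        f = lambda t: sigmoid_model(t, a, b, plateau) - 0.5
        root = brentq(f, 1e-3, 1e5, xtol=1e-9)
        assert tm == pytest.approx(root, abs=1e-6)


class TestFit:
    def test_noiseless_self_consistency(self):
        fit = fit_melting_curve(make_profile(550.0, 10.0, 0.0))
        assert fit.valid
        assert fit.a == pytest.approx(550.0, rel=1e-4)
        assert fit.b == pytest.approx(10.0, rel=1e-4)
        assert abs(fit.plateau) < 1e-4
        assert fit.rss < 1e-10
        assert fit.tm_c == pytest.approx(55.0, abs=1e-3)

    def test_constant_profile_invalid(self):
        p = MeltProfile("P", "vehicle", 1, GRID, np.ones_like(GRID))
        fit = fit_melting_curve(p)
        assert not fit.valid

    def test_too_few_points_is_error(self):
        p = MeltProfile("P", "vehicle", 1, GRID[:4], sigmoid_model(GRID[:4], 550, 10, 0.0))
        with pytest.raises(InputError):
            fit_melting_curve(p)

    def test_noiseless_recovery_over_random_draws(self, small_noiseless):
        melt, truth = small_noiseless
        fits = fit_all_profiles(melt).merge(truth, on="protein_id", suffixes=("", "_true"))
        veh = fits[fits["condition"] == "vehicle"]
        assert np.all(np.abs(veh["a"] - veh["a_vehicle"]) / veh["a_vehicle"] < 1e-4)
        assert np.all(np.abs(veh["b"] - veh["b_true"]) / veh["b_true"] < 1e-4)
        assert np.all(np.abs(veh["plateau"] - veh["plateau_true"]) < 1e-4 * (1 + veh["plateau_true"]))
        assert np.all(np.abs(veh["tm_c"] - veh["tm_vehicle"]) < 1e-3)

    def test_noisy_tm_accuracy_within_one_degree(self):
        cfg = SimulationConfig(
            n_proteins=200, noise_sd=0.05, shift_fraction=0.0, n_replicates=1, seed=21
        )
        melt, truth = simulate_dataset(cfg)
        fits = fit_all_profiles(melt).merge(truth, on="protein_id", suffixes=("", "_true"))
        veh = fits[(fits["condition"] == "vehicle") & fits["tm_c"].notna()]
        assert len(veh) > 180
        median_err = np.median(np.abs(veh["tm_c"] - veh["tm_vehicle"]))
        assert median_err < 1.0


class TestQualityFilter:
    @pytest.mark.parametrize(
        "r2,plateau,tm,expected",
        [
            (0.99, 0.05, 55.0, True),
            (0.5, 0.05, 55.0, False),
            (0.99, 0.45, 55.0, False),
            (0.99, 0.05, None, False),
        ],
    )
    def test_thresholds(self, r2, plateau, tm, expected):
        from tppkit.melting import MeltFit

        fit = MeltFit(a=550, b=10, plateau=plateau, r_squared=r2, tm_c=tm, valid=True)
        assert curve_quality_filter(fit) is expected


class TestDeltaTm:
    def test_simple_differences(self):
        import pandas as pd

        fits = pd.DataFrame(
            {
                "protein_id": ["P1", "P1", "P2", "P2"],
                "replicate": [1, 1, 1, 1],
                "condition": ["vehicle", "treatment"] * 2,
                "tm_c": [55.0, 55.0, 55.0, 58.0],
            }
        )
        out = delta_tm(fits).set_index("protein_id")["delta_tm_c"]
        assert out["P1"] == pytest.approx(0.0)
        assert out["P2"] == pytest.approx(3.0)

    def test_undefined_tm_rows_omitted(self):
        import pandas as pd

        fits = pd.DataFrame(
            {
                "protein_id": ["P1", "P1"],
                "replicate": [1, 1],
                "condition": ["vehicle", "treatment"],
                "tm_c": [math.nan, 58.0],
            }
        )
        assert len(delta_tm(fits)) == 0

    def test_recovers_injected_shift(self):
        cfg = SimulationConfig(
            n_proteins=80, noise_sd=0.03, shift_fraction=1.0,
            delta_tm_mean=3.0, delta_tm_sd=0.0, seed=13,
        )
        melt, _ = simulate_dataset(cfg)
        fits = fit_all_profiles(melt)
        shifts = delta_tm(fits)
        assert len(shifts) > 100
        assert shifts["delta_tm_c"].mean() == pytest.approx(3.0, abs=0.5)


class TestReplicateCorrelation:
    def _fit_frame(self, tm1, tm2):
        import pandas as pd

        n = len(tm1)
        return pd.DataFrame(
            {
                "protein_id": [f"P{i}" for i in range(n)] * 2,
                "condition": ["vehicle"] * (2 * n),
                "replicate": [1] * n + [2] * n,
                "tm_c": list(tm1) + list(tm2),
            }
        )

    def test_identical_replicates_give_r_one(self):
        tm = [50.0, 55.0, 60.0, 65.0]
        corr = replicate_tm_correlation(self._fit_frame(tm, tm))
        assert corr["vehicle"] == pytest.approx(1.0)

    def test_anticorrelated_replicates_give_r_minus_one(self):
        tm = np.array([50.0, 55.0, 60.0, 65.0])
        mirrored = tm.mean() - (tm - tm.mean())
        corr = replicate_tm_correlation(self._fit_frame(tm, mirrored))
        assert corr["vehicle"] == pytest.approx(-1.0)

    def test_insufficient_pairs_is_error(self):
        with pytest.raises(StatisticsError):
            replicate_tm_correlation(self._fit_frame([50.0, 55.0], [50.0, 55.0]))
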