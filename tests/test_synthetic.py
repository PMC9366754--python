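"""The synthetic-data generator: landscapes, coefficients, telemetry, demography."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from elkrsf.raster import floored_log
from elkrsf.synthetic import (
    MIX_LION,
    draw_individual_coefficients,
    generate_landscapes,
    simulate_demography,
    simulate_study,
    simulate_telemetry,
    simulate_used_available,
)


def _r2(a, b):
    return np.corrcoef(a.ravel(), b.ravel())[0, 1] ** 2


class TestLandscapes:
    def test_zero_mix_gives_uncorrelated_fields(self):
        de, lion, _ = generate_landscapes(shape=(128, 128), mix_lion=0.0, seed=3)
        assert _r2(floored_log(lion).values, de.values) < 0.05

    def test_high_mix_approaches_full_correlation(self):
        de, lion, _ = generate_landscapes(shape=(128, 128), mix_lion=0.999, seed=3)
        assert _r2(floored_log(lion).values, de.values) > 0.95

    def test_default_calibration(self):
        """mix ~ 0.59 produces the lion-DE squared correlation of 0.35."""
        de, lion, wolf = generate_landscapes(seed=5)
        assert MIX_LION == pytest.approx(0.5916, abs=0.001)
        assert _r2(floored_log(lion).values, de.values) == pytest.approx(0.35, abs=0.05)
        assert _r2(floored_log(wolf).values, de.values) == pytest.approx(0.15, abs=0.05)

    def test_de_range_and_predator_positivity(self):
        de, lion, wolf = generate_landscapes(shape=(64, 64), seed=9)
        assert de.values.min() == pytest.approx(0.5)
        assert de.values.max() == pytest.approx(3.0)
        assert (lion.values > 0).all() and (wolf.values > 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_landscapes(shape=(0, 10))
        with pytest.raises(ValueError):
            generate_landscapes(mix_lion=1.5)


class TestCoefficients:
    def test_zero_sd_collapses_to_population(self):
        beta = {"de": 0.2, "ml": -0.1}
        g = draw_individual_coefficients(beta, {t: 0.0 for t in beta}, 5, seed=1)
        assert (g["de"] == 0.2).all()
        assert (g["ml"] == -0.1).all()

    def test_sample_mean_matches_population_clt(self):
        g = draw_individual_coefficients({"de": 0.2}, {"de": 0.15}, 10_000, seed=2)
        se = 0.15 / np.sqrt(10_000)
        assert abs(g["de"].mean() - 0.2) < 3 * se
        assert g["de"].std(ddof=1) == pytest.approx(0.15, rel=0.05)

    def test_seed_reproducibility(self):
        a = draw_individual_coefficients({"de": 0.1}, {"de": 0.2}, 20, seed=3)
        b = draw_individual_coefficients({"de": 0.1}, {"de": 0.2}, 20, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            draw_individual_coefficients({"de": 0.1}, {"de": -0.1}, 5)


class TestTelemetry:
    def test_exact_fix_count_and_schedule(self, small_study):
        counts = small_study.telemetry.groupby("animal_id").size()
        assert (counts == 400).all()
        ts = small_study.telemetry["timestamp"]
        assert ts.min() >= pd.Timestamp("2012-06-15")
        assert ts.max() <= pd.Timestamp("2012-09-15")

    def test_neutral_selection_is_uniform_in_disc(self, landscapes):
        de, lion, wolf = landscapes
        gamma = pd.DataFrame(
            {t: [0.0] for t in ("intercept", "de", "ml", "wf", "de:ml", "de:wf")},
            index=["e1"],
        )
        centers = {"e1": (16000.0, 16000.0)}
        telem, _ = simulate_telemetry(
            gamma, de, lion, wolf, centers, hr_radius=4000.0,
            n_per_individual=1096, fix_interval_hours=2.0, seed=6,
        )
        # chi-square uniformity over radial-equal-area rings x 4 quadrants
        dx = telem["x"] - 16000.0
        dy = telem["y"] - 16000.0
        r2 = (dx**2 + dy**2) / 4000.0**2
        ring = np.minimum((r2 * 4).astype(int), 3)
        quad = (dx > 0).astype(int) * 2 + (dy > 0).astype(int)
        counts = np.bincount(ring * 4 + quad, minlength=16)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_positive_de_selection_shifts_used_de(self, landscapes):
        de, lion, wolf = landscapes
        terms = ("intercept", "de", "ml", "wf", "de:ml", "de:wf")
        gsel = pd.DataFrame({t: [0.5 if t == "de" else 0.0] for t in terms}, index=["e1"])
        gnull = pd.DataFrame({t: [0.0] for t in terms}, index=["e2"])
        centers = {"e1": (16000.0, 16000.0), "e2": (16000.0, 16000.0)}
        telem, std = simulate_telemetry(
            pd.concat([gsel, gnull]), de, lion, wolf, centers, hr_radius=4000.0,
            n_per_individual=500, seed=7,
        )
        de_sel = de.value_at(telem.loc[telem.animal_id == "e1", "x"],
                             telem.loc[telem.animal_id == "e1", "y"]).mean()
        de_null = de.value_at(telem.loc[telem.animal_id == "e2", "x"],
                              telem.loc[telem.animal_id == "e2", "y"]).mean()
        assert de_sel > de_null

    def test_schedule_overflow_rejected(self, landscapes):
        de, lion, wolf = landscapes
        gamma = pd.DataFrame({t: [0.0] for t in ("intercept", "de", "ml", "wf",
                                                 "de:ml", "de:wf")}, index=["e1"])
        with pytest.raises(ValueError, match="slots"):
            simulate_telemetry(gamma, de, lion, wolf, {"e1": (16000.0, 16000.0)},
                               hr_radius=2000.0, n_per_individual=100000, seed=1)


class TestDemography:
    def test_noiseless_zero_effects_constant(self):
        demo = simulate_demography(np.zeros(20), alpha=7.5, beta_lact=0.0,
                                   noise_sd=0.0, seed=1)
        assert (demo["ifbf"] == 7.5).all()

    def test_lactation_group_difference(self):
        demo = simulate_demography(np.zeros(20000), beta_lact=-2.89, seed=2)
        gap = (demo.loc[demo.lact == 1, "ifbf"].mean()
               - demo.loc[demo.lact == 0, "ifbf"].mean())
        assert gap == pytest.approx(-2.89, abs=0.15)

    def test_pregnancy_rate_calibration(self):
        demo = simulate_demography(np.zeros(10000), seed=3)
        assert demo["preg"].mean() == pytest.approx(0.76, abs=0.03)

    def test_body_fat_median_calibration(self):
        demo = simulate_demography(np.zeros(10000), seed=4)
        assert np.median(demo["ifbf"]) == pytest.approx(7.5, abs=0.5)
        assert demo["ifbf"].between(0, 30).all()


def test_used_available_truth_is_selected(model_table):
    """Used rows show higher mean DE than available rows when gamma_de > 0."""
    table, gamma = model_table
    for ind in gamma.index[:5]:
        sub = table[table.individual_id == ind]
        diff = (sub.loc[sub.used == 1, "de"].mean()
                - sub.loc[sub.used == 0, "de"].mean())
        assert np.sign(diff) == np.sign(gamma.loc[ind, "de"]) or abs(diff) < 0.1
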