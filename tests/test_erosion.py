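"""Flume detachment rates, empirical erosion models and Monte-Carlo bands."""

import numpy as np
import pytest

from rhizocohere import erosion as er
from rhizocohere.errors import InsufficientDataError
from rhizocohere.synth import PROFILES, NoiseSpec, gen_erosion_runs


def make_run(masses, rld=0.0, genotype="bare", duration=5.0):
    intervals = tuple((10.0 * i, duration, m) for i, m in enumerate(masses))
    return er.ErosionRun(genotype=genotype, plant_count=0, intervals=intervals, rld=rld)


def runs_from_curve(a0, b, rlds, n_intervals=6):
    """Noise-free runs whose rates follow a0 * exp(b * rld) exactly."""
    out = []
    for rld in rlds:
        rate = a0 * np.exp(b * rld)
        out.append(make_run([rate * er.BOX_AREA * 5.0] * n_intervals, rld=rld))
    return out


class TestDetachmentRate:
    def test_single_interval(self):
        assert er.detachment_rate(make_run([0.1])) == pytest.approx(0.32)

    def test_zero_sediment(self):
        assert er.detachment_rate(make_run([0.0, 0.0])) == 0.0

    def test_mean_of_interval_rates(self):
        r1 = er.detachment_rate(make_run([0.1]))
        r2 = er.detachment_rate(make_run([0.3]))
        assert er.detachment_rate(make_run([0.1, 0.3])) == pytest.approx((r1 + r2) / 2)

    def test_invalid_runs_rejected(self):
        with pytest.raises(ValueError):
            make_run([0.1], duration=0.0)
        with pytest.raises(ValueError):
            make_run([-0.1])


class TestRelativeDetachment:
    def test_exact_exponential_self_consistency(self):
        rlds = [0.0, 0.0, 5.0, 10.0, 20.0, 40.0]
        runs = runs_from_curve(2.0, -0.08, rlds)
        ratios = er.relative_detachment(runs)
        assert np.allclose(ratios, np.exp(-0.08 * np.array(rlds)), rtol=1e-6)

    def test_bare_boxes_normalise_to_one(self):
        runs = runs_from_curve(1.5, -0.1, [0.0, 0.0, 0.0, 0.0])
        assert np.allclose(er.relative_detachment(runs), 1.0, rtol=1e-6)

    def test_insufficient_design_rejected(self):
        runs = runs_from_curve(1.0, -0.1, [5.0, 5.0])  # no controls, 1 RLD level
        with pytest.raises(InsufficientDataError):
            er.relative_detachment(runs)

    def test_generator_recovery_of_bare_rate(self):
        runs = gen_erosion_runs(18, PROFILES["wild_type"], bare_rate=0.3,
                                noise=NoiseSpec(seed=17))
        a0, _ = er.extrapolate_bare_rate(runs)
        assert a0 == pytest.approx(0.3, rel=0.10)


class TestEmpiricalFit:
    def test_noiseless_exponential_recovery(self):
        x = np.linspace(0, 50, 12)
        model = er.fit_empirical(list(zip(x, np.exp(-0.095 * x))))
        assert model.b == pytest.approx(-0.095, abs=1e-9)
        assert model.b_se == pytest.approx(0.0, abs=1e-7)

    def test_noiseless_piecewise_plateau(self):
        x = np.concatenate([np.linspace(1, 18, 8), [25, 30, 40, 48]])
        y = np.where(x < 19, np.exp(-0.069 * x), 0.268)
        model = er.fit_empirical(list(zip(x, y)), form="piecewise", breakpoint=19.0)
        assert model.plateau == pytest.approx(0.268, abs=1e-12)
        assert model.b == pytest.approx(-0.069, abs=1e-9)

    def test_decay_to_plateau_form(self):
        x = np.linspace(0, 50, 15)
        y = 0.25 + 0.75 * np.exp(-0.12 * x)
        model = er.fit_empirical(list(zip(x, y)), form="decay-to-plateau")
        assert model.plateau == pytest.approx(0.25, abs=1e-6)
        assert model.b == pytest.approx(-0.12, abs=1e-6)

    def test_noisy_recovery_within_two_se(self):
        prof = PROFILES["wild_type"]
        runs = gen_erosion_runs(18, prof, noise=NoiseSpec(seed=1))
        ratios = er.relative_detachment(runs)
        model = er.fit_empirical([(r.rld, x) for r, x in zip(runs, ratios)])
        assert abs(model.b - prof.empirical_b) <= 2 * model.b_se

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            er.fit_empirical([(0, 1.0), (5, 0.6), (10, 0.4)])


class TestEvaluate:
    def test_printed_wild_type_reductions(self):
        model = er.EmpiricalErosionModel(form="exponential", b=-0.095, b_se=0.0)
        assert er.evaluate_empirical(model, 25) == pytest.approx(0.09, abs=0.005)

    def test_printed_hairy_line_reductions(self):
        model = er.EmpiricalErosionModel(form="exponential", b=-0.066, b_se=0.0)
        assert er.evaluate_empirical(model, 35) == pytest.approx(0.10, abs=0.005)

    def test_unit_ratio_at_zero_rld(self):
        model = er.EmpiricalErosionModel(form="exponential", b=-0.2)
        assert er.evaluate_empirical(model, 0.0) == 1.0

    def test_negative_rld_rejected(self):
        model = er.EmpiricalErosionModel(form="exponential", b=-0.1)
        with pytest.raises(ValueError):
            er.evaluate_empirical(model, -1.0)

    def test_monotone_and_bounded(self):
        model = er.EmpiricalErosionModel(form="exponential", b=-0.095)
        grid = np.linspace(0, 60, 200)
        vals = er.evaluate_empirical(model, grid)
        assert np.all(np.diff(vals) <= 0)
        assert np.all((vals > 0) & (vals <= 1))


class TestMonteCarloBand:
    def test_zero_se_band_collapses(self):
        model = er.EmpiricalErosionModel(form="exponential", b=-0.095, b_se=0.0)
        band = er.monte_carlo_band(model, [0, 10, 25], draws=200, seed=0)
        assert np.allclose(band.lower, band.point)
        assert np.allclose(band.upper, band.point)

    def test_band_contains_point_curve(self):
        model = er.EmpiricalErosionModel(form="exponential", b=-0.095, b_se=0.007)
        band = er.monte_carlo_band(model, [25.0], draws=2000, seed=1)
        assert band.lower[0] <= np.exp(-0.095 * 25) <= band.upper[0]

    def test_band_width_grows_with_se(self):
        grid = np.linspace(1, 50, 10)
        widths = []
        for se in (0.003, 0.012):
            model = er.EmpiricalErosionModel(form="exponential", b=-0.095, b_se=se)
            band = er.monte_carlo_band(model, grid, draws=2000, seed=2)
            widths.append(np.mean(band.upper - band.lower))
        assert widths[1] > widths[0] > 0

    def test_reproducible_given_seed(self):
        model = er.EmpiricalErosionModel(form="exponential", b=-0.08, b_se=0.01)
        b1 = er.monte_carlo_band(model, [5, 15], draws=500, seed=7)
        b2 = er.monte_carlo_band(model, [5, 15], draws=500, seed=7)
        assert np.array_equal(b1.lower, b2.lower) and np.array_equal(b1.upper, b2.upper)

    def test_missing_se_rejected(self):
        model = er.EmpiricalErosionModel(form="exponential", b=-0.08, b_se=None)
        with pytest.raises(ValueError):
            er.monte_carlo_band(model, [5.0], draws=10)


class TestCompareBands:
    @staticmethod
    def band(b, se, grid, seed=0):
        model = er.EmpiricalErosionModel(form="exponential", b=b, b_se=se)
        return er.monte_carlo_band(model, grid, draws=2000, seed=seed)

    def test_identical_models_not_flagged(self):
        grid = np.linspace(0, 50, 8)
        a = self.band(-0.095, 0.007, grid)
        b = self.band(-0.095, 0.007, grid, seed=1)
        assert not er.compare_bands(a, b).any()

    def test_separated_exponents_flagged_at_high_rld(self):
        grid = np.linspace(0, 50, 11)
        a = self.band(-0.095, 1e-4, grid)
        b = self.band(-0.066, 1e-4, grid, seed=1)
        flags = er.compare_bands(a, b)
        assert flags[-1] and not flags[0]

    def test_degenerate_band_against_itself(self):
        grid = np.linspace(0, 50, 5)
        a = self.band(-0.08, 0.0, grid)
        assert not er.compare_bands(a, a).any()

    def test_grid_mismatch_rejected(self):
        a = self.band(-0.08, 0.01, np.linspace(0, 50, 5))
        b = self.band(-0.08, 0.01, np.linspace(0, 40, 5))
        with pytest.raises(ValueError):
            er.compare_bands(a, b)
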