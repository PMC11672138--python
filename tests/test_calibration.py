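"""Calibration fits: parameter recovery, scoring conventions, blueshift
extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nitrileshift import (
    CANONICAL_BLUESHIFT,
    DEFAULT_VSE,
    GridSpec,
    VSEParameters,
    apply_scaling,
    blueshift_surface,
    extract_blueshifts,
    fit_angular,
    fit_headon,
    fit_joint,
    fit_sideon,
    fit_vse_frequency,
    fit_vse_tdm,
    generate_calibration_grid,
    goodness,
    goodness_identity,
    make_records,
    score_vse_frequency,
    vse_frequency,
    vse_tdm,
)


class TestScaling:
    def test_frequency_anchor(self):
        # raw harmonic value that lands on the 2232 cm^-1 gas-phase anchor
        scaled, _ = apply_scaling(2325.48, 0.1)
        assert scaled == pytest.approx(2232.0, abs=0.05)

    def test_tdm_anchor(self):
        _, scaled = apply_scaling(2300.0, 0.1120)
        assert scaled == pytest.approx(0.0500, abs=1e-4)

    def test_identity_when_overridden(self):
        f, t = apply_scaling(2300.0, 0.1, frequency_scale=1.0, tdm_scale=1.0)
        assert (f, t) == (2300.0, 0.1)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            apply_scaling(-1.0, 0.1)


class TestGoodness:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert goodness(y, y) == (1.0, 0.0)

    def test_constant_prediction_at_mean_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        r2, _ = goodness(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_worse_than_mean_is_negative(self):
        r2, _ = goodness([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert r2 < 0

    @given(shift=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, shift):
        obs = np.array([1.0, 3.0, 2.5, 4.0])
        pred = np.array([1.2, 2.7, 2.4, 4.3])
        assert goodness(obs + shift, pred + shift) == pytest.approx(
            goodness(obs, pred))
        assert goodness_identity(obs + shift, pred + shift)[0] == \
            pytest.approx(goodness_identity(obs, pred)[0])

    def test_rmsd_symmetric_under_exchange(self):
        obs = np.array([1.0, 3.0, 2.5, 4.0])
        pred = np.array([1.2, 2.7, 2.4, 4.3])
        assert goodness(obs, pred)[1] == goodness(pred, obs)[1]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            goodness([1.0], [1.0])


class TestStarkFits:
    def test_noiseless_tdm_recovery(self):
        grid = generate_calibration_grid(GridSpec())
        rep = fit_vse_tdm(grid)
        assert rep.parameters["tdm0"] == pytest.approx(DEFAULT_VSE.tdm0,
                                                       rel=1e-6)
        assert rep.parameters["tdm_polarizability"] == pytest.approx(
            DEFAULT_VSE.tdm_polarizability, rel=1e-6)
        assert rep.r_squared == pytest.approx(1.0)

    def test_noisy_tdm_parameters_within_three_stderr(self):
        grid = generate_calibration_grid(GridSpec(noise_sd_tdm=0.001, seed=7))
        rep = fit_vse_tdm(grid)
        for key, truth in [("tdm0", DEFAULT_VSE.tdm0),
                           ("tdm_polarizability",
                            DEFAULT_VSE.tdm_polarizability)]:
            assert abs(rep.parameters[key] - truth) < 3 * rep.stderr[key]

    def test_tdm_r2_high_on_low_noise_grid(self):
        # noise scaled to the high printed correlation class (R^2 > 0.96)
        grid = generate_calibration_grid(GridSpec(noise_sd_tdm=5e-4, seed=1))
        rep = fit_vse_tdm(grid)
        assert rep.r_squared > 0.96
        # the H-bonded subset is described as well as the whole set — the
        # TDM Stark relation does not break down for H-bonded nitriles
        assert rep.r_squared_by_label["water"] > 0.96

    def test_frequency_fit_exact_on_electrostatic_subset(self):
        grid = generate_calibration_grid(GridSpec())
        rep = fit_vse_frequency(grid)
        assert rep.parameters["nu0"] == pytest.approx(DEFAULT_VSE.nu0)
        assert rep.parameters["dmu"] == pytest.approx(DEFAULT_VSE.dmu)
        assert rep.r_squared == pytest.approx(1.0)

    def test_hbonded_subset_scores_negative_with_stark_only(self):
        grid = generate_calibration_grid(GridSpec())
        rep = fit_vse_frequency(grid)
        # the unilateral blueshift makes the Stark-only model worse than
        # predicting the subset mean
        assert rep.r_squared_by_label["water"] < 0

    def test_two_point_linear_fit_passes_through_both(self):
        rec = make_records([-78.0, -64.9], [2215.5, 2219.1], [0.05, 0.05],
                           label="point_charge")
        rep = fit_vse_frequency(rec, quadratic=False)
        assert rep.rmsd == pytest.approx(0.0, abs=1e-9)
        assert rep.parameters["nu0"] == pytest.approx(2236.9, abs=0.05)
        assert rep.parameters["dmu"] == pytest.approx(0.2748, abs=1e-3)

    def test_rank_deficient_design_rejected(self):
        rec = make_records([-10.0] * 5, [2230.0] * 5, [0.05] * 5,
                           label="point_charge")
        with pytest.raises(ValueError, match="rank"):
            fit_vse_frequency(rec)


class TestBlueshiftExtraction:
    def test_electrostatic_records_give_zero(self):
        grid = generate_calibration_grid(GridSpec())
        vsep = fit_vse_frequency(grid).extras["vse_parameters"]
        shifts = extract_blueshifts(grid, vsep)
        chg = grid["d"].isna().to_numpy()
        assert np.allclose(shifts[chg], 0.0, atol=1e-9)

    def test_injected_blueshift_recovered_exactly(self):
        field = np.linspace(-80, -20, 10)
        injected = 23.4
        freq = vse_frequency(field, DEFAULT_VSE) + injected
        rec = make_records(field, freq, np.full(10, 0.05),
                           d=np.full(10, 3.0), theta=np.full(10, 160.0))
        shifts = extract_blueshifts(rec, DEFAULT_VSE)
        assert np.allclose(shifts, injected)

    def test_extracted_range_spans_the_surface(self):
        grid = generate_calibration_grid(GridSpec())
        vsep = fit_vse_frequency(grid).extras["vse_parameters"]
        shifts = extract_blueshifts(grid, vsep)
        hb = grid["d"].notna().to_numpy()
        assert shifts[hb].min() < -2.0
        assert shifts[hb].max() > 45.0


class TestDistanceAngleFits:
    d = np.linspace(2.6, 5.0, 25)

    def test_power_law_recovery(self):
        y = 16.6 * (self.d / 3.36) ** -4.0
        rep = fit_headon(self.d, y, variant="power")
        assert rep.parameters["n1"] == pytest.approx(-4.0, abs=1e-9)
        assert rep.r_squared == pytest.approx(1.0)

    def test_exponential_recovery(self):
        y = 40.0 * np.exp(-1.30 * self.d)
        rep = fit_headon(self.d, y, variant="exponential")
        assert rep.parameters["a"] == pytest.approx(1.300, abs=1e-9)

    def test_power_and_exponential_mutually_consistent(self):
        # fitting the exponential law to power-law data (and vice versa)
        # stays within the head-on residual class of ~1.5 cm^-1
        y = 16.6 * (self.d / 3.36) ** -4.0
        rep = fit_headon(self.d, y, variant="exponential")
        assert rep.rmsd <= 1.5

    def test_degenerate_abscissae_rejected(self):
        with pytest.raises(ValueError):
            fit_headon([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])

    def test_buckingham_recovery_and_zero_crossing(self):
        y = 16.6 * (np.exp(-2.85 * (self.d - 3.36))
                    - (self.d / 3.36) ** -8.0)
        rep = fit_sideon(self.d, y)
        assert rep.parameters["b"] == pytest.approx(2.85, rel=1e-6)
        assert rep.extras["zero_crossing"] == pytest.approx(3.36, abs=0.01)
        assert rep.r_squared == pytest.approx(1.0)

    def test_two_power_exponents_converge_together(self):
        y = 16.6 * (np.exp(-2.85 * (self.d - 3.36))
                    - (self.d / 3.36) ** -8.0)
        rep = fit_sideon(self.d, y, two_power=True)
        p1, p2 = rep.parameters["p1"], rep.parameters["p2"]
        assert p1 == pytest.approx(p2, abs=0.6)
        assert (p1 + p2) / 2 == pytest.approx(-8.0, abs=0.6)

    def test_angular_recovery_and_zero_crossing(self):
        th = np.linspace(70, 175, 22)
        y = 20.0 * np.cos(np.radians(0.82 * (180 - th)))
        rep = fit_angular(th, y)
        assert rep.parameters["m"] == pytest.approx(0.820, abs=1e-6)
        assert rep.extras["zero_crossing_deg"] == pytest.approx(70.2, abs=0.1)

    def test_angular_span_requirement(self):
        th = np.linspace(150, 175, 10)
        with pytest.raises(ValueError, match="span"):
            fit_angular(th, np.ones(10))


class TestJointFit:
    def test_noiseless_recovery_to_per_mille(self):
        grid = generate_calibration_grid(GridSpec())
        rep = fit_joint(grid)
        for key, truth in [("d0", 3.36), ("dnu_d0", 16.6), ("b", 2.85),
                           ("m", 0.91), ("nu0", DEFAULT_VSE.nu0),
                           ("dmu", DEFAULT_VSE.dmu)]:
            assert abs(rep.parameters[key] - truth) / abs(truth) < 1e-3

    def test_refit_reproduces_injected_surface(self):
        grid = generate_calibration_grid(GridSpec())
        blue_fit = fit_joint(grid).extras["blueshift_parameters"]
        d, th = np.meshgrid(np.linspace(2.5, 5.0, 30),
                            np.linspace(70, 175, 30))
        delta = (blueshift_surface(d, th, blue_fit)
                 - blueshift_surface(d, th, CANONICAL_BLUESHIFT))
        assert np.abs(delta).max() < 0.5

    def test_needs_both_environment_kinds(self):
        grid = generate_calibration_grid(GridSpec())
        donors = grid[grid["d"].notna()]
        with pytest.raises(ValueError, match="electrostatic"):
            fit_joint(donors)

    def test_noise_matched_residuals(self):
        grid = generate_calibration_grid(
            GridSpec(noise_sd_frequency=1.8, seed=11))
        rep = fit_joint(grid)
        assert rep.rmsd == pytest.approx(1.8, abs=0.3)
        assert rep.r_squared > 0.9
        lo, hi = rep.extras["residual_range"]
        assert -8.0 < lo < 0 < hi < 8.0
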