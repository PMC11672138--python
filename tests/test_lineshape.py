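"""Lineshape engine: FFA spectra, two-site closed form, motional
narrowing, peak analysis."""

import numpy as np
import pandas as pd
import pytest

from nitrileshift import (
    DEFAULT_VSE,
    CANONICAL_BLUESHIFT,
    DynamicsSpec,
    ProbeTrajectory,
    Spectrum,
    apparent_blueshift,
    blueshift_surface,
    coalescence_rate,
    decompose_two_bands,
    ffa_spectrum,
    inhomogeneous_spectrum,
    kubo_two_state,
    map_trajectory,
    simulate_hb_trajectory,
    vse_frequency,
)
from nitrileshift.lineshape import _detect_peaks


def two_state_traj(split, tau_ps, n, seed=5, dt=20.0, base=2200.0):
    spec = DynamicsSpec(mean_residence_hb=tau_ps, mean_residence_free=tau_ps,
                        hb_d_mean=3.0, hb_theta_mean=180.0, seed=seed,
                        n_frames=n, dt=dt)
    frames = simulate_hb_trajectory(spec)
    nu = base + split * frames["hb_state"].to_numpy()
    return ProbeTrajectory(dt=dt, frequency=nu, tdm=np.ones(n))


class TestMapTrajectory:
    def frames(self, n=2048, field=-60.0, hb=None):
        hb = np.zeros(n, dtype=int) if hb is None else hb
        d = np.where(hb == 1, 3.0, np.nan)
        th = np.where(hb == 1, 160.0, np.nan)
        return pd.DataFrame({"time_fs": np.arange(n) * 20.0,
                             "field": np.full(n, field),
                             "d": d, "theta": th, "hb_state": hb})

    def test_constant_input_gives_constant_series(self):
        traj = map_trajectory(self.frames(), DEFAULT_VSE)
        assert np.ptp(traj.frequency) == 0
        assert np.ptp(traj.tdm) == 0
        assert traj.frequency[0] == vse_frequency(-60.0, DEFAULT_VSE)

    def test_alternating_hb_adds_exact_blueshift(self):
        hb = np.arange(2048) % 2
        traj = map_trajectory(self.frames(hb=hb), DEFAULT_VSE)
        gap = blueshift_surface(3.0, 160.0, CANONICAL_BLUESHIFT)
        diffs = np.unique(np.round(np.diff(traj.frequency), 9))
        assert np.allclose(np.sort(diffs), [-gap, gap])

    def test_nonuniform_sampling_rejected(self):
        frames = self.frames()
        frames.loc[5, "time_fs"] += 3.0
        with pytest.raises(ValueError, match="uniform"):
            map_trajectory(frames, DEFAULT_VSE)


class TestFFASpectrum:
    def test_constant_frequency_peak_position(self):
        n = 2 ** 14
        traj = ProbeTrajectory(dt=20.0, frequency=np.full(n, 2232.0),
                               tdm=np.full(n, 0.05))
        spec = ffa_spectrum(traj)
        assert spec.main_peak[0] == pytest.approx(2232.0, abs=spec.resolution)

    def test_offset_covariance(self):
        n = 2 ** 14
        base = 2220.0 + 5.0 * np.sin(np.arange(n) * 0.01)
        s1 = ffa_spectrum(ProbeTrajectory(20.0, base, np.ones(n)))
        s2 = ffa_spectrum(ProbeTrajectory(20.0, base + 7.0, np.ones(n)))
        assert s2.main_peak[0] - s1.main_peak[0] == pytest.approx(7.0,
                                                                 abs=1e-6)
        assert np.allclose(s1.intensity, s2.intensity)

    def test_integrated_intensity_invariant_across_rates(self):
        split = 20.0
        kc = coalescence_rate(split)
        areas = []
        for mult in (0.1, 1.0, 10.0):
            traj = two_state_traj(split, 2.0 / (mult * kc), 2 ** 17)
            areas.append(ffa_spectrum(traj).integral())
        assert np.ptp(areas) / np.mean(areas) < 0.02

    def test_intensity_scales_with_mean_squared_tdm(self):
        n = 2 ** 14
        nu = np.full(n, 2232.0)
        s1 = ffa_spectrum(ProbeTrajectory(20.0, nu, np.full(n, 0.04)))
        s2 = ffa_spectrum(ProbeTrajectory(20.0, nu, np.full(n, 0.08)))
        assert s2.integral() / s1.integral() == pytest.approx(4.0, rel=1e-6)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError, match="1024|2\\*\\*10|minimum"):
            ffa_spectrum(ProbeTrajectory(20.0, np.full(100, 2232.0),
                                         np.ones(100)))

    def test_nan_frequencies_rejected(self):
        nu = np.full(2048, 2232.0)
        nu[5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ProbeTrajectory(20.0, nu, np.ones(2048))


class TestKuboTwoState:
    def test_static_limit_peaks_at_site_frequencies(self):
        spec = kubo_two_state(20.0, k_exchange=0.0, nu_sites=(0.0, 20.0))
        pos = sorted(p[0] for p in spec.peaks[:2])
        assert pos[0] == pytest.approx(0.0, abs=spec.resolution)
        assert pos[1] == pytest.approx(20.0, abs=spec.resolution)

    def test_fast_limit_single_peak_at_weighted_mean(self):
        spec = kubo_two_state(20.0, k_exchange=1000.0,
                              populations=(0.5, 0.5))
        assert len(spec.peaks) == 1
        assert spec.main_peak[0] == pytest.approx(10.0, abs=spec.resolution)
        skew = kubo_two_state(20.0, k_exchange=1000.0,
                              populations=(0.25, 0.75))
        assert skew.main_peak[0] == pytest.approx(15.0, abs=0.2)

    def test_invalid_populations_rejected(self):
        with pytest.raises(ValueError):
            kubo_two_state(20.0, 1.0, populations=(0.7, 0.7))


class TestNarrowing:
    def test_slow_exchange_resolves_substates(self):
        split = 26.0
        traj = two_state_traj(split, 200.0, 2 ** 20, seed=12)
        spec = ffa_spectrum(traj)
        pos = sorted(p[0] for p in spec.peaks[:2])
        assert pos[0] == pytest.approx(2200.0, abs=1.0)
        assert pos[1] == pytest.approx(2226.0, abs=1.0)

    def test_fast_symmetric_exchange_halves_the_blueshift(self):
        split = 26.0
        traj = two_state_traj(split, 2.0, 2 ** 20, seed=11)
        spec = ffa_spectrum(traj)
        shift = apparent_blueshift(spec, 2200.0)
        assert shift == pytest.approx(split / 2, abs=1.5)

    @pytest.mark.parametrize("mult", [0.1, 10.0])
    def test_ffa_matches_two_site_closed_form(self, mult):
        split = 20.0
        kex = mult * coalescence_rate(split)
        traj = two_state_traj(split, 2.0 / kex, 2 ** 20, seed=6)
        ffa = ffa_spectrum(traj, lifetime=3.0)
        kubo = kubo_two_state(split, kex, nu_sites=(2200.0, 2220.0),
                              lifetime=3.0)
        fpk = sorted(p[0] for p in ffa.peaks[:2])
        kpk = sorted(p[0] for p in kubo.peaks[:2])
        assert len(fpk) == len(kpk)
        for f, k in zip(fpk, kpk):
            assert f == pytest.approx(k, abs=0.5)

    def test_inhomogeneous_limit_agreement(self):
        # exchange far slower than the correlation window: FFA converges on
        # the static TDM^2-weighted frequency distribution
        traj = two_state_traj(26.0, 500.0, 2 ** 20, seed=13)
        ffa = ffa_spectrum(traj)
        inh = inhomogeneous_spectrum(traj.frequency, traj.tdm)
        f = sorted(p[0] for p in ffa.peaks[:2])
        i = sorted(p[0] for p in inh.peaks[:2])
        for a, b in zip(f, i):
            assert a == pytest.approx(b, abs=1.0)


class TestInhomogeneous:
    def test_identical_samples_single_bin(self):
        spec = inhomogeneous_spectrum(np.full(500, 2232.0))
        assert len(spec.peaks) == 1
        assert spec.main_peak[0] == pytest.approx(2232.0, abs=0.5)

    def test_gaussian_samples_peak_at_mode(self):
        rng = np.random.default_rng(3)
        spec = inhomogeneous_spectrum(rng.normal(2232.0, 3.0, 20000))
        assert spec.main_peak[0] == pytest.approx(2232.0, abs=1.0)

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError, match="100"):
            inhomogeneous_spectrum(np.full(10, 2232.0))


class TestPeakAnalysis:
    def gauss_spec(self, centers, amps, sigma=3.5):
        w = np.arange(2200.0, 2260.0, 0.25)
        y = sum(a * np.exp(-0.5 * ((w - c) / sigma) ** 2)
                for c, a in zip(centers, amps))
        return Spectrum(w, y, _detect_peaks(w, y))

    def test_apparent_blueshift_arithmetic(self):
        spec = self.gauss_spec([2230.9], [1.0])
        assert apparent_blueshift(spec, 2219.1) == pytest.approx(11.8,
                                                                 abs=0.05)
        assert apparent_blueshift(spec, 2230.9) == pytest.approx(0.0,
                                                                 abs=0.05)

    def test_no_peak_raises(self):
        w = np.arange(2200.0, 2210.0, 0.5)
        spec = Spectrum(w, np.zeros_like(w), [])
        with pytest.raises(ValueError, match="peak"):
            apparent_blueshift(spec, 2200.0)

    def test_separated_bands_recovered_exactly(self):
        spec = self.gauss_spec([2215.0, 2240.0], [1.0, 0.6])
        res = decompose_two_bands(spec)
        pos = sorted(c[0] for c in res["components"])
        assert pos[0] == pytest.approx(2215.0, abs=0.05)
        assert pos[1] == pytest.approx(2240.0, abs=0.05)
        assert not res["single_band"]

    def test_overlapping_bands_at_solvent_like_split(self):
        spec = self.gauss_spec([2233.3, 2227.8], [1.0, 0.8])
        res = decompose_two_bands(spec)
        pos = sorted(c[0] for c in res["components"])
        assert pos[0] == pytest.approx(2227.8, abs=0.5)
        assert pos[1] == pytest.approx(2233.3, abs=0.5)

    def test_unimodal_input_flagged(self):
        spec = self.gauss_spec([2232.0], [1.0])
        with pytest.warns(UserWarning, match="single"):
            res = decompose_two_bands(spec)
        assert res["single_band"]

    def test_spectrum_validation(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([1.0, 1.0, 2.0]), np.zeros(3))
        with pytest.raises(ValueError):
            Spectrum(np.array([1.0, 2.0]), np.array([-1.0, 0.0]))
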