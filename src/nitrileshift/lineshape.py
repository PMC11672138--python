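"""IR lineshapes from fluctuating frequency trajectories.

A *vibrational spectroscopic map* turns per-frame environment descriptors
(field projection, HB geometry) into instantaneous frequencies and
transition dipoles.  This module converts such trajectories into IR spectra
with the fluctuating frequency approximation (FFA): the linear response is
the Fourier transform of the TDM-weighted phase-accumulation correlation
function

    R(t) = < mu(0) mu(t) exp( i * w_cm * Int_0^t dnu(t') dt' ) >,

with ``dnu`` the instantaneous frequency fluctuation about the trajectory
mean (cm^-1) and ``w_cm`` the package's frequency-time bridge (below).  The
FFA captures motional narrowing: substates exchanging faster than their
frequency gap collapse into one band at the population-weighted mean, while
slow exchange leaves resolved bands whose positions report the substate
frequencies directly (the inhomogeneous limit).

Frequency-time bridge
---------------------
Exchange rates are compared against the *beat period* of the substate
splitting: a gap of ``dnu`` cm^-1 dephases on a time scale ``1/(c*dnu)``
(~1.7 ps for 20 cm^-1), and accordingly the phase kernel above uses
``w_cm = c`` (cm/ps per cm^-1) rather than ``2*pi*c``.  The same constant
maps the spectral axis back to cm^-1, so static frequencies transform to
peaks at exactly their wavenumber; only the *rate scale* of the narrowing
transition depends on this convention.  The textbook kernel carries the
extra ``2*pi`` and would place the narrowing threshold at ~0.3 ps for a
20 cm^-1 gap; see docs/methods.md for the discussion.

The closed-form two-site exchange lineshape (:func:`kubo_two_state`) uses
the identical convention and serves as an independent oracle for the FFA
engine on two-state Markov trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .stark import (
    CANONICAL_BLUESHIFT,
    BlueshiftParameters,
    VSEParameters,
    blueshift_surface,
    vse_frequency,
    vse_tdm,
)

__all__ = [
    "C_CM_PER_PS",
    "OMEGA_PER_CM",
    "coalescence_rate",
    "ProbeTrajectory",
    "Spectrum",
    "map_trajectory",
    "ffa_spectrum",
    "inhomogeneous_spectrum",
    "kubo_two_state",
    "apparent_blueshift",
    "decompose_two_bands",
]

#: Speed of light, cm per ps.
C_CM_PER_PS = 2.99792458e-2

#: Frequency-time bridge: angular rate (rad/ps) per cm^-1 of frequency
#: fluctuation.  Beat-period convention (no 2*pi); see module docstring.
OMEGA_PER_CM = C_CM_PER_PS

MIN_FRAMES = 2 ** 10


def coalescence_rate(delta_nu: float) -> float:
    """Exchange rate (ps^-1, sum of the two site escape rates) at which the
    two-band structure of a symmetric two-site system with frequency gap
    ``delta_nu`` cm^-1 collapses into one band: ``sqrt(2) * OMEGA_PER_CM *
    delta_nu / 2 * 2 = sqrt(2) * OMEGA_PER_CM * delta_nu`` / ... reduced:
    the per-site escape rate at coalescence is ``delta/sqrt(2)`` with
    ``delta = OMEGA_PER_CM * delta_nu / 2`` the half-splitting in rad/ps;
    the returned value is the total exchange rate ``k_ab + k_ba``."""
    delta = OMEGA_PER_CM * float(delta_nu) / 2.0
    return float(np.sqrt(2.0) * delta)


@dataclass(frozen=True)
class ProbeTrajectory:
    """Uniformly sampled frequency/TDM series of one probe.

    ``dt`` in fs; ``frequency`` in cm^-1; ``tdm`` in D; ``hb_state`` an
    optional 0/1 occupancy series of the same length.
    """

    dt: float
    frequency: np.ndarray
    tdm: np.ndarray
    hb_state: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequency, dtype=float)
        tdm = np.asarray(self.tdm, dtype=float)
        object.__setattr__(self, "frequency", freq)
        object.__setattr__(self, "tdm", tdm)
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if freq.ndim != 1 or tdm.shape != freq.shape:
            raise ValueError("frequency and tdm must be equal-length 1-d")
        if not np.all(np.isfinite(freq)) or not np.all(np.isfinite(tdm)):
            raise ValueError("trajectory contains non-finite values")
        if np.any(freq <= 0):
            raise ValueError("frequencies must be positive")
        if self.hb_state is not None:
            hb = np.asarray(self.hb_state)
            object.__setattr__(self, "hb_state", hb)
            if hb.shape != freq.shape:
                raise ValueError("hb_state length mismatch")

    def __len__(self) -> int:
        return self.frequency.size


@dataclass
class Spectrum:
    """Wavenumber grid (cm^-1, strictly increasing) with non-negative
    intensities and detected peaks as (position, height) pairs sorted by
    height, largest first."""

    wavenumber: np.ndarray
    intensity: np.ndarray
    peaks: list = dataclass_field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumber, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        self.wavenumber, self.intensity = w, i
        if w.ndim != 1 or i.shape != w.shape:
            raise ValueError("wavenumber and intensity must match in shape")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def main_peak(self) -> tuple[float, float]:
        if not self.peaks:
            raise ValueError("spectrum has no detected peak")
        return self.peaks[0]

    @property
    def resolution(self) -> float:
        return float(np.median(np.diff(self.wavenumber)))

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.wavenumber))


# ---------------------------------------------------------------------------
# Vibrational spectroscopic map
# ---------------------------------------------------------------------------


def map_trajectory(frames: pd.DataFrame, vse: VSEParameters,
                   blue: BlueshiftParameters = CANONICAL_BLUESHIFT,
                   ) -> ProbeTrajectory:
    """Apply the spectroscopic map to a (field, geometry, occupancy) series.

    ``frames`` must carry uniformly spaced ``time_fs`` plus ``field``,
    ``d``, ``theta`` and ``hb_state`` columns (the format written by the
    synthetic generator).  Frames with ``hb_state == 1`` add the geometric
    blueshift of their contact to the Stark frequency; the TDM follows the
    linear TDM Stark relation in every frame.
    """
    t = frames["time_fs"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("need at least two frames")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("frames are not uniformly sampled")
    fld = frames["field"].to_numpy(dtype=float)
    nu = np.asarray(vse_frequency(fld, vse), dtype=float)
    hb = frames["hb_state"].to_numpy(dtype=int)
    bound = hb == 1
    if bound.any():
        nu[bound] += blueshift_surface(
            frames.loc[bound, "d"].to_numpy(dtype=float),
            frames.loc[bound, "theta"].to_numpy(dtype=float), blue)
    tdm = np.asarray(vse_tdm(fld, vse), dtype=float)
    return ProbeTrajectory(dt=float(steps[0]), frequency=nu, tdm=tdm,
                           hb_state=hb)


# ---------------------------------------------------------------------------
# FFA spectrum
# ---------------------------------------------------------------------------


def _autocorrelation(a: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased complex autocorrelation <a*(t) a(t+l)> for l = 0..max_lag."""
    n = a.size
    nfft = 1 << int(np.ceil(np.log2(n + max_lag + 1)))
    fa = np.fft.fft(a, nfft)
    corr = np.fft.ifft(np.conj(fa) * fa)[: max_lag + 1]
    return corr / (n - np.arange(max_lag + 1))


def _detect_peaks(wavenumber: np.ndarray, intensity: np.ndarray,
                  prominence_frac: float = 0.02,
                  height_frac: float = 0.05) -> list:
    top = float(intensity.max(initial=0.0))
    if top <= 0:
        return []
    idx, _ = signal.find_peaks(intensity, height=height_frac * top,
                               prominence=prominence_frac * top)
    peaks = []
    for i in idx:
        pos, height = float(wavenumber[i]), float(intensity[i])
        if 0 < i < intensity.size - 1:
            y0, y1, y2 = intensity[i - 1: i + 2]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                shift = 0.5 * (y0 - y2) / denom
                if abs(shift) <= 1:
                    step = wavenumber[i + 1] - wavenumber[i]
                    pos += float(shift) * float(step)
                    height = float(y1 - 0.25 * (y0 - y2) * shift)
        peaks.append((pos, height))
    peaks.sort(key=lambda p: p[1], reverse=True)
    return peaks


def ffa_spectrum(traj: ProbeTrajectory, lifetime: Optional[float] = 3.0,
                 resolution: float = 0.5,
                 max_lag: Optional[int] = None) -> Spectrum:
    """IR spectrum of a trajectory via the fluctuating frequency
    approximation.

    Parameters
    ----------
    traj
        Trajectory of at least 2^10 frames.
    lifetime
        Vibrational lifetime T1 in ps; the correlation function is apodized
        by ``exp(-t / (2*T1))``.  ``None`` disables apodization (peak
        positions are essentially insensitive to it).
    resolution
        Targeted wavenumber grid spacing, cm^-1 (zero-padding is chosen to
        reach at least this spacing).
    max_lag
        Longest correlation lag in frames; defaults to
        ``min(n_frames // 4, 2**15)``.  A half-Hann taper over the lag
        window suppresses truncation ripple.

    Notes
    -----
    The response is built from the phase accumulated by trapezoidal
    integration of the frequency fluctuations about the trajectory mean and
    weighted by the instantaneous TDM; the integrated intensity therefore
    scales with the mean squared TDM, independent of the dynamics.
    """
    n = len(traj)
    if n < MIN_FRAMES:
        raise ValueError(
            f"trajectory too short for a meaningful spectrum: {n} frames "
            f"< minimum {MIN_FRAMES}")
    dt_ps = traj.dt * 1e-3
    nu_mean = float(traj.frequency.mean())
    dom = OMEGA_PER_CM * (traj.frequency - nu_mean)   # rad/ps
    # trapezoid-rule cumulative phase
    phase = np.empty(n)
    phase[0] = 0.0
    np.cumsum(0.5 * (dom[1:] + dom[:-1]) * dt_ps, out=phase[1:])
    a = traj.tdm * np.exp(1j * phase)

    if max_lag is None:
        max_lag = min(n // 4, 2 ** 15)
    max_lag = int(min(max_lag, n - 1))
    corr = _autocorrelation(a, max_lag)

    lags = np.arange(max_lag + 1)
    window = 0.5 * (1 + np.cos(np.pi * lags / max_lag))   # Hann half-window
    if lifetime is not None:
        if lifetime <= 0:
            raise ValueError("lifetime must be positive or None")
        window = window * np.exp(-lags * dt_ps / (2.0 * lifetime))
    corr = corr * window

    # two-sided spectrum: S(w) = sum_{-L..L} R(l) e^{-i w l dt}
    pad = max(2 * max_lag + 1,
              int(np.ceil(2 * np.pi / (resolution * OMEGA_PER_CM * dt_ps))))
    nfft = 1 << int(np.ceil(np.log2(pad)))
    spec = np.fft.fft(corr, nfft)
    spec = 2.0 * spec.real - corr[0].real
    omega = 2 * np.pi * np.fft.fftfreq(nfft, d=dt_ps)   # rad/ps
    order = np.argsort(omega)
    wavenumber = nu_mean + omega[order] / OMEGA_PER_CM
    intensity = np.clip(spec[order], 0.0, None)
    peaks = _detect_peaks(wavenumber, intensity)
    return Spectrum(wavenumber=wavenumber, intensity=intensity, peaks=peaks)


def inhomogeneous_spectrum(frequency_samples, tdm_samples=None,
                           resolution: float = 0.5,
                           smoothing: float = 1.0) -> Spectrum:
    """Static (inhomogeneous-limit) spectrum: the TDM^2-weighted density of
    instantaneous frequencies, optionally Gaussian-smoothed (cm^-1)."""
    nu = np.asarray(frequency_samples, dtype=float)
    if nu.size < 100:
        raise ValueError("need at least 100 frequency samples")
    if not np.all(np.isfinite(nu)):
        raise ValueError("frequency samples contain non-finite values")
    w = (np.ones_like(nu) if tdm_samples is None
         else np.asarray(tdm_samples, dtype=float) ** 2)
    lo = nu.min() - max(5 * smoothing, 5 * resolution)
    hi = nu.max() + max(5 * smoothing, 5 * resolution)
    edges = np.arange(lo, hi + resolution, resolution)
    hist, edges = np.histogram(nu, bins=edges, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    intensity = hist.astype(float)
    if smoothing > 0:
        half = int(np.ceil(4 * smoothing / resolution))
        x = np.arange(-half, half + 1) * resolution
        kern = np.exp(-0.5 * (x / smoothing) ** 2)
        kern /= kern.sum()
        intensity = np.convolve(intensity, kern, mode="same")
    peaks = _detect_peaks(centers, intensity)
    return Spectrum(wavenumber=centers, intensity=intensity, peaks=peaks)


# ---------------------------------------------------------------------------
# Two-site exchange closed form
# ---------------------------------------------------------------------------


def kubo_two_state(delta_nu: float, k_exchange: float,
                   populations: tuple[float, float] = (0.5, 0.5),
                   nu_sites: Optional[tuple[float, float]] = None,
                   lifetime: Optional[float] = None,
                   resolution: float = 0.1,
                   span: float = 4.0,
                   linewidth_floor: float = 1e-3) -> Spectrum:
    """Closed-form lineshape of two sites in Markovian exchange.

    Sites at ``nu_sites`` (default ``(0, delta_nu)``) cm^-1 with stationary
    populations ``(p_a, p_b)`` and total exchange rate ``k_exchange =
    k_ab + k_ba`` in ps^-1 (``k_ab = k_exchange * p_b`` by detailed
    balance).  Solves the 2x2 complex resolvent on a wavenumber grid.  In
    the static limit the lines sit exactly at the site frequencies; in the
    fast limit one line sits at the population-weighted mean.  A small
    Lorentzian ``linewidth_floor`` (ps^-1) keeps the static limit
    renderable; ``lifetime`` (T1, ps) adds ``1/(2*T1)`` like the FFA
    apodization.
    """
    p = np.asarray(populations, dtype=float)
    if p.shape != (2,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("populations must be two non-negatives summing to 1")
    if k_exchange < 0:
        raise ValueError("exchange rate must be non-negative")
    nu_a, nu_b = nu_sites if nu_sites is not None else (0.0, float(delta_nu))
    k_ab = k_exchange * p[1]
    k_ba = k_exchange * p[0]
    gamma = linewidth_floor + (0.0 if lifetime is None else 1.0 / (2 * lifetime))

    width = abs(nu_b - nu_a)
    extra = span * max(width, 2.0) + 5.0 * gamma / OMEGA_PER_CM
    lo, hi = min(nu_a, nu_b) - extra, max(nu_a, nu_b) + extra
    grid = np.arange(lo, hi + resolution, resolution)

    w = OMEGA_PER_CM * grid
    wa, wb = OMEGA_PER_CM * nu_a, OMEGA_PER_CM * nu_b
    # resolvent of [i(w - w_site) + gamma + K] with K the jump generator
    A = 1j * (w - wa) + gamma + k_ab
    B = 1j * (w - wb) + gamma + k_ba
    det = A * B - k_ab * k_ba
    # 1^T M^{-1} p with M = [[A, -k_ba], [-k_ab, B]]
    num = (B + k_ba) * p[0] + (A + k_ab) * p[1]
    intensity = np.clip((num / det).real, 0.0, None)
    peaks = _detect_peaks(grid, intensity)
    return Spectrum(wavenumber=grid, intensity=intensity, peaks=peaks)


# ---------------------------------------------------------------------------
# Peak analysis
# ---------------------------------------------------------------------------


def apparent_blueshift(spec: Spectrum, vse_only_frequency: float) -> float:
    """Main-peak position minus the Stark-only reference frequency, cm^-1.

    This is the blueshift an experimentalist would read off the spectrum;
    under fast exchange it is *smaller* than the geometric blueshift of the
    H-bonded substate (motional narrowing averages it with the free
    substate's zero)."""
    pos, _ = spec.main_peak
    return float(pos - vse_only_frequency)


def decompose_two_bands(spec: Spectrum) -> dict:
    """Two-component symmetric-band (Gaussian) decomposition of a spectrum.

    Returns a dict with ``components``: list of (position cm^-1,
    fractional area) sorted by area, and ``single_band``: True when the fit
    collapses onto one dominant component (the second carrying < 2% of the
    area or converging onto the first), which is also signalled with a
    warning.  Raises if the least-squares fit fails outright.
    """
    w, y = spec.wavenumber, spec.intensity
    if y.max(initial=0.0) <= 0:
        raise ValueError("empty spectrum")
    sel = y > 1e-6 * y.max()
    w, y = w[sel], y[sel]

    guesses = spec.peaks[:2]
    if len(guesses) == 0:
        raise ValueError("spectrum has no detected peak")
    mu0 = guesses[0][0]
    mu1 = guesses[1][0] if len(guesses) > 1 else mu0 + 3 * spec.resolution
    amp = float(y.max())
    sig = max(2.0 * spec.resolution,
              float(np.sqrt(np.sum(y * (w - np.average(w, weights=y)) ** 2)
                            / np.sum(y))) / 2)

    def model(x, a1, m1, s1, a2, m2, s2):
        return (a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
                + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2))

    try:
        popt, _ = optimize.curve_fit(
            model, w, y,
            p0=[amp, mu0, sig, 0.5 * amp, mu1, sig],
            bounds=([0, w.min(), 1e-3, 0, w.min(), 1e-3],
                    [np.inf, w.max(), np.ptp(w), np.inf, w.max(), np.ptp(w)]),
            maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"two-band decomposition failed: {err}") from err
    a1, m1, s1, a2, m2, s2 = popt
    areas = np.array([a1 * s1, a2 * s2]) * np.sqrt(2 * np.pi)
    total = areas.sum()
    comps = sorted(zip((m1, m2), areas / total),
                   key=lambda c: c[1], reverse=True)
    single = bool(comps[1][1] < 0.02
                  or abs(comps[0][0] - comps[1][0]) < spec.resolution)
    if single:
        warnings.warn("spectrum is effectively single-banded; second "
                      "component is degenerate", UserWarning, stacklevel=2)
    return {"components": [(float(m), float(frac)) for m, frac in comps],
            "single_band": single}
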