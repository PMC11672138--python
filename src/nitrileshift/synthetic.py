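"""Synthetic calibration grids and two-state hydrogen-bond dynamics.

This module generates the two kinds of inputs the rest of the package
consumes, with full control over the ground truth:

* *calibration grids* that emulate a quantum-chemistry calibration design —
  a nitrile probed by point charges at 5.0-8.0 Å (purely electrostatic) and
  by HB donors at 2.5-5.0 Å, each over approach angles of 70-175 deg, with
  frequencies/TDMs evaluated from known Stark + blueshift parameters plus
  optional Gaussian noise;
* *probe trajectories* in which HB occupancy follows a two-state
  continuous-time Markov chain (exponential dwell times) discretised at the
  sampling interval, the bound-state geometry is drawn around a mean contact
  with the empirically motivated anticorrelated d-theta trend (HBs get
  shorter as they straighten: ~3.35 Å side-on down to ~2.93 Å head-on), and
  the field follows a mean-reverting (Ornstein-Uhlenbeck) process.

Because the electric field is not an observable of the grid geometry, grids
assign fields through a declared monotone surrogate map
``F(d, theta) = -field_scale * (3 Å / d)^2 * cos(180 deg - theta)``:
inverse-square in distance, head-on approaches give the strongest negative
(red-shifting) projection, side-on approaches a weak positive one.

Everything is reproducible from integer seeds via ``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stark import (
    CANONICAL_BLUESHIFT,
    DEFAULT_VSE,
    BlueshiftParameters,
    VSEParameters,
    blueshift_surface,
    vse_frequency,
    vse_tdm,
)
from .calibration import ELECTROSTATIC_LABEL, make_records

__all__ = [
    "COULOMB_MV_PER_CM",
    "GridSpec",
    "DynamicsSpec",
    "geometry_field_map",
    "generate_calibration_grid",
    "simulate_hb_trajectory",
    "field_from_point_charges",
]

#: Field of a unit positive charge at 1 Å, in MV/cm: e/(4 pi eps0 Å^2).
COULOMB_MV_PER_CM = 1439.96455


@dataclass(frozen=True)
class GridSpec:
    """Design of a synthetic calibration grid.

    The donor block is a uniform ``n_d x n_theta`` grid (default 20 x 21 =
    420 configurations over 2.5-5.0 Å and 70-175 deg); the point-charge
    block a ``charge_n_d x charge_n_theta`` grid (default 5 x 25 = 125 over
    5.0-8.0 Å).  Noise standard deviations apply to frequencies (cm^-1)
    and TDMs (D) independently.
    """

    d_range: tuple[float, float] = (2.5, 5.0)
    theta_range: tuple[float, float] = (70.0, 175.0)
    n_d: int = 20
    n_theta: int = 21
    charge_d_range: tuple[float, float] = (5.0, 8.0)
    charge_n_d: int = 5
    charge_n_theta: int = 25
    noise_sd_frequency: float = 0.0
    noise_sd_tdm: float = 0.0
    field_scale: float = 60.0
    label: str = "water"
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.d_range, self.charge_d_range):
            if not (2.5 <= lo < hi <= 8.0):
                raise ValueError("distance ranges must lie within [2.5, 8.0] Å")
        lo, hi = self.theta_range
        if not (70.0 <= lo < hi <= 180.0):
            raise ValueError("theta range must lie within [70, 180] degrees")
        if min(self.n_d, self.n_theta, self.charge_n_d,
               self.charge_n_theta) < 2:
            raise ValueError("need at least 2 grid points per axis")
        if self.noise_sd_frequency < 0 or self.noise_sd_tdm < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class DynamicsSpec:
    """Two-state HB dynamics of one probe trajectory.

    Times in ps except the sampling interval ``dt`` (fs).  The defaults
    describe the symmetric fast-exchange scenario used throughout the
    package's narrowing demonstrations: 2 ps mean residence in both the
    H-bonded and the free state, sampled every 20 fs for 2^20 frames.
    """

    mean_residence_hb: float = 2.0        # ps
    mean_residence_free: float = 2.0      # ps
    hb_d_mean: float = 3.0                # Å
    hb_theta_mean: float = 163.0          # deg
    hb_d_sd: float = 0.0                  # Å
    hb_theta_sd: float = 0.0              # deg
    use_d_theta_trend: bool = False
    field_mean: float = -60.0             # MV/cm
    field_sd: float = 0.0                 # MV/cm
    field_correlation_time: float = 0.5   # ps
    dt: float = 20.0                      # fs
    n_frames: int = 2 ** 20
    seed: int = 0
    start_bound: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("mean_residence_hb", "mean_residence_free",
                     "field_correlation_time", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_frames < 2 ** 10:
            raise ValueError("n_frames must be >= 2^10 for a usable spectrum")
        if self.dt * 1e-3 > min(self.mean_residence_hb,
                                self.mean_residence_free):
            raise ValueError(
                "sampling interval dt exceeds the shortest mean residence "
                "time; the discretised chain would be invalid")


def geometry_field_map(d, theta, field_scale: float = 60.0,
                       d_ref: float = 3.0):
    """Surrogate field projection (MV/cm) for a donor at (d, theta)."""
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return -field_scale * (d_ref / d) ** 2 * np.cos(np.radians(180.0 - theta))


def generate_calibration_grid(
        spec: GridSpec,
        vse: VSEParameters = DEFAULT_VSE,
        blue: BlueshiftParameters = CANONICAL_BLUESHIFT) -> pd.DataFrame:
    """Generate a calibration table from known ground-truth parameters.

    Frequencies are exact model evaluations (Stark term for the charge
    block, Stark plus blueshift surface for the donor block) plus the
    requested Gaussian noise; TDMs come from the linear TDM Stark relation.
    """
    rng = np.random.default_rng(spec.seed)

    dg, tg = np.meshgrid(
        np.linspace(*spec.d_range, spec.n_d),
        np.linspace(*spec.theta_range, spec.n_theta), indexing="ij")
    d_don, th_don = dg.ravel(), tg.ravel()
    f_don = geometry_field_map(d_don, th_don, spec.field_scale)
    nu_don = vse_frequency(f_don, vse) + blueshift_surface(d_don, th_don, blue)

    dg, tg = np.meshgrid(
        np.linspace(*spec.charge_d_range, spec.charge_n_d),
        np.linspace(*spec.theta_range, spec.charge_n_theta), indexing="ij")
    d_chg, th_chg = dg.ravel(), tg.ravel()
    f_chg = geometry_field_map(d_chg, th_chg, spec.field_scale)
    nu_chg = vse_frequency(f_chg, vse)

    field = np.concatenate([f_don, f_chg])
    nu = np.concatenate([nu_don, nu_chg])
    tdm = vse_tdm(field, vse)
    if spec.noise_sd_frequency > 0:
        nu = nu + rng.normal(0.0, spec.noise_sd_frequency, nu.size)
    if spec.noise_sd_tdm > 0:
        tdm = tdm + rng.normal(0.0, spec.noise_sd_tdm, tdm.size)

    donors = make_records(f_don, nu[: f_don.size], tdm[: f_don.size],
                          d=d_don, theta=th_don, label=spec.label)
    charges = make_records(f_chg, nu[f_don.size:], tdm[f_don.size:],
                           label=ELECTROSTATIC_LABEL)
    return pd.concat([donors, charges], ignore_index=True)


def simulate_hb_trajectory(spec: DynamicsSpec) -> pd.DataFrame:
    """Simulate a (field, HB geometry, occupancy) frame series.

    Occupancy follows the discretised two-state Markov chain with per-step
    switching probabilities ``1 - exp(-dt/tau)``; the stationary bound
    fraction is ``tau_hb / (tau_hb + tau_free)``.  While bound, the
    geometry is drawn about the configured mean (optionally along the
    anticorrelated d-theta trend); the angle is truncated to (70, 180].
    Unbound frames carry NaN geometry and occupancy 0.  Columns:
    ``time_fs, field, d, theta, hb_state``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    dt_ps = spec.dt * 1e-3

    p_unbind = -np.expm1(-dt_ps / spec.mean_residence_hb)
    p_bind = -np.expm1(-dt_ps / spec.mean_residence_free)
    occ_frac = spec.mean_residence_hb / (spec.mean_residence_hb
                                         + spec.mean_residence_free)
    u = rng.random(n)
    state = np.empty(n, dtype=np.int8)
    state[0] = (int(rng.random() < occ_frac) if spec.start_bound is None
                else int(spec.start_bound))
    # Sequential scan; the per-step flip threshold depends on the current
    # state (free -> binds with p_bind, bound -> unbinds with p_unbind).
    thresh = (p_bind, p_unbind)
    s = state[0]
    for i in range(1, n):
        if u[i] < thresh[s]:
            s = 1 - s
        state[i] = s

    theta = np.full(n, np.nan)
    d = np.full(n, np.nan)
    bound = state == 1
    nb = int(bound.sum())
    if nb:
        th = rng.normal(spec.hb_theta_mean, spec.hb_theta_sd, nb)
        th = np.clip(th, 70.0 + 1e-9, 180.0)
        if spec.use_d_theta_trend:
            # linear trend: 3.35 Å at 70 deg down to 2.93 Å head-on
            d_mean = 3.35 - 0.42 * (th - 70.0) / 110.0
        else:
            d_mean = spec.hb_d_mean
        dd = d_mean + rng.normal(0.0, spec.hb_d_sd, nb)
        theta[bound] = th
        d[bound] = np.clip(dd, 2.5, None)

    if spec.field_sd > 0:
        rho = np.exp(-dt_ps / spec.field_correlation_time)
        eps = rng.normal(0.0, spec.field_sd * np.sqrt(1 - rho ** 2), n)
        fld = np.empty(n)
        fld[0] = spec.field_mean + rng.normal(0.0, spec.field_sd)
        for i in range(1, n):
            fld[i] = (spec.field_mean
                      + rho * (fld[i - 1] - spec.field_mean) + eps[i])
    else:
        fld = np.full(n, spec.field_mean)

    return pd.DataFrame({
        "time_fs": np.arange(n, dtype=float) * spec.dt,
        "field": fld,
        "d": d,
        "theta": theta,
        "hb_state": state.astype(int),
    })


def field_from_point_charges(charges: Sequence[tuple[Sequence[float], float]],
                             cn_axis: Sequence[float],
                             probe_position: Sequence[float] = (0.0, 0.0, 0.0),
                             ) -> float:
    """Coulomb field projection on the C#N axis at the probe midpoint, MV/cm.

    ``charges`` is a sequence of ``(position_Å, charge_e)`` pairs.  Raises
    if any charge coincides with the probe position.
    """
    axis = np.asarray(cn_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("cn_axis must be non-zero")
    axis = axis / norm
    probe = np.asarray(probe_position, dtype=float)
    proj = 0.0
    for pos, q in charges:
        r = probe - np.asarray(pos, dtype=float)   # field points away from +q
        dist = np.linalg.norm(r)
        if dist < 1e-9:
            raise ValueError("charge coincides with the probe position")
        proj += COULOMB_MV_PER_CM * q * float(np.dot(r, axis)) / dist ** 3
    return proj
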