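"""Closed-form nitrile frequency and intensity models.

The C#N (nitrile) stretching frequency responds to its electrostatic
environment in two distinct ways.  In aprotic environments it follows the
vibrational Stark effect (VSE): the frequency shifts linearly (and weakly
quadratically) with the electric field projected onto the difference-dipole
axis of the vibration.  When the nitrile nitrogen accepts a hydrogen bond
(HB), an additional anomalous *blueshift* appears that no purely dipolar
field term reproduces.  This module evaluates both contributions:

* the dipolar VSE for the frequency and for the transition dipole moment
  (TDM), which governs IR absorption intensity and remains a faithful linear
  field probe even in H-bonded environments;
* an empirical HB blueshift surface written in terms of the heavy-atom HB
  distance ``d`` (nitrile N to donor O/N, Å) and the HB angle ``theta``
  (the C-N···donor angle at the nitrile nitrogen; 180 deg is a collinear,
  head-on HB, ~70-90 deg a side-on approach toward the pi system).

The blueshift surface blends a head-on power law (fixed exponent -4,
reminiscent of repulsive dipole-quadrupole electrostatics) with a side-on
Buckingham-like well (exponential repulsion minus a d^-8 attraction) through
a cosine angular factor whose period is compressed so that the blueshift
crosses zero for donors approaching the nitrile pi system near 70-80 deg:

    dnu(d, theta) = dnu_d0 * [ Theta(theta) * (d/d0)^n1
                               + (1 - Theta(theta)) * (exp(-b (d - d0))
                                                       - (d/d0)^n2) ]
    Theta(theta)  = cos(m * (180 deg - theta))

``dnu_d0`` is the head-on blueshift at the reference distance ``d0``, chosen
as the zero crossing of the Buckingham-like side-on term.  Two simultaneous
HBs act additively.

Units are fixed package-wide: cm^-1, Å, degrees, MV/cm and Debye.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "ExtrapolationWarning",
    "FieldVector",
    "VSEParameters",
    "HBGeometry",
    "BlueshiftParameters",
    "ProbeState",
    "CANONICAL_BLUESHIFT",
    "DEFAULT_VSE",
    "EXPERIMENTAL_OCNF_VSE",
    "vse_frequency",
    "vse_tdm",
    "angular_factor",
    "headon_term",
    "sideon_term",
    "hb_blueshift",
    "blueshift_surface",
    "total_frequency",
]

#: Valid heavy-atom distance window of the calibrated blueshift surface (Å).
#: Below 2.5 Å the Buckingham-like term turns over unphysically; beyond
#: ~5 Å the surface is near zero and by 8 Å entirely negligible.
CALIBRATED_D_RANGE = (2.5, 8.0)


class ExtrapolationWarning(UserWarning):
    """Raised (as a warning) when the blueshift surface is evaluated outside
    the heavy-atom distance window it was calibrated on."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return arr


def _maybe_scalar(arr: np.ndarray, scalar_in: bool):
    return float(arr) if scalar_in else arr


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldVector:
    """Electric field at the nitrile, MV/cm.

    Parameters
    ----------
    components
        Cartesian field vector (3,), MV/cm.
    cn_axis
        Direction of the difference dipole, conventionally the C->N bond
        direction.  Need not be normalised.

    Notes
    -----
    The scalar that enters the VSE expressions is the projection of the
    field onto the unit ``cn_axis``.  The sign convention is such that the
    (negative) fields exerted by H-bond donors and polar solvents *lower*
    the frequency for a positive Stark tuning rate.
    """

    components: tuple[float, float, float]
    cn_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        comp = _as_float_array(self.components, "field components")
        axis = _as_float_array(self.cn_axis, "cn_axis")
        if comp.shape != (3,) or axis.shape != (3,):
            raise ValueError("components and cn_axis must be 3-vectors")
        if np.linalg.norm(axis) == 0:
            raise ValueError("cn_axis must be non-zero")

    @property
    def projection_on_cn(self) -> float:
        """Field projection on the unit C->N direction, MV/cm."""
        axis = np.asarray(self.cn_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        return float(np.dot(np.asarray(self.components, dtype=float), axis))


@dataclass(frozen=True)
class VSEParameters:
    """Vibrational Stark effect parameters of one nitrile probe.

    Attributes
    ----------
    nu0 : float
        Zero-field frequency, cm^-1.
    dmu : float
        Stark tuning rate (difference-dipole magnitude), cm^-1/(MV/cm).
        Positive, with the field-sign convention of :class:`FieldVector`.
    dalpha : float
        Difference polarizability, cm^-1/(MV/cm)^2; quadratic field
        sensitivity, usually negligible.
    tdm0 : float
        Zero-field transition dipole magnitude, D.
    tdm_polarizability : float
        Linear field sensitivity of the TDM, D/(MV/cm).
    """

    nu0: float
    dmu: float
    dalpha: float = 0.0
    tdm0: float = 0.05
    tdm_polarizability: float = 0.0

    def __post_init__(self) -> None:
        if not (self.nu0 > 0):
            raise ValueError(f"nu0 must be positive, got {self.nu0}")
        if not (self.tdm0 > 0):
            raise ValueError(f"tdm0 must be positive, got {self.tdm0}")
        for name in ("nu0", "dmu", "dalpha", "tdm0", "tdm_polarizability"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class HBGeometry:
    """One C#N···donor hydrogen-bond contact.

    ``d`` is the heavy-atom distance N(nitrile)···O/N(donor) in Å; ``theta``
    the C-N···donor angle at the nitrile N in degrees (collinear head-on
    contact = 180).  Heavy atoms are used throughout
    because hydrogen positions are unreliable in both constrained MD and
    crystal structures.
    """

    d: float
    theta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d) and self.d > 0):
            raise ValueError(f"HB distance must be positive, got {self.d}")
        if not (np.isfinite(self.theta) and 0 < self.theta <= 180):
            raise ValueError(
                f"HB angle must lie in (0, 180] degrees, got {self.theta}"
            )


@dataclass(frozen=True)
class BlueshiftParameters:
    """Parameters of the HB-geometry-dependent blueshift surface.

    Defaults are the canonical optimized values (see module docstring for
    the functional form).  ``n1`` and ``n2`` are fixed integer exponents in
    the canonical model; ``a`` is the decay constant of the alternative
    exponential head-on law, selectable but non-default.
    """

    d0: float = 3.36          # Å, zero crossing of the side-on term
    dnu_d0: float = 16.6      # cm^-1, head-on blueshift at d0
    b: float = 2.85           # Å^-1, side-on exponential decay
    m: float = 0.91           # dimensionless cosine period modulation
    n1: int = -4              # head-on power-law exponent
    n2: int = -8              # side-on attractive power exponent
    a: float = 1.30           # Å^-1, exponential head-on variant decay

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError(f"d0 must be positive, got {self.d0}")
        if not (self.b > 0):
            raise ValueError(f"b must be positive, got {self.b}")
        if not (0 < self.m <= 1.2):
            raise ValueError(f"m must lie in (0, 1.2], got {self.m}")
        if not (self.a > 0):
            raise ValueError(f"a must be positive, got {self.a}")

    def replace(self, **kwargs) -> "BlueshiftParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ProbeState:
    """Instantaneous environment of one nitrile probe: the electric-field
    projection on the C#N axis plus zero, one or two HB contacts."""

    field: Union[float, FieldVector]
    hbs: tuple[HBGeometry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "hbs", tuple(self.hbs))
        if len(self.hbs) > 2:
            raise ValueError(
                "at most two simultaneous HBs are supported; additivity has "
                f"only been validated up to two contacts (got {len(self.hbs)})"
            )

    @property
    def field_projection(self) -> float:
        if isinstance(self.field, FieldVector):
            return self.field.projection_on_cn
        return float(self.field)


#: Canonical blueshift surface parameters.
CANONICAL_BLUESHIFT = BlueshiftParameters()

#: Default VSE parameters for an o-tolunitrile-like aromatic nitrile:
#: gas-phase frequency 2232 cm^-1, tuning rate 0.2748 cm^-1/(MV/cm);
#: TDM grows toward more negative (solvent-like) fields.
DEFAULT_VSE = VSEParameters(
    nu0=2232.0, dmu=0.2748, dalpha=0.0, tdm0=0.048,
    tdm_polarizability=-1.5e-4,
)

#: Experimentally anchored VSE line for the o-cyanophenylalanine probe in a
#: protein host (zero-field frequency and tuning rate reproduce the
#: reference peak positions 2215.5 cm^-1 at -78 MV/cm and 2219.1 cm^-1 at
#: -64.9 MV/cm).
EXPERIMENTAL_OCNF_VSE = VSEParameters(
    nu0=2236.9, dmu=0.2748, dalpha=0.0, tdm0=0.048,
    tdm_polarizability=-1.5e-4,
)


# ---------------------------------------------------------------------------
# VSE terms
# ---------------------------------------------------------------------------


def vse_frequency(field_projection, params: VSEParameters):
    """Nitrile frequency from the dipolar VSE alone, cm^-1.

    ``nu = nu0 + dmu * F + dalpha/2 * F**2`` with ``F`` the field projection
    on the C#N axis in MV/cm.  With ``dalpha = 0`` this is the familiar
    linear Stark relation.  Negative (solvent-like) fields red-shift the
    band for positive ``dmu``.
    """
    scalar = np.ndim(field_projection) == 0
    f = _as_float_array(field_projection, "field projection")
    nu = params.nu0 + params.dmu * f + 0.5 * params.dalpha * f ** 2
    return _maybe_scalar(nu, scalar)


def vse_tdm(field_projection, params: VSEParameters):
    """Transition dipole magnitude from the linear VSE, D.

    ``|mu01|(F) = tdm0 + tdm_polarizability * F``.  Monotone in the field
    for non-zero polarizability; the intensity of the IR band scales with
    its square.
    """
    scalar = np.ndim(field_projection) == 0
    f = _as_float_array(field_projection, "field projection")
    tdm = params.tdm0 + params.tdm_polarizability * f
    return _maybe_scalar(tdm, scalar)


# ---------------------------------------------------------------------------
# HB blueshift surface
# ---------------------------------------------------------------------------


def angular_factor(theta, m: float = CANONICAL_BLUESHIFT.m):
    """Angular modulation ``Theta = cos(m * (180 - theta))``, dimensionless.

    Normalised to 1 for a head-on HB (theta = 180 deg) and strictly
    increasing on [70, 180].  The period modulation ``m`` places the zero
    crossing at ``180 - 90/m`` degrees: 70.2 deg for m = 0.82 (where a donor
    engages the nitrile pi orbitals) and 81.1 deg for the canonical
    m = 0.91.
    """
    scalar = np.ndim(theta) == 0
    th = _as_float_array(theta, "theta")
    if np.any((th <= 0) | (th > 180)):
        raise ValueError(f"theta must lie in (0, 180] degrees, got {theta!r}")
    out = np.cos(np.radians(m * (180.0 - th)))
    return _maybe_scalar(out, scalar)


def headon_term(d, params: BlueshiftParameters = CANONICAL_BLUESHIFT,
                variant: str = "power"):
    """Head-on (theta = 180 deg) blueshift vs distance, cm^-1.

    ``variant="power"`` (canonical): ``dnu_d0 * (d/d0)**n1`` with the fixed
    exponent n1 = -4.  ``variant="exponential"``: ``dnu_d0 *
    exp(-a*(d - d0))`` — an equally good description of head-on data that
    would instead point at Pauli repulsion, kept for comparison.  Both decay
    strictly monotonically to zero.
    """
    scalar = np.ndim(d) == 0
    dd = _as_float_array(d, "d")
    if np.any(dd <= 0):
        raise ValueError(f"d must be positive, got {d!r}")
    if variant == "power":
        out = params.dnu_d0 * (dd / params.d0) ** float(params.n1)
    elif variant == "exponential":
        out = params.dnu_d0 * np.exp(-params.a * (dd - params.d0))
    else:
        raise ValueError(f"unknown head-on variant {variant!r}")
    return _maybe_scalar(out, scalar)


def _sideon(d: np.ndarray, params: BlueshiftParameters) -> np.ndarray:
    # Buckingham-like shape, no validity guard; callers guard or warn.
    return params.dnu_d0 * (
        np.exp(-params.b * (d - params.d0)) - (d / params.d0) ** float(params.n2)
    )


def sideon_term(d, params: BlueshiftParameters = CANONICAL_BLUESHIFT):
    """Side-on (theta ~ 70 deg) blueshift vs distance, cm^-1.

    Buckingham-like: ``dnu_d0 * (exp(-b*(d - d0)) - (d/d0)**n2)`` with
    n2 = -8.  Crosses zero at the reference distance ``d0``, passes through
    a shallow negative well at intermediate distance (attractive induced
    higher-multipole interactions, i.e. a small redshift) and vanishes at
    long range.

    Raises
    ------
    ValueError
        For d < 2.5 Å, where the Buckingham-like shape turns over and
        becomes unphysical (lower validity bound of the calibration).
    """
    scalar = np.ndim(d) == 0
    dd = _as_float_array(d, "d")
    if np.any(dd < CALIBRATED_D_RANGE[0]):
        raise ValueError(
            "side-on Buckingham-like term is unphysical below the 2.5 Å "
            f"validity bound, got d={d!r}"
        )
    return _maybe_scalar(_sideon(dd, params), scalar)


def blueshift_surface(d, theta,
                      params: BlueshiftParameters = CANONICAL_BLUESHIFT,
                      headon_variant: str = "power"):
    """Vectorised HB blueshift, cm^-1, for arrays of (d, theta).

    Evaluates the combined surface (module docstring).  Outside the
    calibrated heavy-atom distance window [2.5, 8] Å the value is still
    returned (the functional form extends smoothly and decays to zero) but
    an :class:`ExtrapolationWarning` is emitted.
    """
    scalar = np.ndim(d) == 0 and np.ndim(theta) == 0
    dd = _as_float_array(d, "d")
    th = _as_float_array(theta, "theta")
    if np.any(dd <= 0):
        raise ValueError(f"d must be positive, got {d!r}")
    if np.any((th <= 0) | (th > 180)):
        raise ValueError(f"theta must lie in (0, 180] degrees, got {theta!r}")
    lo, hi = CALIBRATED_D_RANGE
    if np.any((dd < lo) | (dd > hi)):
        warnings.warn(
            f"HB distance outside the calibrated window [{lo}, {hi}] Å; "
            "blueshift extrapolated from the fitted functional form",
            ExtrapolationWarning,
            stacklevel=2,
        )
    thf = angular_factor(th, params.m)
    head = headon_term(dd, params, variant=headon_variant)
    side = _sideon(np.maximum(dd, 1e-12), params)
    out = thf * head + (1.0 - thf) * side
    return _maybe_scalar(out, scalar)


def hb_blueshift(geom: HBGeometry,
                 params: BlueshiftParameters = CANONICAL_BLUESHIFT,
                 headon_variant: str = "power") -> float:
    """HB blueshift for a single validated contact geometry, cm^-1."""
    return float(blueshift_surface(geom.d, geom.theta, params,
                                   headon_variant=headon_variant))


def total_frequency(state: ProbeState, vse: VSEParameters,
                    blue: BlueshiftParameters = CANONICAL_BLUESHIFT) -> float:
    """Total nitrile frequency: VSE term plus one blueshift per HB, cm^-1.

    Each H-bonding interaction contributes independently, so with two
    contacts the blueshifts simply add; with no contact this reduces
    exactly to :func:`vse_frequency`.
    """
    nu = vse_frequency(state.field_projection, vse)
    for geom in state.hbs:
        nu += hb_blueshift(geom, blue)
    return float(nu)
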