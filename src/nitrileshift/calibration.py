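"""Fitting the VSE and blueshift models to calibration tables.

A calibration table holds one row per probe configuration: the electric
field projected on the C#N axis, the HB heavy-atom geometry (absent for
purely electrostatic configurations such as point charges), the observed
frequency and TDM, and an environment label.  The workflow mirrors how the
models are calibrated against quantum-chemical reference data:

1. scale raw frequencies/TDMs to the experimental zero-field observables;
2. fit the TDM Stark relation on everything (it holds with and without HBs);
3. fit the frequency Stark relation on the purely electrostatic subset
   (it fails, often with negative R^2, on H-bonded configurations);
4. read off per-configuration blueshifts as the deviation of the observed
   frequency from that electrostatic-only Stark line;
5. fit the head-on, side-on and angular laws to slices of those blueshifts,
   and finally fit the full frequency model (Stark + blueshift surface)
   jointly on all configurations.

Tables are plain pandas DataFrames with the columns in :data:`COLUMNS`;
``d``/``theta`` are NaN for purely electrostatic rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .stark import (
    CANONICAL_BLUESHIFT,
    BlueshiftParameters,
    VSEParameters,
    blueshift_surface,
    vse_frequency,
    vse_tdm,
)

__all__ = [
    "COLUMNS",
    "FREQUENCY_SCALE",
    "TDM_SCALE",
    "FitReport",
    "apply_scaling",
    "make_records",
    "fit_vse_tdm",
    "fit_vse_frequency",
    "score_vse_frequency",
    "extract_blueshifts",
    "fit_headon",
    "fit_sideon",
    "fit_angular",
    "fit_joint",
    "goodness",
    "goodness_identity",
]

#: Column layout of a calibration table.
COLUMNS = ("field", "d", "theta", "frequency", "tdm", "label")

#: Harmonic-frequency and TDM scaling factors that bring raw
#: quantum-chemical values onto the experimental zero-field observables.
FREQUENCY_SCALE = 0.9598
TDM_SCALE = 0.4464

ELECTROSTATIC_LABEL = "point_charge"


@dataclass
class FitReport:
    """Result of one least-squares calibration fit."""

    parameters: dict
    stderr: dict
    r_squared: float
    rmsd: float
    n_points: int
    r_squared_by_label: dict = dataclass_field(default_factory=dict)
    rmsd_by_label: dict = dataclass_field(default_factory=dict)
    extras: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def to_text(self) -> str:
        lines = [f"n_points\t{self.n_points}",
                 f"r_squared\t{self.r_squared:.6g}",
                 f"rmsd\t{self.rmsd:.6g}"]
        for k, v in self.parameters.items():
            se = self.stderr.get(k)
            se_txt = f"{se:.3g}" if se is not None and np.isfinite(se) else "n/a"
            lines.append(f"param\t{k}\t{v:.8g}\t+-\t{se_txt}")
        for k, v in sorted(self.r_squared_by_label.items()):
            lines.append(f"r_squared[{k}]\t{v:.6g}")
        for k, v in sorted(self.rmsd_by_label.items()):
            lines.append(f"rmsd[{k}]\t{v:.6g}")
        for k, v in self.extras.items():
            lines.append(f"{k}\t{v}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Plumbing
# ---------------------------------------------------------------------------


def apply_scaling(frequency_raw, tdm_raw,
                  frequency_scale: float = FREQUENCY_SCALE,
                  tdm_scale: float = TDM_SCALE):
    """Scale raw (harmonic) frequencies and TDMs to experimental anchors."""
    freq = np.asarray(frequency_raw, dtype=float)
    tdm = np.asarray(tdm_raw, dtype=float)
    if np.any(freq <= 0) or np.any(tdm <= 0):
        raise ValueError("raw frequencies and TDMs must be positive")
    out_f, out_t = freq * frequency_scale, tdm * tdm_scale
    if np.ndim(frequency_raw) == 0:
        out_f = float(out_f)
    if np.ndim(tdm_raw) == 0:
        out_t = float(out_t)
    return out_f, out_t


def make_records(field, frequency, tdm, d=None, theta=None,
                 label: str = "water") -> pd.DataFrame:
    """Assemble a calibration table from per-configuration arrays."""
    field = np.asarray(field, dtype=float)
    n = field.size
    df = pd.DataFrame({
        "field": field,
        "d": np.full(n, np.nan) if d is None else np.asarray(d, dtype=float),
        "theta": (np.full(n, np.nan) if theta is None
                  else np.asarray(theta, dtype=float)),
        "frequency": np.asarray(frequency, dtype=float),
        "tdm": np.asarray(tdm, dtype=float),
        "label": label,
    })
    _validate_records(df)
    return df


def _validate_records(df: pd.DataFrame) -> None:
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calibration table misses columns {sorted(missing)}")
    if (df["frequency"] <= 0).any() or (df["tdm"] <= 0).any():
        raise ValueError("frequencies and TDMs must be positive")


def _is_hbonded(df: pd.DataFrame) -> pd.Series:
    return df["d"].notna() & df["theta"].notna()


# ---------------------------------------------------------------------------
# Goodness-of-fit conventions
# ---------------------------------------------------------------------------


def goodness(observed, predicted) -> tuple[float, float]:
    """(R^2, RMSD) of a fit, with R^2 about the mean of ``observed``.

    ``R^2 = 1 - SS_res / SS_tot`` may be negative when the model does worse
    than predicting the mean.  RMSD is the root-mean-square residual and is
    symmetric under exchanging the two sequences.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-d")
    if obs.size < 2:
        raise ValueError("need at least two points")
    resid = obs - pred
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return r2, float(np.sqrt(np.mean(resid ** 2)))


def goodness_identity(observed, predicted) -> tuple[float, float]:
    """(R^2, RMSD) of predicted-vs-observed points scored about the
    identity line (slope 1, intercept 0).

    Residuals are ``predicted - observed``; the total sum of squares is
    taken about the mean of the *predicted* values, i.e. the predictions
    play the role of the dependent variable plotted against the observed
    ones.  This is the convention for observed-vs-predicted benchmark
    comparisons; use :func:`goodness` for model-vs-data fit quality.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-d")
    if obs.size < 2:
        raise ValueError("need at least two points")
    resid = pred - obs
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((pred - pred.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return r2, float(np.sqrt(np.mean(resid ** 2)))


def _per_label(df: pd.DataFrame, resid: np.ndarray) -> tuple[dict, dict]:
    r2s, rmsds = {}, {}
    obs = df["frequency"].to_numpy() if "frequency" in df else None
    for label, idx in df.groupby("label").groups.items():
        loc = df.index.get_indexer(idx)
        if len(loc) >= 2 and obs is not None:
            r2s[label], rmsds[label] = goodness(obs[loc], obs[loc] - resid[loc])
    return r2s, rmsds


# ---------------------------------------------------------------------------
# Stark fits
# ---------------------------------------------------------------------------


def fit_vse_tdm(records: pd.DataFrame, quadratic: bool = True) -> FitReport:
    """Fit the TDM Stark relation jointly over all environments.

    Linear by default plus an optional quadratic field term.  Reports the
    overall R^2/RMSD and the per-environment-label R^2 — for nitriles the
    TDM relation holds in purely electrostatic *and* H-bonding
    environments, so all subsets should score highly.
    """
    _validate_records(records)
    f = records["field"].to_numpy()
    y = records["tdm"].to_numpy()
    if records.shape[0] < 4 or np.unique(f).size < (3 if quadratic else 2):
        raise ValueError("need >= 4 records with distinct fields")
    order = 2 if quadratic else 1
    design = np.vander(f, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ coef
    resid = y - pred
    dof = max(y.size - coef.size, 1)
    cov = np.linalg.pinv(design.T @ design) * float(np.sum(resid ** 2)) / dof
    names = ["tdm0", "tdm_polarizability", "tdm_quadratic"][: order + 1]
    r2, rmsd = goodness(y, pred)
    r2_by = {}
    for label, sub in records.groupby("label"):
        if sub.shape[0] >= 2:
            r2_by[label] = goodness(sub["tdm"].to_numpy(),
                                    np.vander(sub["field"].to_numpy(),
                                              order + 1, increasing=True) @ coef)[0]
    return FitReport(
        parameters=dict(zip(names, map(float, coef))),
        stderr=dict(zip(names, np.sqrt(np.diag(cov)))),
        r_squared=r2, rmsd=rmsd, n_points=int(y.size),
        r_squared_by_label=r2_by,
    )


def fit_vse_frequency(records: pd.DataFrame,
                      subset: Optional[str] = ELECTROSTATIC_LABEL,
                      quadratic: bool = True) -> FitReport:
    """Fit the frequency Stark relation on one environment subset.

    The fit normally uses the purely electrostatic subset — the only regime
    in which the dipolar VSE describes nitrile frequencies.  The returned
    report also scores every *other* environment subset with the fitted
    parameters (``r_squared_by_label``); H-bonded subsets typically come
    out strongly negative because the blueshift is unilateral.
    """
    _validate_records(records)
    sub = records if subset is None else records[records["label"] == subset]
    f = sub["field"].to_numpy()
    y = sub["frequency"].to_numpy()
    if np.unique(f).size < 2:
        raise ValueError(
            "rank-deficient design: all fields identical in the fit subset"
        )
    order = 2 if (quadratic and np.unique(f).size >= 3) else 1
    design = np.vander(f, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ coef
    resid = y - pred
    dof = max(y.size - coef.size, 1)
    cov = np.linalg.pinv(design.T @ design) * float(np.sum(resid ** 2)) / dof
    params = VSEParameters(
        nu0=float(coef[0]), dmu=float(coef[1]),
        dalpha=float(2 * coef[2]) if order == 2 else 0.0,
        tdm0=1.0, tdm_polarizability=0.0,
    )
    names = ["nu0", "dmu", "dalpha"]
    values = [params.nu0, params.dmu, params.dalpha]
    errs = list(np.sqrt(np.diag(cov)))
    if order == 2:
        errs[2] *= 2
    else:
        errs.append(np.nan)
    r2, rmsd = goodness(y, pred)
    r2_by, rmsd_by = {}, {}
    for label, other in records.groupby("label"):
        if other.shape[0] >= 2:
            r2_by[label], rmsd_by[label] = score_vse_frequency(other, params)
    return FitReport(
        parameters=dict(zip(names, values)),
        stderr=dict(zip(names, errs)),
        r_squared=r2, rmsd=rmsd, n_points=int(y.size),
        r_squared_by_label=r2_by, rmsd_by_label=rmsd_by,
        extras={"vse_parameters": params, "subset": subset},
    )


def score_vse_frequency(records: pd.DataFrame,
                        params: VSEParameters) -> tuple[float, float]:
    """(R^2, RMSD) of given Stark parameters applied unchanged to records."""
    pred = vse_frequency(records["field"].to_numpy(), params)
    return goodness(records["frequency"].to_numpy(), pred)


def extract_blueshifts(records: pd.DataFrame,
                       vse_params: VSEParameters) -> np.ndarray:
    """Per-record HB blueshift: observed frequency minus the Stark line.

    For purely electrostatic records this is a residual scattered about
    zero; for H-bonded records it is the geometric blueshift itself (plus
    whatever noise the frequencies carry).
    """
    _validate_records(records)
    return records["frequency"].to_numpy() - vse_frequency(
        records["field"].to_numpy(), vse_params)


# ---------------------------------------------------------------------------
# Blueshift-law fits
# ---------------------------------------------------------------------------


def _check_points(d, y, minimum: int) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("need equal-length 1-d abscissae and values")
    if d.size < minimum:
        raise ValueError(f"need at least {minimum} points, got {d.size}")
    if np.unique(d).size < minimum:
        raise ValueError("degenerate abscissae")
    return d, y


def fit_headon(d, blueshift, variant: str = "power") -> FitReport:
    """Fit the head-on distance law to (d, blueshift) points.

    ``variant="power"``: ``amp * d**n`` (log-log linear; reports the free
    exponent ``n``, which should come out near -4 for head-on HB data).
    ``variant="exponential"``: ``amp0 * exp(-a*d)`` (log-linear; decay
    constant near 1.3 Å^-1).  Points must be positive for the implicit log
    transform; the returned R^2/RMSD are computed on the original scale.
    """
    d, y = _check_points(d, blueshift, 3)
    if np.any(y <= 0):
        raise ValueError("head-on blueshifts must be positive to fit decays")
    if variant not in ("power", "exponential"):
        raise ValueError(f"unknown head-on variant {variant!r}")
    # log-linear initialisation, then ordinary least squares on the
    # original scale (the log transform would over-weight the tail)
    X = np.log(d) if variant == "power" else d
    slope, intercept = np.polyfit(X, np.log(y), 1)
    if variant == "power":
        def model(x):
            return x[0] * d ** x[1]
        x0 = [np.exp(intercept), slope]
    else:
        def model(x):
            return x[0] * np.exp(-x[1] * d)
        x0 = [np.exp(intercept), -slope]
    res = optimize.least_squares(lambda x: model(x) - y, x0,
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    pred = model(res.x)
    key = "n1" if variant == "power" else "a"
    params = {"amplitude": float(res.x[0]), key: float(res.x[1])}
    r2, rmsd = goodness(y, pred)
    stderr = _lsq_stderr(res, y.size)
    return FitReport(parameters=params,
                     stderr={"amplitude": float(stderr[0]),
                             key: float(stderr[1])},
                     r_squared=r2, rmsd=rmsd, n_points=int(d.size),
                     extras={"variant": variant})


def _buckingham(d, amp, b, d0, n2):
    return amp * (np.exp(-b * (d - d0)) - (d / d0) ** n2)


def fit_sideon(d, blueshift, n2: float = -8.0,
               two_power: bool = False) -> FitReport:
    """Fit the side-on Buckingham-like law to (d, blueshift) points.

    Free parameters: amplitude, exponential decay ``b`` and zero crossing
    ``d0`` (``n2`` fixed by default).  With ``two_power=True`` the single
    power term is replaced by two independent power terms with free
    exponents — for data generated by a single power law both converge to
    the same exponent.  Multi-start nonlinear least squares from a small
    deterministic grid; non-convergence raises with diagnostics.
    """
    d, y = _check_points(d, blueshift, 4)
    if np.any(d < 2.5):
        raise ValueError("side-on fit requires d >= 2.5 Å (validity bound)")

    if not two_power:
        def model(x):
            amp, b, d0 = x
            return _buckingham(d, amp, b, d0, n2)
        starts = [(a0, b0, d00)
                  for a0 in (5.0, 20.0, 50.0)
                  for b0 in (1.5, 3.0)
                  for d00 in (3.0, 3.4, 3.8)]
        names = ["amplitude", "b", "d0"]
        bounds = ([1e-6, 0.1, 2.5], [1e4, 20.0, 8.0])
    else:
        # power terms normalised at 3 Å so their amplitudes stay O(10)
        def model(x):
            amp, b, d0, c1, p1, c2, p2 = x
            return (amp * np.exp(-b * (d - d0))
                    - c1 * (d / 3.0) ** p1 - c2 * (d / 3.0) ** p2)
        scale = max(float(np.abs(y).max()), 1.0)
        starts = [(20.0, b0, 3.4, 0.7 * scale, -6.0, 0.7 * scale, -10.0)
                  for b0 in (2.0, 3.2)]
        names = ["amplitude", "b", "d0", "c1", "p1", "c2", "p2"]
        bounds = ([1e-6, 0.1, 2.5, 0, -15, 0, -15],
                  [1e4, 20.0, 8.0, 1e4, -2, 1e4, -2])

    best, best_cost = None, np.inf
    diagnostics = []
    for x0 in starts:
        try:
            res = optimize.least_squares(
                lambda x: model(x) - y, x0, bounds=bounds,
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20000)
        except Exception as err:  # pragma: no cover - defensive
            diagnostics.append(f"start {x0}: {err}")
            continue
        if res.success and res.cost < best_cost:
            best, best_cost = res, res.cost
        elif not res.success:
            diagnostics.append(f"start {x0}: {res.message}")
    if best is None:
        raise RuntimeError(
            "side-on fit failed to converge from every start:\n"
            + "\n".join(diagnostics))
    pred = model(best.x)
    r2, rmsd = goodness(y, pred)
    stderr = _lsq_stderr(best, y.size)
    report = FitReport(parameters=dict(zip(names, map(float, best.x))),
                       stderr=dict(zip(names, stderr)),
                       r_squared=r2, rmsd=rmsd, n_points=int(d.size),
                       extras={"n2": n2, "two_power": two_power})
    if not two_power:
        report.extras["zero_crossing"] = float(best.x[2])
    return report


def fit_angular(theta, blueshift) -> FitReport:
    """Fit the angular law ``y0 * cos(m*(180 - theta))`` at fixed distance.

    Reports the period modulation ``m`` and the implied zero-crossing angle
    ``180 - 90/m`` degrees.  Requires the sampled angles to span at least
    60 degrees so the period is identifiable.
    """
    th, y = _check_points(theta, blueshift, 4)
    if np.ptp(th) < 60:
        raise ValueError("angular fit needs a theta span of >= 60 degrees")

    def model(x):
        y0, m = x
        return y0 * np.cos(np.radians(m * (180.0 - th)))

    best, best_cost = None, np.inf
    for m0 in (0.7, 0.85, 1.0, 1.15):
        res = optimize.least_squares(
            lambda x: model(x) - y, [max(y.max(), 1.0), m0],
            bounds=([1e-9, 0.3], [1e4, 1.2]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if res.success and res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None:
        raise RuntimeError("angular fit failed to converge")
    pred = model(best.x)
    r2, rmsd = goodness(y, pred)
    stderr = _lsq_stderr(best, y.size)
    m = float(best.x[1])
    return FitReport(
        parameters={"y0": float(best.x[0]), "m": m},
        stderr=dict(zip(["y0", "m"], stderr)),
        r_squared=r2, rmsd=rmsd, n_points=int(th.size),
        extras={"zero_crossing_deg": 180.0 - 90.0 / m},
    )


def _lsq_stderr(res, n: int) -> np.ndarray:
    """Asymptotic standard errors from a scipy least_squares result."""
    dof = max(n - res.x.size, 1)
    try:
        jtj_inv = np.linalg.pinv(res.jac.T @ res.jac)
        return np.sqrt(np.diag(jtj_inv) * 2 * res.cost / dof)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full(res.x.size, np.nan)


# ---------------------------------------------------------------------------
# Joint fit
# ---------------------------------------------------------------------------


def fit_joint(records: pd.DataFrame, quadratic: bool = True) -> FitReport:
    """Simultaneously fit Stark + blueshift surface to all records.

    Free parameters: nu0, dmu (and dalpha when ``quadratic``) plus the four
    surface parameters (d0, dnu_d0, b, m); the power-law exponents stay at
    their canonical integers.  Purely electrostatic records constrain the
    Stark part; H-bonded records constrain the surface.  Multi-start from a
    deterministic grid over (d0, m, b); per-environment residual statistics
    are reported alongside the overall R^2/RMSD.
    """
    _validate_records(records)
    hb = _is_hbonded(records)
    if not hb.any() or hb.all():
        raise ValueError(
            "joint fit needs both electrostatic and H-bonded records")
    f = records["field"].to_numpy()
    y = records["frequency"].to_numpy()
    d = records["d"].to_numpy()
    th = records["theta"].to_numpy()
    mask = hb.to_numpy()

    # Stark-only initial guesses from the electrostatic subset
    design = np.vander(f[~mask], 3 if quadratic else 2, increasing=True)
    coef0, *_ = np.linalg.lstsq(design, y[~mask], rcond=None)

    def predict(x):
        if quadratic:
            nu0, dmu, dalpha, d0, dnu_d0, b, m = x
        else:
            nu0, dmu, d0, dnu_d0, b, m = x
            dalpha = 0.0
        pred = nu0 + dmu * f + 0.5 * dalpha * f ** 2
        thf = np.cos(np.radians(m * (180.0 - th[mask])))
        dd = d[mask]
        head = dnu_d0 * (dd / d0) ** -4.0
        side = dnu_d0 * (np.exp(-b * (dd - d0)) - (dd / d0) ** -8.0)
        out = pred.copy()
        out[mask] += thf * head + (1.0 - thf) * side
        return out

    lo = [0.0, -5.0] + ([-1.0] if quadratic else []) + [2.6, 0.1, 0.2, 0.3]
    hi = [5000.0, 5.0] + ([1.0] if quadratic else []) + [6.0, 200.0, 20.0, 1.2]
    starts = []
    for d00, m0, b0 in itertools.product((3.0, 3.4, 3.8), (0.8, 1.0), (2.0, 3.2)):
        base = [float(coef0[0]), float(coef0[1])]
        if quadratic:
            base.append(float(2 * coef0[2]) if coef0.size > 2 else 0.0)
        starts.append(base + [d00, 15.0, b0, m0])

    best, best_cost = None, np.inf
    messages = []
    for x0 in starts:
        res = optimize.least_squares(
            lambda x: predict(x) - y, x0, bounds=(lo, hi),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=40000)
        if res.success and res.cost < best_cost:
            best, best_cost = res, res.cost
        elif not res.success:
            messages.append(res.message)
    if best is None:
        raise RuntimeError("joint fit failed to converge: "
                           + "; ".join(sorted(set(messages))))
    pred = predict(best.x)
    resid = y - pred
    r2, rmsd = goodness(y, pred)
    if quadratic:
        names = ["nu0", "dmu", "dalpha", "d0", "dnu_d0", "b", "m"]
    else:
        names = ["nu0", "dmu", "d0", "dnu_d0", "b", "m"]
    stderr = _lsq_stderr(best, y.size)
    r2_by, rmsd_by = {}, {}
    for label, sub in records.groupby("label"):
        loc = records.index.get_indexer(sub.index)
        if len(loc) >= 2:
            r2_by[label], rmsd_by[label] = goodness(y[loc], pred[loc])
    pdict = dict(zip(names, map(float, best.x)))
    blue = CANONICAL_BLUESHIFT.replace(
        d0=pdict["d0"], dnu_d0=pdict["dnu_d0"], b=pdict["b"], m=pdict["m"])
    vse = VSEParameters(nu0=pdict["nu0"], dmu=pdict["dmu"],
                        dalpha=pdict.get("dalpha", 0.0),
                        tdm0=1.0, tdm_polarizability=0.0)
    return FitReport(
        parameters=pdict, stderr=dict(zip(names, stderr)),
        r_squared=r2, rmsd=rmsd, n_points=int(y.size),
        r_squared_by_label=r2_by, rmsd_by_label=rmsd_by,
        extras={"blueshift_parameters": blue, "vse_parameters": vse,
                "residual_range": (float(resid.min()), float(resid.max()))},
    )
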