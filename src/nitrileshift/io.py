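"""Delimited-text readers/writers and the parameter config format.

All tables are tab-separated with a mandatory header; spectra are
two-column text with ``#`` comment headers and an optional JSON peak
sidecar.  Parameter configs are YAML with ``vse`` and ``blueshift``
sections whose field names match the model symbols.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np
import pandas as pd
import yaml

from .calibration import COLUMNS, FitReport, _validate_records
from .lineshape import Spectrum
from .stark import (
    CANONICAL_BLUESHIFT,
    DEFAULT_VSE,
    BlueshiftParameters,
    VSEParameters,
)

__all__ = [
    "read_calibration_table", "write_calibration_table",
    "read_trajectory_table", "write_trajectory_table",
    "read_spectrum", "write_spectrum",
    "load_params", "dump_params", "default_params",
    "write_fit_report",
]

TRAJECTORY_COLUMNS = ("time_fs", "field", "d", "theta", "hb_state")

PathLike = Union[str, Path]


def write_calibration_table(df: pd.DataFrame, path: PathLike) -> None:
    _validate_records(df)
    df.loc[:, COLUMNS].to_csv(path, sep="\t", index=False,
                              float_format="%.10g", na_rep="nan")


def read_calibration_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _validate_records(df)
    return df


def write_trajectory_table(df: pd.DataFrame, path: PathLike,
                           header_comment: str = "") -> None:
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table misses columns {sorted(missing)}")
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.loc[:, TRAJECTORY_COLUMNS].to_csv(fh, sep="\t", index=False,
                                             float_format="%.10g",
                                             na_rep="nan")


def read_trajectory_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table misses columns {sorted(missing)}")
    return df.astype({c: float for c in ("time_fs", "field", "d", "theta")})


def write_spectrum(spec: Spectrum, path: PathLike,
                   peaks_sidecar: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1\tintensity\n")
        for w, i in zip(spec.wavenumber, spec.intensity):
            fh.write(f"{w:.10g}\t{i:.10g}\n")
    if peaks_sidecar:
        side = path.with_suffix(path.suffix + ".peaks.json")
        with open(side, "w") as fh:
            json.dump({"peaks": [{"position_cm": round(p, 4),
                                  "height": h} for p, h in spec.peaks]},
                      fh, indent=1)


def read_spectrum(path: PathLike) -> Spectrum:
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path} is not a two-column spectrum file")
    side = Path(path).with_suffix(Path(path).suffix + ".peaks.json")
    peaks = []
    if side.exists():
        with open(side) as fh:
            peaks = [(p["position_cm"], p["height"])
                     for p in json.load(fh)["peaks"]]
    return Spectrum(wavenumber=data[:, 0], intensity=data[:, 1], peaks=peaks)


def default_params() -> dict:
    """Built-in parameter set: canonical blueshift surface constants and the
    default aromatic-nitrile Stark parameters."""
    return {"vse": asdict(DEFAULT_VSE),
            "blueshift": asdict(CANONICAL_BLUESHIFT)}


def load_params(path: Optional[PathLike] = None,
                ) -> tuple[VSEParameters, BlueshiftParameters]:
    """Load a YAML parameter config; missing fields fall back to defaults."""
    merged = default_params()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section in ("vse", "blueshift"):
            merged[section].update(user.get(section, {}) or {})
    return (VSEParameters(**merged["vse"]),
            BlueshiftParameters(**merged["blueshift"]))


def dump_params(vse: VSEParameters, blue: BlueshiftParameters,
                path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"vse": asdict(vse), "blueshift": asdict(blue)},
                       fh, sort_keys=False)


def write_fit_report(report: FitReport, path_or_handle) -> None:
    text = report.to_text()
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)
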