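"""Delimited-text I/O for spectra, batch tables and reports.

All tabular output is comma-separated UTF-8 with a header row and '.'
decimal separator.  Spectra tables put the axis first (header
``wavenumber_cm-1``) followed by one intensity column per measurement;
batch metadata and dissolution tables are tidy tables keyed by
``tablet_id``.  Floats are written with Python's shortest round-trip
representation, so every writer/reader pair is lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WAVENUMBER_COLUMN",
    "write_spectra",
    "read_spectra",
    "write_batch_metadata",
    "read_batch_metadata",
    "write_dissolution",
    "read_dissolution",
]

WAVENUMBER_COLUMN = "wavenumber_cm-1"


def write_spectra(path, wavenumbers: np.ndarray, spectra: np.ndarray, ids: list[str]) -> None:
    """Write spectra as axis + one column per measurement."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[0] != len(ids):
        raise ValueError("one id per spectrum row required")
    df = pd.DataFrame({WAVENUMBER_COLUMN: np.asarray(wavenumbers, dtype=float)})
    for name, row in zip(ids, spectra):
        df[name] = row
    df.to_csv(path, index=False)


def read_spectra(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a spectra table; returns (wavenumbers, spectra rows, ids)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != WAVENUMBER_COLUMN:
        raise ValueError(f"expected first column {WAVENUMBER_COLUMN!r}, got {df.columns[0]!r}")
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    ids = list(df.columns[1:])
    X = df.iloc[:, 1:].to_numpy(dtype=float).T
    return wn, X, ids


def write_batch_metadata(
    path,
    tablet_ids: list[str],
    dose_mg: np.ndarray,
    tablet_mass_mg: np.ndarray | float,
    reference_content_pct: np.ndarray,
    reference_content_mg: np.ndarray | None = None,
) -> None:
    n = len(tablet_ids)
    mass = np.broadcast_to(np.asarray(tablet_mass_mg, dtype=float), (n,))
    df = pd.DataFrame(
        {
            "tablet_id": tablet_ids,
            "dose_mg": np.asarray(dose_mg, dtype=float),
            "tablet_mass_mg": mass,
            "reference_content_pct": np.asarray(reference_content_pct, dtype=float),
        }
    )
    if reference_content_mg is not None:
        df["reference_content_mg"] = np.asarray(reference_content_mg, dtype=float)
    df.to_csv(path, index=False)


def read_batch_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"tablet_id", "dose_mg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"batch metadata missing columns: {sorted(missing)}")
    return df


def write_dissolution(path, tablet_ids: list[str], times_min: np.ndarray, released_pct: np.ndarray) -> None:
    """Write dissolution profiles as a tidy (tablet_id, time_min, released_pct) table."""
    released = np.atleast_2d(np.asarray(released_pct, dtype=float))
    times = np.asarray(times_min, dtype=float)
    rows = {
        "tablet_id": np.repeat(tablet_ids, times.size),
        "time_min": np.tile(times, len(tablet_ids)),
        "released_pct": released.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dissolution(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a tidy dissolution table back into (ids, times, profile matrix)."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("tablet_id", "time_min", "released_pct"):
        if col not in df.columns:
            raise ValueError(f"dissolution table missing column {col!r}")
    ids = list(dict.fromkeys(df["tablet_id"].astype(str)))
    times = np.sort(df["time_min"].unique().astype(float))
    wide = df.pivot(index="tablet_id", columns="time_min", values="released_pct")
    wide = wide.loc[ids, times]
    return ids, times, wide.to_numpy(dtype=float)
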