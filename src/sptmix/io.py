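"""Readers and writers for the pipeline's plain-text formats.

Localizations: CSV ``frame,cell_id,x_um,y_um,sigma_um`` (cell_id and
sigma_um optional on input). Tracks: TSV ``track_id,cell_id,frame,x_um,
y_um``. D* tables: CSV ``track_id,d_star_um2_s,n_steps``. Fit reports:
JSON. Malformed files are rejected with a :class:`ParseError` naming the
offending column or line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .mixture import MixtureFit

__all__ = [
    "ParseError",
    "read_localizations",
    "write_localizations",
    "read_tracks",
    "write_tracks",
    "read_dstars",
    "write_dstars",
    "read_fit",
    "write_fit",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A file does not conform to the expected dialect."""


def _require_columns(df: pd.DataFrame, cols: list[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")


def _coerce_numeric(df: pd.DataFrame, cols: list[str], path: PathLike) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ParseError(f"{path}: non-numeric value in column '{c}' at line {line}")
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise ParseError(f"{path}: empty value in column '{c}' at line {line}")
        df[c] = coerced
    return df


def read_localizations(path: PathLike) -> pd.DataFrame:
    """Read a localization CSV; frames must be sorted non-decreasingly."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["frame", "x_um", "y_um"], path)
    if "cell_id" not in df.columns:
        df["cell_id"] = 0
    if "sigma_um" not in df.columns:
        df["sigma_um"] = 0.0
    df = _coerce_numeric(df, ["frame", "cell_id", "x_um", "y_um", "sigma_um"], path)
    df["frame"] = df["frame"].astype(np.int64)
    df["cell_id"] = df["cell_id"].astype(np.int64)
    if np.any(np.diff(df["frame"].to_numpy()) < 0):
        raise ParseError(f"{path}: frames are not sorted")
    return df[["frame", "cell_id", "x_um", "y_um", "sigma_um"]]


def write_localizations(locs: pd.DataFrame, path: PathLike) -> None:
    locs.to_csv(path, index=False)


def read_tracks(path: PathLike) -> pd.DataFrame:
    """Read a track TSV (long form, one row per localization)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["track_id", "cell_id", "frame", "x_um", "y_um"], path)
    df = _coerce_numeric(df, ["track_id", "cell_id", "frame", "x_um", "y_um"], path)
    for c in ("track_id", "cell_id", "frame"):
        df[c] = df[c].astype(np.int64)
    return df


def write_tracks(tracks: pd.DataFrame, path: PathLike) -> None:
    tracks.to_csv(path, sep="\t", index=False)


def read_dstars(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["track_id", "d_star_um2_s", "n_steps"], path)
    df = _coerce_numeric(df, ["track_id", "d_star_um2_s", "n_steps"], path)
    df["track_id"] = df["track_id"].astype(np.int64)
    df["n_steps"] = df["n_steps"].astype(np.int64)
    return df


def write_dstars(dstars: pd.DataFrame, path: PathLike) -> None:
    dstars.to_csv(path, index=False)


def write_fit(fit: MixtureFit, path: PathLike) -> None:
    payload = {
        "species": [{"D": d, "occupancy": f} for d, f in fit.species],
        "n_steps": fit.n_steps,
        "log_likelihood": fit.log_likelihood,
        "n_tracks": fit.n_tracks,
        "converged": fit.converged,
        "fixed_d": fit.fixed_d,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_fit(path: PathLike) -> MixtureFit:
    try:
        payload = json.loads(Path(path).read_text())
        return MixtureFit(
            species=[(float(s["D"]), float(s["occupancy"])) for s in payload["species"]],
            n_steps=int(payload["n_steps"]),
            log_likelihood=float(payload["log_likelihood"]),
            n_tracks=int(payload["n_tracks"]),
            converged=bool(payload["converged"]),
            fixed_d=payload.get("fixed_d"),
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: malformed fit report ({exc})") from exc
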