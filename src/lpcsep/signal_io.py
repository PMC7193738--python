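"""Data model and file I/O for multi-channel LFP recordings and feature tables.

A recording on disk is a comma-separated file (one column per channel, header
row, optional leading ``time_s`` column) together with a JSON sidecar named
``<stem>.json`` carrying the sampling rate and session labels.  Feature tables
are plain CSV.  Values are written with 9 significant digits, which makes the
read/write round trip lossless at the feature scales used here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "FeatureTable",
    "Config",
    "read_recording",
    "write_recording",
    "read_features",
    "write_features",
]

#: significant digits used for all text output
WRITE_PRECISION = 9
_FLOAT_FMT = f"%.{WRITE_PRECISION}g"

FEATURE_COLUMNS = [
    "subject_id",
    "condition",
    "epoch_index",
    "epoch_length_s",
    "method",
    "value",
]
_FEATURE_KEY = ["subject_id", "condition", "epoch_index", "method"]


@dataclass
class Recording:
    """A multi-channel field-potential session.

    Parameters
    ----------
    channels : array-like, shape (n_channels, n_samples)
        Raw samples in arbitrary units; every channel has the same length.
        Amplitude units are deliberately opaque — the analysis chain
        normalizes each channel to unit power, so gains cancel.
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Subject label.
    condition : str
        Session condition label (e.g. ``"saline"``, ``"levodopa"``).
    meta : dict
        Free-form annotations, carried through I/O untouched.
    """

    channels: np.ndarray
    fs: float
    subject_id: str = "unknown"
    condition: str = "unlabeled"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        chans = self.channels
        if isinstance(chans, (list, tuple)):
            lengths = {len(np.atleast_1d(c)) for c in chans}
            if len(lengths) > 1:
                raise ValueError(
                    f"channels have unequal lengths {sorted(lengths)}; "
                    "all channels must cover the same samples"
                )
        self.channels = np.atleast_2d(np.asarray(chans, dtype=float))
        if self.channels.size == 0 or self.channels.shape[0] == 0:
            raise ValueError("a Recording needs at least one channel")
        if self.n_samples < 2:
            raise ValueError("a Recording needs at least 2 samples per channel")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got fs={self.fs}")
        self.fs = float(self.fs)
        if not self.condition:
            raise ValueError("condition label must be non-empty")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        """Session length in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def ts(self) -> float:
        """Sampling interval in seconds (1/fs)."""
        return 1.0 / self.fs


class FeatureTable:
    """Per-epoch scalar features keyed by (subject, condition, epoch, method).

    Thin validated wrapper around a :class:`pandas.DataFrame` with columns
    ``subject_id, condition, epoch_index, epoch_length_s, method, value``.
    The key quadruple (subject, condition, epoch, method) must be unique and
    every epoch length positive.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"feature table is missing columns {missing}")
        df = df.loc[:, FEATURE_COLUMNS].reset_index(drop=True)
        if len(df):
            df = df.astype(
                {"epoch_index": int, "epoch_length_s": float, "value": float}
            )
        dup = df.duplicated(subset=_FEATURE_KEY)
        if dup.any():
            offenders = df.loc[dup, _FEATURE_KEY].to_dict("records")
            raise ValueError(f"duplicate feature rows for keys {offenders[:5]}")
        if len(df) and not (df["epoch_length_s"] > 0).all():
            raise ValueError("epoch_length_s must be positive in every row")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.df.equals(other.df)

    @classmethod
    def from_rows(cls, rows: Sequence[dict[str, Any]]) -> "FeatureTable":
        return cls(pd.DataFrame(list(rows), columns=FEATURE_COLUMNS))

    @classmethod
    def empty(cls) -> "FeatureTable":
        return cls(pd.DataFrame(columns=FEATURE_COLUMNS))

    def values_for(self, method: str, condition: str) -> np.ndarray:
        """All feature values for one method/condition, pooled across subjects."""
        sel = (self.df["method"] == method) & (self.df["condition"] == condition)
        return self.df.loc[sel, "value"].to_numpy(dtype=float)

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        return FeatureTable(pd.concat([self.df, other.df], ignore_index=True))


@dataclass
class Config:
    """Pipeline configuration with the study's fixed constants as defaults.

    band_lo_hz / band_hi_hz
        Preprocessing bandpass edges (2.5-50 Hz).
    epoch_lengths_min
        Segment lengths analyzed per session, in minutes.
    lpc_order
        Order of the predictive model used for the scalar feature (1 or 2).
    expanding_init_s / expanding_step_s
        Initial window and increment of the expanding-window (real-time
        emulation) analysis, in seconds.
    beta_band
        Band for the power-fraction comparator, Hz.
    pac_nbins
        Number of phase bins of the modulation index.
    seed
        Master seed for any randomized step.
    """

    band_lo_hz: float = 2.5
    band_hi_hz: float = 50.0
    epoch_lengths_min: tuple[float, ...] = (1.0, 3.0, 10.0, 40.0)
    lpc_order: int = 1
    expanding_init_s: float = 1.0
    expanding_step_s: float = 1.0
    beta_band: tuple[float, float] = (12.0, 30.0)
    pac_nbins: int = 18
    seed: int = 0

    def validate(self, fs: float | None = None) -> "Config":
        if not 0 < self.band_lo_hz < self.band_hi_hz:
            raise ValueError("need 0 < band_lo_hz < band_hi_hz")
        if fs is not None and not self.band_hi_hz < fs / 2:
            raise ValueError(f"band_hi_hz={self.band_hi_hz} must lie below Nyquist {fs/2}")
        if self.lpc_order not in (1, 2):
            raise ValueError(f"lpc_order must be 1 or 2, got {self.lpc_order}")
        if any(e <= 0 for e in self.epoch_lengths_min):
            raise ValueError("epoch lengths must be positive")
        return self

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, default=list) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "Config":
        raw = json.loads(Path(path).read_text())
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        return cfg.validate()

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logs."""
        blob = json.dumps(self.__dict__, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_recording(path: str | Path) -> Recording:
    """Read a CSV recording and its JSON sidecar.

    The sidecar ``<stem>.json`` must provide ``fs_hz``; ``subject_id``,
    ``condition`` and any further keys are carried into the recording's
    metadata.  A leading ``time_s`` column in the CSV is ignored.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar} for recording {path}"
        )
    meta = json.loads(sidecar.read_text())
    if "fs_hz" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks required key 'fs_hz'")
    fs = float(meta.pop("fs_hz"))
    if fs <= 0:
        raise ValueError(f"sidecar {sidecar} has non-positive fs_hz={fs}")
    subject = str(meta.pop("subject_id", "unknown"))
    condition = str(meta.pop("condition", "unlabeled"))

    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows: pandas names the line
        raise ValueError(f"malformed recording file {path}: {exc}") from exc
    if "time_s" in df.columns:
        df = df.drop(columns=["time_s"])
    try:
        data = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in recording file {path}: {exc}") from exc
    if np.isnan(data).any():
        bad = int(np.argwhere(np.isnan(data))[0, 0]) + 2  # +header +1-based
        raise ValueError(f"missing or non-numeric cell near line {bad} of {path}")
    return Recording(
        channels=data.T, fs=fs, subject_id=subject, condition=condition, meta=meta
    )


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV plus JSON sidecar; inverse of read_recording."""
    path = Path(path)
    header = ",".join(f"ch{i}" for i in range(rec.n_channels))
    np.savetxt(
        path, rec.channels.T, fmt=_FLOAT_FMT, delimiter=",",
        header=header, comments="",
    )
    sidecar = {
        "fs_hz": rec.fs,
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        **rec.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, default=str) + "\n")
    return path


def write_features(table: FeatureTable, path: str | Path) -> Path:
    path = Path(path)
    table.df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_features(path: str | Path) -> FeatureTable:
    df = pd.read_csv(Path(path))
    if len(df) == 0:
        df = pd.DataFrame(columns=FEATURE_COLUMNS)
    return FeatureTable(df)  # duplicate keys rejected here
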