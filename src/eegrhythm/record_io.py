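"""Reading, validating, epoching and writing tabular EEG record files.

The on-disk format is a 13-column delimited table, one row per sample:
tester number, event number, minutes, seconds, eight channel voltages in
microvolts, and a baseline voltage.  Both tab- and comma-separated dialects
are accepted; the delimiter is sniffed from the header line.  The seconds
column is treated as the authoritative absolute time axis (the minutes
column is redundant and only checked for consistency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .wavelet import BANDS, InsufficientDataError

__all__ = [
    "CHANNELS",
    "Epoch",
    "Montage",
    "Recording",
    "RecordFormatError",
    "RecordParseError",
    "SamplingReport",
    "StructureError",
    "default_montage",
    "epoch_by_event",
    "read_features",
    "read_records",
    "validate_sampling",
    "write_features",
    "write_records",
]

logger = logging.getLogger(__name__)

#: Electrode labels for record columns "Channel 1".."Channel 8", in order.
CHANNELS: Tuple[str, ...] = ("Fp1", "Fp2", "T3", "T4", "C3", "C4", "O1", "O2")

#: Minimum epoch length: a 4-level dyadic decomposition needs 2**4 samples.
MIN_EPOCH_SAMPLES = 16

_HEADER = [
    "Tester", "Event", "Minutes", "Seconds",
    "Channel 1", "Channel 2", "Channel 3", "Channel 4",
    "Channel 5", "Channel 6", "Channel 7", "Channel 8",
    "Baseline",
]

_FEATURE_COLUMNS = ["channel", "band", "task", "rhythm_energy", "energy_ratio"]


class RecordFormatError(ValueError):
    """File does not have the expected 13-column layout."""


class RecordParseError(ValueError):
    """A cell could not be parsed; the message names the offending row."""


class StructureError(ValueError):
    """Event labels are interleaved rather than contiguous runs."""


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """Electrode labels with hemisphere and scalp-region assignments.

    Follows the international 10-20 naming convention: odd suffix = left
    hemisphere, even suffix = right; Fp = frontopolar, T = temporal,
    C = central, O = occipital.
    """

    channels: Tuple[str, ...]
    hemisphere: Mapping[str, str]
    region: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.hemisphere) != set(self.channels):
            raise ValueError("hemisphere map must cover exactly the channels")
        if set(self.region) != set(self.channels):
            raise ValueError("region map must cover exactly the channels")

    def side(self, side: str) -> Tuple[str, ...]:
        return tuple(c for c in self.channels if self.hemisphere[c] == side)

    def in_region(self, region: str) -> Tuple[str, ...]:
        return tuple(c for c in self.channels if self.region[c] == region)

    @property
    def homologous_pairs(self) -> Tuple[Tuple[str, str], ...]:
        """Left/right electrode pairs at mirrored scalp positions."""
        left = self.side("left")
        right = self.side("right")
        return tuple(zip(left, right))


def default_montage() -> Montage:
    """The 8-electrode montage: Fp1/Fp2 frontal, T3/T4/C3/C4 parietal,
    O1/O2 occipital; odd labels left, even labels right."""
    region = {
        "Fp1": "frontal", "Fp2": "frontal",
        "T3": "parietal", "T4": "parietal",
        "C3": "parietal", "C4": "parietal",
        "O1": "occipital", "O2": "occipital",
    }
    hemisphere = {c: ("left" if c in ("Fp1", "T3", "C3", "O1") else "right")
                  for c in CHANNELS}
    return Montage(channels=CHANNELS, hemisphere=hemisphere, region=region)


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """One tester's continuous multichannel voltage trace.

    ``voltages`` is a (n_samples, 8) array in microvolts, column order
    :data:`CHANNELS`.  ``event_ids`` labels each sample with its stimulus
    scene (1..9); 0 is reserved for inter-stimulus gaps.  ``baseline`` is
    the record file's baseline-electrode column, stored opaquely.
    """

    tester_id: int
    event_ids: np.ndarray
    time_s: np.ndarray
    voltages: np.ndarray
    baseline: np.ndarray
    fs: float = 128.0

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if n == 0:
            raise ValueError("recording has no samples")
        if not (len(self.event_ids) == n == len(self.voltages)
                == len(self.baseline)):
            raise ValueError("per-sample arrays have unequal lengths")
        if self.voltages.ndim != 2 or self.voltages.shape[1] != len(CHANNELS):
            raise ValueError(
                f"voltages must be (n, {len(CHANNELS)}), "
                f"got {self.voltages.shape}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time_s)


@dataclass
class Epoch:
    """The contiguous samples of one stimulus scene for one tester."""

    tester_id: int
    event_id: int
    task_label: str
    voltages: np.ndarray
    fs: float = 128.0

    @property
    def n_samples(self) -> int:
        return len(self.voltages)


# ---------------------------------------------------------------------------
# Record table I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","

def _parse_tester(value) -> int:
    """``"Number 01"`` -> 1; plain integers pass through."""
    s = str(value).strip()
    if s.lower().startswith("number"):
        s = s[len("number"):].strip()
    try:
        return int(s)
    except ValueError:
        raise RecordParseError(f"cannot parse tester identifier {value!r}") from None


def read_records(path: str | Path) -> List[Recording]:
    """Read a record-table file; returns one :class:`Recording` per tester.

    Raises :class:`RecordFormatError` for a wrong column count,
    :class:`RecordParseError` (naming the row) for non-numeric voltages, and
    ``ValueError`` for an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise ValueError(f"empty input file: {path}")
    sep = _sniff_delimiter(header_line)

    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    if df.shape[1] != len(_HEADER):
        have = list(df.columns)
        missing = [c for c in _HEADER if c not in have]
        raise RecordFormatError(
            f"expected {len(_HEADER)} columns, found {df.shape[1]}"
            + (f"; missing: {missing}" if missing else "")
        )
    df.columns = _HEADER
    if df.empty:
        raise ValueError(f"no data rows in {path}")

    numeric = {}
    for col in _HEADER[1:]:
        # tolerate the typographic minus sign some tools emit
        raw = df[col].str.replace("−", "-", regex=False)
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.index[parsed.isna() & raw.notna()]
        if len(bad):
            raise RecordParseError(
                f"non-numeric value {df[col].iloc[bad[0]]!r} in column "
                f"{col!r} at data row {int(bad[0])}"
            )
        numeric[col] = parsed.to_numpy(dtype=float)

    testers = df["Tester"].map(_parse_tester).to_numpy()
    seconds = numeric["Seconds"]
    minutes = numeric["Minutes"]
    if np.any(np.abs(minutes * 60.0 - seconds) > 1.0):
        logger.warning(
            "minutes column inconsistent with seconds column by more than "
            "1 s; using seconds as the time axis"
        )

    recordings = []
    for tid in pd.unique(testers):
        mask = testers == tid
        recordings.append(
            Recording(
                tester_id=int(tid),
                event_ids=numeric["Event"][mask].astype(int),
                time_s=seconds[mask],
                voltages=np.column_stack(
                    [numeric[f"Channel {i}"][mask] for i in range(1, 9)]
                ),
                baseline=numeric["Baseline"][mask],
            )
        )
    return recordings


def write_records(
    recordings: Sequence[Recording], path: str | Path, sep: str = "\t"
) -> None:
    """Write recordings back to the 13-column table layout (inverse of
    :func:`read_records` up to float formatting)."""
    frames = []
    for rec in recordings:
        frames.append(pd.DataFrame({
            "Tester": f"Number {rec.tester_id:02d}",
            "Event": rec.event_ids,
            "Minutes": np.round(rec.time_s / 60.0, 3),
            "Seconds": rec.time_s,
            **{f"Channel {i}": rec.voltages[:, i - 1] for i in range(1, 9)},
            "Baseline": rec.baseline,
        }))
    pd.concat(frames).to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Validation and epoching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingReport:
    median_interval_s: float
    expected_interval_s: float
    ok: bool
    message: str


def validate_sampling(rec: Recording, tolerance: float = 0.05) -> SamplingReport:
    """Check the time axis against the nominal sampling frequency.

    Passes when the median inter-sample interval is within ``tolerance``
    (fractional) of ``1/fs``.  Does not mutate the recording.
    """
    if rec.n_samples < 2:
        raise InsufficientDataError(
            "need at least 2 samples to estimate the sampling interval"
        )
    intervals = np.diff(rec.time_s)
    median = float(np.median(intervals))
    expected = 1.0 / rec.fs
    if median <= 0:
        return SamplingReport(
            median, expected, False,
            "non-increasing time axis (zero or negative median interval)",
        )
    ok = abs(median - expected) <= tolerance * expected
    msg = (
        f"median interval {median:.6f} s vs expected {expected:.6f} s "
        f"({'within' if ok else 'outside'} {tolerance:.0%})"
    )
    return SamplingReport(median, expected, ok, msg)


def epoch_by_event(
    rec: Recording,
    task_map: Mapping[int, str],
    min_samples: int = MIN_EPOCH_SAMPLES,
) -> List[Epoch]:
    """Cut a recording into one epoch per contiguous event run.

    Samples labelled 0 (inter-stimulus gaps) are discarded.  Runs shorter
    than ``min_samples`` are dropped with a warning.  Raises
    :class:`StructureError` if a non-gap event id recurs after an
    intervening different event (interleaved labels).
    """
    ids = rec.event_ids
    boundaries = np.flatnonzero(np.diff(ids)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [len(ids)]])

    seen: set[int] = set()
    epochs: List[Epoch] = []
    for start, stop in zip(starts, stops):
        event = int(ids[start])
        if event == 0:
            continue
        if event in seen:
            raise StructureError(
                f"event {event} appears in more than one run; event labels "
                "must form contiguous blocks"
            )
        seen.add(event)
        if stop - start < min_samples:
            logger.warning(
                "dropping event %d of tester %d: run of %d samples is "
                "shorter than the %d-sample minimum",
                event, rec.tester_id, stop - start, min_samples,
            )
            continue
        if event not in task_map:
            raise KeyError(
                f"event {event} has no task label in the task map"
            )
        epochs.append(Epoch(
            tester_id=rec.tester_id,
            event_id=event,
            task_label=task_map[event],
            voltages=rec.voltages[start:stop].copy(),
            fs=rec.fs,
        ))
    return epochs


# ---------------------------------------------------------------------------
# Feature-table I/O
# ---------------------------------------------------------------------------

def write_features(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV.

    Rows are ordered channel-major with bands in delta, theta, alpha, beta
    order within each channel.  A ``tester`` column is kept when present
    (per-subject tables); aggregated tables carry only channel/band/task.
    """
    if table.empty:
        raise ValueError("refusing to write an empty feature table")
    missing = [c for c in _FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    cols = (["tester"] if "tester" in table.columns else []) + _FEATURE_COLUMNS
    out = table[cols].copy()
    out["_band_rank"] = out["band"].map({b: i for i, b in enumerate(BANDS)})
    out["_chan_rank"] = out["channel"].map(
        {c: i for i, c in enumerate(CHANNELS)}
    )
    sort_cols = (["tester"] if "tester" in cols else []) + \
        ["_chan_rank", "_band_rank", "task"]
    out = out.sort_values(sort_cols).drop(columns=["_band_rank", "_chan_rank"])
    out.to_csv(path, index=False, float_format="%.6f")


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV written by :func:`write_features`."""
    df = pd.read_csv(path)
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    return df
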