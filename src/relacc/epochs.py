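"""Epoch-level ENMO processing and delimited-text I/O.

The activity signal used throughout the package is ENMO (Euclidean norm of
the tri-axial acceleration vector minus one gravitational unit, negative
values truncated to zero), aggregated into tumbling epochs (default 5 s) and
expressed in milli-g.  A participant-day is one midnight-to-midnight 24-h
cycle on the local-time epoch grid.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SECONDS_PER_DAY = 86400
#: Files claiming a post-calibration error above this are rejected at ingest.
MAX_CALIBRATION_ERROR_MG = 10.0

DAY_TYPES = ("weekday", "saturday", "sunday")

_FILE_MAGIC = "# relacc epoch file v1"


class EpochFileError(ValueError):
    """Malformed epoch file (bad header, row count, or row content)."""


def day_type_of(date: dt.date) -> str:
    """Classify a calendar date as weekday / saturday / sunday."""
    wd = date.weekday()
    if wd == 5:
        return "saturday"
    if wd == 6:
        return "sunday"
    return "weekday"


@dataclass
class RawSampleBlock:
    """One day of calibrated tri-axial acceleration samples in g units.

    ``times`` are seconds since local midnight; axes must be equal length.
    Nominal sample rate is 50 Hz but any positive rate is accepted.
    """

    sample_rate: float
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.times)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("x, y, z and times must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if n and (self.times.min() < 0 or self.times.max() >= SECONDS_PER_DAY):
            raise ValueError("sample times must lie within [0, 86400) seconds")


@dataclass
class EpochSeries:
    """One participant-day of epoch-level ENMO values (milli-g).

    ``enmo`` holds NaN for epochs with no usable data (e.g. an empty epoch at
    ingest, or a non-wear epoch that could not be imputed).  ``wear`` marks
    epochs where the device was worn; ``imputed`` marks epochs whose value
    was filled in from sibling days.
    """

    participant_id: str
    date: dt.date
    epoch_seconds: int
    enmo: np.ndarray
    wear: np.ndarray
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]
    calibration_error_mg: float | None = None

    def __post_init__(self) -> None:
        if SECONDS_PER_DAY % self.epoch_seconds != 0:
            raise ValueError("epoch_seconds must divide 86400")
        n = SECONDS_PER_DAY // self.epoch_seconds
        self.enmo = np.asarray(self.enmo, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros(n, dtype=bool)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if len(self.enmo) != n:
            raise ValueError(
                f"expected {n} epochs for {self.epoch_seconds}-s epochs, "
                f"got {len(self.enmo)}"
            )
        if not (len(self.wear) == len(self.imputed) == n):
            raise ValueError("wear/imputed must match the epoch count")
        finite = self.enmo[np.isfinite(self.enmo)]
        if finite.size and finite.min() < 0:
            raise ValueError("ENMO values must be non-negative")

    @property
    def n_epochs(self) -> int:
        return len(self.enmo)

    @property
    def day_type(self) -> str:
        return day_type_of(self.date)

    def copy(self) -> "EpochSeries":
        return EpochSeries(
            participant_id=self.participant_id,
            date=self.date,
            epoch_seconds=self.epoch_seconds,
            enmo=self.enmo.copy(),
            wear=self.wear.copy(),
            imputed=self.imputed.copy(),
            calibration_error_mg=self.calibration_error_mg,
        )


def compute_enmo(block: RawSampleBlock, epoch_seconds: int = 5) -> np.ndarray:
    """Tumbling-epoch ENMO in milli-g from raw tri-axial samples.

    Per sample, ENMO = max(0, sqrt(x^2 + y^2 + z^2) - 1) in g; truncation at
    zero happens *per sample, before* epoch averaging (averaging first and
    truncating after gives a different, smaller value whenever sub-1-g
    samples occur).  The epoch value is the sample mean times 1000.  Epochs
    containing no samples are returned as NaN (missing, not zero).
    """
    if SECONDS_PER_DAY % epoch_seconds != 0:
        raise ValueError("epoch_seconds must divide 86400")
    n_epochs = SECONDS_PER_DAY // epoch_seconds
    mag = np.sqrt(block.x**2 + block.y**2 + block.z**2)
    enmo_g = np.maximum(mag - 1.0, 0.0)
    idx = (block.times // epoch_seconds).astype(np.int64)
    sums = np.bincount(idx, weights=enmo_g, minlength=n_epochs)
    counts = np.bincount(idx, minlength=n_epochs)
    out = np.full(n_epochs, np.nan)
    np.divide(sums, counts, out=out, where=counts > 0)
    return out * 1000.0


def series_from_raw(
    block: RawSampleBlock,
    participant_id: str,
    date: dt.date,
    epoch_seconds: int = 5,
    calibration_error_mg: float | None = None,
) -> EpochSeries:
    """Build an :class:`EpochSeries` from raw samples; empty epochs -> non-wear."""
    _check_calibration(calibration_error_mg)
    enmo = compute_enmo(block, epoch_seconds)
    wear = np.isfinite(enmo)
    return EpochSeries(
        participant_id=participant_id,
        date=date,
        epoch_seconds=epoch_seconds,
        enmo=enmo,
        wear=wear,
        calibration_error_mg=calibration_error_mg,
    )


def _check_calibration(err: float | None) -> None:
    if err is not None and err > MAX_CALIBRATION_ERROR_MG:
        raise EpochFileError(
            f"post-calibration error {err:g} mg exceeds the "
            f"{MAX_CALIBRATION_ERROR_MG:g} mg exclusion limit; file rejected"
        )


def _clock(epoch_index: int, epoch_seconds: int) -> str:
    s = epoch_index * epoch_seconds
    return f"{s // 3600:02d}:{(s % 3600) // 60:02d}:{s % 60:02d}"


def write_epoch_file(series: EpochSeries, path: str | Path) -> None:
    """Write one participant-day as a commented CSV (UTF-8, ISO-8601 date)."""
    path = Path(path)
    lines = [
        _FILE_MAGIC,
        f"# participant_id: {series.participant_id}",
        f"# date: {series.date.isoformat()}",
        f"# epoch_seconds: {series.epoch_seconds}",
    ]
    if series.calibration_error_mg is not None:
        lines.append(f"# calibration_error_mg: {series.calibration_error_mg:.6g}")
    lines.append("time,enmo_mg,wear,imputed")
    eps = series.epoch_seconds
    for i in range(series.n_epochs):
        v = series.enmo[i]
        sval = "nan" if not np.isfinite(v) else format(v, ".17g")
        lines.append(
            f"{_clock(i, eps)},{sval},{int(series.wear[i])},{int(series.imputed[i])}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_epoch_file(path: str | Path) -> EpochSeries:
    """Read a participant-day epoch file; ``read(write(s)) == s`` field-by-field.

    Raises :class:`EpochFileError` naming the offending row for malformed
    rows, negative ENMO, wrong epoch counts, or a claimed post-calibration
    error above the 10 mg exclusion limit.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[int, str]] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols[:3] != ["time", "enmo_mg", "wear"]:
                    raise EpochFileError(
                        f"{path.name}: line {lineno}: unexpected column header {cols!r}"
                    )
                header_seen = True
                continue
            rows.append((lineno, line))
    for key in ("participant_id", "date", "epoch_seconds"):
        if key not in meta:
            raise EpochFileError(f"{path.name}: missing required header key '{key}'")
    try:
        date = dt.date.fromisoformat(meta["date"])
        epoch_seconds = int(meta["epoch_seconds"])
    except ValueError as exc:
        raise EpochFileError(f"{path.name}: bad header value: {exc}") from exc
    calib = None
    if "calibration_error_mg" in meta:
        calib = float(meta["calibration_error_mg"])
        _check_calibration(calib)
    if SECONDS_PER_DAY % epoch_seconds != 0:
        raise EpochFileError(f"{path.name}: epoch_seconds must divide 86400")
    n_expected = SECONDS_PER_DAY // epoch_seconds
    if len(rows) != n_expected:
        raise EpochFileError(
            f"{path.name}: expected {n_expected} epoch rows for "
            f"{epoch_seconds}-s epochs, found {len(rows)}"
        )
    enmo = np.empty(n_expected)
    wear = np.zeros(n_expected, dtype=bool)
    imputed = np.zeros(n_expected, dtype=bool)
    for i, (lineno, line) in enumerate(rows):
        parts = line.split(",")
        if len(parts) not in (3, 4):
            raise EpochFileError(
                f"{path.name}: line {lineno}: expected 3 or 4 fields, got {len(parts)}"
            )
        try:
            val = float(parts[1])
            w = int(parts[2])
            imp = int(parts[3]) if len(parts) == 4 else 0
        except ValueError as exc:
            raise EpochFileError(f"{path.name}: line {lineno}: {exc}") from exc
        if np.isfinite(val) and val < 0:
            raise EpochFileError(
                f"{path.name}: line {lineno}: negative ENMO value {val:g}"
            )
        enmo[i] = val
        wear[i] = bool(w)
        imputed[i] = bool(imp)
    return EpochSeries(
        participant_id=meta["participant_id"],
        date=date,
        epoch_seconds=epoch_seconds,
        enmo=enmo,
        wear=wear,
        imputed=imputed,
        calibration_error_mg=calib,
    )
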