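"""On-disk formats for sway trials: per-trace CSV files and the cohort manifest.

A trial trace is one device's one-channel position series for one 20-s quiet
standing trial.  The canonical interchange format is a two-column CSV
(``time_s,position_cm``), one file per (subject, condition, trial, direction,
device), plus a ``manifest.csv`` indexing every trace in a cohort directory.
External force-plate or headset exports must be converted to this schema.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

CONDITIONS = ("EO", "EC")
DIRECTIONS = ("ML", "AP")
DEVICES = ("FP", "VR")

MANIFEST_COLUMNS = ["subject_id", "condition", "trial", "direction", "device", "rate_hz", "path"]

_HEADER = "time_s,position_cm"
_FNAME_RE = re.compile(r"^S(\d+)_(EO|EC)_T(\d+)_(ML|AP)_(FP|VR)\.csv$")

# real devices drop samples; tolerate this much relative jitter in time steps
_DT_JITTER_TOL = 0.005


class TraceParseError(ValueError):
    """A trace CSV failed to parse; the message names the offending line."""

    def __init__(self, path, line_no: int | None, message: str):
        self.path = str(path)
        self.line_no = line_no
        where = f"{path}" if line_no is None else f"{path}, line {line_no}"
        super().__init__(f"{where}: {message}")


class CohortValidationError(ValueError):
    """A cohort manifest violated structural invariants.

    Carries the complete list of violations, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            f"{len(self.violations)} cohort validation error(s):\n  " + "\n  ".join(self.violations)
        )


@dataclass(frozen=True, order=True)
class TraceMeta:
    """Identity of one trace within the subject x condition x trial x direction x device grid."""

    subject_id: int
    condition: str
    trial: int
    direction: str
    device: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.device not in DEVICES:
            raise ValueError(f"device must be one of {DEVICES}, got {self.device!r}")

    @property
    def filename(self) -> str:
        return f"S{self.subject_id:02d}_{self.condition}_T{self.trial}_{self.direction}_{self.device}.csv"

    @property
    def pair_key(self) -> tuple:
        """Key shared by the FP/VR pair observing the same trial."""
        return (self.subject_id, self.condition, self.trial, self.direction)


def meta_from_filename(name: str) -> TraceMeta | None:
    m = _FNAME_RE.match(name)
    if m is None:
        return None
    return TraceMeta(
        subject_id=int(m.group(1)),
        condition=m.group(2),
        trial=int(m.group(3)),
        direction=m.group(4),
        device=m.group(5),
    )


@dataclass
class TrialTrace:
    """One device's position series for one trial.

    values : position in cm on a uniform time grid that includes t = 0, so a
        trial of ``duration`` seconds at ``rate`` Hz holds
        round(duration * rate) + 1 samples.
    """

    values: np.ndarray
    rate: float
    duration: float
    meta: TraceMeta | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if not (self.rate > 0):
            raise ValueError("sampling rate must be positive")
        if not (self.duration > 0):
            raise ValueError("duration must be positive")
        expected = self.duration * self.rate + 1
        if abs(self.values.size - expected) > 1:
            raise ValueError(
                f"length {self.values.size} inconsistent with duration*rate+1 = {expected:.1f}"
            )

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.rate


def write_trace(trace: TrialTrace, path) -> None:
    """Write one trace as ``time_s,position_cm`` CSV, positions to 6 decimals."""
    path = Path(path)
    t = trace.times
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_HEADER + "\n")
        for ti, pi in zip(t, trace.values):
            fh.write(f"{ti:.6f},{pi:.6f}\n")


def read_trace(path) -> TrialTrace:
    """Parse a trace CSV; rate is inferred from the median time step.

    Raises :class:`TraceParseError` naming the offending line for malformed
    headers, non-numeric rows, non-monotonic time, or excessive step jitter.
    """
    path = Path(path)
    if not path.is_file():
        raise TraceParseError(path, None, "file does not exist")
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _HEADER:
        raise TraceParseError(path, 1, f"header must be exactly {_HEADER!r}")
    times, values = [], []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise TraceParseError(path, i, f"expected 2 comma-separated fields, got {len(parts)}")
        try:
            t = float(parts[0])
            p = float(parts[1])
        except ValueError:
            raise TraceParseError(path, i, f"non-numeric row: {line!r}") from None
        if not (np.isfinite(t) and np.isfinite(p)):
            raise TraceParseError(path, i, f"non-finite value in row: {line!r}")
        times.append(t)
        values.append(p)
    if len(values) < 2:
        raise TraceParseError(path, None, "fewer than 2 data rows")
    t_arr = np.array(times)
    dt = np.diff(t_arr)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise TraceParseError(path, bad + 3, "time column is not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt / med - 1.0)) > _DT_JITTER_TOL:
        bad = int(np.argmax(np.abs(dt / med - 1.0)))
        raise TraceParseError(path, bad + 3, "time-step jitter exceeds 0.5% of the median step")
    rate = round(1.0 / med, 1)
    duration = float(t_arr[-1] - t_arr[0])
    return TrialTrace(
        values=np.array(values), rate=rate, duration=duration, meta=meta_from_filename(path.name)
    )


@dataclass
class CohortManifest:
    """Index over a cohort's traces, optionally holding them in memory.

    ``records`` is a DataFrame with columns ``subject_id, condition, trial,
    direction, device, rate_hz, path``; ``root`` is the cohort directory (None
    for a purely in-memory cohort from the generator).
    """

    records: pd.DataFrame
    root: Path | None = None
    traces: dict[TraceMeta, TrialTrace] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> list[TraceMeta]:
        return [
            TraceMeta(int(r.subject_id), r.condition, int(r.trial), r.direction, r.device)
            for r in self.records.itertuples()
        ]

    def get_trace(self, meta: TraceMeta) -> TrialTrace:
        if meta in self.traces:
            return self.traces[meta]
        if self.root is None:
            raise KeyError(f"no stored trace for {meta}")
        row = self.records[
            (self.records.subject_id == meta.subject_id)
            & (self.records.condition == meta.condition)
            & (self.records.trial == meta.trial)
            & (self.records.direction == meta.direction)
            & (self.records.device == meta.device)
        ]
        if row.empty:
            raise KeyError(f"no manifest record for {meta}")
        trace = read_trace(self.root / row.iloc[0]["path"])
        trace.meta = meta
        return trace

    def iter_traces(self) -> Iterator[tuple[TraceMeta, TrialTrace]]:
        for meta in self.keys():
            yield meta, self.get_trace(meta)

    def write(self, path) -> None:
        self.records.to_csv(path, index=False)


def load_cohort(manifest_path) -> CohortManifest:
    """Load and fully validate a cohort directory from its manifest.

    Every referenced file must exist and parse, keys must be unique, and every
    force-plate record must have a paired headset record (and vice versa).
    Raises :class:`CohortValidationError` listing every violation.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.is_file():
        raise CohortValidationError([f"manifest not found: {manifest_path}"])
    records = pd.read_csv(manifest_path)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in records.columns]
    if missing_cols:
        raise CohortValidationError([f"manifest missing columns: {missing_cols}"])
    if records.empty:
        raise CohortValidationError(["no records in manifest"])

    root = manifest_path.parent
    violations: list[str] = []
    seen: dict[tuple, int] = {}
    traces: dict[TraceMeta, TrialTrace] = {}
    for r in records.itertuples():
        try:
            meta = TraceMeta(int(r.subject_id), str(r.condition), int(r.trial), str(r.direction), str(r.device))
        except ValueError as exc:
            violations.append(f"row {r.Index}: invalid metadata ({exc})")
            continue
        key = (meta.subject_id, meta.condition, meta.trial, meta.direction, meta.device)
        if key in seen:
            violations.append(f"duplicate key {key} (rows {seen[key]} and {r.Index})")
            continue
        seen[key] = int(r.Index)
        fpath = root / str(r.path)
        if not fpath.is_file():
            violations.append(f"missing file for {key}: {r.path}")
            continue
        try:
            trace = read_trace(fpath)
        except TraceParseError as exc:
            violations.append(f"unreadable trace for {key}: {exc}")
            continue
        if abs(trace.rate - float(r.rate_hz)) > 0.1:
            violations.append(
                f"rate mismatch for {key}: manifest says {r.rate_hz} Hz, file implies {trace.rate} Hz"
            )
        trace.meta = meta
        traces[meta] = trace

    # pairing: every FP record needs its VR partner and vice versa
    by_pair: dict[tuple, set] = {}
    for meta in traces:
        by_pair.setdefault(meta.pair_key, set()).add(meta.device)
    for pair_key, devices in sorted(by_pair.items()):
        for dev, partner in (("FP", "VR"), ("VR", "FP")):
            if dev in devices and partner not in devices:
                violations.append(
                    f"unpaired {dev} record (no {partner}) for subject={pair_key[0]} "
                    f"condition={pair_key[1]} trial={pair_key[2]} direction={pair_key[3]}"
                )

    if violations:
        raise CohortValidationError(violations)
    return CohortManifest(records=records, root=root, traces=traces)
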