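"""Reading, validation and regularisation of facial-feature recordings.

Raw recordings arrive as per-second (or coarser, ~3 s) samples of named
scalar features — distances between facial landmarks such as mouth width
(``h9``), eyebrow height (``a1``), eyes opening (``a3``) and mouth-corner
lowering (``a4``).  Downstream change scoring needs a gap-free, uniformly
sampled series, so this module resamples onto a fixed grid with forward
fill, optionally strips gross outliers, and reads/writes the CSV dialects
used throughout the package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InputFormatError

VALID_POLARITIES = ("happy_onset", "happy_offset")


@dataclass
class RawRecording:
    """Irregular observations as (timestamp, feature, value) records.

    ``value`` may be NaN for a missing cell; timestamps are seconds from
    the start of the recording and must be non-decreasing per feature.
    """

    records: list[tuple[float, str, float]]
    feature_names: list[str]

    def __post_init__(self) -> None:
        last: dict[str, float] = {}
        seen_value: set[str] = set()
        for t, name, value in self.records:
            if t < 0:
                raise InputFormatError(f"negative timestamp {t} for feature {name!r}")
            if name in last and t < last[name]:
                raise InputFormatError(
                    f"timestamps decrease for feature {name!r} at t={t}"
                )
            last[name] = t
            if np.isfinite(value):
                seen_value.add(name)
        for name in self.feature_names:
            if name not in seen_value:
                raise EmptyInputError(f"feature {name!r} has no non-missing value")


@dataclass
class FeatureSeries:
    """Uniformly sampled multi-feature series (time x feature matrix)."""

    start_time: float
    step: float
    names: list[str]
    values: np.ndarray  # shape (n, len(names)), no NaN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be (n, n_features)")
        if np.isnan(self.values).any():
            raise ValueError("FeatureSeries may not contain missing entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.step * np.arange(self.n)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "t", self.times)
        return df

    def replace(self, **changes) -> "FeatureSeries":
        return dataclasses.replace(self, **changes)


@dataclass
class EventAnnotation:
    """Annotated moments at which the face visibly becomes (or stops being)
    happy-looking; ground truth for recall/precision."""

    events: list[tuple[float, str]]  # (time, polarity), strictly increasing

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InputFormatError("event times must be strictly increasing")
        for _, pol in self.events:
            if pol not in VALID_POLARITIES:
                raise InputFormatError(f"unknown polarity {pol!r}")

    @property
    def n_e(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.events], dtype=float)


def read_feature_csv(
    path: str | Path, column_spec: dict[str, str] | None = None
) -> RawRecording:
    """Read a feature CSV (header row; a ``t`` column in seconds plus one
    column per feature) into a :class:`RawRecording`.

    ``column_spec`` maps CSV column names to feature labels and fixes the
    feature order; by default every non-time column is taken as a feature
    under its own name.  Unparseable cells become missing records.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: no rows") from exc
    if "t" not in df.columns:
        raise InputFormatError(f"{path}: missing timestamp column 't'")
    if column_spec is None:
        column_spec = {c: c for c in df.columns if c != "t"}
    missing = [c for c in column_spec if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: feature columns not found: {missing}")

    t = pd.to_numeric(df["t"], errors="coerce")
    if t.notna().sum() == 0:
        raise EmptyInputError(f"{path}: zero parseable rows")
    records: list[tuple[float, str, float]] = []
    for col, label in column_spec.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        for ti, vi in zip(t, vals):
            if np.isnan(ti):
                continue
            records.append((float(ti), label, float(vi) if pd.notna(vi) else np.nan))
    records.sort(key=lambda r: r[0])
    return RawRecording(records=records, feature_names=list(column_spec.values()))


def regularize(raw: RawRecording, step: float = 1.0) -> FeatureSeries:
    """Resample onto a uniform grid with forward fill.

    Each grid point ``start + k*step`` takes the most recent observation at
    or before it; grid points before a feature's first observation are
    back-filled with that first observation (forward fill alone is
    undefined there).  Grid spans the full recording: length is
    ``floor((last_t - first_t)/step) + 1``.
    """
    if not raw.records:
        raise EmptyInputError("empty recording")
    per_feature: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in raw.feature_names:
        obs = [(t, v) for t, f, v in raw.records if f == name and np.isfinite(v)]
        ts = np.array([t for t, _ in obs], dtype=float)
        vs = np.array([v for _, v in obs], dtype=float)
        per_feature[name] = (ts, vs)

    all_t = [t for t, _, v in raw.records if np.isfinite(v)]
    first_t, last_t = min(all_t), max(all_t)
    n = int(np.floor((last_t - first_t) / step)) + 1
    grid = first_t + step * np.arange(n)

    out = np.empty((n, len(raw.feature_names)))
    for j, name in enumerate(raw.feature_names):
        ts, vs = per_feature[name]
        idx = np.searchsorted(ts, grid, side="right") - 1
        idx = np.clip(idx, 0, len(ts) - 1)  # leading gap -> first observation
        out[:, j] = vs[idx]
    return FeatureSeries(
        start_time=first_t, step=step, names=list(raw.feature_names), values=out
    )


def remove_outliers(
    series: FeatureSeries, method: str = "none", k: float = 5.0
) -> FeatureSeries:
    """Optionally strip gross spikes from each feature column.

    ``method="mad"`` marks points with ``|x - median| > k * 1.4826 * MAD``
    (strict) as missing and re-fills them by forward fill (first value
    back-filled).  With MAD = 0 the strict inequality removes any point
    off the median while leaving constant columns untouched.  The default
    ``method="none"`` never alters the data.
    """
    if method == "none":
        return series
    if method != "mad":
        raise ValueError(f"unknown outlier method {method!r}")
    values = series.values.copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        med = np.median(col)
        mad = np.median(np.abs(col - med))
        bad = np.abs(col - med) > k * 1.4826 * mad
        if not bad.any():
            continue
        kept = col.copy()
        kept[bad] = np.nan
        filled = pd.Series(kept).ffill().bfill().to_numpy()
        values[:, j] = filled
    return series.replace(values=values)


def read_events_csv(path: str | Path) -> EventAnnotation:
    """Read an event-point CSV with header ``t,polarity``."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputFormatError(f"{path}: missing header") from exc
    if not {"t", "polarity"}.issubset(df.columns):
        raise InputFormatError(f"{path}: expected columns t,polarity")
    events = []
    for _, row in df.iterrows():
        t = pd.to_numeric(row["t"], errors="coerce")
        if pd.isna(t):
            raise InputFormatError(f"{path}: unparseable event time {row['t']!r}")
        pol = str(row["polarity"]).strip()
        if pol not in VALID_POLARITIES:
            raise InputFormatError(f"{path}: unknown polarity {pol!r}")
        events.append((float(t), pol))
    events.sort(key=lambda e: e[0])
    return EventAnnotation(events=events)


def write_series_csv(series: FeatureSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def write_events_csv(annotation: EventAnnotation, path: str | Path) -> None:
    pd.DataFrame(annotation.events, columns=["t", "polarity"]).to_csv(
        path, index=False
    )
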