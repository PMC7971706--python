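"""Reading, quality filtering, period labeling and symbol coding of
fixation records.

Input is a delimited-text fixation table (one row per fixation: onset,
duration, AOI label, tracker confidence, participant, session) plus a
trial-event table (trial onset = deceleration of the front car, lane
change, trial end, difficulty, validity).  Quality control keeps
fixations with duration in [min, max] ms inclusive (defaults 100-1500)
and confidence >= threshold (default 0.9).  Period labeling follows the
trial structure: fixations in [onset, lane_change) are *before lane
change*, in [lane_change, end] *after lane change*, and the (up to) five
fixations immediately preceding a valid trial's onset form the
*baseline*; everything else is unlabeled.  Symbol coding turns the AOI
column of a single recording into a :class:`~scanpath_ais.infotheory.ScanPath`
with a back-index into the source rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .infotheory import ScanPath

__all__ = [
    "SchemaError",
    "FixationValidationError",
    "FilterLog",
    "FIXATION_COLUMNS",
    "EVENT_COLUMNS",
    "read_fixation_table",
    "read_trial_events",
    "filter_fixations",
    "assign_periods",
    "encode_symbols",
]

FIXATION_COLUMNS = ("onset", "duration_ms", "aoi", "confidence", "participant", "session")
EVENT_COLUMNS = ("trial_id", "onset", "lane_change", "end", "difficulty", "valid")

PERIODS = ("baseline", "before_lane_change", "after_lane_change")


class SchemaError(ValueError):
    """A required column cannot be resolved in the input table."""


class FixationValidationError(ValueError):
    """Rows violate a fixation-table invariant."""


@dataclass(frozen=True)
class FilterLog:
    """Per-criterion removal counts from quality filtering."""

    n_input: int
    n_short_duration: int
    n_long_duration: int
    n_low_confidence: int
    n_retained: int

    def __str__(self) -> str:
        return (
            f"fixation filter: {self.n_input} in, {self.n_retained} retained "
            f"({self.n_short_duration} below min duration, "
            f"{self.n_long_duration} above max duration, "
            f"{self.n_low_confidence} below min confidence)"
        )


def _resolve_schema(df: pd.DataFrame, schema: dict | None, required: tuple[str, ...]) -> pd.DataFrame:
    schema = schema or {}
    mapping = {schema.get(name, name): name for name in required}
    missing = [src for src in mapping if src not in df.columns]
    if missing:
        raise SchemaError(
            f"missing column(s) {missing}; available: {list(df.columns)}"
        )
    out = df.rename(columns=mapping)
    return out[[c for c in out.columns if c in required]]


def _require_numeric(df: pd.DataFrame, columns: list[str], label: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = (bad + 2).tolist()[:10]  # 1-based + header row
            raise FixationValidationError(
                f"non-numeric {col!r} in {label} at line(s) {lines}"
            )
        if coerced.isna().any():
            bad = (df.index[coerced.isna()] + 2).tolist()[:10]
            raise FixationValidationError(f"missing {col!r} in {label} at line(s) {bad}")
        df[col] = coerced
    return df


def read_fixation_table(source, schema: dict | None = None, A: int = 8, sep: str = ",") -> pd.DataFrame:
    """Read a delimited fixation table into the standard column layout.

    ``schema`` maps standard names (``onset``, ``duration_ms``, ``aoi``,
    ``confidence``, ``participant``, ``session``) to the file's column
    names.  Rows are validated (positive durations, AOI within ``1..A``,
    confidence in [0, 1]) and sorted by (participant, session, onset).
    """
    df = pd.read_csv(source, sep=sep)
    df = _resolve_schema(df, schema, FIXATION_COLUMNS)
    df = _require_numeric(df, ["onset", "duration_ms", "aoi", "confidence"], "fixation table")
    df["aoi"] = df["aoi"].astype(np.int64)
    return validate_fixation_table(df, A=A)


def validate_fixation_table(df: pd.DataFrame, A: int = 8) -> pd.DataFrame:
    """Check invariants and return the table sorted by recording and onset."""
    bad = df.index[(df["aoi"] < 1) | (df["aoi"] > A)]
    if len(bad):
        raise FixationValidationError(
            f"AOI labels outside 1..{A} at row(s) {bad.tolist()[:20]}"
        )
    bad = df.index[df["duration_ms"] <= 0]
    if len(bad):
        raise FixationValidationError(f"non-positive durations at row(s) {bad.tolist()[:20]}")
    bad = df.index[(df["confidence"] < 0) | (df["confidence"] > 1)]
    if len(bad):
        raise FixationValidationError(f"confidence outside [0, 1] at row(s) {bad.tolist()[:20]}")
    return df.sort_values(["participant", "session", "onset"], kind="stable").reset_index(drop=True)


def read_trial_events(source, schema: dict | None = None, sep: str = ",") -> pd.DataFrame:
    """Read a trial-event table (onset < lane_change < end per trial)."""
    df = pd.read_csv(source, sep=sep)
    required = EVENT_COLUMNS + (("participant",) if "participant" in df.columns or (schema or {}).get("participant") else ())
    df = _resolve_schema(df, schema, required)
    df = _require_numeric(df, ["onset", "lane_change", "end"], "event table")
    if df["valid"].dtype == object:
        df["valid"] = df["valid"].astype(str).str.lower().isin(("true", "1", "yes"))
    df["valid"] = df["valid"].astype(bool)
    return validate_trial_events(df)


def validate_trial_events(df: pd.DataFrame) -> pd.DataFrame:
    bad = df.index[~((df["onset"] < df["lane_change"]) & (df["lane_change"] < df["end"]))]
    if len(bad):
        raise FixationValidationError(
            f"trial events must satisfy onset < lane_change < end; rows {bad.tolist()}"
        )
    keys = ["participant"] if "participant" in df.columns else []
    df = df.sort_values(keys + ["onset"], kind="stable").reset_index(drop=True)
    for _, grp in df.groupby(keys) if keys else [(None, df)]:
        ends = grp["end"].to_numpy()
        onsets = grp["onset"].to_numpy()
        if np.any(onsets[1:] < ends[:-1]):
            raise FixationValidationError("trials overlap in time")
    return df


def filter_fixations(
    table: pd.DataFrame,
    min_duration_ms: float = 100.0,
    max_duration_ms: float = 1500.0,
    min_confidence: float = 0.9,
) -> tuple[pd.DataFrame, FilterLog]:
    """Quality-filter fixations; bounds are inclusive.

    A fixation is retained iff ``min_duration_ms <= duration <=
    max_duration_ms`` and ``confidence >= min_confidence`` (the exclusion
    rules drop what lies *below*/*above* the bounds, so exact boundary
    values stay).  Returns the filtered table and a :class:`FilterLog`
    with per-criterion removal counts.  An empty result is a warning, not
    an error.
    """
    if not 0 < min_duration_ms < max_duration_ms:
        raise ValueError("need 0 < min_duration_ms < max_duration_ms")
    dur = table["duration_ms"]
    conf = table["confidence"]
    short = dur < min_duration_ms
    long = dur > max_duration_ms
    low = conf < min_confidence
    keep = ~(short | long | low)
    log = FilterLog(
        n_input=len(table),
        n_short_duration=int(short.sum()),
        n_long_duration=int(long.sum()),
        n_low_confidence=int(low.sum()),
        n_retained=int(keep.sum()),
    )
    out = table[keep].reset_index(drop=True)
    if out.empty and len(table):
        warnings.warn("all fixations removed by quality filter", stacklevel=2)
    return out, log


def assign_periods(
    table: pd.DataFrame, events: pd.DataFrame, baseline_len: int = 5
) -> pd.DataFrame:
    """Label fixations with trial periods.

    ``before_lane_change`` covers onsets in ``[trial onset, lane_change)``,
    ``after_lane_change`` covers ``[lane_change, end]`` (half-open at the
    lane change so the partition is unambiguous), and ``baseline`` is the
    up to ``baseline_len`` yet-unlabeled fixations immediately preceding a
    valid trial's onset.  Invalid trials produce no labels.  Adds
    ``period``, ``trial_id`` and (if present in ``events``)
    ``difficulty`` columns; baseline fixations inherit the upcoming
    trial's id and difficulty.
    """
    events = validate_trial_events(events)
    out = table.copy()
    out["period"] = "none"
    out["trial_id"] = 0
    has_diff = "difficulty" in events.columns
    if has_diff:
        out["difficulty"] = ""

    per_participant = "participant" in events.columns
    for key, fx in out.groupby(["participant", "session"], sort=False):
        ev = events[events["participant"] == key[0]] if per_participant else events
        onset = fx["onset"].to_numpy()
        for _, tr in ev.iterrows():
            if not tr["valid"]:
                continue
            blc = (onset >= tr["onset"]) & (onset < tr["lane_change"])
            alc = (onset >= tr["lane_change"]) & (onset <= tr["end"])
            idx = fx.index
            labeled = out.loc[idx, "period"].to_numpy() != "none"
            if np.any((blc | alc) & labeled):
                raise FixationValidationError(
                    f"trial {tr['trial_id']} overlaps an already labeled period"
                )
            before = np.flatnonzero((onset < tr["onset"]) & ~labeled)
            base = before[-baseline_len:]
            if base.size < baseline_len:
                warnings.warn(
                    f"trial {tr['trial_id']}: baseline of only {base.size} fixations",
                    stacklevel=2,
                )
            for mask_or_pos, period in ((base, "baseline"), (np.flatnonzero(blc), "before_lane_change"), (np.flatnonzero(alc), "after_lane_change")):
                rows = idx[mask_or_pos]
                out.loc[rows, "period"] = period
                out.loc[rows, "trial_id"] = int(tr["trial_id"])
                if has_diff:
                    out.loc[rows, "difficulty"] = tr["difficulty"]
    return out


def encode_symbols(table: pd.DataFrame, A: int = 8) -> ScanPath:
    """Encode the AOI column of one recording as a scan path.

    The table must hold a single (participant, session); the returned
    path carries a back-index of source row labels so per-fixation local
    measures can be re-attached (after filtering the back-index is simply
    non-contiguous).
    """
    if table.empty:
        raise ValueError("cannot encode an empty fixation table")
    rec = table[["participant", "session"]].drop_duplicates()
    if len(rec) > 1:
        raise ValueError(
            f"table holds {len(rec)} recordings; split by (participant, session) first"
        )
    return ScanPath(
        symbols=table["aoi"].to_numpy(np.int64),
        A=A,
        back_index=table.index.to_numpy(),
    )
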