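"""Per-minute depth and rate summaries over the 12-minute analysis span.

Minute ``m`` (1-based) covers the half-open interval ``[60*(m-1), 60*m)``
seconds.  Mean depth is the arithmetic mean of the peak depths of the
compressions delivered in that minute.  Rate is the *active* compression
rate: ``60 / mean(inter-compression intervals)`` over intervals no longer
than the pause threshold, each interval attributed to the minute containing
its midpoint.  Hands-off gaps therefore do not dilute the rate — a provider
compressing at 110/min with a 20 s rhythm-check pause in the minute still
scores 110/min, mirroring how compression rate and a substantial no-flow
fraction coexist in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .events import AttemptRecord

DEFAULT_ANALYSIS_MINUTES = 12
DEFAULT_PAUSE_THRESHOLD_S = 1.5


@dataclass(frozen=True)
class MinuteSummary:
    """Summary of one analysis minute.

    ``mean_depth`` is None iff no compression fell in the minute; ``rate`` is
    None iff no qualifying inter-compression interval had its midpoint there.
    """

    minute: int
    mean_depth: float | None
    rate: float | None
    n_compressions: int


def minute_summaries(
    record: AttemptRecord,
    analysis_minutes: int = DEFAULT_ANALYSIS_MINUTES,
    pause_threshold: float = DEFAULT_PAUSE_THRESHOLD_S,
    allow_short: bool = False,
) -> list[MinuteSummary]:
    """Reduce an attempt's event stream to per-minute summaries.

    Events at or beyond ``60 * analysis_minutes`` seconds are ignored
    (attempts longer than the analysis span are truncated).  An attempt
    shorter than the span is an error unless ``allow_short`` is set, in which
    case only the complete minutes are analysed.

    Parameters
    ----------
    record : AttemptRecord
        Validated attempt.
    analysis_minutes : int
        Length of the analysis span in minutes (12 by default).
    pause_threshold : float
        Inter-compression intervals longer than this many seconds are treated
        as hands-off time and excluded from the rate.
    allow_short : bool
        Analyse ``floor(duration / 60)`` minutes when the attempt is shorter
        than the requested span instead of raising.
    """
    if analysis_minutes < 1:
        raise ValidationError(f"analysis_minutes must be >= 1, got {analysis_minutes}")
    span = 60.0 * analysis_minutes
    if record.duration < span:
        if not allow_short:
            raise ValidationError(
                f"attempt {record.attempt_id!r} lasts {record.duration} s, shorter "
                f"than the {span:.0f} s analysis span; pass allow_short=True to "
                f"analyse complete minutes only"
            )
        analysis_minutes = int(record.duration // 60)
        if analysis_minutes < 1:
            raise ValidationError(
                f"attempt {record.attempt_id!r} is shorter than one minute"
            )
        span = 60.0 * analysis_minutes

    times = np.asarray(record.times, dtype=float)
    depths = np.asarray(record.depths, dtype=float)
    in_span = times < span
    t = times[in_span]
    d = depths[in_span]
    minute_idx = np.floor(t / 60.0).astype(int)  # 0-based window index

    # depth and count per minute
    n_comp = np.bincount(minute_idx, minlength=analysis_minutes)[:analysis_minutes]
    depth_sum = np.bincount(minute_idx, weights=d, minlength=analysis_minutes)[
        :analysis_minutes
    ]

    # rate: qualifying intervals between consecutive compressions (full
    # stream, so an interval may straddle the span boundary; it counts iff
    # its midpoint lies inside the span)
    int_sum = np.zeros(analysis_minutes)
    int_n = np.zeros(analysis_minutes, dtype=int)
    if len(times) >= 2:
        lengths = np.diff(times)
        mids = (times[:-1] + times[1:]) / 2.0
        ok = (lengths <= pause_threshold) & (mids < span)
        mid_minute = np.floor(mids[ok] / 60.0).astype(int)
        int_sum = np.bincount(
            mid_minute, weights=lengths[ok], minlength=analysis_minutes
        )[:analysis_minutes]
        int_n = np.bincount(mid_minute, minlength=analysis_minutes)[:analysis_minutes]

    out: list[MinuteSummary] = []
    for m in range(analysis_minutes):
        n = int(n_comp[m])
        mean_depth = float(depth_sum[m] / n) if n > 0 else None
        rate = float(60.0 * int_n[m] / int_sum[m]) if int_n[m] > 0 else None
        out.append(
            MinuteSummary(minute=m + 1, mean_depth=mean_depth, rate=rate, n_compressions=n)
        )
    return out


def depth_trajectory(
    summaries: Sequence[MinuteSummary],
) -> list[tuple[int, float | None]]:
    """Reshape summaries into ordered (minute, mean_depth) pairs.

    Undefined depths are preserved as None; output is sorted by minute.
    """
    return [(s.minute, s.mean_depth) for s in sorted(summaries, key=lambda s: s.minute)]


def summaries_frame(
    summaries: Sequence[MinuteSummary], attempt_id: str
) -> pd.DataFrame:
    """Per-minute summary table for one attempt (CSV-exportable)."""
    return pd.DataFrame(
        {
            "attempt_id": attempt_id,
            "minute": [s.minute for s in summaries],
            "mean_depth_mm": [
                np.nan if s.mean_depth is None else s.mean_depth for s in summaries
            ],
            "rate_per_min": [np.nan if s.rate is None else s.rate for s in summaries],
            "n_compressions": [s.n_compressions for s in summaries],
        }
    )
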