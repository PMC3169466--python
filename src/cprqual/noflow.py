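"""Hands-off pause detection and the no-flow ratio (NFR).

The no-flow ratio is the fraction of scenario time during which no chest
compressions are delivered; lower is better, as coronary perfusion pressure
collapses within seconds of stopping compressions.  A *pause* is any maximal
compression-free interval longer than a threshold (1.5 s by default, the
convention in CPR-quality work — roughly three missed compressions at
guideline rate), including the leading interval from scenario start to the
first compression (initial patient assessment is genuine no-flow) and the
trailing interval after the last compression.  When a gap exceeds the
threshold the entire gap counts as hands-off, not just the excess.

NFR is reported overall and in four three-minute windows (Norwegian ALS
guidelines schedule rhythm checks every three minutes); a pause spanning a
window boundary contributes its within-window portion to each side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .events import AttemptRecord

DEFAULT_PAUSE_THRESHOLD_S = 1.5
DEFAULT_ANALYSIS_END_S = 720.0
WINDOW_S = 180.0
N_WINDOWS = 4


@dataclass(frozen=True)
class PauseInterval:
    """One maximal hands-off interval, in seconds from scenario start."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError(
                f"pause end must exceed start, got [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class NFRSeries:
    """No-flow ratio per three-minute window plus the overall ratio.

    ``window_nfr[k] = hands_off_seconds[k] / 180`` for windows 1-3, 4-6,
    7-9 and 10-12 minutes; ``overall_nfr`` is total hands-off time over the
    720 s span and equals the mean of the four window ratios.
    """

    hands_off_seconds: tuple[float, float, float, float]
    window_nfr: tuple[float, float, float, float]
    overall_nfr: float


def detect_pauses(
    record: AttemptRecord,
    pause_threshold: float = DEFAULT_PAUSE_THRESHOLD_S,
    analysis_end: float = DEFAULT_ANALYSIS_END_S,
) -> list[PauseInterval]:
    """Find all hands-off pauses in ``[0, analysis_end)``.

    Candidate gaps are the leading interval ``[0, first compression)``, every
    inter-compression interval, and the trailing interval from the last
    compression to the scenario end; a gap longer than ``pause_threshold``
    becomes a pause, clipped to the analysis span.  An attempt with no
    compressions at all is a single pause covering the whole span.
    """
    if not analysis_end > 0:
        raise ValidationError(f"analysis_end must be positive, got {analysis_end}")
    times = record.times
    if not times:
        return [PauseInterval(0.0, analysis_end)]
    bounds = [0.0, *times, max(record.duration, times[-1])]
    pauses: list[PauseInterval] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a > pause_threshold:
            start, end = max(a, 0.0), min(b, analysis_end)
            if end > start:
                pauses.append(PauseInterval(start, end))
    return pauses


def nfr_series(
    record: AttemptRecord,
    pause_threshold: float = DEFAULT_PAUSE_THRESHOLD_S,
) -> NFRSeries:
    """Compute the windowed and overall no-flow ratio of one attempt.

    The attempt must cover the full 720 s analysis span.
    """
    analysis_end = WINDOW_S * N_WINDOWS
    if record.duration < analysis_end:
        raise ValidationError(
            f"attempt {record.attempt_id!r} lasts {record.duration} s; "
            f"NFR needs the full {analysis_end:.0f} s span"
        )
    pauses = detect_pauses(record, pause_threshold, analysis_end)
    hands_off = np.zeros(N_WINDOWS)
    for p in pauses:
        for k in range(N_WINDOWS):
            lo, hi = k * WINDOW_S, (k + 1) * WINDOW_S
            overlap = min(p.end, hi) - max(p.start, lo)
            if overlap > 0:
                hands_off[k] += overlap
    window_nfr = hands_off / WINDOW_S
    overall = float(hands_off.sum() / analysis_end)
    return NFRSeries(
        hands_off_seconds=tuple(float(h) for h in hands_off),
        window_nfr=tuple(float(r) for r in window_nfr),
        overall_nfr=overall,
    )


@dataclass(frozen=True)
class CohortNFR:
    """Cohort-level NFR summary.

    ``window_means`` are arithmetic means over attempts of the per-window
    ratios; ``overall_range`` is (min, max) of the per-attempt overall NFR.
    """

    per_attempt: dict[str, NFRSeries]
    window_means: tuple[float, float, float, float]
    overall_mean: float
    overall_range: tuple[float, float]

    def matrix(self) -> np.ndarray:
        """Attempts x windows NFR matrix (attempt order = insertion order)."""
        return np.array([s.window_nfr for s in self.per_attempt.values()])

    def frame(self) -> pd.DataFrame:
        """Long-format table: attempt_id, window, hands_off_s, nfr."""
        rows = []
        for aid, series in self.per_attempt.items():
            for k in range(N_WINDOWS):
                rows.append(
                    {
                        "attempt_id": aid,
                        "window": k + 1,
                        "hands_off_s": series.hands_off_seconds[k],
                        "nfr": series.window_nfr[k],
                    }
                )
        return pd.DataFrame(rows)


def cohort_nfr(
    cohort: Sequence[AttemptRecord],
    pause_threshold: float = DEFAULT_PAUSE_THRESHOLD_S,
) -> CohortNFR:
    """Per-attempt NFR series plus cohort means and range."""
    if not cohort:
        raise ValidationError("cohort must contain at least one attempt")
    per_attempt = {
        rec.attempt_id: nfr_series(rec, pause_threshold) for rec in cohort
    }
    mat = np.array([s.window_nfr for s in per_attempt.values()])
    overalls = np.array([s.overall_nfr for s in per_attempt.values()])
    return CohortNFR(
        per_attempt=per_attempt,
        window_means=tuple(float(x) for x in mat.mean(axis=0)),
        overall_mean=float(overalls.mean()),
        overall_range=(float(overalls.min()), float(overalls.max())),
    )
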