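"""Good / bad / decay classification of compression quality.

Each attempt is classified twice, independently: once on per-minute mean
depth against a minimum-depth criterion, once on per-minute rate against a
guideline band.  The scheme follows the 2005 resuscitation guidelines
(depth >= 40 mm, rate 100-120/min) and operationalises provider fatigue as
*decay*: quality that starts inside the criterion and later falls outside.

    good  - every analysed minute satisfies the criterion
    bad   - minute 1 already fails it (the label is frozen at minute 1:
            an attempt that starts bad stays bad even if later minutes
            come into range)
    decay - minute 1 satisfies it but some later minute does not; the
            onset is the first failing minute

A minute with an undefined metric (no compressions) fails the criterion:
a minute without compressions cannot satisfy "for every minute".
Boundary values are inclusive: depth exactly at the minimum and rate exactly
at either band edge count as good.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .errors import ValidationError
from .events import AttemptRecord
from .minutes import (
    DEFAULT_ANALYSIS_MINUTES,
    DEFAULT_PAUSE_THRESHOLD_S,
    MinuteSummary,
    minute_summaries,
)

Label = Literal["good", "bad", "decay"]
Dimension = Literal["depth", "rate"]

LABELS: tuple[Label, ...] = ("good", "bad", "decay")


@dataclass(frozen=True)
class Thresholds:
    """Guideline criteria for compression quality.

    Defaults are the 2005 guideline values; ``depth_min`` can be raised to
    50 mm to assess against the 2010 recommendation.
    """

    depth_min: float = 40.0
    rate_low: float = 100.0
    rate_high: float = 120.0

    def __post_init__(self) -> None:
        if not self.depth_min > 0:
            raise ValidationError(f"depth_min must be positive, got {self.depth_min}")
        if not self.rate_low < self.rate_high:
            raise ValidationError(
                f"rate_low must be below rate_high, got [{self.rate_low}, {self.rate_high}]"
            )


@dataclass(frozen=True)
class QualityLabel:
    """Classification of one attempt along one dimension.

    ``onset_minute`` is the first failing minute for a decay label and None
    otherwise.
    """

    dimension: Dimension
    label: Label
    onset_minute: int | None = None

    def __post_init__(self) -> None:
        if (self.onset_minute is None) == (self.label == "decay"):
            raise ValidationError(
                f"onset_minute must be set iff label is 'decay' "
                f"(label={self.label!r}, onset={self.onset_minute!r})"
            )


def _classify(
    ok_per_minute: Sequence[bool], dimension: Dimension, expected_minutes: int
) -> QualityLabel:
    if len(ok_per_minute) < expected_minutes:
        raise ValidationError(
            f"need {expected_minutes} minute summaries, got {len(ok_per_minute)}"
        )
    ok = list(ok_per_minute[:expected_minutes])
    if not ok[0]:
        return QualityLabel(dimension=dimension, label="bad")
    for i, good_minute in enumerate(ok):
        if not good_minute:
            return QualityLabel(dimension=dimension, label="decay", onset_minute=i + 1)
    return QualityLabel(dimension=dimension, label="good")


def classify_depth(
    summaries: Sequence[MinuteSummary],
    th: Thresholds = Thresholds(),
    expected_minutes: int = DEFAULT_ANALYSIS_MINUTES,
) -> QualityLabel:
    """Classify an attempt's depth trajectory as good, bad or decay."""
    ok = [s.mean_depth is not None and s.mean_depth >= th.depth_min for s in summaries]
    return _classify(ok, "depth", expected_minutes)


def classify_rate(
    summaries: Sequence[MinuteSummary],
    th: Thresholds = Thresholds(),
    expected_minutes: int = DEFAULT_ANALYSIS_MINUTES,
) -> QualityLabel:
    """Classify an attempt's rate trajectory as good, bad or decay."""
    ok = [
        s.rate is not None and th.rate_low <= s.rate <= th.rate_high for s in summaries
    ]
    return _classify(ok, "rate", expected_minutes)


def classify_cohort(
    cohort: Sequence[AttemptRecord],
    th: Thresholds = Thresholds(),
    analysis_minutes: int = DEFAULT_ANALYSIS_MINUTES,
    pause_threshold: float = DEFAULT_PAUSE_THRESHOLD_S,
) -> tuple[pd.DataFrame, dict[Dimension, dict[Label, int]]]:
    """Classify every attempt in a cohort along both dimensions.

    Returns
    -------
    table : DataFrame
        Columns ``attempt_id, depth_label, depth_onset_min, rate_label,
        rate_onset_min``, one row per attempt in input order.
    counts : dict
        ``counts[dimension][label]`` group sizes; per dimension they sum to
        the cohort size.
    """
    if not cohort:
        raise ValidationError("cohort must contain at least one attempt")
    rows = []
    counts: dict[Dimension, dict[Label, int]] = {
        "depth": {lab: 0 for lab in LABELS},
        "rate": {lab: 0 for lab in LABELS},
    }
    for rec in cohort:
        try:
            summ = minute_summaries(
                rec, analysis_minutes=analysis_minutes, pause_threshold=pause_threshold
            )
            dlab = classify_depth(summ, th, expected_minutes=analysis_minutes)
            rlab = classify_rate(summ, th, expected_minutes=analysis_minutes)
        except ValidationError as exc:
            raise ValidationError(f"attempt {rec.attempt_id!r}: {exc}") from exc
        counts["depth"][dlab.label] += 1
        counts["rate"][rlab.label] += 1
        rows.append(
            {
                "attempt_id": rec.attempt_id,
                "depth_label": dlab.label,
                "depth_onset_min": dlab.onset_minute,
                "rate_label": rlab.label,
                "rate_onset_min": rlab.onset_minute,
            }
        )
    table = pd.DataFrame(rows).astype(
        {"depth_onset_min": "Int64", "rate_onset_min": "Int64"}
    )
    return table, counts


def count_percentages(
    counts: dict[Label, int]
) -> dict[Label, int]:
    """Group sizes as integer percentages of the cohort (nearest percent)."""
    n = sum(counts.values())
    return {lab: round(100.0 * counts[lab] / n) for lab in LABELS}
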