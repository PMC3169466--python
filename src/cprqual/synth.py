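"""Synthetic manikin-recording generator.

Emulates 12-minute advanced-life-support (ALS) scenarios in which a single
provider delivers all chest compressions on a recording manikin: the patient
is found in ventricular fibrillation, converts to pulseless electrical
activity (PEA) after the first shock, and is intubated around five minutes,
after which compressions can continue through ventilations and hands-off
time shrinks.

Each attempt is driven by a provider profile: a depth baseline with optional
linear fatigue decay after a provider-specific onset minute, a rate baseline
with optional linear drift, per-compression Gaussian noise on both, and a
scenario pause schedule (initial assessment, defibrillation, three-minute
rhythm checks, intubation).  Compressions are laid down sequentially: the
next compression falls one inter-compression interval ``60 / rate(t)`` after
the previous one, jumping to the end of any scheduled pause it lands in.

:func:`reference_cohort` builds the shipped fixed-seed 19-attempt
demonstration cohort whose group structure mirrors a typical ALS manikin
study: depth groups 5 good / 9 bad / 5 decay (onsets at minutes 2, 4, 8, 11,
12, plus one bad attempt adequate only during minutes 3-8), rate groups
6 good / 6 bad / 7 decay (a single onset within the first five minutes; two
bad attempts in band from minute 2 onward), and a no-flow ratio that starts
near 22% and falls to 10% by the final period.  Its per-attempt trajectories
and pause durations are invented tuning constants — plausible synthetic
stand-ins, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .events import AttemptRecord, CompressionEvent

DEFAULT_MASTER_SEED = 4040
_MIN_RATE = 30.0  # floor guarding against noise driving the rate nonpositive


@dataclass(frozen=True)
class Pause:
    """Scheduled hands-off interval with its scenario cause."""

    start_s: float
    duration_s: float
    cause: str = "pause"

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic attempt.

    Depth model: ``depth(t) = depth_baseline_mm + slope * max(0, t/60 -
    (onset - 1)) + N(0, depth_noise_sd_mm)``, truncated at 0 — decay begins
    at the start of the 1-based onset minute.  Rate model: ``rate(t) =
    rate_baseline + rate_drift_per_min * t/60 + N(0, rate_noise_sd)``.

    ``depth_minute_means`` / ``rate_minute_means`` (one value per analysis
    minute) override the parametric mean with a piecewise-constant profile;
    noise still applies.
    """

    attempt_id: str = "SYN"
    depth_baseline_mm: float = 45.0
    depth_noise_sd_mm: float = 0.0
    depth_decay_onset_min: int | None = None
    depth_decay_slope_mm_per_min: float = 0.0
    rate_baseline: float = 110.0
    rate_noise_sd: float = 0.0
    rate_drift_per_min: float = 0.0
    depth_minute_means: tuple[float, ...] | None = None
    rate_minute_means: tuple[float, ...] | None = None
    pause_schedule: tuple[Pause, ...] = ()
    duration_s: float = 720.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_noise_sd_mm < 0 or self.rate_noise_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if self.depth_decay_slope_mm_per_min > 0:
            raise ValidationError("depth decay slope must be <= 0 (mm/min)")
        if self.depth_decay_onset_min is not None and self.depth_decay_onset_min < 1:
            raise ValidationError("decay onset minute must be >= 1")
        pauses = tuple(sorted(self.pause_schedule, key=lambda p: p.start_s))
        prev_end = 0.0
        for p in pauses:
            if p.duration_s <= 0:
                raise ValidationError(f"pause at {p.start_s} has nonpositive duration")
            if p.start_s < prev_end:
                raise ValidationError(f"pauses overlap near t={p.start_s}")
            if p.end_s > self.duration_s:
                raise ValidationError(f"pause at {p.start_s} extends past duration")
            prev_end = p.end_s
        object.__setattr__(self, "pause_schedule", pauses)

    def depth_mean(self, t: float) -> float:
        """Noise-free depth at time t (s)."""
        if self.depth_minute_means is not None:
            idx = min(int(t // 60), len(self.depth_minute_means) - 1)
            return self.depth_minute_means[idx]
        d = self.depth_baseline_mm
        if self.depth_decay_onset_min is not None:
            elapsed = t / 60.0 - (self.depth_decay_onset_min - 1)
            if elapsed > 0:
                d += self.depth_decay_slope_mm_per_min * elapsed
        return d

    def rate_mean(self, t: float) -> float:
        """Noise-free rate at time t (s)."""
        if self.rate_minute_means is not None:
            idx = min(int(t // 60), len(self.rate_minute_means) - 1)
            return self.rate_minute_means[idx]
        return self.rate_baseline + self.rate_drift_per_min * t / 60.0


def generate_attempt(config: SyntheticConfig) -> AttemptRecord:
    """Generate one attempt's compression event stream; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    pauses = config.pause_schedule
    events: list[CompressionEvent] = []
    t = 0.0
    while True:
        rate = config.rate_mean(t)
        if config.rate_noise_sd > 0:
            rate += rng.normal(0.0, config.rate_noise_sd)
        rate = max(rate, _MIN_RATE)
        t_next = t + 60.0 / rate
        moved = True
        while moved:
            moved = False
            for p in pauses:
                if p.start_s <= t_next < p.end_s:
                    t_next = p.end_s
                    moved = True
        if t_next >= config.duration_s:
            break
        depth = config.depth_mean(t_next)
        if config.depth_noise_sd_mm > 0:
            depth += rng.normal(0.0, config.depth_noise_sd_mm)
        depth = max(depth, 0.0)
        events.append(CompressionEvent(time=t_next, depth=depth))
        t = t_next
    if not events:
        raise ValidationError(
            f"config {config.attempt_id!r}: pause schedule leaves no room "
            f"for compressions"
        )
    return AttemptRecord(
        attempt_id=config.attempt_id, events=tuple(events), duration=config.duration_s
    )


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """n independent per-attempt sub-seeds from a master seed."""
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n)]


def generate_cohort(configs: Sequence[SyntheticConfig]) -> list[AttemptRecord]:
    """Generate one attempt per config; ids must be distinct."""
    if not configs:
        raise ValidationError("need at least one config")
    ids = [c.attempt_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValidationError("attempt ids must be distinct")
    return [generate_attempt(c) for c in configs]


# --------------------------------------------------------------------------
# Reference cohort: 19 attempts, hand-tuned constants.
#
# Depth profiles (mm, one mean per minute).  Group design:
#   good  (5): A01-A05, comfortably above 40 mm throughout
#   bad   (9): A06-A14, minute 1 below 40 mm; A06 climbs into range during
#              minutes 3-8 only (bad label is frozen at minute 1)
#   decay (5): A15-A19, in range at minute 1, first sub-40 minute at
#              2, 4, 8, 11 and 12 respectively
# Rate profiles (per minute).  Group design:
#   good  (6): A01, A06, A07, A08, A15, A16 inside 100-120 throughout
#   bad   (6): A02, A03, A10, A11 fast throughout; A09 fast and A12 slow in
#              minute 1 only (both in band from minute 2)
#   decay (7): A04-A05, A13-A14, A17-A19; only A13's onset (minute 4) falls
#              within the first five minutes
# --------------------------------------------------------------------------

def _const(x: float, n: int = 12) -> tuple[float, ...]:
    return (x,) * n


def _step(pre: float, post_start: float, onset: int, per_min_drop: float = 0.8
          ) -> tuple[float, ...]:
    """In range for minutes < onset, then declining from ``post_start``."""
    return tuple(
        pre if m < onset else post_start - per_min_drop * (m - onset)
        for m in range(1, 13)
    )


_DEPTH_PROFILES: dict[str, tuple[float, ...]] = {
    "A01": _const(44.0),
    "A02": _const(46.0),
    "A03": _const(43.0),
    "A04": _const(48.0),
    "A05": _const(42.0),
    "A06": (37.0, 37.0, 42.0, 42.0, 42.0, 42.0, 42.0, 42.0, 37.0, 37.0, 37.0, 37.0),
    "A07": _const(34.0),
    "A08": _const(36.0),
    "A09": _const(38.0),
    "A10": _const(32.0),
    "A11": _const(35.0),
    "A12": _const(33.0),
    "A13": _const(36.0),
    "A14": _const(38.0),
    "A15": _step(43.0, 38.0, onset=2),
    "A16": _step(44.0, 38.0, onset=4),
    "A17": _step(42.0, 38.0, onset=8, per_min_drop=1.0),
    "A18": _step(45.0, 38.5, onset=11, per_min_drop=1.5),
    "A19": _step(41.5, 38.0, onset=12),
}

_RATE_PROFILES: dict[str, tuple[float, ...]] = {
    "A01": _const(107.0),
    "A02": _const(123.0),
    "A03": _const(126.0),
    "A04": _const(112.0, 5) + _const(124.0, 7),
    "A05": _const(108.0, 6) + _const(95.0, 6),
    "A06": _const(108.0),
    "A07": _const(112.0),
    "A08": _const(105.0),
    "A09": (125.0,) + _const(110.0, 11),
    "A10": _const(128.0),
    "A11": _const(124.0),
    "A12": (95.0,) + _const(105.0, 11),
    "A13": _const(110.0, 3) + _const(95.0, 9),
    "A14": _const(115.0, 7) + _const(124.0, 5),
    "A15": _const(110.0),
    "A16": _const(115.0),
    "A17": _const(110.0, 8) + _const(96.0, 4),
    "A18": _const(105.0, 9) + _const(94.0, 3),
    "A19": _const(112.0, 11) + (125.0,),
}

# Per-attempt hands-off scaling: window hands-off seconds are
# s_i * (39.6, 39.6, 25.2, 18.0), i.e. s_i * 180 * (0.22, 0.22, 0.14, 0.10).
# The factors average exactly 1.0, so cohort window NFR means land on
# 22/22/14/10% and the overall mean on 17%; the extremes put the overall
# per-attempt range at ~10% and ~32%.
_NFR_SCALE: dict[str, float] = {
    "A01": 0.59, "A02": 1.88, "A03": 0.70, "A04": 0.78, "A05": 0.85,
    "A06": 0.90, "A07": 0.95, "A08": 1.00, "A09": 1.05, "A10": 1.10,
    "A11": 1.15, "A12": 0.88, "A13": 0.92, "A14": 0.98, "A15": 1.02,
    "A16": 1.08, "A17": 1.12, "A18": 0.80, "A19": 1.25,
}

_WINDOW_HANDS_OFF_S = (39.6, 39.6, 25.2, 18.0)

FIXTURE_DEPTH_NOISE_SD_MM = 1.5
FIXTURE_RATE_NOISE_SD = 3.0


def _scenario_pauses(scale: float) -> tuple[Pause, ...]:
    """Pause schedule for one attempt, scaled by its hands-off factor.

    Narrative: initial assessment from t = 0, one defibrillation around 60 s
    (the first shock converts VF to PEA, so no later shocks), rhythm checks
    at 180/360/540 s, intubation around 300 s; after intubation the
    ventilation-related gaps shrink, so windows 3 and 4 carry less hands-off
    time than windows 1 and 2.
    """
    h1, h2, h3, h4 = (scale * w for w in _WINDOW_HANDS_OFF_S)
    return (
        Pause(0.0, 0.45 * h1, "assessment"),
        Pause(60.0, 0.55 * h1, "defibrillation"),
        Pause(180.0, 0.50 * h2, "rhythm_check"),
        Pause(300.0, 0.50 * h2, "intubation"),
        Pause(360.0, 0.70 * h3, "rhythm_check"),
        Pause(450.0, 0.30 * h3, "ventilation"),
        Pause(540.0, 0.70 * h4, "rhythm_check"),
        Pause(630.0, 0.30 * h4, "ventilation"),
    )


def reference_configs(
    master_seed: int = DEFAULT_MASTER_SEED,
) -> list[SyntheticConfig]:
    """The 19 hand-tuned attempt configs behind :func:`reference_cohort`."""
    ids = sorted(_DEPTH_PROFILES)
    seeds = derive_seeds(master_seed, len(ids))
    return [
        SyntheticConfig(
            attempt_id=aid,
            depth_minute_means=_DEPTH_PROFILES[aid],
            rate_minute_means=_RATE_PROFILES[aid],
            depth_noise_sd_mm=FIXTURE_DEPTH_NOISE_SD_MM,
            rate_noise_sd=FIXTURE_RATE_NOISE_SD,
            pause_schedule=_scenario_pauses(_NFR_SCALE[aid]),
            duration_s=720.0,
            seed=seed,
        )
        for aid, seed in zip(ids, seeds)
    ]


def reference_cohort(
    master_seed: int = DEFAULT_MASTER_SEED,
) -> list[AttemptRecord]:
    """Generate the fixed-seed 19-attempt demonstration cohort.

    Regenerating with the same master seed yields identical records (and
    therefore byte-identical files when written).
    """
    return generate_cohort(reference_configs(master_seed))
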