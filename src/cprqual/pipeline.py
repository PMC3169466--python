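"""End-to-end analysis runs: cohort in, report bundle out.

A run reads a cohort (directory or manifest), computes per-minute summaries,
quality classifications, no-flow ratios and — when at least two attempts are
present — the NFR trend statistics, and writes a deterministic report
bundle::

    minutes.csv          per attempt-minute depth/rate/count table
    classification.csv   good/bad/decay labels and decay onsets
    nfr.csv              per attempt-window hands-off seconds and NFR
    nfr_summary.csv      cohort window means, overall mean and range
    stats.json           ANOVA + pairwise tests + adjusted alpha
    summary.txt          human-readable digest (integer percentages)
    run_manifest.json    config hash, package version, cohort size

Rerunning with the same inputs and configuration produces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .classify import Thresholds, classify_cohort, count_percentages, LABELS
from .errors import CprQualError, ZeroVarianceError
from .events import AttemptRecord, read_cohort
from .minutes import (
    DEFAULT_ANALYSIS_MINUTES,
    DEFAULT_PAUSE_THRESHOLD_S,
    minute_summaries,
    summaries_frame,
)
from .noflow import cohort_nfr
from .stats import nfr_trend_analysis

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6f"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run."""

    input_path: str
    output_dir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    pause_threshold: float = DEFAULT_PAUSE_THRESHOLD_S
    analysis_minutes: int = DEFAULT_ANALYSIS_MINUTES
    family_alpha: float = 0.05

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory results (classification table, counts,
    cohort NFR, trend report or None).  Any stage failure removes partial
    outputs and re-raises with stage context.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        cohort = read_cohort(config.input_path)
        logger.info("read %d attempts from %s", len(cohort), config.input_path)
        return _run_on_cohort(cohort, config, out, written)
    except CprQualError:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_on_cohort(
    cohort: Sequence[AttemptRecord], config: RunConfig, out: Path, written: list[Path]
) -> dict:
    def _write_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
        written.append(p)

    # stage: minute metrics
    minute_tables = []
    for rec in cohort:
        summ = minute_summaries(
            rec,
            analysis_minutes=config.analysis_minutes,
            pause_threshold=config.pause_threshold,
        )
        minute_tables.append(summaries_frame(summ, rec.attempt_id))
    _write_csv(pd.concat(minute_tables, ignore_index=True), "minutes.csv")

    # stage: classification
    table, counts = classify_cohort(
        cohort,
        th=config.thresholds,
        analysis_minutes=config.analysis_minutes,
        pause_threshold=config.pause_threshold,
    )
    _write_csv(table, "classification.csv")

    # stage: no-flow ratio
    nfr = cohort_nfr(cohort, pause_threshold=config.pause_threshold)
    _write_csv(nfr.frame(), "nfr.csv")
    summary_df = pd.DataFrame(
        {
            "window": [1, 2, 3, 4, "overall_mean", "overall_min", "overall_max"],
            "nfr": [*nfr.window_means, nfr.overall_mean, *nfr.overall_range],
        }
    )
    _write_csv(summary_df, "nfr_summary.csv")

    # stage: trend statistics (needs >= 2 attempts)
    report = None
    if len(cohort) >= 2:
        try:
            report = nfr_trend_analysis(nfr.matrix(), family_alpha=config.family_alpha)
        except ZeroVarianceError as exc:
            logger.warning("trend statistics skipped: %s", exc)
    else:
        logger.warning("trend statistics skipped: only %d attempt(s)", len(cohort))
    stats_path = out / "stats.json"
    stats_payload = report.to_dict() if report is not None else {"skipped": True}
    stats_path.write_text(
        json.dumps(stats_payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    written.append(stats_path)

    # stage: human-readable summary
    (out / "summary.txt").write_text(
        _summary_text(len(cohort), counts, nfr, report), encoding="utf-8"
    )
    written.append(out / "summary.txt")

    manifest = {
        "config_hash": config.config_hash(),
        "cprqual_version": __version__,
        "n_attempts": len(cohort),
        "config": asdict(config),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    written.append(out / "run_manifest.json")
    return {
        "classification": table,
        "counts": counts,
        "nfr": nfr,
        "trend": report,
    }


def _summary_text(n: int, counts, nfr, report) -> str:
    lines = [f"Cohort of {n} resuscitation attempt(s), 12-minute analysis span", ""]
    for dim in ("depth", "rate"):
        pct = count_percentages(counts[dim])
        parts = ", ".join(
            f"{lab} {counts[dim][lab]}/{n} ({pct[lab]}%)" for lab in LABELS
        )
        lines.append(f"Compression {dim}: {parts}")
    lines.append("")
    win = ", ".join(
        f"{lo}-{hi} min {round(100 * v)}%"
        for (lo, hi), v in zip(((1, 3), (4, 6), (7, 9), (10, 12)), nfr.window_means)
    )
    lines.append(f"No-flow ratio by period: {win}")
    lines.append(
        f"Overall no-flow ratio: mean {round(100 * nfr.overall_mean)}%, "
        f"range {round(100 * nfr.overall_range[0])}-{round(100 * nfr.overall_range[1])}%"
    )
    if report is not None:
        a = report.anova
        lines.append(
            f"NFR trend: F({a.df_effect},{a.df_error}) = {a.f_stat:.2f}, "
            f"p = {a.p_value:.3g}; pairwise vs period 1 at alpha "
            f"{report.alpha_adjusted:.3f}: "
            + ", ".join(
                f"1v{t.periods[1]} p={t.p_value:.3g}"
                f"{'*' if t.significant_at_bonferroni else ''}"
                for t in report.pairwise
            )
        )
    else:
        lines.append("NFR trend statistics: skipped")
    return "\n".join(lines) + "\n"
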