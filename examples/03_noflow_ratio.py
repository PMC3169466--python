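"""No-flow ratio of a single attempt, windowed in three-minute periods.

The no-flow ratio (NFR) is hands-off time over scenario time.  Pauses are
maximal compression-free gaps longer than 1.5 s, including the leading
assessment interval; a pause spanning a window boundary is split between
the windows.
"""

from cprqual import Pause, SyntheticConfig, detect_pauses, generate_attempt, nfr_series

cfg = SyntheticConfig(
    attempt_id="demo-nfr",
    rate_baseline=110.0,
    pause_schedule=(
        Pause(0.0, 18.0, "assessment"),
        Pause(60.0, 22.0, "defibrillation"),
        Pause(180.0, 20.0, "rhythm_check"),
        Pause(300.0, 15.0, "intubation"),
        Pause(360.0, 12.0, "rhythm_check"),
        Pause(540.0, 8.0, "rhythm_check"),
    ),
    seed=3,
)
record = generate_attempt(cfg)

pauses = detect_pauses(record)
print(f"{len(pauses)} pauses detected:")
for p in pauses:
    print(f"  [{p.start:6.1f}, {p.end:6.1f}) s  length {p.length:5.1f} s")

series = nfr_series(record)
for k, (h, r) in enumerate(zip(series.hands_off_seconds, series.window_nfr), 1):
    print(f"period {k} (minutes {3*k-2}-{3*k}): hands-off {h:5.1f} s, NFR {100*r:.1f}%")
print(f"overall NFR: {100 * series.overall_nfr:.1f}%")
# Scheduled hands-off time concentrates early (assessment + shock), so the
# per-period NFR declines over the scenario, as it does when a patient in
# PEA needs no further defibrillation and intubation allows continuous
# compressions.
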