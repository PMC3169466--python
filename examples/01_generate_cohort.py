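"""Generate the reference cohort and write it as attempt CSV files.

Builds the shipped fixed-seed 19-attempt synthetic cohort (12-minute ALS
scenarios with provider-specific depth/rate profiles and a scenario pause
schedule) and writes one CSV per attempt plus a manifest.
"""

from pathlib import Path

from cprqual import reference_cohort, write_cohort

cohort = reference_cohort()
out = Path("scratch_example_cohort")
manifest = write_cohort(cohort, out)

print(f"wrote {len(cohort)} attempts under {out}/ (manifest: {manifest})")
first = cohort[0]
print(
    f"attempt {first.attempt_id}: {len(first.events)} compressions over "
    f"{first.duration:.0f} s; first at t={first.events[0].time:.2f} s, "
    f"depth {first.events[0].depth:.1f} mm"
)
# Each attempt is one event stream: ~1100-1300 compressions in 12 minutes,
# with hands-off gaps where the scenario pauses (assessment, shock, rhythm
# checks, intubation) interrupt compressions.
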