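"""Full cohort pipeline: classification counts, NFR trajectory, trend tests.

Runs every stage on the 19-attempt reference cohort and prints the numbers
a study report would quote: group percentages per quality dimension, the
cohort NFR trajectory, and the repeated-measures ANOVA with Bonferroni-
corrected paired comparisons against the first period.
"""

from cprqual import (
    classify_cohort,
    cohort_nfr,
    count_percentages,
    nfr_trend_analysis,
    reference_cohort,
)

cohort = reference_cohort()
table, counts = classify_cohort(cohort)

for dim in ("depth", "rate"):
    pct = count_percentages(counts[dim])
    print(
        f"{dim:5s}: good {counts[dim]['good']}/19 ({pct['good']}%), "
        f"bad {counts[dim]['bad']}/19 ({pct['bad']}%), "
        f"decay {counts[dim]['decay']}/19 ({pct['decay']}%)"
    )
print("depth decay onsets (min):",
      sorted(table["depth_onset_min"].dropna().astype(int).tolist()))

nfr = cohort_nfr(cohort)
print("NFR by period:", ", ".join(f"{100*v:.0f}%" for v in nfr.window_means),
      f"| overall mean {100*nfr.overall_mean:.0f}%, "
      f"range {100*nfr.overall_range[0]:.0f}-{100*nfr.overall_range[1]:.0f}%")

report = nfr_trend_analysis(nfr.matrix())
a = report.anova
print(f"rm-ANOVA: F({a.df_effect},{a.df_error}) = {a.f_stat:.1f}, p = {a.p_value:.2g}")
for t in report.pairwise:
    flag = "significant" if t.significant_at_bonferroni else "n.s."
    print(f"period 1 vs {t.periods[1]}: t = {t.t_stat:6.2f}, p = {t.p_value:.2g} "
          f"({flag} at alpha = {report.alpha_adjusted:.3f})")
# The NFR holds steady across the first two periods, then falls; the
# omnibus test and the period-1-vs-3/4 comparisons are significant while
# 1-vs-2 is not -- hands-off time shrinks once the patient is intubated and
# no further shocks are needed.
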