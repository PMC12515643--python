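"""Pre/post clinical outcomes of the embedded 20-patient score table.

Prints the FMA-UE and ARAT summary (mean ± SD before and after the rTMS
course) with the paired t statistic, alongside the normality-gated
Wilcoxon alternative.
"""

import motorstates as ms

scores = ms.clinical_fixture()
print(f"n = {len(scores)} patients, mean age {scores['age'].mean():.2f} "
      f"± {scores['age'].std(ddof=1):.2f} years")
print(f"pulses per rTMS session: {ms.rtms_pulse_count(10, 2, 60)}\n")

report = ms.clinical_outcomes_report(scores)
cols = ["pre_mean", "pre_sd", "post_mean", "post_sd", "t", "p", "selected_test"]
print(report[cols].round(3))
# A positive t means scores improved after treatment; 'selected_test' shows
# which test the Shapiro-Wilk normality gate would report.
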