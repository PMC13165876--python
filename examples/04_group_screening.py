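"""Screen every feature for group differences with the Mann-Whitney U test.

Runs the full pipeline (preprocessing, event segmentation, feature
extraction) on a small cohort and reports two-sided rank-test p-values with
group medians. The direction column is +1 when the cognitive-decline group's
median is higher.
"""

import gazecog as gc
from gazecog.stats import stats_table

cohort = gc.generate_cohort(gc.CohortConfig(n_hc=8, n_cd=8, seed=2))
fvs = {r.subject_id: gc.extract_all(r, t.rois)
       for r, t in zip(cohort.sessions, cohort.truth)}
covs = {c.subject_id: c for c in cohort.covariates}
table = gc.assemble_baseline_table(fvs, covs)

results = gc.mannwhitney_all(table, table["label"].to_numpy(),
                             columns=gc.FEATURE_NAMES)
print(stats_table(results).round(4).to_string(index=False))
n_sig = sum(r.p_value < 0.05 for r in results)
print(f"\n{n_sig}/{len(results)} features with p < 0.05 at n=8/8")
# At the default 20/20 cohort size every injected effect reaches p < 0.05;
# at n=8/8 the weaker ones may not.
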