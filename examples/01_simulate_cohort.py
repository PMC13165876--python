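"""Generate a small synthetic cohort and write it to disk.

Each subject gets a full five-paradigm session at 120 Hz (visual search,
memory calculation, pupillary light reflex, pro/anti-saccades, facial
expression) plus demographics and MoCA-B covariates. The ground-truth JSON
records every injected behavioral value for later recovery checks.
"""

from pathlib import Path

import gazecog as gc
from gazecog.synth import write_cohort

cfg = gc.CohortConfig(n_hc=4, n_cd=4, seed=0)
cohort = gc.generate_cohort(cfg)
out = Path("scratch_example_cohort")
write_cohort(cohort, out)

for rec, cov in zip(cohort.sessions, cohort.covariates):
    print(f"{rec.subject_id}  group={rec.group.value}  "
          f"samples={len(rec)}  duration={len(rec) / 120:.0f} s  "
          f"age={cov.age:.0f}  MoCA-B={cov.moca_total:.0f}")
print(f"\nwrote {len(cohort.sessions)} session CSVs + covariates + "
      f"ground truth to {out}/")
# Each session is ~150 s of synchronized eye-tracking (11 channels), eye
# openness, and facial blend-shape streams with task labels per sample.
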