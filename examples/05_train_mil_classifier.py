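"""Train the multi-scale convolutional MIL classifier at reduced scale.

Each subject's per-task channel matrix (11 oculomotor + 6 facial channels,
z-scored with training statistics) is cut into overlapping 150-sample
windows (stride 50). Phase 1 fits the four-stream convolutional encoder on
windows with inherited subject labels under soft loss weighting; phase 2
freezes the encoder and fits gated-attention pooling with a bag-level
classifier. Five task models vote by majority for the subject diagnosis.

This demo shrinks the cohort and the training budget so it finishes in
about a minute; the full protocol lives in `evaluate_protocol`.
"""

import numpy as np

import gazecog as gc
from gazecog.model import mil

cohort = gc.generate_cohort(gc.CohortConfig(n_hc=10, n_cd=10, seed=5))
subjects = [mil.prepare_subject(rec, int(rec.group is gc.Group.CD))
            for rec in cohort.sessions]

train = subjects[:7] + subjects[10:17]
test = subjects[7:10] + subjects[17:]
rng = np.random.default_rng(0)
models = mil.train_task_models(
    train, val=[], rng=rng,
    p1_cfg=mil.SoftWeightConfig(epochs=6),
    p2_cfg=mil.Phase2Config(epochs=12))

print("held-out predictions (CD = 1):")
y_true, y_pred = [], []
for sub in test:
    vote = mil.predict_subject(sub, models)
    votes = {t.value: v for t, v in vote.votes.items()}
    print(f"  {sub.subject_id}  true={sub.label}  fused={vote.final}  "
          f"per-task={votes}")
    y_true.append(sub.label)
    y_pred.append(vote.final)
m = gc.classification_metrics(np.array(y_true), np.array(y_pred))
print({k: round(v, 3) for k, v in m.items()})
# The fused vote needs 3 of 5 task models to agree; with 5 voters a binary
# vote cannot tie.
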