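"""Preprocess one session and segment gaze into fixations and saccades.

The pipeline: blink detection on eye openness (threshold 0.9), linear
interpolation of the gaps, causal 2nd-order Butterworth low-pass on pupil
diameter (cutoff fs/8), cyclopean gaze merging with angular velocity, then
I-VDT event segmentation (velocity 30 deg/s, window 130 ms, dispersion 2
deg, minimum saccade duration 40 ms).
"""


import gazecog as gc
from gazecog.events import events_table

cohort = gc.generate_cohort(gc.CohortConfig(n_hc=1, n_cd=1, seed=4))
rec = cohort.sessions[0]

clean, blink_mask = gc.preprocess_recording(rec)
print(f"samples: {len(rec)}, blink-marked: {blink_mask.sum()} "
      f"({100 * blink_mask.mean():.1f}%)")

segments = gc.segment_tasks(clean)
search = next(s for s in segments
              if s.task is gc.Task.VSST and s.phase is gc.Phase.SEARCH)
gaze = gc.merge_gaze(clean, search.start, search.stop)
events = gc.ivdt_segment(gaze)

table = events_table(events)
print("\nevents in the 8-s visual-search phase:")
print(table.round(3).to_string(index=False))
n_fix = (table["kind"] == "fixation").sum()
print(f"\n{n_fix} fixations, {len(table) - n_fix} saccades; fixation time "
      f"{table.loc[table.kind == 'fixation', 'offset'].sub(table.loc[table.kind == 'fixation', 'onset']).sum():.2f} s")
# Saccade amplitudes are in degrees of visual angle seen from the cyclopean
# origin; velocities in deg/s.
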