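"""Transition-point annotation: intervals to per-frame labels and back.

Annotators mark only the frames where the stone's focus state changes;
expansion recovers one label per frame.  Corruption emulates the 37.5%
interobserver mismatch measured between two annotators.
"""

import numpy as np

from lithofocus import IntervalLabel, corrupt_labels, expand_intervals
from lithofocus.annotations import compress_labels

# in focus from the start; transition to out of focus at frame 9
intervals = [IntervalLabel(0, "in_focus"), IntervalLabel(9, "out_of_focus"),
             IntervalLabel(42, "in_focus")]
labels = expand_intervals(intervals, n_frames=120, patient_id="demo")
print(f"records: {len(intervals)} -> frames: {len(labels)}")
print(f"frames in focus: {labels.n_focus}")
print(f"round trip intact: {compress_labels(labels) == intervals}")

noisy = corrupt_labels(labels, mismatch_rate=0.375, seed=0)
mismatch = np.mean(noisy.labels != labels.labels)
print(f"simulated interobserver mismatch: {mismatch:.1%}")

# Three transition records stand in for 120 frame labels; the mismatch
# fraction approaches the requested 37.5% as sequences grow.
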