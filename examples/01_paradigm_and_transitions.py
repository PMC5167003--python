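"""Block paradigm: labels, transitions, and transition-period exclusion.

Builds the 300-s visuomotor schedule (five cycles of alternating 30-s
task/rest blocks) and shows which frames of a TR = 2 s acquisition fall in
the k-point windows around each state switch.
"""

import numpy as np

import blockdecode as bd

p = bd.Paradigm(block_duration=30.0, n_cycles=5, first_state=bd.TASK)
print(f"total duration : {p.total_duration:.0f} s in {p.n_blocks} blocks")
print(f"transitions    : {p.n_transitions} at {p.transition_times()} s")

times = np.arange(0, p.total_duration, 2.0)  # TR = 2 s -> 150 frames
print(f"frames         : {len(times)} (TR 2 s)")
print(f"label at 15 s  : {p.label_at_time(15)}  (+1 = task)")
print(f"label at 45 s  : {p.label_at_time(45)}  (-1 = rest)")

for k in range(4):
    excl = p.excluded_frame_indices(times, k)
    print(f"k = {k}: {len(excl):2d} frames excluded, {len(times) - len(excl)} retained")
# Each transition removes the last k frames of the outgoing block and the
# first k of the incoming one; with 9 transitions that is up to 18k frames.
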