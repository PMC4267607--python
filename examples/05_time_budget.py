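"""Hourly time budget from classified segments.

Simulates two hours of bouts (one bout every 30 s), classifies nothing —
the ground-truth majority labels stand in for classifier output here — and
aggregates the proportion of time per behaviour per hour, the summary an
ecologist reads off a tag deployment.
"""

from ethoseg import SegmentationConfig, SimConfig, simulate_dataset, time_budget
from ethoseg.classification import label_segments
from ethoseg.segmentation import segment_bout_fixed

bouts = simulate_dataset(SimConfig(), 240, seed=3)  # 240 x 30 s = 2 h
segments = []
for bout in bouts:
    segments.extend(segment_bout_fixed(
        bout, SegmentationConfig("fixed", fixed_length=1.0)))
segments = label_segments(bouts, segments)

budget = time_budget(segments, bouts, bin_seconds=3600.0)
print("proportion of classified time per behaviour, by hour:")
print(budget.round(3).to_string())
print("rows sum to 1:", budget.sum(axis=1).round(6).tolist())
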