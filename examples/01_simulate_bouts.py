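"""Simulate annotated accelerometer bouts and inspect their composition.

Generates 200 ten-second bouts (200 records at 20 Hz) from the shipped
8-class behaviour models and prints the record-level share of each class.
Shares track the configured occupancy weights: inactive and walk dominate,
attack/fly/peck are rare.
"""

import numpy as np

from ethoseg import BEHAVIORS, SimConfig, simulate_dataset

config = SimConfig()
bouts = simulate_dataset(config, n_bouts=200, seed=42)

labels = np.concatenate([b.labels for b in bouts])
total_weight = sum(m.occupancy_weight for m in config.models)

print(f"{len(bouts)} bouts x {len(bouts[0])} records at "
      f"{config.sample_rate:g} Hz")
print(f"{'class':>10}  {'records':>7}  {'share':>6}  {'target':>6}")
for c in BEHAVIORS:
    n = int((labels == c).sum())
    target = config.model(c).occupancy_weight / total_weight
    print(f"{c:>10}  {n:7d}  {n / labels.size:6.1%}  {target:6.1%}")
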