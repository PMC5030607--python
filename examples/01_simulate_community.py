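"""Simulate a 12-chimpanzee community and inspect the raw observation logs.

Generates focal-follow scan logs (9 scans at 2-minute intervals per
18-minute follow) and a gesture-event log from a latent bond model with
planted modality effects, then prints headline counts and writes the
dataset as plain CSVs.
"""
from collections import Counter

import gestnet as g

ds = g.simulate_dataset(n=12, seed=1)  # sampling effort varies per focal

print(f"individuals : {len(ds.attributes)}")
print(f"focal scans : {len(ds.scans)}  (follows of 9 scans, 2 min apart)")
print(f"gesture events: {len(ds.events)}")
hours = {a.id: round(a.observation_hours, 1) for a in ds.attributes}
print(f"observation hours per focal: {hours}")

by_modality = Counter(e.modality.value for e in ds.events)
print("events by modality:", dict(by_modality))
# visual/tactile/auditory-long are frequent by design; auditory-short is rare

g.write_dataset(ds, "scratch/example_dataset")
print("wrote attributes/scans/events CSVs + truth.json to scratch/example_dataset/")
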