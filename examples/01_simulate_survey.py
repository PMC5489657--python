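"""Simulate a multiyear bog-lake survey with planted ground truth.

Builds a scaled-down survey (8 lakes x 2 layers x 2 summers of weekly
samples) and prints its design: how many samples and OTUs, the planted
core set, regime indicators, and scheduled mixing events.
"""

import bogwater as bw

cfg = bw.small_config(seed=1)
table, metadata, tree, truth = bw.simulate_timeseries(cfg)

print(f"simulated {table.n_samples} samples x {table.n_otus} OTUs "
      f"(after dropping never-observed pool members: "
      f"{int((table.counts.sum(axis=0) > 0).sum())} observed)")
print(f"lakes: {sorted({m.lake for m in metadata})}")
print(f"years: {sorted({m.year for m in metadata})}")
print(f"planted core OTUs: {len(truth.core_set)}")
for regime, otus in truth.indicator_map.items():
    print(f"planted {regime} indicators: {len(otus)}")
for lake, date, frac, samples in truth.event_log:
    print(f"mixing event: {lake} on {date} "
          f"(top {frac:.0%} of taxa survive, {len(samples)} samples hit)")

# Sample identifiers encode lake, layer and date, e.g. TBE01JUN07 is the
# Trout Bog epilimnion on 2007-06-01.
first = metadata[0]
print(f"first sample: {first.sample_id} -> {first.lake} {first.layer} "
      f"{first.date} ({first.mixing_regime})")
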