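"""Calcium transient detection and well-level event rates.

Simulates jRGECO-style fluorescence traces (100 s at 5 Hz) with planted
transients, computes dF/F0 against a rolling 10th-percentile 10-second
baseline, detects events above 0.2 dF/F0, and averages rates at the well
level (each well = one biological replicate).
"""

import numpy as np
import pandas as pd

import scresilience as sr

rng = np.random.default_rng(5)
event_times = {}
meta_rows = []
for w, (well, condition, rate) in enumerate(
    [("w0", "ctrl", 6), ("w1", "ctrl", 5), ("w2", "amyloid", 14), ("w3", "amyloid", 12)]
):
    for f in range(2):
        tid = f"{well}_f{f}"
        n = rng.poisson(rate)
        event_times[tid] = list(np.sort(rng.uniform(2.0, 98.0, size=n)))
        meta_rows.append({"trace_id": tid, "well_id": well,
                          "field_id": f"f{f}", "condition": condition})
meta = pd.DataFrame(meta_rows).set_index("trace_id")

traces, truth = sr.simulate_calcium(event_times_s=event_times, event_amp=0.5,
                                    decay_s=0.8, noise_sd=0.03, seed=5,
                                    trace_meta=meta)
events = sr.event_table(traces)
wells, conditions = sr.summarize_rates(events)

print("per-trace events:")
print(events[["event_count", "events_per_min", "well_id", "condition"]].to_string())
print("\nwell-level means (biological replicates):")
print(wells.round(2).to_string(index=False))
print("\ncondition summaries (mean of well means):")
print(conditions.round(2).to_string())
planted = {t: len(v) for t, v in truth.calcium_event_times.items()}
print(f"\nplanted event counts: {planted}")
print("Amyloid wells were planted with ~2.4x the control event rate; the"
      "\ncondition means above should reflect that hyperexcitability.")
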