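"""Across-trial synchrony and Ca2+ <-> release correlation at 10 Hz drive.

Runs a presynaptic glutamate train, then computes (1) the
phase-projection synchrony of Ca2+ event times across trials (1 =
perfectly aligned, ~0 = random) probed at several inter-event
intervals, and (2) the peak short-lag cross-correlation between Ca2+
and release events from the shuffle-corrected joint peristimulus time
histogram.
"""

import numpy as np

import gliosim as g

proto = g.StimulusProtocol(kind="glutamate-train", rate_hz=10.0,
                           train_onset_s=0.0, train_duration_s=11.0)
cfg = g.SimulationConfig(protocol=proto, n_trials=40, base_seed=4,
                         duration_s=11.0)
batch = g.run_batch(cfg)
print(f"{batch.ca_events.n_events} Ca2+ events, "
      f"{batch.kr_events.n_events} KR + {batch.ff_events.n_events} FF "
      f"releases in {cfg.n_trials} trials")

intervals = np.array([0.05, 0.1, 0.2, 0.5, 1.0])
sync = g.pinsky_rinzel_synchrony(batch.ca_events, intervals=intervals)
print("\nCa2+ event synchrony vs probed inter-event interval:")
for iv, s in zip(intervals, sync.synchrony):
    print(f"  {1e3 * iv:6.0f} ms : s = {s:.3f}")

peak, profile = g.jpsth_cross_correlation(batch.ca_events,
                                          batch.release_events,
                                          window=0.1, duration=11.0)
print(f"\npeak Ca2+ <-> release cross-correlation (100 ms window): "
      f"{peak:.3f}")
print(f"mean over the 11 s train: {np.nanmean(profile):.3f}")
print()
print("Stimulus-locked IP3 buildup aligns events weakly across trials; "
      "release draws track the Ca2+ events that trigger them, so the "
      "within-window correlation is high while docked vesicles last.")
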