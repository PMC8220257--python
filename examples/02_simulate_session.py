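"""Simulate one figure-detection recording session and summarize behavior.

A session bundle holds 20 stimuli x 10 repetitions = 200 trials, one 1-kHz
envelope trace per (site, trial), and the planted ground truth per site.
"""

from figground import behavior, generate_session

bundle = generate_session(seed=1)

print(f"sites: {len(bundle.sites)}, trials: {len(bundle.trials)}, "
      f"trace shape: {bundle.traces.shape} (t0 = {bundle.t0_ms} ms)")
print("outcomes:", bundle.trials["outcome"].value_counts().to_dict())

summary = behavior.session_behavior(bundle.trials)
cols = ["coherence", "hit_rate", "fa_rate", "dprime", "mean_rt_ms", "cv_rt"]
print(summary[cols].round(3).to_string(index=False))
# d' = Z(hit) - Z(FA) per coherence with the shared control false-alarm rate;
# higher coherence should yield higher d' and faster reaction times.
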