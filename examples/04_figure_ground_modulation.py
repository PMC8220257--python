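"""Classify figure-modulated sites and quantify modulation in one session.

Runs the full pipeline: baseline normalization, window scalars, the
response-aligned two-sample t-test classifier, neurometric d-prime, AUROC
contrasts and the bootstrap modulation-onset latency for modulated sites.
"""

import numpy as np

from figground import generate_session, pipeline

bundle = generate_session(seed=1)
results = pipeline.analyze_session(bundle, seed=0, compute_latency=True)

n_mod = int(results["is_modulated"].sum())
print(f"modulated sites: {n_mod}/{len(results)} "
      f"(t-test p < 0.01 and 20-Hz sound responsive)")

mod = results[results["is_modulated"]]
print(f"median figure-vs-control d' (onset window): "
      f"{mod['dprime_fig_ctr'].median():.3f}")
print(f"median AUROC fig-vs-ctr: onset {mod['auroc_fig_vs_ctr_onset'].median():.3f}, "
      f"response {mod['auroc_fig_vs_ctr_response'].median():.3f}")
lat = mod["latency_ms"].dropna()
print(f"modulation-onset latencies (ms): {sorted(lat.astype(int).tolist())}")
print(f"median latency: {lat.median():.0f} ms "
      f"(planted figure-gain latency: {bundle.sites[0].fig_latency_ms:.0f} ms + 100 ms ramp)")
# AUROC 0.5 = indistinguishable; values above ~0.6 indicate reliable
# single-trial discrimination of figure from control responses.
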