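"""Bar-release control: motor contribution to pre-response activity.

Simulates a silent session in which releases are self-paced (no auditory
drive), then contrasts the response-aligned window (-301..-100 ms before
release) with the preceding baseline window (-501..-300 ms).
"""

from figground import generate_bar_release_session
from figground.figure_ground import motor_control_analysis

bundle = generate_bar_release_session(n_sites=6, n_releases=150, seed=1)
res = motor_control_analysis(bundle)

print(f"per-site response-minus-baseline differences: "
      f"{[round(float(d), 4) for d in res['per_site_difference']]}")
print(f"mean +- SEM: {res['mean_difference']:.4f} +- {res['sem_difference']:.4f}")
print(f"signed-rank test vs 0: p = {res['p']:.4f}")
# A small positive difference reflects the planted pre-release motor
# transient; it is an order of magnitude below typical figure-evoked
# modulation, mirroring the motor-contribution control analysis.
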