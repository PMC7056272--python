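"""Unitary IPSC connectivity calling and short-term depression.

Simulates paired recordings (6-pulse 10-Hz presynaptic trains), averages
the postsynaptic sweeps, calls each pair connected when the first-pulse
uIPSC is at least 3x the baseline SD, and summarizes two groups.
"""

import numpy as np

from ephyskit import quantal, synth

# A "control" group of strong connections and a comparison group in which
# several pairs are unconnected.
rng = np.random.default_rng(0)
group_a, group_b = [], []
for i in range(12):
    cfg = synth.UIPSCSimConfig(first_amplitude_pa=150.0, seed=100 + i)
    group_a.append(quantal.analyze_uipsc(synth.generate_uipsc_sweeps(cfg)))
for i in range(12):
    connected = i % 4 != 0  # every fourth pair unconnected
    cfg = synth.UIPSCSimConfig(first_amplitude_pa=150.0, connected=connected, seed=200 + i)
    group_b.append(quantal.analyze_uipsc(synth.generate_uipsc_sweeps(cfg)))

summary = quantal.connectivity_summary(group_a, group_b)
print(f"group A: {summary['n_connected_a']}/{summary['n_pairs_a']} connected "
      f"(rate {summary['rate_a']:.2f})")
print(f"group B: {summary['n_connected_b']}/{summary['n_pairs_b']} connected "
      f"(rate {summary['rate_b']:.2f})")
print(f"connectivity reduction: {summary['percent_reduction']}%")

conn = group_a[0]
print("normalized train amplitudes (pulse k / pulse 1):",
      np.round(conn.normalized_train_amplitudes, 2),
      "- values below 1 show short-term synaptic depression")
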