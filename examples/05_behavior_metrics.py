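"""The closed-form behavioral metrics, applied to example trial scores."""

from ephyskit import behavior as beh

# Novel-object recognition: time with the novel object vs familiar object 2.
p = beh.preference_index(beh.InteractionTimes(t_a=42.0, t_b=18.0))
print(f"novel-object preference index = {p:.2f} (0.5 = no preference)")

# Pre-pulse inhibition of the acoustic startle.
ppi = beh.prepulse_inhibition(prepulse_trial_response=0.35, test_trial_response=1.4)
print(f"pre-pulse inhibition = {ppi:.2f} (1 = complete suppression)")

# Fear conditioning: freezing in the context test minus pre-training baseline.
fz = beh.corrected_freezing(test_pct=62.0, baseline_pct=8.0)
print(f"corrected contextual freezing = {fz:.0f} percentage points")

# Wire-grid locomotion and tube-test dominance.
print(f"foot slips per meter = {beh.footslips_per_distance(9, 4.5):.1f}")
print(f"tube-test score = {beh.tube_score(['win', 'win', 'loss']):.2f} "
      "(mean over three bouts; > 0.5 = dominant)")
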