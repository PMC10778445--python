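"""Deviation and symmetry index from raw platform trials.

Builds one dog-session of 20 stance-analyzer readings, aggregates them
and prints the two outcome measures.
"""

from stancemcid import TrialMeasurement, aggregate_trials

# 20 trials: left hind bears ~15.8%, right hind ~18.6% of body weight,
# forelimbs absorb the rest.  A sound hind limb would bear 20%.
trials = []
for i in range(1, 21):
    lh = 15.8 + 0.1 * ((i % 5) - 2)  # small trial-to-trial wobble
    rh = 18.6 - 0.1 * ((i % 3) - 1)
    fore = (100.0 - lh - rh) / 2.0
    trials.append(TrialMeasurement("rex", "T0", i, fore, fore, lh, rh))

left, right, dog = aggregate_trials(trials)

print(f"left hind : mean load {left.wb_mean:5.2f}%  deviation {left.deviation:4.2f}")
print(f"right hind: mean load {right.wb_mean:5.2f}%  deviation {right.deviation:4.2f}")
print(f"symmetry index: {dog.si:5.2f}")
print()
print("Deviation is |20 - load| in percent body-weight points (0 = normal")
print("loading); the symmetry index is the normalised left-right difference")
print("(0 = perfect symmetry).  Both fall as a dog improves.")
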