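"""Simulate one participant's session and write it as a BrainVision triplet.

Builds the counterbalanced trial table (16 blocks of 40 trials, rivalry
and fusion interleaved), draws behavioral outcomes from the group-level
probabilities (37/57/6 % changed/same/no-response on rivalry trials,
94 % correct on fusion trials), synthesizes continuous 500-Hz EEG with
P1/N1/late-positivity components and 1/f background noise, adds blinks,
and writes the standard file triplet plus an events sidecar.
"""

import numpy as np

from rivalerp import (
    BehaviorParams,
    EffectParams,
    NoiseParams,
    default_montage,
    inject_blinks,
    make_design,
    simulate_behavior,
    simulate_recording,
    write_brainvision,
    write_events_json,
)

rng = np.random.default_rng(0)
montage = default_montage()

trials = make_design(n_blocks=2, trials_per_block=40, seed=rng)  # short demo
participant = BehaviorParams().draw_participant(rng)
trials = simulate_behavior(trials, participant, seed=rng)

print(trials["outcome"].value_counts())
print(f"this participant's drawn P(correct|fusion): {participant.p_correct_fusion:.2f} "
      f"(group mean 0.94); observed accuracy: {trials['response_correct'].mean():.2%}")

raw = simulate_recording(trials, EffectParams(), NoiseParams(), montage, seed=rng)
raw, blinks = inject_blinks(raw, NoiseParams(), seed=rng)
print(f"recording: {raw.n_channels} channels x {raw.n_samples} samples "
      f"({raw.duration_s:.0f} s), {len(raw.events)} markers, {len(blinks)} blinks")

write_brainvision(raw, "scratch_demo")
write_events_json(raw, "scratch_demo.events.json")
print("wrote scratch_demo.vhdr/.vmrk/.eeg")
# The outcome counts approximate the configured multinomial; the marker
# count is three per trial (S1 with condition/outcome code, S2, mask).
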