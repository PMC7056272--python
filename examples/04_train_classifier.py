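"""Train the convolutional candidate classifier on labeled segments.

The threshold stage is tuned for sensitivity; this example trains the
small 1-D CNN that scores candidate segments (three EEG channels, 1.25 s)
and removes false positives, then reports the confusion at the default
0.5 operating point.
"""

import numpy as np

from ephyskit import classifier as clf
from ephyskit import swd, synth

# A dense recording to harvest labeled segments from: true SWD epochs are
# positives, event-free epochs are negatives.
config = synth.EEGSimConfig(duration_s=900.0, swd_rate_per_hr=900.0, seed=21)
recording, truth = synth.generate_eeg(config)
filtered = swd.bandpass_filter(recording)

swds = [a for a in truth if a.event_kind == "SWD"]
pos = np.array([int((a.onset_s + a.offset_s) / 2 / 0.25) for a in swds])[:200]
occupied = np.zeros(3601, dtype=bool)
for a in swds:
    occupied[int(a.onset_s / 0.25) : int(a.offset_s / 0.25) + 2] = True
rng = np.random.default_rng(0)
neg = np.array([i for i in rng.permutation(3590) if not occupied[max(0, i - 5) : i + 6].any()])[:200]

segments = clf.extract_segments(filtered, np.concatenate([pos, neg]))
labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])

model = clf.build_model(sample_rate_hz=5000.0, seed=1)
model = clf.train(model, segments, labels, seed=1)
hist = model.history
print(f"trained for {len(hist['train_loss'])} iterations "
      f"(early stop: patience 3 on validation loss)")
print(f"final train acc {hist['train_acc'][-1]:.3f}, val acc {hist['val_acc'][-1]:.3f}")

kept, rejected, probs = clf.classify_candidates(model, segments)
keep = probs >= 0.5
print(f"recall {keep[labels == 1].mean():.3f}, "
      f"false-positive removal {1 - keep[labels == 0].mean():.3f} "
      "(fraction of background segments rejected)")
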