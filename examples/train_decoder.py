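"""Train the LSP + DBN decoder on intact synthetic motor-imagery EEG.

Pipeline: band-pass filter (5th-order Butterworth, 8-35 Hz, gain 1.5) ->
1-s sliding windows every 0.2 s -> least-squares Lomb-Scargle band powers
in the alpha/sigma/low-beta/high-beta sub-bands -> min-max normalization
(fit on the training split only) -> three stacked RBMs (60/50/35 hidden
units) pretrained with CD-1 and fine-tuned with a softmax output layer.
"""

import numpy as np

from lspdbn import (MotorImageryConfig, SplitSpec, TrainConfig, apply_minmax,
                    fit_minmax, generate_dataset, majority_vote_trial,
                    split_dataset)
from lspdbn.dbn import fit_dbn, predict
from lspdbn.evaluate import features_from_masks, prepare_segments

config = MotorImageryConfig()
trials = generate_dataset(config, trials_per_class=30, seed=7)
segments = prepare_segments(trials)
print(f"{segments.n_segments} segments of "
      f"{segments.values.shape[1]} channels x {segments.n_samples} samples")

full = np.ones((segments.n_segments, segments.n_samples), dtype=bool)
X = features_from_masks(segments, full, "lsp")
print(f"feature matrix: {X.shape} (4 sub-bands x {config.n_channels} channels)")

split = split_dataset(segments.n_segments, segments.trial_ids, SplitSpec(seed=1))
stats = fit_minmax(X[split.train_idx])
Xtr = apply_minmax(X[split.train_idx], stats)
Xte = apply_minmax(X[split.test_idx], stats)

# the default schedule (50 pre-training + 200 fine-tuning epochs) converges
# on datasets of any size; larger sweeps use the shorter harness schedule
model = fit_dbn(Xtr, segments.labels[split.train_idx], (60, 50, 35),
                TrainConfig(seed=0), class_count=3)
pred = predict(model, Xte)
acc = np.mean(pred == segments.labels[split.test_idx])
print(f"segment-level test accuracy: {acc:.3f} (chance 0.333)")

trial_ids, voted = majority_vote_trial(pred, segments.trial_ids[split.test_idx])
truth = np.array([segments.labels[segments.trial_ids == t][0] for t in trial_ids])
print(f"trial-level accuracy after majority voting over segments: "
      f"{np.mean(voted == truth):.3f}")
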