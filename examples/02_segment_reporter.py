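"""Segment the transduced volume with the sparse-annotation pixel classifier.

A handful of annotated voxels on three planes at ¼, ½ and ¾ of the stack
depth (spanning the depth-dependent gain) trains a bagged-tree classifier on multiscale features.
The probability map is thresholded at 0.5 and objects ≤ 10 µm³ are dropped.
"""

import numpy as np

from shellcount import (
    PhantomConfig,
    ProbabilityVolume,
    annotation_from_truth,
    extract_features,
    generate_phantom,
    segment_transduced,
    train_pixel_classifier,
)

res = generate_phantom(
    PhantomConfig(volume_shape=(100, 256, 256), n_nuclei=400,
                  transduction_prob=0.7, seed=7)
)
ann = annotation_from_truth(res, seed=7)
print(f"annotated voxels       : {len(ann.labels)} on planes {ann.plane_depths_um} µm")

feats = extract_features(res.reporter_channel)
clf = train_pixel_classifier(feats, ann, seed=7)
print(f"training accuracy      : {clf.training_accuracy:.3f}")

prob = ProbabilityVolume(clf.predict_volume(feats), res.reporter_channel.geometry)
mask = segment_transduced(prob, res.reporter_channel.geometry,
                          prob_threshold=0.5, min_object_um3=10.0)

truth = res.transduced_mask.data
tp = np.sum(mask.data & truth)
fp = np.sum(mask.data & ~truth)
fn = np.sum(~mask.data & truth)
print(f"mask voxels            : {int(mask.data.sum())}")
print(f"voxel-wise F1 vs truth : {2 * tp / (2 * tp + fp + fn):.3f}")

# F1 well above 0.85 means the classifier separates dim cytoplasm from
# background despite the per-cell brightness spread and the depth gain.
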