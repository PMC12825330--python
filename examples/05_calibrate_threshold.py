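"""Calibrate the shell-overlap threshold against manual counts.

The overlap threshold is the pipeline's one free parameter.  Candidate
thresholds are swept; for each, a 2D surrogate efficiency — the transduced
fraction among shells intersecting the upper (¼ depth) and centre (½ depth)
planes — is compared with the annotator-mean manual efficiency, and the
threshold with the smallest deviation wins, ties toward the more
conservative (larger) value.  The mask comes from the trained classifier,
as it would in a real calibration run.
"""

import numpy as np
import pandas as pd

from shellcount import (
    PhantomConfig,
    ProbabilityVolume,
    annotation_from_truth,
    calibrate_threshold,
    extract_features,
    generate_phantom,
    segment_transduced,
    train_pixel_classifier,
)
from shellcount.nuclei import filter_nuclei
from shellcount.quantify import threshold_sweep
from shellcount.shells import build_shells, filter_shells, overlap_fractions

res = generate_phantom(
    PhantomConfig(volume_shape=(100, 256, 256), n_nuclei=400,
                  transduction_prob=0.7, seed=5)
)
feats = extract_features(res.reporter_channel)
clf = train_pixel_classifier(feats, annotation_from_truth(res, seed=5), seed=5)
prob = ProbabilityVolume(clf.predict_volume(feats), res.reporter_channel.geometry)
mask = segment_transduced(prob, res.reporter_channel.geometry)

cleaned, _ = filter_nuclei(res.labels, 100.0)
shells = build_shells(cleaned)
shells, _ = filter_shells(shells, min_shell_um3=50.0)
records = overlap_fractions(shells, mask)

PLANES = (12.5, 25.0)  # ¼ and ½ of the 50 µm demo stack
software = threshold_sweep(
    shells, records, planes_um=PLANES,
    thresholds=tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
)

# synthetic "manual counts": three annotators counting ≈ the true fraction
rng = np.random.default_rng(5)
manual = pd.DataFrame(
    [
        {"plane_depth_um": p, "annotator_id": f"a{i}",
         "n_transduced": int(100 * np.clip(0.70 + rng.normal(0, 0.03), 0, 1)),
         "n_total": 100}
        for p in PLANES for i in range(3)
    ]
)

report = calibrate_threshold(software, manual, planes_um=PLANES)
print(report["sweep"].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"manual reference: "
      f"{ {p: round(e, 3) for p, e in report['manual_reference'].items()} }")
print(f"chosen threshold: {report['chosen_threshold']}")

# On this phantom the sweep is nearly flat: the classifier mask covers the
# shells of transduced cells almost completely, so overlap fractions are
# bimodal and most thresholds classify identically.  The tie-break then picks
# the most conservative matching threshold.  On real tissue, partial
# cytoplasmic coverage spreads the fractions out and the sweep discriminates
# sharply, which is what makes the calibration against annotators meaningful.
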