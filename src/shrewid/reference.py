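"""Reference test-set confusion matrices for *Suncus murinus* skull
identification.

These are the published museum-specimen results the pipeline re-implements:
one matrix for the view task (20 test images per view) and one per view for
the population-sex task (20 test images per class). They serve as worked
examples for the evaluation module — `accuracy_report` must reproduce every
per-class and overall percentage exactly — and as fixed reference inputs
for the reporting scripts.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix

__all__ = ["VIEW_TEST", "DORSAL_TEST", "LATERAL_TEST", "JAW_TEST", "REFERENCE_MATRICES"]

VIEW_TEST = ConfusionMatrix(
    labels=("Dorsal", "Jaw", "Lateral"),
    counts=np.array([
        [20, 0, 0],
        [0, 20, 0],
        [0, 0, 20],
    ]),
)

DORSAL_TEST = ConfusionMatrix(
    labels=("NM", "NF", "SM", "SF"),
    counts=np.array([
        [9, 0, 7, 4],
        [0, 16, 2, 2],
        [1, 2, 14, 3],
        [0, 0, 1, 19],
    ]),
)

LATERAL_TEST = ConfusionMatrix(
    labels=("NM", "NF", "SM", "SF"),
    counts=np.array([
        [19, 0, 1, 0],
        [0, 17, 3, 0],
        [1, 3, 14, 2],
        [0, 0, 0, 20],
    ]),
)

JAW_TEST = ConfusionMatrix(
    labels=("NM", "NF", "SM", "SF"),
    counts=np.array([
        [15, 4, 1, 0],
        [2, 16, 2, 0],
        [0, 1, 16, 3],
        [0, 1, 2, 17],
    ]),
)

REFERENCE_MATRICES = {
    "views": VIEW_TEST,
    "dorsal": DORSAL_TEST,
    "lateral": LATERAL_TEST,
    "jaw": JAW_TEST,
}
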