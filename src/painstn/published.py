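"""Reference results for four-level pain estimation on the UNBC-McMaster
shoulder-pain archive.

These are published 4x4 confusion matrices (rows = true level, columns =
predicted level) and the archive's pain-level sample counts, used as
fixed inputs for metric arithmetic: the archive itself is
access-restricted, but the matrices let the evaluation code be checked
against the metrics reported alongside them.

Known internal inconsistencies, kept verbatim and documented rather than
repaired:

* the ``no-stn-no-att`` matrix has row sums that disagree with the other
  three ablation modes, and its reported accuracy (32.7%) cannot be
  recomputed from it;
* the reported MSEs for ``stn-no-att`` (1.4033) and ``no-stn-att``
  (1.3185) do not match the level-index MSE of their matrices — only the
  ``stn-att`` MSE (1.1014) is internally consistent;
* the ``lbp`` and ``region-cnn`` comparison matrices recompute to
  accuracies 23.2% and 35.2%, 0.1 below their reported 23.3% and 35.3%.
"""

from __future__ import annotations

import numpy as np

#: Sample counts per pain level in the archive (levels 0-3) and the
#: level-0 count retained after balancing.
LEVEL_COUNTS = (40007, 5260, 2456, 653)
LEVEL0_KEEP = 5260

#: Reported level portions, percent, one decimal.
LEVEL_PORTIONS = (82.7, 10.9, 5.1, 1.3)

#: Ablation-mode confusion matrices (true level x predicted level).
MODE_CONFUSIONS = {
    "no-stn-no-att": np.array(
        [
            [2254, 1443, 312, 118],
            [1946, 231, 80, 43],
            [916, 263, 78, 89],
            [175, 96, 98, 0],
        ]
    ),
    "stn-no-att": np.array(
        [
            [3406, 292, 59, 70],
            [1891, 305, 66, 38],
            [890, 253, 116, 87],
            [187, 86, 96, 0],
        ]
    ),
    "no-stn-att": np.array(
        [
            [3368, 297, 64, 98],
            [1882, 337, 51, 30],
            [974, 295, 40, 37],
            [183, 92, 94, 0],
        ]
    ),
    "stn-att": np.array(
        [
            [3495, 246, 42, 44],
            [1870, 368, 47, 15],
            [877, 199, 141, 129],
            [170, 95, 104, 0],
        ]
    ),
}

#: Confusion matrices of earlier comparison methods on the same samples.
COMPARISON_CONFUSIONS = {
    "head-analysis": np.array(
        [
            [1870, 1457, 415, 85],
            [1934, 264, 72, 30],
            [831, 348, 66, 101],
            [172, 103, 94, 0],
        ]
    ),
    "lbp": np.array(
        [
            [1604, 1650, 423, 150],
            [2001, 167, 84, 48],
            [844, 325, 52, 125],
            [178, 97, 94, 0],
        ]
    ),
    "lpq": np.array(
        [
            [1606, 1669, 417, 135],
            [1997, 173, 84, 46],
            [846, 323, 53, 124],
            [180, 96, 93, 0],
        ]
    ),
    "bsif": np.array(
        [
            [1618, 1659, 419, 131],
            [1995, 184, 77, 44],
            [846, 319, 58, 123],
            [183, 92, 94, 0],
        ]
    ),
    "region-cnn": np.array(
        [
            [2349, 1107, 252, 119],
            [1915, 278, 65, 42],
            [839, 305, 137, 65],
            [173, 89, 107, 0],
        ]
    ),
}
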