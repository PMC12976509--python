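"""Published reference bookkeeping for the HeLa three-condition dataset.

The full-resolution fluorescence dataset this pipeline was designed around is
not redistributable, but its published summary numbers are: per-condition
field counts, per-fold train/test counts of the grouped five-fold
cross-validation, the per-fold mean classifier scores of the two binary
models, and the binary hyperfission-task precision/recall.  They are kept
here so fold bookkeeping and score-aggregation arithmetic can be validated
against known report values without the images.
"""

from __future__ import annotations

import pandas as pd

#: fields per treatment condition (NC = untreated control, CCCP = 5 uM
#: uncoupler / hyperfission, FL3 = 40 nM flavagline / hyperfusion)
FIELD_COUNTS = {"NC": 197, "CCCP": 241, "FL3": 239}

#: per-fold train/test field counts of the grouped 5-fold cross-validation
_FOLD_COUNT_ROWS = [
    # fold, train (CCCP, FL3, NC), test (CCCP, FL3, NC)
    (0, 224, 191, 170, 17, 48, 27),
    (1, 173, 190, 183, 68, 49, 14),
    (2, 210, 221, 186, 31, 18, 11),
    (3, 206, 221, 190, 35, 18, 7),
    (4, 205, 209, 177, 36, 30, 20),
]


def fold_counts() -> pd.DataFrame:
    return pd.DataFrame(
        _FOLD_COUNT_ROWS,
        columns=["fold", "train_CCCP", "train_FL3", "train_NC", "test_CCCP", "test_FL3", "test_NC"],
    )


def cccp_nc_fold_scores() -> pd.DataFrame:
    """Per-fold mean scores of the hyperfission (CCCP-NC) binary model:
    CCCP-score and NC-score for the CCCP-treated and control test groups."""
    rows = [
        (0.9782, 0.0218, 0.0000, 1.0000),
        (0.9611, 0.0389, 0.0024, 0.9976),
        (0.9819, 0.0181, 0.0001, 0.9999),
        (0.9760, 0.0240, 0.0000, 1.0000),
        (0.9754, 0.0246, 0.0002, 0.9998),
    ]
    return pd.DataFrame(
        rows,
        columns=["CCCP_group_CCCP_score", "CCCP_group_NC_score", "NC_group_CCCP_score", "NC_group_NC_score"],
    )


def fl3_nc_fold_scores() -> pd.DataFrame:
    """Per-fold mean scores of the hyperfusion (FL3-NC) binary model."""
    rows = [
        (0.7172, 0.2828, 0.0047, 0.9953),
        (0.7067, 0.2933, 0.0940, 0.9060),
        (0.9760, 0.0240, 0.0057, 0.9943),
        (0.9555, 0.0445, 0.0013, 0.9987),
        (0.9565, 0.0435, 0.0045, 0.9955),
    ]
    return pd.DataFrame(
        rows,
        columns=["FL3_group_FL3_score", "FL3_group_NC_score", "NC_group_FL3_score", "NC_group_NC_score"],
    )


#: reported binary hyperfission-task precision/recall (pooled over folds)
CCCP_NC_PRECISION = 1.0000
CCCP_NC_RECALL = 0.9941
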