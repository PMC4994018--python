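"""Helpers for scoring inferred clusterings against reference labels."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["align_labels"]


def align_labels(pred: pd.Series, truth: pd.Series) -> dict[int, int]:
    """Best bijective map from predicted cluster ids to reference ids.

    Maximizes total overlap via the Hungarian algorithm on the contingency
    table.  Predicted ids without a counterpart (more predicted than
    reference clusters) are left unmapped.
    """
    common = pred.index.intersection(truth.index)
    ct = pd.crosstab(pred[common], truth[common])
    ri, ci = linear_sum_assignment(-ct.to_numpy())
    return {int(ct.index[r]): int(ct.columns[c]) for r, c in zip(ri, ci)}
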