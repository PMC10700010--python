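"""Two-model confidence combination and extreme-sample selection.

Two classifiers trained on images from different cameras produce weakly
correlated confidence scores; combining them with an AND rule over per-model
thresholds (both confidences must clear their threshold for a positive call)
trades recall for positive precision.  The threshold pair is found by
exhaustive search over the grid of observed confidence values, maximising
accuracy subject to a positive-precision floor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "confidence_correlation",
    "threshold_search",
    "select_extreme_samples",
]


def _matched(records_a: pd.DataFrame, records_b: pd.DataFrame) -> pd.DataFrame:
    try:
        m = records_a.merge(records_b, on="fruit_id", suffixes=("_a", "_b"),
                            validate="one_to_one")
    except pd.errors.MergeError as exc:
        raise ValueError(f"records not unique by fruit_id: {exc}") from exc
    if len(m) < len(records_a) or len(m) < len(records_b):
        raise ValueError("records A and B do not match one-to-one by fruit_id")
    return m


def confidence_correlation(records_a: pd.DataFrame, records_b: pd.DataFrame) -> float:
    """Pearson r between the two models' positive-class confidences."""
    m = _matched(records_a, records_b)
    if len(m) < 3:
        raise ValueError("need at least 3 matched records")
    a = m["confidence_positive_a"].to_numpy(float)
    b = m["confidence_positive_b"].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one model's confidences")
    return float(np.corrcoef(a, b)[0, 1])


def threshold_search(records_a: pd.DataFrame, records_b: pd.DataFrame,
                     min_positive_precision: float = 0.8):
    """Best (tA, tB) >= 0.5 on the observed-confidence grid.

    A fruit is called positive iff confA >= tA AND confB >= tB.  Among grid
    points meeting the positive-precision floor the maximiser of accuracy is
    returned; ties break toward higher positive precision, then lower
    (tA, tB).  Returns a dict; ``feasible`` is False when no grid point
    meets the floor.
    """
    m = _matched(records_a, records_b)
    y = m["true_label_a"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("true labels required for threshold search")
    y = y.astype(int)
    a = m["confidence_positive_a"].to_numpy(float)
    b = m["confidence_positive_b"].to_numpy(float)

    grid_a = np.unique(np.concatenate([[0.5], a[a >= 0.5]]))
    grid_b = np.unique(np.concatenate([[0.5], b[b >= 0.5]]))

    best = None
    for ta in grid_a:
        call_a = a >= ta
        for tb in grid_b:
            call = call_a & (b >= tb)
            acc = float((call == (y == 1)).mean())
            npos = int(call.sum())
            prec = float((y[call] == 1).mean()) if npos else np.nan
            if npos and prec >= min_positive_precision:
                key = (-acc, -prec, ta, tb)
                if best is None or key < best[0]:
                    best = (key, dict(t_a=float(ta), t_b=float(tb), accuracy=acc,
                                      positive_precision=prec, n_called=npos,
                                      feasible=True))
    if best is None:
        return dict(t_a=None, t_b=None, accuracy=None, positive_precision=None,
                    n_called=0, feasible=False)
    return best[1]


def select_extreme_samples(records_a: pd.DataFrame, records_b: pd.DataFrame,
                           k_pos: int, k_neg: int):
    """Pick the k_pos fruits ranked highest by min(confA, confB) and the
    k_neg ranked lowest by max(confA, confB); ties fall back to fruit_id
    order.  The two sets are guaranteed disjoint."""
    m = _matched(records_a, records_b)
    if k_pos + k_neg > len(m):
        raise ValueError("k_pos + k_neg exceeds the number of matched records")
    m = m.sort_values("fruit_id", kind="stable").reset_index(drop=True)
    lo = np.minimum(m["confidence_positive_a"], m["confidence_positive_b"])
    hi = np.maximum(m["confidence_positive_a"], m["confidence_positive_b"])

    pos_order = np.lexsort((np.arange(len(m)), -lo.to_numpy()))
    pos_ids = list(m["fruit_id"].iloc[pos_order[:k_pos]])
    remaining = ~m["fruit_id"].isin(pos_ids).to_numpy()
    rem = m[remaining]
    neg_order = np.lexsort((np.arange(len(rem)), hi.to_numpy()[remaining]))
    neg_ids = list(rem["fruit_id"].iloc[neg_order[:k_neg]])
    return pos_ids, neg_ids
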