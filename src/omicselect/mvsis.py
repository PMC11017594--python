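"""Mean-variance (MV) model-free screening for binary discriminant analysis.

The MV index of a feature x against binary labels y is the
class-probability-weighted integrated squared gap between the conditional
and pooled empirical CDFs, evaluated over the pooled empirical measure:

    MV(x, y) = (1/n) * sum_j sum_r  p_r * (F_r(x_j) - F(x_j))^2

with F_r the empirical CDF within class r, F the pooled empirical CDF and
p_r = n_r / n. It is rank-based (invariant under strictly increasing
transforms of x), zero for a feature independent of y in-sample only when
the conditional CDFs coincide, and bounded above by p_1 * p_2 for binary
labels. Screening ranks all features by MV and carries the top-k forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateLabelsError, ValueDomainError
from .io_tables import FeatureTable

__all__ = ["ScreeningResult", "mv_statistic", "mvsis_screen"]


@dataclass
class ScreeningResult:
    """Per-feature MV statistics with a dense ranking and top-k set."""

    feature_ids: list[str]
    mv: np.ndarray
    rank: np.ndarray  # dense, 1 = largest mv; ties share a rank
    top_k: int
    top_k_set: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "mv": [float(v) for v in self.mv],
            "rank": [int(r) for r in self.rank],
            "top_k": int(self.top_k),
            "top_k_set": sorted(self.top_k_set),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningResult":
        return cls(
            feature_ids=list(d["feature_ids"]),
            mv=np.asarray(d["mv"], dtype=float),
            rank=np.asarray(d["rank"], dtype=int),
            top_k=int(d["top_k"]),
            top_k_set=set(d["top_k_set"]),
        )


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateLabelsError(f"need exactly 2 classes, got {classes.size}")
    return (y == classes[1]).astype(int)


def mv_statistic(x, y) -> float:
    """MV index of one feature against binary labels.

    Raises :class:`DegenerateLabelsError` unless both classes occur, and
    :class:`ValueDomainError` on non-finite values. Requires n >= 4.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueDomainError("mv_statistic requires finite values")
    y01 = _check_labels(y)
    n = x.size
    if n < 4:
        raise ValueDomainError(f"mv_statistic needs n >= 4, got {n}")
    # le[i, j] = 1{x_i <= x_j}; column means are the empirical CDFs at x_j
    le = x[:, None] <= x[None, :]
    F = le.mean(axis=0)
    total = 0.0
    for r in (0, 1):
        mask = y01 == r
        p_r = mask.mean()
        F_r = le[mask].mean(axis=0)
        total += p_r * np.sum((F_r - F) ** 2)
    return float(total / n)


def mvsis_screen(table: FeatureTable, y, top_k: int | None = 300) -> ScreeningResult:
    """Rank every feature by MV and record the top-k carry-forward set.

    ``top_k`` is capped at the number of features (None means all).
    Ties in MV are broken lexicographically by feature id, so the top-k
    set is deterministic.
    """
    p = table.n_features
    if top_k is None:
        top_k = p
    if top_k > p:
        raise ValueDomainError(f"top_k={top_k} exceeds feature count {p}")
    X = table.values
    mv = np.array([mv_statistic(X[:, j], y) for j in range(p)])
    # dense ranking: 1 = largest; exact ties share a rank
    order_vals = np.sort(np.unique(mv))[::-1]
    rank = np.searchsorted(-order_vals, -mv) + 1
    ids = np.array(table.feature_ids)
    sel_order = np.lexsort((ids, -mv))  # mv descending, then id ascending
    top_k_set = set(ids[sel_order[:top_k]])
    return ScreeningResult(
        feature_ids=list(ids), mv=mv, rank=rank, top_k=int(top_k), top_k_set=top_k_set
    )
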