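"""Joint association and classification across 2-3 omic views.

Each view d contributes a sparse coefficient vector w_d. The convex
objective mixes an optimal-scoring classification loss per view with a
cross-view score-agreement loss,

    F = sum_d (1-a)/(2n) ||ytilde - X_d w_d||^2
      + sum_{d<d'} a/(2n) ||X_d w_d - X_d' w_d'||^2
      + sum_d lam_d ||w_d||_1 ,       0 <= a < 1,

where ytilde is the optimal-scoring recoding of the binary labels
(zero mean, unit norm). Selected features therefore both discriminate
the groups and produce sample scores X_d w_d that agree across views.
Optimization is block coordinate descent: each block update is a lasso
in w_d with working response r_d = [(1-a)*ytilde + a*sum_{d'!=d}
X_d' w_d'] / c_d and curvature weight c_d = (1-a) + a*(D-1). The
penalty level is chosen by a one-dimensional leave-one-out search over a
shared multiplier t with lam_d = t * lam_max,d.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._solvers import cd_lasso
from .errors import (
    AlignmentError,
    ConfigError,
    DegenerateLabelsError,
    DegenerateScoreError,
    ValueDomainError,
)
from .preprocess import standardize_fit

__all__ = [
    "OptimalScores",
    "JointFit",
    "optimal_scores",
    "fit_jaca",
    "jaca_loocv",
    "jaca_classify",
    "score_correlations",
    "lambda_max_per_view",
    "jaca_objective",
]

OUTER_TOL = 1e-8
OUTER_COORD_TOL = 1e-8
OUTER_MAX_ITER = 500
INNER_TOL = 1e-9
INNER_MAX_SWEEPS = 10_000


@dataclass
class OptimalScores:
    """Zero-mean, unit-norm numeric recoding of binary class labels."""

    ytilde: np.ndarray
    n1: int
    n2: int

    @property
    def majority_class(self) -> int:
        return 0 if self.n1 >= self.n2 else 1


def optimal_scores(y) -> OptimalScores:
    """ytilde_i = sqrt(n2/(n*n1)) for class 0 and -sqrt(n1/(n*n2)) for class 1.

    By construction sum(ytilde) = 0 and sum(ytilde^2) = 1.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateLabelsError(f"need exactly 2 classes, got {classes.size}")
    y01 = (y == classes[1]).astype(int)
    n = y01.size
    n1 = int((y01 == 0).sum())
    n2 = n - n1
    ytilde = np.where(y01 == 0, np.sqrt(n2 / (n * n1)), -np.sqrt(n1 / (n * n2)))
    return OptimalScores(ytilde=ytilde, n1=n1, n2=n2)


@dataclass
class JointFit:
    view_names: list[str]
    w: dict[str, np.ndarray]
    alpha: float
    lambdas: dict[str, float]
    selected: dict[str, set[str]]
    feature_ids: dict[str, list[str]]
    scores: dict[str, np.ndarray]
    pairwise_corr: dict[str, float]  # key "view1|view2"
    threshold: float
    orientation: int
    majority_class: int
    converged: bool
    objective_trace: list[float]
    loocv_mcr: float | None = None

    def to_dict(self) -> dict:
        return {
            "view_names": list(self.view_names),
            "w": {k: [float(x) for x in v] for k, v in self.w.items()},
            "alpha": float(self.alpha),
            "lambdas": {k: float(v) for k, v in self.lambdas.items()},
            "selected": {k: sorted(v) for k, v in self.selected.items()},
            "feature_ids": {k: list(v) for k, v in self.feature_ids.items()},
            "scores": {k: [float(x) for x in v] for k, v in self.scores.items()},
            "pairwise_corr": {k: float(v) for k, v in self.pairwise_corr.items()},
            "threshold": float(self.threshold),
            "orientation": int(self.orientation),
            "majority_class": int(self.majority_class),
            "converged": bool(self.converged),
            "objective_trace": [float(x) for x in self.objective_trace],
            "loocv_mcr": None if self.loocv_mcr is None else float(self.loocv_mcr),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointFit":
        return cls(
            view_names=list(d["view_names"]),
            w={k: np.asarray(v, dtype=float) for k, v in d["w"].items()},
            alpha=d["alpha"],
            lambdas=dict(d["lambdas"]),
            selected={k: set(v) for k, v in d["selected"].items()},
            feature_ids={k: list(v) for k, v in d["feature_ids"].items()},
            scores={k: np.asarray(v, dtype=float) for k, v in d["scores"].items()},
            pairwise_corr=dict(d["pairwise_corr"]),
            threshold=d["threshold"],
            orientation=d["orientation"],
            majority_class=d["majority_class"],
            converged=d["converged"],
            objective_trace=list(d["objective_trace"]),
            loocv_mcr=d.get("loocv_mcr"),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.view_names:
            for fid, coef in zip(self.feature_ids[name], self.w[name]):
                if coef != 0:
                    rows.append({"view": name, "feature_id": fid, "loading": coef})
        return pd.DataFrame(rows, columns=["view", "feature_id", "loading"])


def lambda_max_per_view(views: dict[str, np.ndarray], ytilde: np.ndarray, alpha: float) -> dict[str, float]:
    """Smallest per-view penalty for which the all-zero solution is optimal.

    With every other block at zero, the gradient of the smooth part at
    w_d = 0 is -(1-alpha)/n * X_d' ytilde, so lam_max,d is its sup-norm.
    """
    n = ytilde.size
    # hair of headroom so a fit at exactly lam_max is all-zero regardless
    # of floating-point op order inside the solver
    return {
        name: float(np.max(np.abs((1.0 - alpha) / n * (X.T @ ytilde)))) * (1 + 1e-10)
        for name, X in views.items()
    }


def jaca_objective(
    views: dict[str, np.ndarray],
    w: dict[str, np.ndarray],
    ytilde: np.ndarray,
    alpha: float,
    lambdas: dict[str, float],
) -> float:
    n = ytilde.size
    names = list(views)
    scores = {d: views[d] @ w[d] for d in names}
    val = 0.0
    for d in names:
        val += (1.0 - alpha) / (2 * n) * float(np.sum((ytilde - scores[d]) ** 2))
        val += lambdas[d] * float(np.abs(w[d]).sum())
    for d, e in itertools.combinations(names, 2):
        val += alpha / (2 * n) * float(np.sum((scores[d] - scores[e]) ** 2))
    return val


def fit_jaca(
    views: dict[str, np.ndarray],
    y,
    alpha: float = 0.5,
    lambdas: dict[str, float] | float | None = None,
    feature_ids: dict[str, list[str]] | None = None,
    w0: dict[str, np.ndarray] | None = None,
) -> JointFit:
    """Fit the joint sparse model by block coordinate descent.

    ``views`` maps view name to an (n x p_d) standardized matrix with a
    shared sample ordering. ``lambdas`` may be one float for all views or
    a per-view mapping. The outer loop stops when the relative objective
    change drops below 1e-8 (at most 500 iterations; non-convergence is
    recorded on the fit). The objective value is recorded per iteration.
    """
    if not 0 <= alpha < 1:
        raise ConfigError("alpha must be in [0, 1); at alpha >= 1 the objective degenerates")
    names = list(views)
    D = len(names)
    if D not in (2, 3):
        raise ConfigError(f"need 2 or 3 views, got {D}")
    mats = {d: np.asarray(views[d], dtype=float) for d in names}
    n = mats[names[0]].shape[0]
    if any(m.shape[0] != n for m in mats.values()):
        raise AlignmentError("views disagree on sample count")
    os_ = optimal_scores(y)
    ytilde = os_.ytilde
    if lambdas is None:
        raise ValueDomainError("lambdas must be provided")
    if np.isscalar(lambdas):
        lam = {d: float(lambdas) for d in names}
    else:
        lam = {d: float(lambdas[d]) for d in names}
    if any(v <= 0 for v in lam.values()):
        raise ValueDomainError("penalties must be positive")
    ids = feature_ids or {d: [f"{d}:{j}" for j in range(mats[d].shape[1])] for d in names}

    w = {
        d: (np.array(w0[d], dtype=float) if w0 is not None else np.zeros(mats[d].shape[1]))
        for d in names
    }
    c = (1.0 - alpha) + alpha * (D - 1)
    trace = [jaca_objective(mats, w, ytilde, alpha, lam)]
    converged = False
    scores = {d: mats[d] @ w[d] for d in names}
    for _ in range(OUTER_MAX_ITER):
        max_coord_change = 0.0
        for d in names:
            others = np.zeros(n)
            for e in names:
                if e != d:
                    others += scores[e]
            r = ((1.0 - alpha) * ytilde + alpha * others) / c
            w_old = w[d].copy()
            cd_lasso(mats[d], r, c, lam[d], w[d], INNER_TOL, INNER_MAX_SWEEPS)
            if w[d].size:
                max_coord_change = max(max_coord_change,
                                       float(np.abs(w[d] - w_old).max()))
            scores[d] = mats[d] @ w[d]
        trace.append(jaca_objective(mats, w, ytilde, alpha, lam))
        prev, cur = trace[-2], trace[-1]
        # the objective criterion alone can stop while the block iterates
        # are still measurably asymmetric; require coordinate stability too
        if (abs(prev - cur) <= OUTER_TOL * max(abs(prev), 1.0)
                and max_coord_change < OUTER_COORD_TOL):
            converged = True
            break

    pooled = np.zeros(n)
    for d in names:
        pooled += scores[d]
    pooled /= D
    y01 = (np.asarray(y) == np.unique(np.asarray(y))[1]).astype(int)
    m1 = pooled[y01 == 0].mean()
    m2 = pooled[y01 == 1].mean()
    corr = {}
    for d, e in itertools.combinations(names, 2):
        sd1, sd2 = scores[d].std(), scores[e].std()
        if sd1 > 0 and sd2 > 0:
            corr[f"{d}|{e}"] = float(np.corrcoef(scores[d], scores[e])[0, 1])
        else:
            corr[f"{d}|{e}"] = float("nan")
    return JointFit(
        view_names=names,
        w=w,
        alpha=float(alpha),
        lambdas=lam,
        selected={d: {ids[d][j] for j in np.flatnonzero(w[d] != 0)} for d in names},
        feature_ids=ids,
        scores=scores,
        pairwise_corr=corr,
        threshold=0.5 * (m1 + m2),
        orientation=1 if m2 >= m1 else -1,
        majority_class=os_.majority_class,
        converged=converged,
        objective_trace=trace,
    )


def jaca_classify(fit: JointFit, new_views: dict[str, np.ndarray]) -> np.ndarray:
    """Nearest projected-centroid rule on the pooled score (1/D) sum X_d w_d."""
    names = fit.view_names
    missing = set(names) - set(new_views)
    if missing:
        raise AlignmentError(f"missing views: {sorted(missing)}")
    mats = {d: np.atleast_2d(np.asarray(new_views[d], dtype=float)) for d in names}
    for d in names:
        if mats[d].shape[1] != fit.w[d].size:
            raise AlignmentError(
                f"view {d!r}: expected {fit.w[d].size} features, got {mats[d].shape[1]}"
            )
    if all(not np.any(fit.w[d]) for d in names):
        n_new = mats[names[0]].shape[0]
        return np.full(n_new, fit.majority_class, dtype=int)
    pooled = np.zeros(mats[names[0]].shape[0])
    for d in names:
        pooled += mats[d] @ fit.w[d]
    pooled /= len(names)
    return (fit.orientation * (pooled - fit.threshold) > 0).astype(int)


def jaca_loocv(
    views: dict[str, np.ndarray],
    y,
    alpha: float = 0.5,
    grid_size: int = 20,
    feature_ids: dict[str, list[str]] | None = None,
    t_min: float = 1e-2,
) -> JointFit:
    """One-dimensional LOO search over a shared penalty multiplier.

    The grid is log-spaced over [t_min, 1] and lam_d = t * lam_max,d (the
    fold's own lam_max); each left-out sample is standardized with the
    training fold's mean/sd and classified by :func:`jaca_classify`. The
    returned fit is refit on the full data at the misclassification-
    minimizing t (ties toward larger t, i.e. the sparser model), with the
    achieved LOO MCR attached.
    """
    names = list(views)
    raw = {d: np.asarray(views[d], dtype=float) for d in names}
    n = raw[names[0]].shape[0]
    if n < 6:
        raise ValueDomainError(f"LOO needs n >= 6, got {n}")
    y01 = (np.asarray(y) == np.unique(np.asarray(y))[1]).astype(int)
    t_grid = np.geomspace(1.0, t_min, int(grid_size))

    miscount = np.zeros(t_grid.size, dtype=int)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        yt = y01[keep]
        if np.unique(yt).size < 2:
            raise DegenerateLabelsError("a LOO fold lost a class")
        train, held = {}, {}
        for d in names:
            Xs, mean, sd, _ = standardize_fit(raw[d][keep])
            train[d] = Xs
            held[d] = ((raw[d][i] - mean) / sd)[None, :]
        lam_max = lambda_max_per_view(train, optimal_scores(yt).ytilde, alpha)
        w_warm = None
        for g, t in enumerate(t_grid):
            lam = {d: max(t * lam_max[d], 1e-12) for d in names}
            fit = fit_jaca(train, yt, alpha=alpha, lambdas=lam, w0=w_warm)
            w_warm = {d: fit.w[d].copy() for d in names}
            if jaca_classify(fit, held)[0] != y01[i]:
                miscount[g] += 1

    best = miscount.min()
    idx = int(np.argmin(miscount))  # first minimum = largest t
    t_best = float(t_grid[idx])

    full = {d: standardize_fit(raw[d])[0] for d in names}
    lam_max_full = lambda_max_per_view(full, optimal_scores(y01).ytilde, alpha)
    lam = {d: max(t_best * lam_max_full[d], 1e-12) for d in names}
    fit = fit_jaca(full, y01, alpha=alpha, lambdas=lam, feature_ids=feature_ids)
    fit.loocv_mcr = float(best / n)
    return fit


def score_correlations(fit: JointFit, views: dict[str, np.ndarray]):
    """Pairwise Pearson correlations of the per-view sample scores.

    Returns (correlations dict keyed "view1|view2", DataFrame of per-sample
    projections, one column per view) for plotting pairwise projections.
    """
    names = fit.view_names
    scores = {}
    for d in names:
        X = np.asarray(views[d], dtype=float)
        s = X @ fit.w[d]
        if s.std() == 0:
            raise DegenerateScoreError(f"view {d!r} has a zero-variance score")
        scores[d] = s
    corr = {
        f"{d}|{e}": float(np.corrcoef(scores[d], scores[e])[0, 1])
        for d, e in itertools.combinations(names, 2)
    }
    return corr, pd.DataFrame(scores)
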