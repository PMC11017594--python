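"""Consensus feature selection across screening, discriminant, and joint fits.

The core set of a view is the three-way intersection of the screening
top-k set, the sparse-discriminant selection, and the joint-model
selection. It is then augmented by (1) features highly correlated
(|R| above a threshold, default 0.95) with the top-loading discriminant
feature and (2) the top third (by loading magnitude, ceiling) of the
joint-model selection. Each entry carries a provenance tag; when a
feature qualifies under several rules the priority is
selected_by_all > correlate_of_top > jaca_top_fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import FeatureTable
from .joint_multiview import JointFit
from .sparse_discriminant import DiscriminantFit, correlated_expansion

__all__ = [
    "ConsensusEntry",
    "ConsensusReport",
    "intersect_selections",
    "augment",
    "truth_metrics",
]

logger = logging.getLogger(__name__)

PROVENANCE_PRIORITY = ("selected_by_all", "correlate_of_top", "jaca_top_fraction")


@dataclass
class ConsensusEntry:
    feature_id: str
    provenance: str  # one of PROVENANCE_PRIORITY
    detail: str = ""  # e.g. "R=0.97 with <anchor>" or "JACA rank 3"

    def to_dict(self) -> dict:
        return {"feature_id": self.feature_id, "provenance": self.provenance,
                "detail": self.detail}


@dataclass
class ConsensusReport:
    """Per-view consensus entries with provenance, plus the method inputs."""

    view: str
    entries: list[ConsensusEntry]
    core_set: set[str]
    screening_set: set[str] = field(default_factory=set)
    discriminant_set: set[str] = field(default_factory=set)
    joint_set: set[str] = field(default_factory=set)

    @property
    def selected(self) -> set[str]:
        return {e.feature_id for e in self.entries}

    def to_dict(self) -> dict:
        return {
            "view": self.view,
            "entries": [e.to_dict() for e in sorted(
                self.entries,
                key=lambda e: (PROVENANCE_PRIORITY.index(e.provenance), e.feature_id),
            )],
            "core_set": sorted(self.core_set),
            "screening_set": sorted(self.screening_set),
            "discriminant_set": sorted(self.discriminant_set),
            "joint_set": sorted(self.joint_set),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConsensusReport":
        return cls(
            view=d["view"],
            entries=[ConsensusEntry(**e) for e in d["entries"]],
            core_set=set(d["core_set"]),
            screening_set=set(d["screening_set"]),
            discriminant_set=set(d["discriminant_set"]),
            joint_set=set(d["joint_set"]),
        )

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        return pd.DataFrame(
            [{"feature_id": e["feature_id"], "view": self.view,
              "provenance": e["provenance"], "detail": e["detail"]}
             for e in d["entries"]],
            columns=["feature_id", "view", "provenance", "detail"],
        )


def intersect_selections(mvsis_top: set, discriminant_set: set, joint_set: set) -> set:
    """Features selected by all three approaches (exact intersection)."""
    return set(mvsis_top) & set(discriminant_set) & set(joint_set)


def _top_fraction_entries(joint_fit: JointFit, view: str, top_fraction: float):
    ids = joint_fit.feature_ids[view]
    w = joint_fit.w[view]
    selected = [(fid, abs(coef)) for fid, coef in zip(ids, w) if coef != 0]
    if not selected:
        return []
    m = len(selected)
    n_top = math.ceil(m * top_fraction)
    # rank 1 = largest |loading|; ties by |loading| then id (deterministic)
    selected.sort(key=lambda t: (-t[1], t[0]))
    return [(fid, rank + 1) for rank, (fid, _) in enumerate(selected[:n_top])]


def augment(
    core: set,
    discriminant_fit: DiscriminantFit,
    joint_fit: JointFit,
    table: FeatureTable,
    view: str,
    corr_threshold: float = 0.95,
    top_fraction: float = 1 / 3,
    screening_set: set | None = None,
) -> ConsensusReport:
    """Build the per-view consensus report from a core set and two fits.

    Criterion (1): features whose |Pearson R| with the top-loading
    discriminant feature exceeds ``corr_threshold`` on ``table`` (the
    matrix the discriminant was fit to). Criterion (2): the top
    ceil(m * top_fraction) joint-selected features by |loading|. Core
    members always keep the selected_by_all tag.
    """
    entries: dict[str, ConsensusEntry] = {
        fid: ConsensusEntry(fid, "selected_by_all") for fid in sorted(core)
    }

    # (1) correlates of the top discriminant feature
    if discriminant_fit.selected:
        v_abs = np.abs(discriminant_fit.v)
        anchor = discriminant_fit.feature_ids[int(np.argmax(v_abs))]
        correlates = correlated_expansion(table, [anchor], corr_threshold)
        for fid, (anc, r) in sorted(correlates.items()):
            if fid not in entries:
                entries[fid] = ConsensusEntry(
                    fid, "correlate_of_top", f"R={r:.3f} with {anc}"
                )

    # (2) top fraction of joint-model loadings
    top = _top_fraction_entries(joint_fit, view, top_fraction)
    if not top and top_fraction > 0:
        logger.info("augment: joint selection empty for view %r; criterion (2) "
                    "contributes nothing", view)
    for fid, rank in top:
        if fid not in entries:
            entries[fid] = ConsensusEntry(fid, "jaca_top_fraction", f"JACA rank {rank}")

    return ConsensusReport(
        view=view,
        entries=list(entries.values()),
        core_set=set(core),
        screening_set=set(screening_set or set()),
        discriminant_set=set(discriminant_fit.selected),
        joint_set=set(joint_fit.selected.get(view, set())),
    )


def truth_metrics(selected, truth) -> tuple[float, float]:
    """(sensitivity, FDR) of a selection against a planted truth set.

    sensitivity = |sel & truth| / |truth|; FDR = |sel - truth| / max(|sel|, 1).
    An empty selection scores (0, 0).
    """
    sel = selected.selected if isinstance(selected, ConsensusReport) else set(selected)
    truth = set(truth)
    if not truth:
        raise ValueError("truth set must be non-empty for sensitivity")
    tp = len(sel & truth)
    sens = tp / len(truth)
    fdr = len(sel - truth) / max(len(sel), 1)
    return sens, fdr
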