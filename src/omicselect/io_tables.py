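"""Feature tables, study designs, and their delimited-text serialization.

The exchange object throughout the package is :class:`FeatureTable`, a
sample-by-feature numeric matrix backed by a :class:`pandas.DataFrame`
with a ``view_kind`` tag describing the measurement scale (raw counts,
intensities, relative abundances, paired differences, or generic).
"""

from __future__ import annotations

import enum
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateLabelsError,
    DuplicateIdError,
    ParseError,
    ValueDomainError,
)

__all__ = [
    "ViewKind",
    "FeatureTable",
    "StudyDesign",
    "AlignedDataset",
    "read_feature_table",
    "read_design",
    "align_views",
    "write_report",
    "read_report",
]


class ViewKind(str, enum.Enum):
    counts = "counts"
    intensities = "intensities"
    relative_abundance = "relative_abundance"
    differences = "differences"
    generic = "generic"


@dataclass
class FeatureTable:
    """A samples x features numeric matrix with identifiers.

    Parameters
    ----------
    data
        DataFrame with sample ids as the index and feature ids as columns.
    view_kind
        Measurement scale of the values; enforced invariants depend on it
        (counts must be non-negative, relative-abundance rows sum to 1).
    """

    data: pd.DataFrame
    view_kind: ViewKind = ViewKind.generic

    def __post_init__(self) -> None:
        if not isinstance(self.view_kind, ViewKind):
            self.view_kind = ViewKind(self.view_kind)
        idx = self.data.index.astype(str).str.strip()
        cols = self.data.columns.astype(str).str.strip()
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate feature ids: {dups}")
        self.data = self.data.copy()
        self.data.index = idx
        self.data.columns = cols
        values = self.data.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueDomainError(
                f"non-finite value at sample {idx[i]!r}, feature {cols[j]!r}"
            )
        if self.view_kind == ViewKind.counts and (values < 0).any():
            raise ValueDomainError("counts view contains negative entries")
        if self.view_kind == ViewKind.relative_abundance:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueDomainError("relative_abundance rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "FeatureTable":
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise AlignmentError(f"unknown sample ids: {sorted(missing)}")
        return FeatureTable(self.data.loc[list(sample_ids)], self.view_kind)

    def subset_features(self, feature_ids) -> "FeatureTable":
        missing = set(feature_ids) - set(self.feature_ids)
        if missing:
            raise AlignmentError(f"unknown feature ids: {sorted(missing)}")
        return FeatureTable(self.data[list(feature_ids)], self.view_kind)

    def to_tsv(self, path) -> None:
        sep = "\t" if str(path).endswith(".tsv") or not str(path).endswith(".csv") else ","
        self.data.to_csv(path, sep=sep, index_label="sample_id")

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.view_kind == other.view_kind
            and self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.allclose(self.values, other.values, rtol=1e-12, atol=0)
        )


@dataclass
class StudyDesign:
    """Per-sample subject, group, and day assignments.

    ``group`` is binary-coded 0/1; string labels are accepted and coded with
    ``control`` mapping to 0 when present, otherwise by sorted order.
    ``day`` must be 0 or 10. Each (subject, day) occurs at most once.
    """

    table: pd.DataFrame  # columns: sample_id, subject_id, group, day

    def __post_init__(self) -> None:
        required = {"sample_id", "subject_id", "group", "day"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueDomainError(f"design table missing columns: {sorted(missing)}")
        t = self.table.copy()
        for c in ("sample_id", "subject_id"):
            t[c] = t[c].astype(str).str.strip()
        if t["sample_id"].duplicated().any():
            raise DuplicateIdError("duplicate sample_id in design")
        t["group"] = _encode_groups(t["group"])
        t["day"] = t["day"].astype(int)
        if not set(t["day"]).issubset({0, 10}):
            raise ValueDomainError("day must be 0 or 10")
        if t.duplicated(subset=["subject_id", "day"]).any():
            raise DuplicateIdError("a (subject, day) pair appears more than once")
        if t["group"].nunique() < 2:
            raise DegenerateLabelsError("both groups must be present in the design")
        self.table = t.reset_index(drop=True)

    def labels_for(self, sample_ids) -> np.ndarray:
        lookup = dict(zip(self.table["sample_id"], self.table["group"]))
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise AlignmentError(f"sample {e.args[0]!r} absent from design") from None

    def subject_groups(self) -> dict[str, int]:
        """Group label per subject (constant across a subject's samples)."""
        per = self.table.groupby("subject_id")["group"].agg(["min", "max"])
        if (per["min"] != per["max"]).any():
            bad = per.index[per["min"] != per["max"]].tolist()
            raise ValueDomainError(f"subjects with inconsistent group: {bad}")
        return per["min"].to_dict()

    def samples_on_day(self, day: int) -> pd.DataFrame:
        return self.table[self.table["day"] == int(day)]


def _encode_groups(col: pd.Series) -> pd.Series:
    vals = col
    uniq = sorted(set(str(v).strip() for v in vals))
    if set(uniq) <= {"0", "1"}:
        return vals.astype(int)
    if len(uniq) != 2:
        raise ValueDomainError(f"group must be binary, got {uniq}")
    lower = [u.lower() for u in uniq]
    if "control" in lower:
        order = sorted(uniq, key=lambda u: u.lower() != "control")
    else:
        order = uniq
    mapping = {order[0]: 0, order[1]: 1}
    return vals.astype(str).str.strip().map(mapping).astype(int)


@dataclass
class AlignedDataset:
    """Views restricted to a common, identically ordered sample set."""

    views: dict[str, FeatureTable]
    labels: np.ndarray
    design: StudyDesign | None = None

    def __post_init__(self) -> None:
        orders = [tuple(v.sample_ids) for v in self.views.values()]
        if len(set(orders)) > 1:
            raise AlignmentError("views do not share an identical sample ordering")
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(orders[0]) if orders else 0
        if len(self.labels) != n:
            raise AlignmentError("labels length does not match sample count")
        if n and len(set(self.labels.tolist())) < 2:
            raise DegenerateLabelsError("both label values must occur")

    @property
    def sample_ids(self) -> list[str]:
        first = next(iter(self.views.values()))
        return first.sample_ids


def _read_delimited(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    header = [h.strip() for h in header]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise DuplicateIdError(f"duplicate feature ids in header: {dups}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        src = raw[col]
        bad = converted.isna() & ~src.isna()
        if bad.any() or src.isna().any():
            nabad = converted.isna()
            i = int(np.argmax(nabad.to_numpy()))
            raise ParseError(
                f"non-numeric or missing cell at row {raw.index[i]!r}, "
                f"column {col!r} (position {i}, {j})"
            )
        out[col] = converted.to_numpy(dtype=float)
    return out


def read_feature_table(
    path, orientation: str = "samples_in_rows", view_kind: ViewKind | str = ViewKind.generic
) -> FeatureTable:
    """Read a delimited table into a FeatureTable.

    The delimiter follows the extension (``.csv`` comma, otherwise tab).
    ``orientation='features_in_rows'`` transposes on read so the returned
    table is always samples-in-rows. Non-numeric or missing cells raise
    :class:`ParseError` with coordinates; duplicate identifiers raise
    :class:`DuplicateIdError`.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path)
    if orientation == "features_in_rows":
        df = df.T
    return FeatureTable(df, view_kind)


def read_design(path) -> StudyDesign:
    sep = "," if str(path).endswith(".csv") else "\t"
    return StudyDesign(pd.read_csv(path, sep=sep, dtype=str))


def align_views(views: dict[str, FeatureTable], design) -> AlignedDataset:
    """Restrict all views to their common samples, identically ordered.

    ``design`` may be a :class:`StudyDesign` (labels via sample_id) or a
    plain mapping sample_id -> 0/1 label. Sample order is the order of the
    first view, restricted to the intersection. Idempotent.
    """
    if not views:
        raise AlignmentError("no views supplied")
    names = list(views)
    common = set(views[names[0]].sample_ids)
    for name in names[1:]:
        common &= set(views[name].sample_ids)
    if not common:
        raise AlignmentError("no samples shared across all views")
    order = [s for s in views[names[0]].sample_ids if s in common]
    aligned = {name: views[name].subset_samples(order) for name in names}
    if isinstance(design, StudyDesign):
        labels = design.labels_for(order)
        kept_design = design
    else:
        try:
            labels = np.array([int(design[s]) for s in order])
        except KeyError as e:
            raise AlignmentError(f"sample {e.args[0]!r} has no label") from None
        kept_design = None
    if len(set(labels.tolist())) < 2:
        raise DegenerateLabelsError("a group is absent after intersection")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 2:
        raise DegenerateLabelsError("each group needs >=2 samples after alignment")
    return AlignedDataset(views=aligned, labels=labels, design=kept_design)


def write_report(report, path) -> None:
    """Serialize a report object to JSON, plus a per-feature/per-λ TSV.

    Any object exposing ``to_dict()`` and ``to_frame()`` is accepted
    (ConsensusReport, PathFit, JointFit). The TSV is written next to the
    JSON with the same stem.
    """
    d = report.to_dict()
    d["kind"] = type(report).__name__
    path = str(path)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)
    stem, _ = os.path.splitext(path)
    report.to_frame().to_csv(stem + ".tsv", sep="\t", index=False)


def read_report(path):
    """Inverse of :func:`write_report` (from the JSON form)."""
    from . import consensus, joint_multiview, sparse_discriminant

    with open(path) as fh:
        d = json.load(fh)
    kind = d.pop("kind")
    registry = {
        "ConsensusReport": consensus.ConsensusReport,
        "PathFit": sparse_discriminant.PathFit,
        "JointFit": joint_multiview.JointFit,
        "DiscriminantFit": sparse_discriminant.DiscriminantFit,
    }
    return registry[kind].from_dict(d)
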