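"""View-specific preprocessing for the three omic layers.

Metabolite intensities are median-rescaled (every feature's across-sample
median set to 1) and drug features removed; amplicon counts are collapsed
to genus, prevalence-filtered, and converted to relative abundance; paired
designs are reduced to per-subject day-10 minus day-0 differences; host
gene counts get a log2 counts-per-million transform. Standardization
(mean 0, sd 1 per feature) precedes the penalized solvers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    MissingTaxonomyError,
    PairingError,
    ValueDomainError,
    ZeroSampleError,
)
from .io_tables import FeatureTable, StudyDesign, ViewKind

__all__ = [
    "TaxonomyMap",
    "median_normalize",
    "remove_feature",
    "aggregate_to_genus",
    "prevalence_filter",
    "relative_abundance",
    "paired_difference",
    "log_cpm",
    "standardize_columns",
    "read_taxonomy",
]

logger = logging.getLogger(__name__)


@dataclass
class TaxonomyMap:
    """ASV id -> genus label; "unassigned" is a legal label."""

    mapping: dict[str, str]

    def genus_of(self, asv_id: str) -> str:
        try:
            return self.mapping[asv_id]
        except KeyError:
            raise MissingTaxonomyError(f"ASV {asv_id!r} has no taxonomy entry") from None


def read_taxonomy(path) -> TaxonomyMap:
    """Two-column TSV (asv_id, genus), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueDomainError("taxonomy file needs two columns: asv_id, genus")
    first = df.iloc[0]
    if str(first[0]).lower() in ("asv_id", "asv", "feature_id"):
        df = df.iloc[1:]
    return TaxonomyMap(dict(zip(df[0].str.strip(), df[1].str.strip())))


def median_normalize(table: FeatureTable) -> FeatureTable:
    """Divide each feature by its across-sample median (target median 1).

    Features with zero median are left unscaled and logged; negative
    intensities are a domain error.
    """
    values = table.values
    if (values < 0).any():
        raise ValueDomainError("median normalization requires non-negative intensities")
    med = np.median(values, axis=0)
    flagged = [f for f, m in zip(table.feature_ids, med) if m == 0]
    if flagged:
        logger.warning("median_normalize: %d features with zero median left unscaled: %s",
                       len(flagged), flagged[:10])
    scale = np.where(med == 0, 1.0, med)
    out = table.data / scale
    return FeatureTable(out, ViewKind.intensities)


def remove_feature(table: FeatureTable, feature_id: str) -> FeatureTable:
    """Drop one feature column (e.g. the administered drug itself)."""
    if feature_id not in table.data.columns:
        raise KeyError(f"feature {feature_id!r} not present in table")
    return FeatureTable(table.data.drop(columns=[feature_id]), table.view_kind)


def aggregate_to_genus(table: FeatureTable, taxonomy: TaxonomyMap) -> FeatureTable:
    """Sum ASV counts into genus columns; per-sample totals are conserved."""
    if table.view_kind != ViewKind.counts:
        raise ValueDomainError("genus aggregation expects a counts view")
    genera = [taxonomy.genus_of(f) for f in table.feature_ids]
    grouped = table.data.T.groupby(pd.Index(genera, name="genus")).sum().T
    return FeatureTable(grouped, ViewKind.counts)


def prevalence_filter(table: FeatureTable, min_samples: int = 6) -> FeatureTable:
    """Keep features with a strictly positive value in >= min_samples samples.

    The default 6 removes features present in 5 or fewer samples.
    """
    if min_samples > table.n_samples:
        raise ConfigError(
            f"min_samples={min_samples} exceeds sample count {table.n_samples}"
        )
    prevalence = (table.values > 0).sum(axis=0)
    keep = [f for f, c in zip(table.feature_ids, prevalence) if c >= min_samples]
    return FeatureTable(table.data[keep], table.view_kind)


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Row-normalize counts to proportions summing to 1."""
    if table.view_kind != ViewKind.counts:
        raise ValueDomainError("relative abundance expects a counts view")
    totals = table.values.sum(axis=1)
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ZeroSampleError(f"sample {bad!r} has zero total count")
    return FeatureTable(table.data.div(totals, axis=0), ViewKind.relative_abundance)


def paired_difference(table: FeatureTable, design: StudyDesign) -> FeatureTable:
    """Per-subject day-10 minus day-0 differences.

    Returns one row per subject (indexed by subject id). Subjects missing
    either day are dropped and logged; if none remain, PairingError.
    """
    meta = design.table.set_index("sample_id")
    in_table = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    rows = {}
    dropped = []
    for subject, sub in in_table.groupby("subject_id"):
        days = dict(zip(sub["day"], sub.index))
        if 0 in days and 10 in days:
            rows[subject] = table.data.loc[days[10]] - table.data.loc[days[0]]
        else:
            dropped.append(subject)
    if dropped:
        logger.warning("paired_difference: dropped subjects missing a day: %s", dropped)
    if not rows:
        raise PairingError("no subject has both day-0 and day-10 samples")
    out = pd.DataFrame(rows).T
    out.index.name = "subject_id"
    return FeatureTable(out.sort_index(), ViewKind.differences)


def log_cpm(table: FeatureTable) -> FeatureTable:
    """log2(1e6 * count / sample_total + 1) per entry."""
    if table.view_kind != ViewKind.counts:
        raise ValueDomainError("log-CPM expects a counts view")
    totals = table.values.sum(axis=1)
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ZeroSampleError(f"sample {bad!r} has zero total count")
    cpm = table.data.div(totals, axis=0) * 1e6
    return FeatureTable(np.log2(cpm + 1.0), ViewKind.generic)


def standardize_columns(table: FeatureTable) -> FeatureTable:
    """Center and scale every feature to mean 0, sd 1 (denominator n).

    Zero-variance features become all-zero columns (logged); idempotent
    on already-standardized input.
    """
    Xs, _, _, flagged = standardize_fit(table.values)
    if flagged:
        logger.warning("standardize_columns: %d zero-variance features set to zero",
                       len(flagged))
    out = pd.DataFrame(Xs, index=table.sample_ids, columns=table.feature_ids)
    return FeatureTable(out, ViewKind.generic)


def standardize_fit(X: np.ndarray):
    """Standardize an array, returning (Xs, mean, sd, zero-variance indices).

    The returned mean/sd reproduce the transform on new data (sd of
    zero-variance columns is reported as 1 so the transform is defined).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueDomainError("standardization needs at least 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd, denominator n
    flagged = np.flatnonzero(sd == 0).tolist()
    safe_sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / safe_sd, mean, safe_sd, flagged
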