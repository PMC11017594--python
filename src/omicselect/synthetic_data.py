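"""Synthetic paired multi-view datasets with planted ground truth.

The generator emulates a two-arm longitudinal design: two groups of
subjects sampled at day 0 (baseline, no group effect) and day 10
(post-treatment), with three measurement layers sharing one latent group
signal. Per subject, a latent factor z ~ Normal(group * effect, 1) at
day 10 (effect 0 at day 0) loads with weight rho onto a known subset of
informative features in every view; remaining features are independent
noise. The layers are then mapped onto realistic scales:

* metabolome analogue — lognormal intensities (exp of the Gaussian),
  day 0 and day 10;
* microbiome analogue — per-sample softmax over features, then
  multinomial counts at fixed depth 1e4 (compositional), day 0 and 10;
* exfoliome analogue — negative-binomial counts via an exponential
  link (gamma-Poisson mixture, dispersion 0.5), day 10 only.

Because day-0 data carry no group effect, the day10 - day0 paired
difference preserves the planted day-10 signal while removing
subject-level baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_tables import FeatureTable, StudyDesign, ViewKind

__all__ = ["SyntheticSpec", "SyntheticTruth", "SimulatedStudy",
           "simulate_multiomic", "default_study_analogue", "DEFAULT_SEED"]

DEFAULT_SEED = 20240415
MULTINOMIAL_DEPTH = 10_000
NB_DISPERSION = 0.5
NB_BASE_MEAN = 50.0
VIEW_NAMES = ("metabolome", "microbiome", "exfoliome")


@dataclass
class SyntheticSpec:
    """Study-analogue generator settings.

    Defaults mirror the emulated design: 9 subjects per group, feature
    counts 300/150/500 and informative counts 8/4/17 for the metabolome,
    microbiome, and exfoliome analogues, a latent mean shift of 2 within-
    group standard deviations, and informative-feature loading rho = 0.8
    on the shared factor. ``noise_sd`` defaults to sqrt(1 - rho^2) so
    informative columns have unit total variance like the noise columns.
    """

    n_per_group: int = 9
    p_d: tuple[int, int, int] = (300, 150, 500)
    k_d: tuple[int, int, int] = (8, 4, 17)
    effect: float = 2.0
    rho: float = 0.8
    noise_sd: float | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("need at least 2 subjects per group")
        if len(self.p_d) != 3 or len(self.k_d) != 3:
            raise ConfigError("p_d and k_d must have one entry per view")
        if any(k > p for k, p in zip(self.k_d, self.p_d)):
            raise ConfigError("k_d must not exceed p_d")
        if self.effect < 0:
            raise ConfigError("effect must be >= 0")
        if not 0 <= self.rho <= 1:
            raise ConfigError("rho must be in [0, 1]")
        if self.noise_sd is None:
            self.noise_sd = float(np.sqrt(max(1.0 - self.rho**2, 0.0)))


@dataclass
class SyntheticTruth:
    """Planted informative feature ids per view, latent factors, labels."""

    informative: dict[str, list[str]]
    latent_day10: np.ndarray
    latent_day0: np.ndarray
    groups: dict[str, int]

    @property
    def union(self) -> set[str]:
        return set().union(*self.informative.values())


@dataclass
class SimulatedStudy:
    """Raw per-view tables plus the design; input to the pipeline.

    Views 1-2 (metabolome, microbiome) carry day-0 and day-10 samples;
    the exfoliome carries day-10 only. Alignment to one common subject
    ordering happens downstream, after paired differencing.
    """

    views: dict[str, FeatureTable]
    design: StudyDesign
    truth: SyntheticTruth
    spec: SyntheticSpec


def _feature_ids(prefix: str, p: int) -> list[str]:
    width = len(str(p))
    return [f"{prefix}{j + 1:0{width}d}" for j in range(p)]


def _latent_matrix(rng, z, p, informative_idx, rho, noise_sd):
    n = z.size
    G = rng.standard_normal((n, p))
    G[:, informative_idx] = rho * z[:, None] + noise_sd * rng.standard_normal(
        (n, len(informative_idx))
    )
    return G


def _softmax_rows(G: np.ndarray) -> np.ndarray:
    e = np.exp(G - G.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def simulate_multiomic(spec: SyntheticSpec) -> tuple[SimulatedStudy, SyntheticTruth]:
    """Generate one paired three-view study with known informative features.

    Fully reproducible from ``spec.seed``: all randomness flows through a
    single :class:`numpy.random.Generator`.
    """
    if not isinstance(spec, SyntheticSpec):
        raise ConfigError("spec must be a SyntheticSpec")
    rng = np.random.default_rng(spec.seed)
    n_sub = 2 * spec.n_per_group
    subjects = [f"C{i + 1:02d}" for i in range(spec.n_per_group)] + [
        f"T{i + 1:02d}" for i in range(spec.n_per_group)
    ]
    groups = np.array([0] * spec.n_per_group + [1] * spec.n_per_group)

    z10 = groups * spec.effect + rng.standard_normal(n_sub)
    z0 = rng.standard_normal(n_sub)  # baseline: no group effect

    prefixes = ("met_", "gen_", "gene_")
    informative: dict[str, list[str]] = {}
    tables: dict[str, FeatureTable] = {}
    design_rows = []

    for view, prefix, p, k in zip(VIEW_NAMES, prefixes, spec.p_d, spec.k_d):
        ids = _feature_ids(prefix, p)
        info_idx = np.sort(rng.choice(p, size=k, replace=False))
        informative[view] = [ids[j] for j in info_idx]

        days = (0, 10) if view != "exfoliome" else (10,)
        frames = []
        for day in days:
            z = z10 if day == 10 else z0
            G = _latent_matrix(rng, z, p, info_idx, spec.rho, spec.noise_sd)
            sample_ids = [f"{s}_d{day}" for s in subjects]
            if view == "metabolome":
                values = np.exp(G)
                kind = ViewKind.intensities
            elif view == "microbiome":
                probs = _softmax_rows(G)
                values = np.vstack(
                    [rng.multinomial(MULTINOMIAL_DEPTH, pr) for pr in probs]
                ).astype(float)
                kind = ViewKind.counts
            else:  # exfoliome: gamma-Poisson (negative binomial), exp link
                mu = NB_BASE_MEAN * np.exp(G)
                shape = 1.0 / NB_DISPERSION
                lam = rng.gamma(shape, mu * NB_DISPERSION)
                values = rng.poisson(lam).astype(float)
                kind = ViewKind.counts
            frames.append(pd.DataFrame(values, index=sample_ids, columns=ids))
        tables[view] = FeatureTable(pd.concat(frames), kind)
        for day in days:
            for s, g in zip(subjects, groups):
                design_rows.append(
                    {"sample_id": f"{s}_d{day}", "subject_id": s,
                     "group": int(g), "day": day}
                )

    # one design row per (sample) across views; deduplicate shared days
    design_df = pd.DataFrame(design_rows).drop_duplicates("sample_id")
    design = StudyDesign(design_df)
    truth = SyntheticTruth(
        informative=informative,
        latent_day10=z10,
        latent_day0=z0,
        groups=dict(zip(subjects, groups.tolist())),
    )
    study = SimulatedStudy(views=tables, design=design, truth=truth, spec=spec)
    return study, truth


def default_study_analogue() -> tuple[SimulatedStudy, SyntheticTruth]:
    """The repository's end-to-end fixture: defaults, fixed seed."""
    return simulate_multiomic(SyntheticSpec())
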