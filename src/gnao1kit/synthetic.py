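"""Synthetic study data: fluorescence traces, patient cohorts, phenotype
tables.

Everything downstream of this module (fitting, cycling, clinical scoring,
correlation) is exercised on data generated here with known ground truth.
Three generators are provided, all pure functions of (spec, seed):

* BODIPY-GTPγS traces — single-exponential binding with iid Gaussian read
  noise proportional to amplitude;
* BODIPY-GTP traces — the sequential two-step (Bateman) rise-and-fall;
* patient cohorts — per-mutation onsets drawn log-normal around configured
  medians, rounded to whole days as onsets are reported clinically;
* phenotype tables — per-variant metric means with a configurable monotone
  association to the cohort's per-mutation median onset, plus Gaussian
  noise clipped at zero.

The default cohort spec encodes the study's group structure (29 DEE17
patients of which 13 carry biochemically inactive mutations, 31 NEDIM
patients); its per-mutation medians are calibrated so that, at the default
log-scale dispersion of 0.25, the log-normal mixture medians of the
DEE17, NEDIM and inactive groups equal 43, 569 and 31 days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clinical import Disorder, PatientRecord
from .kinetics import (
    FluorescenceTrace,
    KineticParams,
    KineticsError,
    Ligand,
    bateman_curve,
    binding_curve,
)

__all__ = [
    "SamplingSchedule",
    "NoiseModel",
    "CohortEntry",
    "CohortSpec",
    "MetricSpec",
    "PhenotypeSpec",
    "DEFAULT_SCHEDULE",
    "default_cohort_spec",
    "default_phenotype_spec",
    "simulate_gtpgs_trace",
    "simulate_gtp_trace",
    "simulate_cohort",
    "simulate_phenotype_table",
]


@dataclass(frozen=True)
class SamplingSchedule:
    """Uniform acquisition grid: n_points from t_start to t_end inclusive."""

    t_start: float = 0.0
    t_end: float = 3600.0
    n_points: int = 721  # 5 s cadence over one hour

    def __post_init__(self) -> None:
        if self.t_start < 0 or self.t_end <= self.t_start:
            raise KineticsError("need 0 <= t_start < t_end")
        if self.n_points < 2:
            raise KineticsError("n_points must be >= 2")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_points)


DEFAULT_SCHEDULE = SamplingSchedule()


@dataclass(frozen=True)
class NoiseModel:
    """iid Gaussian read noise with s.d. = sigma_rel × amplitude."""

    sigma_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise KineticsError("sigma_rel must be >= 0")


def _with_noise(
    clean: np.ndarray, amplitude: float, noise: NoiseModel
) -> np.ndarray:
    if noise.sigma_rel == 0.0 or amplitude == 0.0:
        return clean.copy()
    rng = np.random.default_rng(noise.seed)
    return clean + rng.normal(0.0, noise.sigma_rel * amplitude, size=clean.shape)


def simulate_gtpgs_trace(
    params: KineticParams,
    schedule: SamplingSchedule = DEFAULT_SCHEDULE,
    noise: NoiseModel = NoiseModel(),
    variant: str = "",
    replicate: int = 0,
) -> FluorescenceTrace:
    """Binding-only trace: F(t) = F0 + A·(1 − e^(−k_bind·t)) plus noise."""
    t = schedule.times
    clean = binding_curve(t, params.k_bind, params.amplitude, params.baseline)
    return FluorescenceTrace(
        times=t,
        values=_with_noise(clean, params.amplitude, noise),
        ligand=Ligand.GTPGS,
        variant=variant,
        replicate=replicate,
    )


def simulate_gtp_trace(
    params: KineticParams,
    schedule: SamplingSchedule = DEFAULT_SCHEDULE,
    noise: NoiseModel = NoiseModel(),
    variant: str = "",
    replicate: int = 0,
) -> FluorescenceTrace:
    """Binding-plus-hydrolysis trace following the Bateman intermediate.

    With k_hydr = 0 the output is identical (bitwise, for equal seeds) to
    :func:`simulate_gtpgs_trace` apart from the ligand tag.
    """
    t = schedule.times
    clean = bateman_curve(
        t, params.k_bind, params.k_hydr, params.amplitude, params.baseline
    )
    return FluorescenceTrace(
        times=t,
        values=_with_noise(clean, params.amplitude, noise),
        ligand=Ligand.GTP,
        variant=variant,
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortEntry:
    mutation: str
    disorder: Disorder
    n_patients: int
    median_onset_days: float
    dispersion: float = 0.25  # s.d. of log(onset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "disorder", Disorder(self.disorder))
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.median_onset_days <= 0:
            raise ValueError("median_onset_days must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    entries: tuple[CohortEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        object.__setattr__(self, "entries", entries)
        if not entries:
            raise ValueError("cohort spec must contain at least one mutation")
        labels = [e.mutation for e in entries]
        if len(set(labels)) != len(labels):
            raise ValueError("mutation labels must be unique")


#: (mutation, disorder, n_patients, median days) — counts reflect the study
#: cohort (29 DEE17 / 31 NEDIM patients, 13 of the DEE17 patients carrying
#: inactive mutations); medians calibrated for group mixture medians of
#: 43 / 569 / 31 days at dispersion 0.25 (see docs/methods.md).
_DEFAULT_COHORT: tuple[tuple[str, str, int, float], ...] = (
    ("G45E", "DEE17", 2, 5.98),
    ("F275S", "DEE17", 2, 7.18),
    ("I279N", "DEE17", 2, 9.57),
    ("G40R", "DEE17", 2, 37.10),
    ("D174G", "DEE17", 2, 53.86),
    ("Q52R", "DEE17", 1, 71.81),
    ("N270H", "DEE17", 1, 77.79),
    ("Q52P", "DEE17", 1, 83.78),
    ("L199P", "DEE17", 2, 6.50),
    ("G203R", "DEE17", 5, 39.95),
    ("A227V", "DEE17", 4, 48.31),
    ("Y231C", "DEE17", 3, 59.46),
    ("S47G", "DEE17", 2, 111.48),
    ("R209C", "NEDIM", 10, 474.83),
    ("E246K", "NEDIM", 8, 540.35),
    ("E237K", "NEDIM", 5, 569.79),
    ("C215Y", "NEDIM", 4, 759.72),
    ("Q233P", "NEDIM", 4, 854.69),
)


def default_cohort_spec(
    dispersion: float = 0.25, n_scale: int = 1
) -> CohortSpec:
    """The study-structured default cohort.

    ``n_scale`` multiplies every per-mutation patient count; use it to grow
    the cohort for Monte-Carlo work while preserving the group proportions.
    Changing ``dispersion`` away from 0.25 shifts the group mixture medians
    slightly off their calibrated 43/569/31-day targets.
    """
    return CohortSpec(
        entries=tuple(
            CohortEntry(m, d, n * n_scale, med, dispersion)
            for m, d, n, med in _DEFAULT_COHORT
        )
    )


def simulate_cohort(spec: CohortSpec, seed: int = 0) -> list[PatientRecord]:
    """Draw per-patient onsets: log-normal around each mutation's median.

    onset = round(median·exp(dispersion·z)), z ~ N(0,1), floored at 0 days.
    Zero dispersion makes every onset exactly the (rounded) median.
    """
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    counter = 1
    for entry in spec.entries:
        z = rng.standard_normal(entry.n_patients)
        onsets = entry.median_onset_days * np.exp(entry.dispersion * z)
        for onset in onsets:
            records.append(
                PatientRecord(
                    patient_id=f"P{counter:04d}",
                    mutation=entry.mutation,
                    onset_days=max(int(round(onset)), 0),
                    disorder=entry.disorder,
                )
            )
            counter += 1
    return records


# ---------------------------------------------------------------------------
# phenotype tables


@dataclass(frozen=True)
class MetricSpec:
    """One phenotype metric of the synthetic table.

    ``association_sign`` sets the sign of the metric's rank association
    with per-mutation median onset (+1 increasing, −1 decreasing, 0 none);
    ``span`` sets how far the per-variant means spread around the
    wild-type value (means run linearly in onset rank from
    wt·(1 − span/2) to wt·(1 + span/2), direction per sign).
    ``target_means`` may instead fix per-variant means explicitly.
    """

    name: str
    wildtype_value: float = 1.0
    noise_sd: float = 0.0
    association_sign: int = 0
    span: float = 1.2
    target_means: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.association_sign not in (-1, 0, 1):
            raise ValueError("association_sign must be -1, 0 or +1")
        if self.wildtype_value <= 0:
            raise ValueError("wildtype_value must be > 0")
        if not 0 < self.span < 2:
            raise ValueError("span must lie in (0, 2)")


@dataclass(frozen=True)
class PhenotypeSpec:
    metrics: tuple[MetricSpec, ...]

    def __post_init__(self) -> None:
        metrics = tuple(self.metrics)
        object.__setattr__(self, "metrics", metrics)
        if not metrics:
            raise ValueError("phenotype spec needs at least one metric")
        names = [m.name for m in metrics]
        if len(set(names)) != len(names):
            raise ValueError("metric names must be unique")


def default_phenotype_spec(noise_sd: float = 0.1) -> PhenotypeSpec:
    """Metrics emulating the study's quantifications.

    Ric8B co-IP carries the strongest (negative) association with onset —
    the stronger the neomorphic Ric8B binding, the earlier the disease —
    while expression, plasma-membrane localization and Gβγ binding rise
    with onset (severe variants express and localize poorly), and RGS19
    binding, Ric8A binding and ΔBRET carry no configured association.
    """
    return PhenotypeSpec(
        metrics=(
            MetricSpec("expression", 1.0, noise_sd, +1, span=1.2),
            MetricSpec("pm_ratio", 0.8, noise_sd, +1, span=1.0),
            MetricSpec("golgi_ratio", 0.3, noise_sd, -1, span=1.0),
            MetricSpec("gbg_coip", 1.0, noise_sd, +1, span=1.2),
            MetricSpec("rgs19_coip", 0.4, noise_sd, 0),
            MetricSpec("ric8a_coip", 1.0, noise_sd, 0),
            MetricSpec("ric8b_coip", 1.0, noise_sd, -1, span=1.6),
            MetricSpec("ric8b_golgi_ratio", 0.5, noise_sd, -1, span=1.2),
            MetricSpec("delta_bret", 0.05, noise_sd * 0.05, 0),
        )
    )


def _per_variant_onsets(cohort: Sequence[PatientRecord]) -> pd.Series:
    frame = pd.DataFrame(
        [(r.mutation, r.onset_days) for r in cohort],
        columns=["mutation", "onset_days"],
    )
    return frame.groupby("mutation", sort=True)["onset_days"].median()


def simulate_phenotype_table(
    spec: PhenotypeSpec,
    cohort: Sequence[PatientRecord],
    seed: int = 0,
) -> pd.DataFrame:
    """One row per variant: metric means plus Gaussian noise, clipped at 0.

    Means with a configured association sign follow a monotone (linear in
    onset rank) map of the per-mutation median onset, so at zero noise the
    Spearman correlation against onset is exactly ±1.  The returned frame
    is indexed by variant and carries ``onset_median_days``.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must be non-empty")
    onset = _per_variant_onsets(cohort)
    variants = list(onset.index)
    n = len(variants)
    rng = np.random.default_rng(seed)
    # average ranks scaled to [-0.5, 0.5]; ties in onset share a rank
    rank01 = (sps.rankdata(onset.to_numpy(), method="average") - 1) / max(n - 1, 1)
    centered = rank01 - 0.5

    data: dict[str, np.ndarray] = {}
    for metric in spec.metrics:
        if metric.target_means is not None:
            unknown = set(metric.target_means) - set(variants)
            if unknown:
                raise ValueError(
                    f"metric {metric.name!r} targets unknown variants: "
                    f"{sorted(unknown)}"
                )
            means = np.array(
                [
                    metric.target_means.get(v, metric.wildtype_value)
                    for v in variants
                ]
            )
        elif metric.association_sign == 0:
            means = np.full(n, metric.wildtype_value)
        else:
            means = metric.wildtype_value * (
                1.0 + metric.association_sign * metric.span * centered
            )
        noise = rng.normal(0.0, metric.noise_sd, size=n) if metric.noise_sd else 0.0
        data[metric.name] = np.clip(means + noise, 0.0, None)
    table = pd.DataFrame(data, index=pd.Index(variants, name="variant"))
    table["onset_median_days"] = onset.to_numpy(dtype=float)
    return table
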