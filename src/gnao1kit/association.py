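"""Genotype–phenotype statistics: normalization, ΔBRET, rank correlation,
Mann–Whitney comparison and biomarker ranking.

The cohorts here are tiny (5–17 variants per scatterplot, a handful of
replicates per group), so the p-values that matter are the small-sample
ones.  Spearman's rank correlation and the Mann–Whitney U test are
therefore implemented with exact permutation enumeration at small n,
seeded Monte-Carlo permutation at intermediate n (Spearman), and the usual
large-sample approximations beyond that; the method actually used is
recorded in every result.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "TestResult",
    "BiomarkerResult",
    "UndefinedCorrelationError",
    "localization_ratio",
    "delta_bret",
    "normalize_to_wildtype",
    "spearman",
    "mann_whitney",
    "rank_biomarkers",
    "PHENOTYPE_METRICS",
]

#: canonical phenotype-table metric columns (all dimensionless; co-IP and
#: expression are wild-type-normalized, pm/golgi are region/total-cell
#: fluorescence ratios, delta_bret is in BRET-ratio units)
PHENOTYPE_METRICS: tuple[str, ...] = (
    "expression",
    "pm_ratio",
    "golgi_ratio",
    "gbg_coip",
    "rgs19_coip",
    "ric8a_coip",
    "ric8b_coip",
    "ric8b_golgi_ratio",
    "delta_bret",
)

ONSET_COLUMN = "onset_median_days"


class UndefinedCorrelationError(ValueError):
    """Correlation requested against a constant vector."""


class PValueMethod(str, enum.Enum):
    EXACT_PERMUTATION = "exact_permutation"
    MONTE_CARLO_PERMUTATION = "monte_carlo_permutation"
    T_APPROXIMATION = "t_approximation"
    NORMAL_APPROXIMATION = "normal_approximation"


@dataclass(frozen=True)
class CorrelationResult:
    r_s: float
    p_value: float
    n: int
    method: PValueMethod


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: PValueMethod


# ---------------------------------------------------------------------------
# quantification helpers


def localization_ratio(region_mean: float, total_mean: float) -> float:
    """Region-mean fluorescence over total-cell mean (e.g. Golgi/total)."""
    if total_mean <= 0:
        raise ValueError(f"total_mean must be > 0, got {total_mean!r}")
    if region_mean < 0:
        raise ValueError(f"region_mean must be >= 0, got {region_mean!r}")
    return region_mean / total_mean


def delta_bret(
    times: Sequence[float],
    ratios: Sequence[float],
    injection_time: float,
    pre_window: float = 30.0,
    post_window: float = 50.0,
) -> float:
    """Agonist-induced BRET change: mean post-injection minus mean
    pre-injection ratio.

    The pre window is [injection_time − pre_window, injection_time), the
    post window (injection_time, injection_time + post_window]; each must
    contain at least 2 samples.  Defaults mirror a ~30 s baseline read and
    ~50 s of post-injection recording.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("times and ratios must be equally long 1-D vectors")
    if pre_window <= 0 or post_window <= 0:
        raise ValueError("windows must have positive length")
    pre = (t >= injection_time - pre_window) & (t < injection_time)
    post = (t > injection_time) & (t <= injection_time + post_window)
    if pre.sum() < 2 or post.sum() < 2:
        raise ValueError(
            f"need >= 2 samples in each window (got {int(pre.sum())} pre, "
            f"{int(post.sum())} post)"
        )
    return float(np.mean(r[post]) - np.mean(r[pre]))


def normalize_to_wildtype(
    table: pd.DataFrame,
    reference_variant: str = "WT",
    columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Divide phenotype columns by the reference (wild-type) row.

    The reference row becomes exactly 1.0 in the normalized columns, so the
    operation is idempotent.  ``columns`` defaults to every numeric column
    except the onset column.  The table must be indexed by variant.
    """
    if reference_variant not in table.index:
        raise KeyError(f"reference variant {reference_variant!r} not in table")
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c != ONSET_COLUMN and pd.api.types.is_numeric_dtype(table[c])
        ]
    ref = table.loc[reference_variant, list(columns)]
    if (ref <= 0).any():
        bad = [c for c in columns if table.loc[reference_variant, c] <= 0]
        raise ValueError(
            f"reference values must be > 0 to normalize; offending: {bad}"
        )
    out = table.copy()
    out[list(columns)] = table[list(columns)] / ref
    return out


# ---------------------------------------------------------------------------
# Spearman rank correlation


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    return float(a @ b) / denom


@lru_cache(maxsize=16)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact_n_max: int = 8,
    monte_carlo_n_max: int = 12,
    n_permutations: int = 100_000,
    seed: int = 0,
) -> CorrelationResult:
    """Two-tailed Spearman rank correlation with small-n exact p-values.

    r_s is the Pearson correlation of average ranks.  The two-tailed
    p-value is P(|r_s*| ≥ |r_s|) under uniformly random pairing: exact
    enumeration of all n! pairings for n ≤ ``exact_n_max``, seeded
    Monte-Carlo permutation (with the +1 correction, so p > 0) up to
    ``monte_carlo_n_max``, and the t-approximation
    t = r_s·√((n−2)/(1−r_s²)) on n−2 df beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equally long 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for a correlation")
    rx, ry = _rank(x), _rank(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError(
            "correlation is undefined for a constant vector"
        )
    r_obs = _pearson(rx, ry)
    tol = 1e-12

    if n <= exact_n_max:
        perms = _permutation_matrix(n)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        r_all = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(r_all) >= abs(r_obs) - tol))
        method = PValueMethod.EXACT_PERMUTATION
    elif n <= monte_carlo_n_max:
        rng = np.random.default_rng(seed)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        hits = 0
        block = 20_000
        done = 0
        while done < n_permutations:
            m = min(block, n_permutations - done)
            idx = rng.permuted(
                np.broadcast_to(np.arange(n), (m, n)).copy(), axis=1
            )
            r_mc = (ryc[idx] @ rxc) / denom
            hits += int(np.sum(np.abs(r_mc) >= abs(r_obs) - tol))
            done += m
        p = (hits + 1) / (n_permutations + 1)
        method = PValueMethod.MONTE_CARLO_PERMUTATION
    else:
        if abs(r_obs) >= 1.0:
            p = float(np.finfo(float).tiny)
        else:
            t_stat = r_obs * math.sqrt((n - 2) / (1.0 - r_obs**2))
            p = float(2.0 * sps.t.sf(abs(t_stat), df=n - 2))
            p = min(max(p, np.finfo(float).tiny), 1.0)
        method = PValueMethod.T_APPROXIMATION
    return CorrelationResult(r_s=r_obs, p_value=p, n=n, method=method)


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=64)
def _combination_matrix(n: int, k: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    exact_total_max: int = 12,
) -> TestResult:
    """Two-tailed Mann–Whitney U test with exact small-sample enumeration.

    The statistic is U of the first sample (wins of a over b, ties counting
    one half), computed from average ranks.  For n1 + n2 ≤
    ``exact_total_max`` the permutation distribution of U is enumerated
    over all C(n1+n2, n1) group assignments of the observed pooled values
    (ties included), and p = P(|U* − n1·n2/2| ≥ |U − n1·n2/2|).  Larger
    samples use the normal approximation with tie-corrected variance and
    a 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty 1-D vectors")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _rank(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    center = n1 * n2 / 2.0
    tol = 1e-9

    if n1 + n2 <= exact_total_max:
        combos = _combination_matrix(n1 + n2, n1)
        rank_sums = ranks[combos].sum(axis=1)
        u_all = rank_sums - n1 * (n1 + 1) / 2.0
        p = float(np.mean(np.abs(u_all - center) >= abs(u1 - center) - tol))
        method = PValueMethod.EXACT_PERMUTATION
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:  # all values identical
            return TestResult(u1, 1.0, n1, n2, PValueMethod.NORMAL_APPROXIMATION)
        z = (abs(u1 - center) - 0.5) / math.sqrt(sigma2)
        p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
        p = max(p, np.finfo(float).tiny)
        method = PValueMethod.NORMAL_APPROXIMATION
    return TestResult(u1, p, n1, n2, method)


# ---------------------------------------------------------------------------
# biomarker ranking


@dataclass(frozen=True)
class BiomarkerResult:
    metric: str
    result: Optional[CorrelationResult]
    error: str = ""

    @property
    def abs_r(self) -> float:
        return abs(self.result.r_s) if self.result is not None else -math.inf


def rank_biomarkers(
    table: pd.DataFrame,
    onset_column: str = ONSET_COLUMN,
    metrics: Optional[Sequence[str]] = None,
    holm: bool = False,
    seed: int = 0,
) -> list[BiomarkerResult]:
    """Rank phenotype metrics by |Spearman r_s| against disease onset.

    Every numeric metric column is correlated with the per-variant median
    onset; results are sorted by descending |r_s| with no significance
    filtering (a constant metric is kept, flagged, and sorted last).  With
    ``holm=True`` p-values are Holm-adjusted across metrics.  Onset enters
    on the day scale; any log display scale would not change ranks.
    """
    if onset_column not in table.columns:
        raise KeyError(f"table lacks the {onset_column!r} column")
    if len(table) < 3:
        raise ValueError("need >= 3 variants to rank biomarkers")
    if metrics is None:
        metrics = [
            c
            for c in table.columns
            if c != onset_column and pd.api.types.is_numeric_dtype(table[c])
        ]
    onset = table[onset_column].to_numpy(dtype=float)
    results: list[BiomarkerResult] = []
    for metric in sorted(metrics):
        try:
            res = spearman(table[metric].to_numpy(dtype=float), onset, seed=seed)
            results.append(BiomarkerResult(metric, res))
        except UndefinedCorrelationError as exc:
            results.append(BiomarkerResult(metric, None, error=str(exc)))
    if holm:
        from statsmodels.stats.multitest import multipletests

        idx = [i for i, r in enumerate(results) if r.result is not None]
        if idx:
            adj = multipletests(
                [results[i].result.p_value for i in idx], method="holm"
            )[1]
            for i, p_adj in zip(idx, adj):
                old = results[i].result
                results[i] = BiomarkerResult(
                    results[i].metric,
                    CorrelationResult(old.r_s, float(p_adj), old.n, old.method),
                )
    # descending |r_s|; ties broken by metric name for a stable order
    results.sort(key=lambda r: (-r.abs_r, r.metric))
    return results
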