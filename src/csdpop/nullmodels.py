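"""Resampling null models: reference pools, occurrence spectra, overlaps.

The study's reference datasets (expA/expB, rA, rB, rAB, r-redAB) are pools
of D draws with replacement from N equally frequent elements.  Observed
occurrence spectra (how many alleles were seen once, twice, ...) and the
spatial overlap between two populations are compared against the mean of
such resampled pools — 100 replicates by default — with a Pearson
chi-square statistic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OccurrenceSpectrum",
    "OverlapPartition",
    "ChiSquareResult",
    "sample_pool",
    "spectrum",
    "mean_spectrum",
    "expected_spectrum_analytic",
    "overlap_partition",
    "expected_overlap",
    "expected_shared_analytic",
    "apiary_dedup",
    "chi_square_compare",
]


@dataclass(frozen=True)
class OccurrenceSpectrum:
    """Count-of-counts: how many distinct alleles occur exactly k times."""

    counts: dict[int, float]

    def __post_init__(self) -> None:
        for k in self.counts:
            if k < 1:
                raise ValueError("occurrence count k must be >= 1")

    @property
    def n_observations(self) -> float:
        return sum(k * c for k, c in self.counts.items())

    @property
    def n_distinct(self) -> float:
        return sum(self.counts.values())

    def get(self, k: int, default: float = 0.0) -> float:
        return self.counts.get(k, default)


@dataclass(frozen=True)
class OverlapPartition:
    """Distinct alleles exclusive to A, exclusive to B, and shared."""

    only_a: float
    only_b: float
    shared: float

    def as_dict(self) -> dict[str, float]:
        return {"only_a": self.only_a, "only_b": self.only_b, "shared": self.shared}


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    df: int
    #: groups of original category labels after pooling of sparse bins
    categories_used: tuple[tuple, ...]

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "categories_used": [list(g) for g in self.categories_used],
        }


def sample_pool(N: int, D: int, rng: np.random.Generator) -> np.ndarray:
    """D iid uniform draws with replacement from element ids 1..N."""
    if N < 1 or D < 1:
        raise ValueError("N and D must be positive")
    return rng.integers(1, N + 1, size=D)


def spectrum(observations: Iterable) -> OccurrenceSpectrum:
    """Exact count-of-counts of a multiset of observations."""
    per_element = Counter(
        observations.tolist() if isinstance(observations, np.ndarray) else observations
    )
    return OccurrenceSpectrum(counts=dict(Counter(per_element.values())))


def mean_spectrum(
    N: int, D: int, reps: int = 100, rng: np.random.Generator | None = None
) -> OccurrenceSpectrum:
    """Mean occurrence spectrum over ``reps`` resampled pools of D draws."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    totals: Counter = Counter()
    for _ in range(reps):
        totals.update(spectrum(sample_pool(N, D, rng)).counts)
    return OccurrenceSpectrum(counts={k: v / reps for k, v in sorted(totals.items())})


def expected_spectrum_analytic(N: int, D: int, k: int) -> float:
    """E[#elements seen exactly k times] = N * C(D,k) (1/N)^k (1-1/N)^(D-k)."""
    return float(N * stats.binom.pmf(k, D, 1.0 / N))


def overlap_partition(a: Iterable, b: Iterable) -> OverlapPartition:
    """Partition two allele sets into exclusive and shared distinct counts."""
    sa, sb = set(a), set(b)
    shared = len(sa & sb)
    return OverlapPartition(
        only_a=len(sa) - shared, only_b=len(sb) - shared, shared=shared
    )


def expected_overlap(
    N: int,
    D_a: int,
    D_b: int,
    reps: int = 100,
    rng: np.random.Generator | None = None,
) -> OverlapPartition:
    """Mean overlap partition of two independent resampled pools.

    Both pools draw from the same N equally frequent elements, with D_a and
    D_b draws respectively.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    acc = np.zeros(3)
    for _ in range(reps):
        part = overlap_partition(sample_pool(N, D_a, rng), sample_pool(N, D_b, rng))
        acc += (part.only_a, part.only_b, part.shared)
    acc /= reps
    return OverlapPartition(only_a=acc[0], only_b=acc[1], shared=acc[2])


def expected_shared_analytic(N: int, D_a: int, D_b: int) -> float:
    """E[shared] = N * (1-(1-1/N)^D_a) * (1-(1-1/N)^D_b) for independent pools."""
    pa = 1.0 - (1.0 - 1.0 / N) ** D_a
    pb = 1.0 - (1.0 - 1.0 / N) ** D_b
    return N * pa * pb


def apiary_dedup(table: pd.DataFrame) -> pd.DataFrame:
    """Count each allele at most once per apiary.

    One row is kept per (apiary_id, allele_id) pair; the number of colonies
    that carried the allele within the apiary is preserved in ``n_colonies``.
    Idempotent: re-applying leaves the rows and colony counts unchanged.
    """
    for col in ("allele_id", "apiary_id"):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    if table["apiary_id"].isna().any():
        raise ValueError("apiary_id missing on some rows")
    if table.empty:
        out = table.copy()
        out["n_colonies"] = pd.Series(dtype=int)
        return out

    def _n_colonies(group: pd.DataFrame) -> int:
        if "n_colonies" in group.columns:
            return int(group["n_colonies"].sum())
        if "colony_id" in group.columns:
            return int(group["colony_id"].nunique())
        return len(group)

    kept = []
    for (_, _), group in table.groupby(["apiary_id", "allele_id"], sort=False):
        row = group.iloc[0].to_dict()
        row["n_colonies"] = _n_colonies(group)
        kept.append(row)
    out = pd.DataFrame(kept)
    return out.reset_index(drop=True)


def _as_category_map(x) -> dict:
    if isinstance(x, OccurrenceSpectrum):
        return dict(x.counts)
    if isinstance(x, OverlapPartition):
        return x.as_dict()
    if isinstance(x, Mapping):
        return dict(x)
    raise TypeError(f"cannot interpret {type(x).__name__} as categories")


def chi_square_compare(
    observed,
    expected,
    pool_threshold: float = 1.0,
) -> ChiSquareResult:
    """Pearson chi-square between observed counts and null-model means.

    Categories are aligned on the union of keys (missing entries are 0).
    Bins whose expected count falls below ``pool_threshold`` are pooled into
    the adjacent tail bin before the statistic is computed, and the pooling
    is reported in ``categories_used``.  df = number of bins - 1.
    """
    obs_map = _as_category_map(observed)
    exp_map = _as_category_map(expected)
    keys = sorted(set(obs_map) | set(exp_map), key=lambda k: (str(type(k)), k))

    bins: list[tuple[list, float, float]] = []  # (labels, obs, exp)
    for k in keys:
        bins.append(([k], float(obs_map.get(k, 0.0)), float(exp_map.get(k, 0.0))))

    # pool sparse bins into the adjacent tail (next bin; trailing sparse
    # bins fold back into the last retained bin)
    pooled: list[tuple[list, float, float]] = []
    carry_labels: list = []
    carry_obs = carry_exp = 0.0
    for labels, o, e in bins:
        labels = carry_labels + labels
        o, e = carry_obs + o, carry_exp + e
        if e < pool_threshold:
            carry_labels, carry_obs, carry_exp = labels, o, e
        else:
            pooled.append((labels, o, e))
            carry_labels, carry_obs, carry_exp = [], 0.0, 0.0
    if carry_labels:
        if pooled:
            labels, o, e = pooled.pop()
            pooled.append((labels + carry_labels, o + carry_obs, e + carry_exp))
        elif carry_exp > 0:
            pooled.append((carry_labels, carry_obs, carry_exp))

    if not pooled:
        raise ValueError("zero categories with positive expected count after pooling")
    if len(pooled) == 1:
        raise ValueError("only one category after pooling; chi-square undefined")

    obs_arr = np.array([o for _, o, _ in pooled])
    exp_arr = np.array([e for _, _, e in pooled])
    statistic = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    df = len(pooled) - 1
    p_value = float(stats.chi2.sf(statistic, df))
    return ChiSquareResult(
        statistic=statistic,
        p_value=p_value,
        df=df,
        categories_used=tuple(tuple(labels) for labels, _, _ in pooled),
    )
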