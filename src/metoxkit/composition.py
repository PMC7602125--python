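"""Empirical resampling nulls for per-set composition statistics.

The central question: is a summary statistic (mean/median methionine
frequency, mean/median length, IDR fraction, mean abundance) of an
oxidized protein set extreme relative to equally sized random draws from
the whole proteome?  The null is built by drawing many random samples of
the same cardinality from the proteome pool (oxidized plus background
proteins) and recording the statistic of each sample; empirical one-sided
p-values use the (k+1)/(N+1) correction so that "no resample as extreme"
reports p = 1/(N+1) rather than zero.

Also provides the abundance rank comparison between the two oxidized
sets (Wilcoxon–Mann–Whitney) and the complementary cumulative abundance
distribution (CCDF) used for rank-frequency plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProteinRecord

#: Statistics supported by :func:`resample_null`, mapped to the per-protein
#: feature they summarize and the reduction applied to each sample.
STATISTICS = {
    "mean_met_freq": ("met_freq", np.mean),
    "median_met_freq": ("met_freq", np.median),
    "mean_length": ("length", np.mean),
    "median_length": ("length", np.median),
    "idr_fraction": ("idr", np.mean),
    "mean_abundance": ("abundance", np.mean),
}


@dataclass
class NullDistribution:
    """A resampled null: statistic values, the observed value, empirical p.

    ``p_upper = (#{values >= observed} + 1) / (n_resamples + 1)`` and
    symmetrically for ``p_lower``.
    """

    statistic_name: str
    sample_size: int
    n_resamples: int
    values: np.ndarray
    observed: float
    p_upper: float
    p_lower: float
    n_skipped: int = 0

    @classmethod
    def from_values(
        cls,
        statistic_name: str,
        sample_size: int,
        values: np.ndarray,
        observed: float,
        n_skipped: int = 0,
    ) -> "NullDistribution":
        values = np.asarray(values, dtype=float)
        n = len(values)
        p_upper = (np.count_nonzero(values >= observed) + 1) / (n + 1)
        p_lower = (np.count_nonzero(values <= observed) + 1) / (n + 1)
        return cls(
            statistic_name=statistic_name,
            sample_size=sample_size,
            n_resamples=n,
            values=values,
            observed=float(observed),
            p_upper=float(p_upper),
            p_lower=float(p_lower),
            n_skipped=n_skipped,
        )


def met_frequency(record: ProteinRecord | str) -> float:
    """Relative methionine frequency of a sequence: count('M') / length."""
    seq = record if isinstance(record, str) else record.sequence
    if len(seq) == 0:
        raise ValueError("empty sequence")
    return seq.count("M") / len(seq)


def _feature_vector(proteins: Sequence[ProteinRecord], feature: str) -> np.ndarray:
    """Per-protein feature values; missing annotations become NaN."""
    if feature == "met_freq":
        return np.array([met_frequency(p) for p in proteins], dtype=float)
    if feature == "length":
        return np.array([len(p.sequence) for p in proteins], dtype=float)
    if feature == "idr":
        return np.array(
            [np.nan if p.idr is None else float(p.idr) for p in proteins], dtype=float
        )
    if feature == "abundance":
        return np.array(
            [np.nan if p.abundance_ppm is None else p.abundance_ppm for p in proteins],
            dtype=float,
        )
    raise ValueError(f"unknown feature {feature!r}")


def resample_null(
    proteome: Sequence[ProteinRecord],
    statistic: str,
    observed_set: Sequence[ProteinRecord],
    sample_size: int | None = None,
    n_resamples: int = 100_000,
    seed: int | np.random.Generator | None = None,
    replace_within: bool = False,
) -> NullDistribution:
    """Resampling null for a composition statistic of a designated set.

    Each resample draws ``sample_size`` proteins (default: the size of the
    observed set) from the full proteome pool — without replacement within
    a sample unless ``replace_within`` — and records the statistic.  The
    observed value is computed on ``observed_set`` with the same reduction.
    Proteins with a missing annotation for the chosen feature are excluded
    from both the pool and the observed set.
    """
    if statistic not in STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from {sorted(STATISTICS)}"
        )
    feature, reduce = STATISTICS[statistic]
    pool = _feature_vector(proteome, feature)
    pool = pool[~np.isnan(pool)]
    obs_values = _feature_vector(observed_set, feature)
    obs_values = obs_values[~np.isnan(obs_values)]
    if len(obs_values) == 0:
        raise ValueError("observed set has no usable values for this statistic")
    if sample_size is None:
        sample_size = len(obs_values)
    if sample_size < 1:
        raise ValueError("sample_size must be positive")
    if not replace_within and sample_size > len(pool):
        raise ValueError(
            f"sample_size {sample_size} exceeds proteome pool size {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    observed = float(reduce(obs_values))

    values = np.empty(n_resamples, dtype=float)
    if replace_within:
        chunk = max(1, min(n_resamples, 10_000_000 // max(sample_size, 1)))
        done = 0
        while done < n_resamples:
            k = min(chunk, n_resamples - done)
            idx = rng.integers(0, len(pool), size=(k, sample_size))
            values[done : done + k] = reduce(pool[idx], axis=1)
            done += k
    else:
        # chunked partial-permutation sampling: argpartition of random keys
        # gives a uniform without-replacement subset per row
        chunk = max(1, min(n_resamples, 5_000_000 // max(len(pool), 1)))
        done = 0
        while done < n_resamples:
            k = min(chunk, n_resamples - done)
            keys = rng.random((k, len(pool)))
            idx = np.argpartition(keys, sample_size - 1, axis=1)[:, :sample_size]
            values[done : done + k] = reduce(pool[idx], axis=1)
            done += k
    return NullDistribution.from_values(statistic, sample_size, values, observed)


def abundance_rank_test(
    abundances_a: Iterable[float],
    abundances_b: Iterable[float],
) -> tuple[float, float, pd.DataFrame]:
    """Wilcoxon–Mann–Whitney comparison of two abundance samples.

    Missing values are removed per side.  Uses exact enumeration when both
    sides have at most 50 observations and there are no ties, and the
    normal approximation with tie correction otherwise.  Returns the U
    statistic (for the first sample), the two-sided p-value, and the merged
    increasing-abundance rank table (columns ``rank``, ``abundance``,
    ``set``) for rank-frequency style displays.
    """
    a = np.asarray([x for x in abundances_a if x is not None], dtype=float)
    b = np.asarray([x for x in abundances_b if x is not None], dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each set needs at least one non-missing abundance")
    merged = np.concatenate([a, b])
    has_ties = len(np.unique(merged)) < len(merged)
    method = "exact" if (max(len(a), len(b)) <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    order = np.argsort(merged, kind="stable")
    labels = np.array(["A"] * len(a) + ["B"] * len(b))
    ranks = pd.DataFrame(
        {
            "rank": np.arange(1, len(merged) + 1),
            "abundance": merged[order],
            "set": labels[order],
        }
    )
    return float(res.statistic), float(res.pvalue), ranks


def abundance_ccdf(
    proteins: Iterable[ProteinRecord] | Iterable[float],
) -> pd.DataFrame:
    """Complementary CDF of abundance: fraction of proteins with value >= x.

    Returns a table with one row per distinct abundance, nonincreasing in
    ``ccdf`` and starting at 1 at the minimum abundance.
    """
    values = []
    for item in proteins:
        x = item.abundance_ppm if isinstance(item, ProteinRecord) else item
        if x is not None and not np.isnan(x):
            values.append(float(x))
    if not values:
        raise ValueError("no proteins with abundance")
    arr = np.sort(np.asarray(values))
    xs, first_idx = np.unique(arr, return_index=True)
    ccdf = 1.0 - first_idx / len(arr)
    return pd.DataFrame({"abundance": xs, "ccdf": ccdf})
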