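"""Co-regulated protein pair analysis.

Do exclusively-ex-vivo oxidized proteins appear together in co-regulated
pairs more often than chance?  With N oxidized proteins of which N_vv
belong to the ex-vivo set, and all unordered pairs equiprobable, the
expected fraction of "pure ex vivo" pairs among sampled pairs is

    E[F] = N_vv (N_vv - 1) / (N (N - 1)).

The observed fraction F = (#pure ex-vivo pairs)/(#pairs) is compared to a
Monte-Carlo null where each of the n pairs is independently pure ex vivo
with probability E[F] (a Binomial(n, E[F]) count per iteration).  The
exact binomial upper tail serves as a closed-form cross-check, and a
hypergeometric variant (sampling pairs without replacement from the full
pair universe) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .composition import NullDistribution
from .io import PairRecord, ProteinRecord


@dataclass
class PairCensus:
    """Counts of co-regulated pairs by type within the oxidized universe."""

    n_pairs: int
    n_pure_ex: int
    n_mixed: int
    n_pure_vt: int
    N: int
    N_vv: int

    def __post_init__(self) -> None:
        if self.n_pure_ex + self.n_mixed + self.n_pure_vt != self.n_pairs:
            raise ValueError("pair type counts do not sum to n_pairs")

    @property
    def observed_pure_fraction(self) -> float:
        if self.n_pairs == 0:
            raise ValueError("no pairs in census")
        return self.n_pure_ex / self.n_pairs

    @property
    def expected_pure_fraction(self) -> float:
        return expected_pure_fraction(self.N, self.N_vv)


def filter_pairs(
    pairs: Iterable[PairRecord | tuple[str, str]],
    set_a: Sequence[ProteinRecord] | Iterable[str],
    set_b: Sequence[ProteinRecord] | Iterable[str],
) -> PairCensus:
    """Census of pairs whose both members lie in the oxidized universe A ∪ B.

    Pairs touching any protein outside A ∪ B are dropped; self-pairs are an
    error.  The census is invariant to pair orientation.
    """
    ids_a = {p.id if isinstance(p, ProteinRecord) else p for p in set_a}
    ids_b = {p.id if isinstance(p, ProteinRecord) else p for p in set_b}
    overlap = ids_a & ids_b
    if overlap:
        raise ValueError(f"sets A and B are not disjoint: {sorted(overlap)[:5]}")
    n_pure_ex = n_mixed = n_pure_vt = 0
    for pair in pairs:
        a, b = (pair.id_a, pair.id_b) if isinstance(pair, PairRecord) else pair
        if a == b:
            raise ValueError(f"self-pair ({a}, {b})")
        in_a = (a in ids_a, b in ids_a)
        in_b = (a in ids_b, b in ids_b)
        if not all(x or y for x, y in zip(in_a, in_b)):
            continue
        if all(in_a):
            n_pure_ex += 1
        elif all(in_b):
            n_pure_vt += 1
        else:
            n_mixed += 1
    return PairCensus(
        n_pairs=n_pure_ex + n_mixed + n_pure_vt,
        n_pure_ex=n_pure_ex,
        n_mixed=n_mixed,
        n_pure_vt=n_pure_vt,
        N=len(ids_a) + len(ids_b),
        N_vv=len(ids_a),
    )


def expected_pure_fraction(N: int, N_vv: int) -> float:
    """Closed-form E[F] = N_vv(N_vv-1) / (N(N-1)) under equiprobable pairs."""
    if N < 2:
        raise ValueError("need at least two proteins")
    if not 0 <= N_vv <= N:
        raise ValueError("N_vv must lie in [0, N]")
    return N_vv * (N_vv - 1) / (N * (N - 1))


def mc_null_pure_fraction(
    n_pairs: int,
    p: float,
    observed: float,
    n_iter: int = 100_000,
    seed: int | np.random.Generator | None = None,
    model: str = "binomial",
) -> NullDistribution:
    """Monte-Carlo null distribution of the pure ex-vivo pair fraction F.

    ``model='binomial'`` treats each of the ``n_pairs`` pairs as an
    independent Bernoulli(p) event, as in the published procedure;
    ``model='hypergeometric'`` instead samples ``n_pairs`` pairs without
    replacement from the full pair universe implied by ``p`` — it requires
    p to equal E[F] computed from a (N, N_vv) census, so use
    :func:`mc_null_pure_fraction_hypergeom` directly for that variant.
    The reported ``p_upper`` is the empirical P[F >= observed] with the
    (k+1)/(N+1) correction.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be a probability")
    if model != "binomial":
        raise ValueError("use mc_null_pure_fraction_hypergeom for that variant")
    rng = np.random.default_rng(seed)
    values = rng.binomial(n_pairs, p, size=n_iter) / n_pairs
    return NullDistribution.from_values("pure_ex_fraction", n_pairs, values, observed)


def mc_null_pure_fraction_hypergeom(
    n_pairs: int,
    N: int,
    N_vv: int,
    observed: float,
    n_iter: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> NullDistribution:
    """Hypergeometric variant: pairs drawn without replacement from the
    universe of C(N,2) potential pairs, C(N_vv,2) of which are pure ex vivo."""
    total = N * (N - 1) // 2
    good = N_vv * (N_vv - 1) // 2
    if n_pairs > total:
        raise ValueError("more pairs requested than exist in the universe")
    rng = np.random.default_rng(seed)
    values = rng.hypergeometric(good, total - good, n_pairs, size=n_iter) / n_pairs
    return NullDistribution.from_values("pure_ex_fraction", n_pairs, values, observed)


def exact_tail_pure_fraction(n_pairs: int, p: float, observed: float) -> float:
    """Exact binomial upper tail P[X >= ceil(observed * n_pairs)]."""
    k = int(np.ceil(observed * n_pairs - 1e-9))
    return float(stats.binom.sf(k - 1, n_pairs, p))
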