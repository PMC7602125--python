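"""Subcellular localization equivalence classes and Fisher enrichment.

Each protein carries a 10-dimensional 0/1 membership vector over the
compartments (Mit, Nuc, Lys, ER, Plm, Gol, End, Ske, Per, Cyt).  Two
proteins are equivalent when their vectors are identical; the resulting
equivalence classes ("clusters") partition the oxidized universe A ∪ B.
Although 2^10 = 1024 keys are theoretically possible, real data populates
only a small fraction of them, and only clusters with at least 10 members
are tested.  Each retained cluster is tested for a differential ex-vivo /
in-vitro preference with a two-sided Fisher exact test on the 2×2 table

    | cluster ∩ A      cluster ∩ B  |
    | A \\ cluster     B \\ cluster |
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import COMPARTMENTS, ProteinRecord


@dataclass
class Cluster:
    """One localization equivalence class over the oxidized universe."""

    key: tuple[int, ...]
    members: frozenset[str]
    n_ex: int
    n_vt: int

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def name(self) -> str:
        present = [abbr for abbr, bit in zip(COMPARTMENTS, self.key) if bit]
        return "-".join(present) if present else "None"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (cluster×ex, cluster×vt; others×ex, others×vt)."""

    a11: int
    a12: int
    a21: int
    a22: int

    def as_array(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]])


def build_clusters(proteins: Iterable[ProteinRecord]) -> list[Cluster]:
    """Group the ex-vivo / in-vitro proteins by identical compartment vectors.

    Proteins labeled ``both`` or ``background`` are ignored.  Proteins with
    an all-zero vector form their own cluster.
    """
    buckets: dict[tuple[int, ...], list[ProteinRecord]] = {}
    for p in proteins:
        if p.group not in ("ex_vivo", "in_vitro"):
            continue
        buckets.setdefault(tuple(p.compartments), []).append(p)
    clusters = []
    for key, members in sorted(buckets.items()):
        clusters.append(
            Cluster(
                key=key,
                members=frozenset(m.id for m in members),
                n_ex=sum(m.group == "ex_vivo" for m in members),
                n_vt=sum(m.group == "in_vitro" for m in members),
            )
        )
    return clusters


def filter_clusters(clusters: Iterable[Cluster], min_size: int = 10) -> list[Cluster]:
    """Keep clusters with at least ``min_size`` total members (A ∪ B)."""
    return [c for c in clusters if c.size >= min_size]


def cluster_table(cluster: Cluster, n_a: int, n_b: int) -> ContingencyTable2x2:
    """2×2 table of cluster membership against oxidation group.

    ``n_a`` and ``n_b`` are the total sizes of the ex-vivo and in-vitro
    sets (the column margins).
    """
    if cluster.n_ex > n_a or cluster.n_vt > n_b:
        raise ValueError("cluster counts exceed group totals")
    return ContingencyTable2x2(
        a11=cluster.n_ex,
        a12=cluster.n_vt,
        a21=n_a - cluster.n_ex,
        a22=n_b - cluster.n_vt,
    )


def fisher_exact_2x2(
    table: ContingencyTable2x2, odds: str = "sample"
) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2×2 table.

    The p-value sums hypergeometric probabilities not exceeding that of
    the observed table.  ``odds='sample'`` (default) reports the sample
    odds ratio a11·a22 / (a12·a21); ``odds='conditional'`` the conditional
    maximum-likelihood odds ratio.  A zero margin yields p = 1 and an
    undefined (NaN) odds ratio.
    """
    arr = table.as_array()
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if arr.sum() == 0:
        raise ValueError("at least one count must be positive")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    if odds == "sample":
        denom = table.a12 * table.a21
        oratio = (table.a11 * table.a22) / denom if denom else float("inf")
    elif odds == "conditional":
        oratio = float(stats.contingency.odds_ratio(arr, kind="conditional").statistic)
    else:
        raise ValueError("odds must be 'sample' or 'conditional'")
    return float(oratio), float(p)


def enrichment_report(
    set_a: Sequence[ProteinRecord],
    set_b: Sequence[ProteinRecord],
    min_size: int = 10,
    alpha: float = 0.005,
) -> pd.DataFrame:
    """Per-cluster enrichment table over the oxidized universe.

    Columns: cluster key string, name, n_ex, n_vt, size, percent_ex,
    odds_ratio, p, q (Benjamini–Hochberg, reported for reference only)
    and ``significant`` (raw p < alpha, the decision rule used).
    Row order is by ascending p; the content is invariant to input order.
    """
    clusters = filter_clusters(build_clusters(list(set_a) + list(set_b)), min_size)
    n_a, n_b = len(set_a), len(set_b)
    rows = []
    for c in clusters:
        oratio, p = fisher_exact_2x2(cluster_table(c, n_a, n_b))
        rows.append(
            {
                "key": "".join(map(str, c.key)),
                "name": c.name,
                "n_ex": c.n_ex,
                "n_vt": c.n_vt,
                "size": c.size,
                "percent_ex": 100.0 * c.n_ex / c.size,
                "odds_ratio": oratio,
                "p": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "key", "name", "n_ex", "n_vt", "size", "percent_ex", "odds_ratio", "p",
        ],
    )
    if len(df):
        df["q"] = stats.false_discovery_control(df["p"], method="bh")
        df["significant"] = df["p"] < alpha
        df = df.sort_values(["p", "key"], kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
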