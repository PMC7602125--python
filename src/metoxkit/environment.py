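"""Positional amino-acid analysis of MetO site sequence environments.

For every oxidized site with a full ±10-residue window, the frequency of
each standard amino acid at each flanking position (offsets −10..−1,
+1..+10) is tabulated, and compared with the same tabulation over paired
control sites: for each MetO site a non-oxidized methionine of the same
protein is drawn at random (without replacement by default).  Proteins
with more MetO sites than candidate control methionines are skipped.

The standardized difference for residue i at position j is

    Z_ij = (f_ij^MetO - f_ij^Met)
           / sqrt( (f_ij^MetO (1 - f_ij^MetO) + f_ij^Met (1 - f_ij^Met)) / n )

with n the number of MetO sites analyzed.  Under the null of identical
environments Z_ij ~ N(0, 1); |Z| > 2.807 marks the two-sided 99.5%
significance band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, ProteinRecord, SiteRecord

logger = logging.getLogger(__name__)

#: Flanking offsets relative to the central methionine (0 excluded).
OFFSETS = tuple(range(-10, 0)) + tuple(range(1, 11))

#: Two-sided 99.5% band: the 0.9975 standard-normal quantile, 2.8070.
DEFAULT_ALPHA_BAND = 2.807

WINDOW_RADIUS = 10


@dataclass
class FrequencyMatrix:
    """20 residues × 20 flanking positions of relative frequencies.

    Rows follow the alphabetical one-letter order of :data:`AMINO_ACIDS`;
    columns follow :data:`OFFSETS`.  Nonstandard residues ('X') are
    excluded from both numerator and denominator of their column, so each
    column sums to 1 over the standard alphabet.
    """

    values: np.ndarray
    n_sites: int
    condition: str | None = None
    site_class: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise ValueError("frequency matrix must be 20x20")
        if self.n_sites < 1:
            raise ValueError("need at least one site")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(AMINO_ACIDS), columns=list(OFFSETS)
        )


@dataclass
class ZMatrix:
    """Standardized MetO-vs-control frequency differences with its band."""

    values: np.ndarray
    n: int
    alpha_band: float = DEFAULT_ALPHA_BAND

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(AMINO_ACIDS), columns=list(OFFSETS)
        )

    def significant_cells(self) -> pd.DataFrame:
        """Long table of cells beyond the band: residue, offset, z."""
        rows = []
        for i, aa in enumerate(AMINO_ACIDS):
            for j, off in enumerate(OFFSETS):
                z = self.values[i, j]
                if np.isfinite(z) and abs(z) > self.alpha_band:
                    rows.append({"residue": aa, "offset": off, "z": z})
        return pd.DataFrame(rows, columns=["residue", "offset", "z"])


@dataclass
class EnvironmentReport:
    """Bookkeeping for one environment analysis run."""

    condition: str
    n_sites: int
    n_proteins: int
    n_skipped_proteins: int
    n_dropped_ineligible: int
    n_dropped_shared: int
    significant: pd.DataFrame = field(default_factory=pd.DataFrame)


def eligible_sites(protein: ProteinRecord | str, positions: Iterable[int]) -> list[int]:
    """Keep 1-based positions with at least 10 residues on each side."""
    seq = protein if isinstance(protein, str) else protein.sequence
    length = len(seq)
    return [
        p
        for p in positions
        if p - WINDOW_RADIUS >= 1 and p + WINDOW_RADIUS <= length
    ]


def pick_controls(
    protein: ProteinRecord | str,
    meto_positions: Sequence[int],
    rng: int | np.random.Generator | None = None,
    replace: bool = False,
) -> list[int] | None:
    """One control methionine per MetO site, or None to skip the protein.

    Controls are drawn from the protein's non-oxidized methionines that
    satisfy the same full-window eligibility, uniformly without
    replacement (unless ``replace``).  Returns ``None`` when the protein
    has more MetO sites than candidate controls.
    """
    seq = protein if isinstance(protein, str) else protein.sequence
    oxidized = set(meto_positions)
    candidates = eligible_sites(
        seq,
        [i + 1 for i, c in enumerate(seq) if c == "M" and i + 1 not in oxidized and i > 0],
    )
    if (not replace and len(oxidized) > len(candidates)) or not candidates:
        return None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    chosen = gen.choice(len(candidates), size=len(oxidized), replace=replace)
    return [candidates[i] for i in chosen]


def extract_window(sequence: str, position: int) -> str:
    """The 21-mer centred on a 1-based position (must fit fully)."""
    if position - WINDOW_RADIUS < 1 or position + WINDOW_RADIUS > len(sequence):
        raise ValueError(f"window around position {position} does not fit")
    return sequence[position - WINDOW_RADIUS - 1 : position + WINDOW_RADIUS]


def frequency_matrix(
    windows: Sequence[str],
    condition: str | None = None,
    site_class: str | None = None,
) -> FrequencyMatrix:
    """Relative frequency of each standard residue at each flanking position.

    Every window must be a 21-mer with methionine at its centre.  At each
    column, windows contributing a nonstandard residue are excluded from
    that column's denominator (the column is renormalized over the rest).
    """
    if not windows:
        raise ValueError("no windows")
    arr = np.empty((len(windows), 21), dtype="S1")
    for k, w in enumerate(windows):
        if len(w) != 21:
            raise ValueError(f"window {k} has length {len(w)}, expected 21")
        if w[WINDOW_RADIUS] != "M":
            raise ValueError(f"window {k} is not centred on methionine")
        arr[k] = np.frombuffer(w.encode(), dtype="S1")
    flanks = np.delete(arr, WINDOW_RADIUS, axis=1)  # drop the central column
    values = np.zeros((20, 20))
    aa_bytes = [aa.encode() for aa in AMINO_ACIDS]
    for j in range(20):
        col = flanks[:, j]
        counts = np.array([np.count_nonzero(col == aab) for aab in aa_bytes])
        total = counts.sum()  # excludes nonstandard symbols
        values[:, j] = counts / total if total else np.nan
    return FrequencyMatrix(
        values=values,
        n_sites=len(windows),
        condition=condition,
        site_class=site_class,
    )


def z_matrix(f_meto: FrequencyMatrix, f_met: FrequencyMatrix) -> ZMatrix:
    """Element-wise standardized difference between MetO and control matrices.

    ``n`` is the number of MetO sites analyzed.  Cells where both
    frequencies are simultaneously 0 or simultaneously 1 have a zero
    denominator and are flagged NaN.
    """
    if f_meto.n_sites != f_met.n_sites:
        raise ValueError(
            f"site counts differ: {f_meto.n_sites} MetO vs {f_met.n_sites} control"
        )
    n = f_meto.n_sites
    a, b = f_meto.values, f_met.values
    var = (a * (1.0 - a) + b * (1.0 - b)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (a - b) / np.sqrt(var), np.nan)
    return ZMatrix(values=z, n=n)


def environment_analysis(
    proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
    sites: Sequence[SiteRecord],
    condition: str,
    subset_filter: Callable[[ProteinRecord], bool] | None = None,
    seed: int | np.random.Generator | None = None,
    alpha_band: float = DEFAULT_ALPHA_BAND,
    control_replace: bool = False,
) -> tuple[ZMatrix, EnvironmentReport, FrequencyMatrix, FrequencyMatrix]:
    """Full MetO-vs-control environment comparison for one condition.

    Sites reported in both conditions at the same protein position are
    excluded from either condition-specific run.  ``subset_filter``
    optionally restricts the analysis to proteins satisfying a predicate
    (e.g. ``lambda p: p.compartments[9] == 1`` for the cytosolic subset).
    """
    by_id = (
        dict(proteins)
        if isinstance(proteins, Mapping)
        else {p.id: p for p in proteins}
    )
    seen: dict[tuple[str, int], set[str]] = {}
    for s in sites:
        seen.setdefault((s.protein_id, s.position), set()).add(s.condition)
    shared = {key for key, conds in seen.items() if len(conds) > 1}

    per_protein: dict[str, list[int]] = {}
    n_dropped_shared = 0
    for s in sites:
        if s.condition != condition:
            continue
        if (s.protein_id, s.position) in shared:
            n_dropped_shared += 1
            continue
        prot = by_id[s.protein_id]
        if subset_filter is not None and not subset_filter(prot):
            continue
        per_protein.setdefault(s.protein_id, []).append(s.position)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meto_windows: list[str] = []
    control_windows: list[str] = []
    n_skipped = n_dropped_ineligible = 0
    n_proteins = 0
    for pid in sorted(per_protein):
        prot = by_id[pid]
        positions = sorted(set(per_protein[pid]))
        kept = eligible_sites(prot, positions)
        n_dropped_ineligible += len(positions) - len(kept)
        if not kept:
            continue
        controls = pick_controls(prot, kept, rng, replace=control_replace)
        if controls is None:
            n_skipped += 1
            logger.info("%s: more MetO sites than control Met, skipped", pid)
            continue
        n_proteins += 1
        meto_windows.extend(extract_window(prot.sequence, p) for p in kept)
        control_windows.extend(extract_window(prot.sequence, p) for p in controls)

    if not meto_windows:
        raise ValueError(f"no eligible {condition} sites to analyze")
    f_meto = frequency_matrix(meto_windows, condition, "MetO")
    f_met = frequency_matrix(control_windows, condition, "control")
    zm = z_matrix(f_meto, f_met)
    zm.alpha_band = alpha_band
    report = EnvironmentReport(
        condition=condition,
        n_sites=len(meto_windows),
        n_proteins=n_proteins,
        n_skipped_proteins=n_skipped,
        n_dropped_ineligible=n_dropped_ineligible,
        n_dropped_shared=n_dropped_shared,
        significant=zm.significant_cells(),
    )
    return zm, report, f_meto, f_met
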