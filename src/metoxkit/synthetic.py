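"""Seeded synthetic proteome generator with planted, recoverable effects.

Generates a proteome that mimics the statistical structure the downstream
analyses assume, so the whole pipeline can be exercised and calibrated
without any external downloads:

- two disjoint oxidized groups (default 1113 ex vivo / 503 in vitro) plus
  a never-oxidized background pool for resampling nulls;
- i.i.d. sequences from a human-like amino-acid composition, with an
  additive methionine-frequency boost in the oxidized groups;
- log-normal lengths (ex vivo longest) and log-normal ppm abundances
  (ex vivo least abundant);
- Bernoulli IDR flags, higher in oxidized groups;
- per-compartment membership probabilities biased toward the nucleus and
  mitochondrion ex vivo and the cytosol in vitro;
- GO terms assigned by group-specific functional "modules" (a module is a
  fixed block of terms; same-module proteins share most terms), which
  plants assortative mixing in the Jaccard similarity graph;
- MetO sites whose flanking windows are rewritten with per-position
  log-odds tilts (acidic enrichment in both conditions, aromatic/His
  depletion ex vivo only);
- co-regulated pairs with a configurable excess of pure ex-vivo pairs
  over the equiprobable expectation E[F].

One integer seed drives everything; per-table substreams are derived
deterministically from it, so identical configs give identical tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .coregulation import expected_pure_fraction
from .io import (
    AMINO_ACIDS,
    COMPARTMENTS,
    PairRecord,
    ProteinRecord,
    SiteRecord,
    write_pairs,
    write_proteins,
    write_sites,
)

logger = logging.getLogger(__name__)

#: Human-like background amino-acid composition (relative frequencies,
#: alphabetical one-letter order), normalized at use.
BACKGROUND_COMPOSITION = {
    "A": 0.0701, "C": 0.0230, "D": 0.0473, "E": 0.0710, "F": 0.0365,
    "G": 0.0658, "H": 0.0263, "I": 0.0434, "K": 0.0573, "L": 0.0996,
    "M": 0.0213, "N": 0.0359, "P": 0.0631, "Q": 0.0477, "R": 0.0564,
    "S": 0.0833, "T": 0.0535, "V": 0.0597, "W": 0.0122, "Y": 0.0266,
}

#: Per-compartment membership probabilities (p_ex_vivo, p_in_vitro).
#: Nucleus and mitochondrion favor the ex-vivo group; cytosol the in-vitro
#: group; the remaining compartments are unbiased at a modest baseline.
DEFAULT_COMPARTMENT_BIAS = {
    "Mit": (0.16, 0.02),
    "Nuc": (0.38, 0.07),
    "Lys": (0.04, 0.04),
    "ER": (0.08, 0.08),
    "Plm": (0.12, 0.12),
    "Gol": (0.05, 0.05),
    "End": (0.05, 0.05),
    "Ske": (0.07, 0.07),
    "Per": (0.02, 0.02),
    "Cyt": (0.22, 0.58),
}


def default_env_effects() -> dict[str, dict[str, dict[int, float]]]:
    """Per-condition, per-residue, per-offset log-odds tilts for MetO windows.

    Acidic residues (Glu, Asp) are boosted at offsets −2..+2 in both
    conditions; Tyr, Trp and His are penalized at offsets −3..+3 in the
    ex-vivo condition only.
    """
    acidic = {aa: {off: 0.9 for off in range(-2, 3) if off != 0} for aa in "ED"}
    aromatic = {aa: {off: -1.5 for off in range(-3, 4) if off != 0} for aa in "YWH"}
    return {
        "ex_vivo": {**acidic, **aromatic},
        "in_vitro": {**{k: dict(v) for k, v in acidic.items()}},
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic proteome; defaults are the study conditions.

    Group sizes default to 1113 ex vivo / 503 in vitro with a 3000-protein
    unoxidized background.  Lengths and abundances are log-normal with
    group-specific log-means; ``met_freq_boost`` is added to the background
    methionine frequency in oxidized groups (other residues renormalized).
    """

    n_ex_vivo: int = 1113
    n_in_vitro: int = 503
    n_background: int = 3000
    length_log_mean_ex: float = math.log(650.0)
    length_log_mean_vt: float = math.log(450.0)
    length_log_mean_bg: float = math.log(375.0)
    length_log_sd: float = 0.6
    met_freq_boost: float = 0.010
    abundance_log_mean_ex: float = math.log(5.0)
    abundance_log_mean_vt: float = math.log(25.0)
    abundance_log_mean_bg: float = math.log(10.0)
    abundance_log_sd: float = 1.5
    idr_prob_ox: float = 0.55
    idr_prob_bg: float = 0.30
    compartment_bias: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_BIAS)
    )
    go_pool_size: int = 400
    go_terms_per_protein: int = 10
    jaccard_within_boost: float = 0.9
    coreg_pair_count: int = 5530
    coreg_pure_ex_excess: float = 0.018
    sites_mean_ex: float = 1904 / 1113
    sites_mean_vt: float = 1994 / 503
    env_effect_sizes: dict[str, dict[str, dict[int, float]]] = field(
        default_factory=default_env_effects
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ex_vivo", "n_in_vitro", "n_background"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        probs = [
            self.idr_prob_ox,
            self.idr_prob_bg,
            self.jaccard_within_boost,
            *(p for pair in self.compartment_bias.values() for p in pair),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        comp = _normalized_composition()
        if not 0.0 <= comp["M"] + self.met_freq_boost <= 1.0:
            raise ValueError("met_freq_boost pushes Met frequency outside [0, 1]")
        if set(self.compartment_bias) != set(COMPARTMENTS):
            raise ValueError("compartment_bias must cover exactly the 10 compartments")
        ef = expected_pure_fraction(
            self.n_ex_vivo + self.n_in_vitro, self.n_ex_vivo
        )
        if not 0.0 <= ef + self.coreg_pure_ex_excess <= 1.0:
            raise ValueError("coreg_pure_ex_excess pushes pair probability out of [0,1]")
        if self.go_pool_size < self.go_terms_per_protein:
            raise ValueError("go_pool_size must be >= go_terms_per_protein")


def _normalized_composition() -> dict[str, float]:
    total = sum(BACKGROUND_COMPOSITION.values())
    return {aa: f / total for aa, f in BACKGROUND_COMPOSITION.items()}


def _group_composition(config: GeneratorConfig, oxidized: bool) -> np.ndarray:
    """Composition vector over AMINO_ACIDS; Met boosted in oxidized groups."""
    comp = _normalized_composition()
    p = np.array([comp[aa] for aa in AMINO_ACIDS])
    if oxidized and config.met_freq_boost:
        m = AMINO_ACIDS.index("M")
        boost = config.met_freq_boost
        scale = (1.0 - (p[m] + boost)) / (1.0 - p[m])
        p = p * scale
        p[m] = comp["M"] + boost
    return p / p.sum()


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # deterministic per-table substreams of one master seed
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def _draw_sequences(
    rng: np.random.Generator, lengths: np.ndarray, p: np.ndarray
) -> list[str]:
    codes = rng.choice(len(_AA_BYTES), size=int(lengths.sum()), p=p)
    raw = _AA_BYTES[codes].tobytes()
    out, start = [], 0
    for n in lengths:
        out.append(raw[start : start + int(n)].decode())
        start += int(n)
    return out


def generate_proteome(config: GeneratorConfig) -> list[ProteinRecord]:
    """Generate the full synthetic proteome (oxidized groups + background)."""
    rng = _rng(config, 0)
    records: list[ProteinRecord] = []
    group_specs = [
        ("ex_vivo", "EX", config.n_ex_vivo, config.length_log_mean_ex,
         config.abundance_log_mean_ex, True, 0),
        ("in_vitro", "VT", config.n_in_vitro, config.length_log_mean_vt,
         config.abundance_log_mean_vt, True, 1),
        ("background", "BG", config.n_background, config.length_log_mean_bg,
         config.abundance_log_mean_bg, False, 2),
    ]
    comp_probs = {
        name: np.array(config.compartment_bias[name]) for name in COMPARTMENTS
    }
    n_modules = config.go_pool_size // config.go_terms_per_protein
    shared_pool_size = 10 * config.go_pool_size

    for group, prefix, n, loglen, logabun, oxidized, gidx in group_specs:
        lengths = np.maximum(
            21, np.rint(rng.lognormal(loglen, config.length_log_sd, n))
        ).astype(int)
        p = _group_composition(config, oxidized)
        seqs = _draw_sequences(rng, lengths, p)
        abundances = rng.lognormal(logabun, config.abundance_log_sd, n)
        idr_p = config.idr_prob_ox if oxidized else config.idr_prob_bg
        idr = rng.random(n) < idr_p
        comp_matrix = np.empty((n, 10), dtype=int)
        for j, name in enumerate(COMPARTMENTS):
            p_ex, p_vt = comp_probs[name]
            prob = {0: p_ex, 1: p_vt, 2: 0.5 * (p_ex + p_vt)}[gidx]
            comp_matrix[:, j] = rng.random(n) < prob
        modules = rng.integers(0, n_modules, size=n)
        for i in range(n):
            base = modules[i] * config.go_terms_per_protein
            terms = []
            for t in range(config.go_terms_per_protein):
                if rng.random() < config.jaccard_within_boost:
                    terms.append(f"GO:{prefix}{base + t:06d}")
                else:
                    terms.append(f"GO:SH{rng.integers(0, shared_pool_size):06d}")
            records.append(
                ProteinRecord(
                    id=f"{prefix}{i:05d}",
                    sequence=seqs[i],
                    group=group,
                    abundance_ppm=float(abundances[i]),
                    idr=bool(idr[i]),
                    go_terms=frozenset(terms),
                    compartments=tuple(int(c) for c in comp_matrix[i]),
                )
            )
    return records


def _tilted_column(
    base: np.ndarray, effects: dict[str, dict[int, float]], offset: int
) -> np.ndarray:
    w = base.copy()
    for aa, per_offset in effects.items():
        if offset in per_offset:
            w[AMINO_ACIDS.index(aa)] *= math.exp(per_offset[offset])
    return w / w.sum()


def generate_sites(
    proteome: Sequence[ProteinRecord], config: GeneratorConfig
) -> list[SiteRecord]:
    """Choose MetO sites on oxidized proteins and rewrite their flanks.

    For each oxidized protein at least one site is chosen among its
    fully-windowed methionines (never position 1, and never so many that
    fewer non-oxidized methionines than sites would remain).  The ±10
    flanking residues of each chosen site are re-sampled from the
    background composition tilted by the per-position log-odds of the
    protein's condition; chosen central methionines are never overwritten.
    Sequences of the passed records are updated in place.
    """
    rng = _rng(config, 1)
    base = _normalized_composition()
    base_p = np.array([base[aa] for aa in AMINO_ACIDS])
    # per-condition, per-offset tilted sampling distributions
    col_probs = {
        cond: {
            off: _tilted_column(base_p, config.env_effect_sizes.get(cond, {}), off)
            for off in range(-10, 11)
            if off != 0
        }
        for cond in ("ex_vivo", "in_vitro")
    }
    sites: list[SiteRecord] = []
    for rec in proteome:
        if rec.group not in ("ex_vivo", "in_vitro"):
            continue
        seq = rec.sequence
        L = len(seq)
        eligible = [
            p for p in range(11, L - 9) if seq[p - 1] == "M"
        ]  # 1-based, full window, excludes position 1 by construction
        if not eligible:
            logger.warning("%s: no eligible Met residue, no site emitted", rec.id)
            continue
        mean = config.sites_mean_ex if rec.group == "ex_vivo" else config.sites_mean_vt
        want = 1 + rng.poisson(max(mean - 1.0, 0.0))
        n_sites = min(want, max(1, len(eligible) // 2))
        chosen = sorted(
            rng.choice(len(eligible), size=n_sites, replace=False).tolist()
        )
        positions = {eligible[i] for i in chosen}
        chars = list(seq)
        probs = col_probs[rec.group]
        for pos in sorted(positions):
            for off in range(-10, 11):
                if off == 0:
                    continue
                q = pos + off
                if q in positions:
                    continue
                w = probs[off]
                chars[q - 1] = AMINO_ACIDS[rng.choice(len(w), p=w)]
        rec.sequence = "".join(chars)
        for pos in sorted(positions):
            sites.append(SiteRecord(rec.id, pos, rec.group))
    return sites


def generate_coreg_pairs(
    proteome: Sequence[ProteinRecord], config: GeneratorConfig
) -> list[PairRecord]:
    """Sample distinct unordered co-regulated pairs over the oxidized universe.

    Each pair is pure ex vivo with probability E[F] + coreg_pure_ex_excess;
    otherwise it is mixed or pure in vitro in their equiprobable-null
    proportions.  No self-pairs, no duplicates.
    """
    ids_ex = [p.id for p in proteome if p.group == "ex_vivo"]
    ids_vt = [p.id for p in proteome if p.group == "in_vitro"]
    n_ex, n_vt = len(ids_ex), len(ids_vt)
    n = n_ex + n_vt
    if n_ex + n_vt < 2 or n_ex < 2:
        raise ValueError("need at least two oxidized proteins")
    max_pairs = n * (n - 1) // 2
    if config.coreg_pair_count > max_pairs:
        raise ValueError(
            f"coreg_pair_count {config.coreg_pair_count} exceeds the "
            f"{max_pairs} distinct pairs available"
        )
    p_pure = expected_pure_fraction(n, n_ex) + config.coreg_pure_ex_excess
    # conditional split of non-pure-ex pairs in their null proportions
    w_mixed = n_ex * n_vt
    w_vt = n_vt * (n_vt - 1) / 2
    p_mixed_given_not = w_mixed / (w_mixed + w_vt) if (w_mixed + w_vt) else 0.0

    rng = _rng(config, 2)
    seen: set[tuple[str, str]] = set()
    pairs: list[PairRecord] = []
    attempts = 0
    limit = 200 * config.coreg_pair_count + 10_000
    while len(pairs) < config.coreg_pair_count:
        attempts += 1
        if attempts > limit:
            raise RuntimeError("pair sampling failed to find enough distinct pairs")
        u = rng.random()
        if u < p_pure:
            i, j = rng.choice(n_ex, size=2, replace=False)
            a, b = ids_ex[i], ids_ex[j]
        elif rng.random() < p_mixed_given_not and n_vt:
            a = ids_ex[rng.integers(n_ex)]
            b = ids_vt[rng.integers(n_vt)]
        elif n_vt >= 2:
            i, j = rng.choice(n_vt, size=2, replace=False)
            a, b = ids_vt[i], ids_vt[j]
        else:
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(PairRecord(*key))
    return pairs


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[ProteinRecord], list[SiteRecord], list[PairRecord]]:
    """Full generation: proteome, MetO sites (with rewritten flanks), pairs."""
    proteome = generate_proteome(config)
    sites = generate_sites(proteome, config)
    pairs = generate_coreg_pairs(proteome, config)
    return proteome, sites, pairs


def write_dataset(
    config: GeneratorConfig,
    outdir: str | Path,
    fasta: bool = False,
) -> None:
    """Generate and write proteins.tsv, sites.tsv, pairs.tsv and config.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome, sites, pairs = generate_dataset(config)
    write_proteins(proteome, outdir / "proteins.tsv")
    write_sites(sites, outdir / "sites.tsv")
    write_pairs(pairs, outdir / "pairs.tsv")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
    if fasta:
        from .io import write_fasta

        write_fasta(proteome, outdir / "proteins.fasta")


def config_to_dict(config: GeneratorConfig) -> dict:
    d = {
        k: v
        for k, v in config.__dict__.items()
        if k not in ("compartment_bias", "env_effect_sizes")
    }
    d["compartment_bias"] = {k: list(v) for k, v in config.compartment_bias.items()}
    d["env_effect_sizes"] = {
        cond: {aa: {int(o): float(w) for o, w in per.items()} for aa, per in m.items()}
        for cond, m in config.env_effect_sizes.items()
    }
    return d


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["compartment_bias"] = {
        k: tuple(v) for k, v in raw.get("compartment_bias", {}).items()
    }
    return GeneratorConfig(**raw)


def null_config(**overrides) -> GeneratorConfig:
    """A configuration with every planted effect switched off.

    Useful for calibration: all groups share composition, lengths,
    abundances, IDR rates and compartment probabilities; GO modules still
    exist but group pools are left distinct; window tilts are zero and the
    co-regulation excess is zero.
    """
    base = GeneratorConfig(**overrides)
    flat_bias = {name: (0.15, 0.15) for name in COMPARTMENTS}
    defaults = dict(
        met_freq_boost=0.0,
        length_log_mean_ex=base.length_log_mean_bg,
        length_log_mean_vt=base.length_log_mean_bg,
        abundance_log_mean_ex=base.abundance_log_mean_bg,
        abundance_log_mean_vt=base.abundance_log_mean_bg,
        idr_prob_ox=base.idr_prob_bg,
        compartment_bias=flat_bias,
        coreg_pure_ex_excess=0.0,
        env_effect_sizes={"ex_vivo": {}, "in_vitro": {}},
    )
    defaults.update(overrides)
    return replace(base, **defaults)
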