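# Methods

This note documents the statistical procedures implemented in metoxkit,
the synthetic data model used to validate them, the defaults and the
numerical choices, in that order.

## Data model

A *protein record* carries an accession, an amino-acid sequence over the
20 standard letters (plus an optional unknown symbol `X`), an oxidation
group label (`ex_vivo`, `in_vitro`, `both`, `background`), an optional
ppm abundance, an optional IDR (intrinsically disordered region) flag, a
GO-term set, and a 10-dimensional 0/1 localization vector over
mitochondrion, nucleus, lysosome, ER, plasma membrane, Golgi, endosome,
cytoskeleton, peroxisome and cytosol (in that fixed column order).
A *site record* is a 1-based methionine position with a condition label;
position 1 (the initiator methionine) is always excluded. Comparative
analyses use the two *exclusive* sets A (ex vivo) and B (in vitro);
records labeled `both` are carried by the loader but belong to neither
set, because every contrast below is defined on the exclusive groups.
Missing abundance or IDR annotations are excluded per analysis, never
imputed, so composition statistics do not depend on annotation coverage.

## Resampling nulls for composition statistics

For a statistic T (mean/median Met frequency, mean/median length, IDR
fraction, mean abundance) of a set of size k, the null distribution is
built from `n_resamples` random samples of k distinct proteins drawn from
the whole proteome pool (oxidized + background). Sampling is without
replacement within a sample (a sample represents a set of distinct
proteins); a with-replacement switch exists for sensitivity analysis.
Empirical one-sided p-values use the (k+1)/(N+1) correction, so a value
more extreme than all N resamples reports p = 1/(N+1) rather than 0 —
with the conventional N = 100,000 this reads "p ≈ 10⁻⁵", consistent with
reporting "p < 10⁻⁴" when no resample is as extreme. Resamples are
generated by chunked partial permutation (argpartition of uniform keys),
which is exactly uniform over k-subsets and fast at proteome scale.

The abundance contrast between the two oxidized sets is a two-sided
Wilcoxon–Mann–Whitney test: exact enumeration when both sides have ≤ 50
observations and no ties, otherwise the normal approximation with tie
correction. The complementary cumulative distribution (fraction of
proteins with abundance ≥ x) is emitted as a plot-ready table.

## Localization clusters

Proteins are grouped by identical localization vectors (an equivalence
relation; 2¹⁰ = 1024 possible keys — an occasionally quoted count of 1025
miscounts the powerset of a 10-set). Clusters with at least 10 total
members (A ∪ B combined, not per group) are tested with a two-sided
Fisher exact test on the table
[[cluster∩A, cluster∩B], [A∖cluster, B∖cluster]], using the "sum of
hypergeometric probabilities ≤ observed" two-sided rule (the convention
of the standard implementations; a conditional-MLE odds ratio is
available, the default is the sample odds ratio). Flags use raw p < 0.005
as the decision rule; a Benjamini–Hochberg column is emitted for
reference but deliberately not used for flagging, so reports match the
raw-p convention of the comparative literature.

## GO-similarity network and assortativity

Protein i and j are connected iff Jaccard(GOᵢ, GOⱼ) ≥ 0.5 (inclusive).
Empty GO sets have similarity 0 with everything (never 0/0 = related) and
remain as isolated nodes. With two node types, each undirected edge
contributes both ordered ends to the mixing matrix e (making it
symmetric); with numeric labels {0,1} Newman's coefficient reduces to
r = (Σᵢeᵢᵢ − Σᵢaᵢ²)/(1 − Σᵢaᵢ²), which equals the Pearson correlation of
endpoint labels over the edge-end list. Both identities are asserted in
the tests against networkx and a brute-force Pearson oracle.

Two null models: (1) *relabeling* — topology fixed, labels permuted
preserving the group counts (an i.i.d. Bernoulli mode exists as an
option; count-preserving is the default because the companion null also
fixes counts). Note that a permutation null on a finite graph centers
slightly below zero (≈ −1/(n−1)), not exactly at 0. (2) *subsampling* —
from a graph over the full proteome, each iteration takes a random
induced subgraph with as many nodes as the labeled network and assigns
the group counts at random; this null centers at a slightly negative
value, since a randomly mixed finite network is marginally closer to
disassortative than assortative. Iterations with undefined r (all edge
ends one type, or no edges) are skipped and counted, never imputed.
Observed r is compared one-sided (p_upper).

## Co-regulated pairs

Pairs are unordered and deduplicated; the census keeps only pairs with
both members in A ∪ B and classifies them as pure ex vivo, mixed, or pure
in vitro. Under equiprobable pairs the expected pure ex-vivo fraction is
E[F] = N_vv(N_vv−1)/(N(N−1)). The null treats each of the n pairs as an
independent Bernoulli(E[F]) event — 100,000 Binomial(n, E[F]) draws — as
in the published procedure; the exact binomial upper tail is computed as
a closed-form cross-check, and a hypergeometric variant (sampling pairs
without replacement from the C(N,2) pair universe) is available for
sensitivity analysis. The comparison is one-sided, P[F ≥ observed].

## Site environments

Only methionines with ≥ 10 neighbors on both sides enter the analysis
(MetO *and* control sites — the same eligibility keeps the two frequency
matrices position-comparable). For each eligible MetO site one control is
drawn uniformly without replacement from the protein's eligible
non-oxidized methionines (a with-replacement option exists); proteins
with more MetO sites than candidate controls are skipped and counted, and
n is the post-skip MetO count. Sites oxidized in both conditions are
excluded from both condition-specific runs. Frequencies are tabulated per
residue per offset (−10..−1, +1..+10); windows contributing a nonstandard
residue at a position are excluded from that column's numerator and
denominator, so columns stay stochastic over the standard alphabet.
The standardized difference is
Z = (f^MetO − f^Met)/√((f^MetO(1−f^MetO)+f^Met(1−f^Met))/n); cells with a
zero denominator are flagged undefined (NaN). The significance band is
|Z| > 2.807, the two-sided 99.5% standard-normal band (exact quantile
2.8070). A subset predicate (e.g. cytosolic proteins only) restricts the
analysis for stratified runs.

## Synthetic data model

The generator's purpose is validation: every downstream analysis must
recover its planted effect at the default settings and stay calibrated
when the effect is switched off (`null_config`). Defaults encode the
study conditions: 1113 ex-vivo and 503 in-vitro proteins (disjoint — the
comparative analyses only use exclusive sets), 3000 background proteins
as the resampling pool, 5530 co-regulated pairs, and per-protein MetO
site counts of 1 + Poisson with means matching 1904/1113 (ex vivo) and
1994/503 (in vitro) sites per protein.

Values the study conditions do not fix were chosen once as realistic for
a human proteome and are not tuned: i.i.d. sequences from a human-like
composition (Met ≈ 0.021) with an additive Met boost of +0.01 in oxidized
groups; log-normal lengths (σ = 0.6) with medians 650 / 450 / 375
residues for ex vivo / in vitro / background, reproducing the direction
"ex vivo larger"; log-normal ppm abundances (σ = 1.5) with medians
5 / 25 / 10 ppm ("ex vivo less abundant"); IDR probabilities 0.55
(oxidized) vs 0.30 (background); compartment membership probabilities
favoring nucleus (0.38 vs 0.07) and mitochondrion (0.16 vs 0.02) in the
ex-vivo group and cytosol (0.22 vs 0.58) in the in-vitro group.

GO terms are assigned by *functional modules*: each group's term pool
(400 terms) is split into blocks of 10; a protein takes its module's
terms, each independently kept with probability 0.9 or replaced by a
random shared-pool term. Same-module proteins therefore share most terms
(Jaccard typically ≥ 0.5), modules are group-pure, and the resulting
similarity graph is strongly assortative — with disjoint group pools the
planted r is 1, an intentionally clean positive control. Background
proteins get their own modules so the proteome-wide graph used by the
subsampling null is non-trivial.

MetO flanking windows are rewritten by re-sampling each flank residue
from the background composition tilted by per-residue, per-offset
log-odds: +0.9 for Glu/Asp at offsets −2..+2 in both conditions, −1.5 for
Tyr/Trp/His at offsets −3..+3 ex vivo only. Chosen site methionines are
never overwritten. Co-regulated pairs are sampled so a pair is pure
ex vivo with probability E[F] + 0.018 (the default excess equals the
published observed−expected gap), with the remainder split between mixed
and pure in-vitro pairs in their equiprobable-null proportions.

What the generator does **not** emulate: real GO term hierarchies and
annotation depth, sequence correlations (residue order is i.i.d.),
mass-spectrometry detectability biases, annotation missingness, overlap
("both") proteins, and the heavy tail of real length distributions
(titin-scale outliers). Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated, not that any particular
biological effect size holds in real data.

## Numerical and design choices

- One integer seed drives the generator; per-table substreams are spawned
  deterministically, so equal configs give byte-identical tables.
- Empirical p-values are never 0 by construction ((k+1)/(N+1)).
- The Z statistic of the site-environment analysis is discrete (it is
  built from binomial counts), so at moderate n its distribution has
  atoms (e.g. at exactly 0); calibration checks therefore test the tail
  mass, the first two moments, and normality on a subsample, rather than
  a maximal-power KS test that any lattice distribution would fail.
- Degenerate inputs: empty sequences, all-missing abundance sides,
  zero-margin contingency tables, single-label graphs, proteins without
  eligible methionines and oversubscribed pair requests all raise or
  skip-and-count explicitly; nothing is silently coerced.
- Problem sizes in the test suite: full default-scale generation is run
  once per session (seed 1) for planted-effect recovery; calibration
  sweeps use reduced sizes (e.g. 150/60 proteins, 500–2,000 resamples,
  20–50 seeds) chosen so binomial/KS error bands, not runtime, set the
  sensitivity.

## Known limitations

- The subsampling null rebuilds induced subgraphs in a Python loop; at
  10,000 iterations on very dense proteome graphs it is the slowest step.
- Exact Wilcoxon enumeration is delegated to scipy and only used for
  small tie-free samples; with ties the tie-corrected normal
  approximation is reported even for small n.
- The generator plants assortativity via group-pure modules; it cannot
  produce intermediate target r values directly (only via the
  keep-probability), so tests assert significance, not a specific r.
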