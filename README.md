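# metoxkit

Tools for the comparative, protein- and site-centric characterization of
methionine sulfoxidation (MetO) in human proteins, contrasting oxidation
that happened **inside living cells** ("ex vivo": cells exposed to H₂O₂,
where methionine sulfoxide reductases are active) with oxidation of
**cell-free extracts** ("in vitro", where the back-reduction cannot occur).
It is aimed at redox-proteomics analysts who have site tables exported
from a MetO site database (with PaxDB abundances, DisProt disorder flags
and GO annotations) and want reproducible, permutation-calibrated answers
to the questions:

- Are the oxidized sets unusual in composition? Empirical null
  distributions are built by drawing many random same-sized samples from
  the proteome and recording mean/median methionine frequency, protein
  length, IDR fraction or mean ppm abundance; one-sided empirical
  p-values use the (k+1)/(N+1) correction. The ex-vivo / in-vitro
  abundance contrast uses a Wilcoxon–Mann–Whitney rank test and a
  complementary cumulative abundance distribution.
- Where do they live? Proteins are grouped into localization equivalence
  classes by their 10-compartment membership vector (Mit, Nuc, Lys, ER,
  Plm, Gol, End, Ske, Per, Cyt); every class with ≥ 10 members is tested
  for group preference with a two-sided Fisher exact test.
- Do they share functions? Two proteins are connected when the Jaccard
  similarity of their GO-term sets is ≥ 0.5; the assortative mixing of
  the red (ex vivo) / blue (in vitro) labels on this graph is Newman's
  coefficient
  `r = Σᵢⱼ i·j(eᵢⱼ − aᵢbⱼ) / (σₐσᵦ)`
  computed from the mixing matrix `eᵢⱼ` (fraction of edge ends joining
  type *i* to type *j*), with label-permutation and proteome-subsampling
  null models.
- Are ex-vivo proteins co-regulated? With `N` oxidized proteins (`N_vv`
  ex vivo), the expected fraction of pure ex-vivo pairs among equiprobable
  co-regulated pairs is `E[F] = N_vv(N_vv−1)/(N(N−1))`; the observed
  fraction is compared against 100,000 Binomial(n_pairs, E[F]) draws, with
  the exact binomial tail as a cross-check.
- What surrounds the oxidized methionine? For each MetO site with a full
  ±10-residue window, flanking residue frequencies are compared with
  randomly paired non-oxidized Met sites of the same proteins via
  `Z = (f^MetO − f^Met) / √((f^MetO(1−f^MetO) + f^Met(1−f^Met))/n)`,
  with |Z| > 2.807 marking the two-sided 99.5% band.

A seeded synthetic-proteome generator (`metoxkit.synthetic`) plants all
of these effects — Met enrichment, longer/less-abundant ex-vivo proteins,
nuclear/mitochondrial vs cytosolic localization biases, module-structured
GO annotations, excess pure ex-vivo pairs, acidic enrichment and
ex-vivo-only Tyr/Trp/His depletion around sites — so the full pipeline is
testable end to end without any downloads.

## Worked example

Generate a synthetic dataset at the default study conditions (1113
ex-vivo, 503 in-vitro, 3000 background proteins; 5530 co-regulated pairs)
and run the analyses:

```sh
$ metoxkit simulate --outdir demo --seed 1
$ metoxkit coregulation --proteins demo/proteins.tsv --pairs demo/pairs.tsv \
      --n-iter 100000 --seed 1
pairs=5530 pure_ex=2701 mixed=2289 pure_vt=540
E[F]=0.4742 observed F=0.4884 empirical p=0.01733 exact tail=0.01784
$ metoxkit network --proteins demo/proteins.tsv --n-iter 1000 --seed 1
nodes=1616 edges=16820 r=1.0000 null_mean=-0.0009 p_upper=0.000999 skipped=0
$ metoxkit composition --proteins demo/proteins.tsv \
      --statistic mean_met_freq --n-resamples 10000 --seed 1
mean_met_freq (ex_vivo): observed=0.0307173 p_upper=0.0001 p_lower=1
$ metoxkit environment --proteins demo/proteins.tsv --sites demo/sites.tsv \
      --condition ex_vivo --seed 1
ex_vivo: n_sites=1858 proteins=1109 skipped=3 significant cells=31
```

Reading the numbers: the sampled pairs contain a planted excess of pure
ex-vivo pairs (observed F = 0.488 vs E[F] = 0.474; the Monte-Carlo and
exact binomial tails agree, p ≈ 0.018); the GO graph is perfectly
assortative by construction (r = 1) while its label-permutation null
centers at ≈ 0, so no permutation reaches the observed value; the ex-vivo
set's mean methionine frequency (0.0307) exceeds every one of 10,000
background resamples; and the site-environment Z matrix flags 31 of 400
cells beyond |Z| = 2.807, driven by the planted acidic enrichment and
aromatic/His depletion. `metoxkit clusters` prints the per-cluster Fisher
report (the nucleus cluster is ~90% ex vivo, the cytosol cluster
in-vitro-leaning, matching the planted biases).

The same subcommands run unchanged on real exports that follow the TSV
schemas documented in `metoxkit/io.py` (`metoxkit validate` checks them).

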