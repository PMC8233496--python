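# chronotree

Relaxed-clock timetree inference for rooted phylogenies, as a Python
library and command-line tool. It is aimed at molecular evolutionists and
pathogen genomic epidemiologists who have a rooted tree with branch
lengths (substitutions/site) — with or without the alignment behind it —
and want node ages, confidence intervals, and the diagnostics that go with
them.

## What it does

- **Relative-rate dating.** From a rooted phylogram alone, estimate a
  relative rate for every lineage and a relative time t ∈ [0, 1] for every
  node, without assuming a molecular clock. At a node with children
  c₁…c_k, with d(c) the branch length plus mean rate-adjusted tip depth
  below c, local rates are r(c_j) = k·d(c_j)/Σd(c_i); lineage rates are
  products of local rates from the root, and adjusted heights
  h(i) = h(c) + b(c)/r(c) are identical through every child.
- **Node dating.** Convert relative to absolute times using calibration
  densities — normal(mean, sd), lognormal(offset, mean, sd),
  exponential(offset, decay), uniform(min, max) — or point/min/max bounds,
  or a fixed evolutionary rate. The scale factor f maximizes
  Σₖ log pₖ(f·tₖ) inside the feasible interval; Monte-Carlo CIs combine
  rate heterogeneity with fresh calibration draws.
- **Tip dating.** For serially sampled sequences, fit the clock
  D_j = μ(s_j − T0) on rate-adjusted root-to-tip depths (dates parsed from
  taxon names or a TSV), and date every node with CIs.
- **Rate-autocorrelation test.** A CorrScore in [0, 1] with a
  simulation-calibrated P-value for whether branch rates are inherited
  along the tree.
- **Neutral evolutionary probabilities (EP).** Per site, the posterior
  probability of each of the 4 (or 20) possible alleles in the focal
  (first) sequence given the other taxa and the timetree; EP < 0.05 flags
  nonneutral alleles.
- **Pattern-compressed likelihood.** Alignments collapse to their m ≤ L
  distinct site configurations; log L = Σ_p w_p log L_p with likelihoods
  by Felsenstein pruning under JC/HKY/Poisson (± discrete gamma), plus ML
  branch-length optimization on a fixed topology.
- **Simulator.** Yule timetrees, strict / independent-lognormal /
  autocorrelated branch rates, serial tip sampling and sequence evolution,
  with true parameters recorded — every estimator here has a recovery
  target.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Date the human–chimp split on a 3-taxon phylogram with a normal
calibration at 6.5 ± 0.5 Ma:

```sh
cat apes.nwk
# ((human:0.012,chimp:0.010):0.005,gorilla:0.018);
cat cal.txt
# mrca human chimp normal mean=6.5 sd=0.5
chronotree date --tree apes.nwk --calibrations cal.txt --outdir out --seed 7
cat out/timetree.tsv
```

```
node    span_a  span_b  rel_time        time    ci_lo   ci_hi   lineage_rate
n0      human   gorilla 1       9.454545455     6.936134512     13.10039936     1
n1      human   chimp   0.6875  6.5     5.505250006     7.5039412       0.9411764706
human   human   human   0       0       0       0       1.026737968
chimp   chimp   chimp   0       0       0       0       0.8556149733
gorilla gorilla gorilla 0       0       0       0       1.058823529
```

Reading it: the human–chimp node sits at relative time 0.6875, so pinning
it near 6.5 Ma dates the root (human–gorilla) at 9.45 Ma with a 95%
interval of 6.9–13.1 Ma; the chimp lineage evolved at ~0.86× the average
rate, the gorilla lineage at ~1.06×. `out/timetree.nwk` carries the same
numbers as `[&time=…,ci_lo=…,ci_hi=…]` annotations, and `manifest.json`
records inputs, parameters and seed; rerunning with the same seed
reproduces every output byte.

The other subcommands follow the same shape: `reltime` (relative times
only), `tipdate` (tip-date regression; prints μ and T0 at the top of its
table), `ep`, `corrtest`, `compress`, `patristic`, and `simulate`.
`--help` on any of them shows the options.

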