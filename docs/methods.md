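# Methods

This document specifies the analysis implemented by `pdxcna`: the data
model, each computational layer with its parameters and defaults, the
synthetic-data generator used for validation, and the numerical and
design decisions that shape the results.

## 1. Genome model and binning

The genome is represented as a fixed grid of non-overlapping bins
(default width 1 Mb), tiled from coordinate 0 to the end of each
chromosome. Arm membership (p/q) is assigned by the bin midpoint against
an arm table; bins whose midpoints fall inside the centromere gap are
unassigned and never contribute to arm calls. The package ships an hg19
autosome arm table (`pdxcna/data/hg19_arms.tsv`, UCSC centromere
boundaries); any arm table with columns `chromosome, start, end, arm`
can be substituted, and the simulator writes its own.

Segmented profiles (`sample_id, chromosome, start, end, value`, with
`value` the segmented log2 copy-number ratio) are projected onto the
grid. A bin covered by several segments takes the value of the segment
with the largest `|value|`; ties resolve to the segment with the
earliest start. Bins not covered by any segment are masked for that
sample. Coordinates are half-open 0-based by default; a
`one_based_inclusive` flag converts on read.

## 2. Threshold (relative) discordance

For a pair of samples with bin values `A` and `B`, a bin is discordant
when any of four symmetric clauses holds:

1. `A ≥ 0.3` and `B < 0.3`, and (`A − B ≥ 0.3` or `B < 0.1`)
2. `A ≤ −0.3` and `B > −0.3`, and (`A − B ≤ −0.3` or `B > −0.1`)
3. clause 1 with A and B swapped
4. clause 2 with A and B swapped

i.e. one sample carries a called gain (`≥ 0.3`) or loss (`≤ −0.3`) the
other lacks, and the disagreement is either large (gap ≥ 0.3) or the
other sample is effectively neutral (`|·| < 0.1`). The call is
antisymmetric: swapping the samples flips its direction, which the code
records as a per-bin status in {−1, 0, +1} (plus "not evaluable").

Pair-level quantities:

- **fraction discordant** — discordant bins / bins unmasked in *both*
  samples;
- **arm discordance** — an arm is discordant when ≥ 75% of its evaluable
  bins are discordant *in a uniform direction*; arms with fewer than 10
  evaluable bins are not assessed;
- **purity filter** — a sample fails when fewer than 5% of its unmasked
  bins carry `|value| ≥ 0.3` (flat profiles are uninformative, usually
  from low tumor content); pairs containing a failing sample are
  excluded unless the filter is disabled.

Constants: gain/loss threshold 0.3, gap threshold 0.3, near-neutral band
0.1, arm fraction 0.75, minimum arm bins 10, minimum altered fraction
0.05.

## 3. Integer copy-number discordance

When absolute integer copy-number calls with tumor ploidy are available,
a ploidy-normalized calculus is used instead:

- adjusted value `a = cn / ploidy × 2`; rounding is half-away-from-zero;
  a rounded value > 2 is a gain, < 2 a loss;
- subclonal events resolve by prevalence: > 0.9 treated as clonal,
  < 0.1 replaced by the neutral copy number `round(ploidy)`, and
  prevalence in [0.1, 0.9] excludes the bin from the comparison;
- a bin is discordant when exactly one sample shows a (rounded) gain or
  loss **and** the adjusted values differ by ≥ 0.5;
- sample inclusion requires tumor fraction ≥ 0.05 and ≥ 5% clonally
  altered bins;
- when a model's samples disagree on ploidy by more than 0.2, a rerun
  directive is emitted: the PT re-fit at the PDX ploidy; with two PDXs,
  the lower-tumor-fraction sample re-fit (ties to the higher ploidy);
  with more, re-fit at the modal rounded ploidy (ties broken by a
  seeded draw).

The calculus is invariant to jointly scaling `cn` and ploidy, which is
one of the acceptance checks.

## 4. Pairing, cohorts, and passage drift

Pairs are the cartesian product of PTs and PDXs within a model
(PT-PDX), plus unordered PDX-PDX pairs at unequal passages. Cohorts
(tumor types) with fewer than 5 pairs of a comparison type are dropped
from cohort-level summaries. PDX-PDX pairs stratify by passage
difference: low 1–2, intermediate 3–5, high ≥ 6; strata are compared
pairwise by two-sided Mann-Whitney U. Per PT, the earliest- and
latest-passage PDXs form a trio; PT-vs-late > PT-vs-early is tested by
one-sided Wilcoxon signed-rank. Cohort summaries report median, IQR,
Tukey whiskers and exceedance (1 − eCDF) on a 0.05 threshold grid, and
the Pearson correlation of PT copy-number burden with PT-PDX
discordance (skipped when either side is constant).

## 5. Gene projection and enrichment

Per-bin discordance prevalence (discordant pairs / evaluable pairs, per
bin) is projected to genes as the unweighted mean of the gene's
overlapping unmasked bins. A cohort's discordant gene set is the
intersection of the top 2.5% of genes by prevalence (ties at the cut
included) and genes with prevalence > 0.25. Enrichment of a gene set of
size `g` in a universe of `G` genes, with `x` of the `N` selected genes
in the set, is

```
ES = ln( (x/N) / (g/G) ),    p = P[X ≥ x],  X ~ Hypergeom(G, g, N)
```

computed with `scipy.stats.hypergeom.sf(x−1, G, g, N)`, with
`N` clipped to `G` and `x = 0` reported as `ES = −inf, p = 1`.
Benjamini-Hochberg q-values come from
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`. Genes
recurrently discordant (prevalence above threshold in ≥ 5 cohorts,
optionally restricted to a cancer-gene list) are reported separately.

## 6. Power analysis

For a recurrent arm event with PT prevalence `p0 > 0.25`, the number of
PT-PDX pairs needed to detect a decrease to `p = p0 − 0.1` with a
one-sided one-sample proportion test at `α = 0.05`, power `1 − β = 0.8`:

```
n = ceil( p0(1−p0) · ( (z_{1−α} + z_{1−β}·sqrt(p(1−p)/(p0(1−p0)))) / (p − p0) )² )
```

Worked values: `n(p0=0.50) = 153`, `n(p0=0.25+) = 103`. The formula is
validated against an independent oracle that numerically inverts the
exact normal-approximation power function; agreement is within ±1
across `p0 ∈ [0.15, 0.95]`. Note that `n` is **not** monotone in `p0`:
it tracks the binomial variance `p0(1−p0)` and peaks near `p0 ≈ 0.55`.

## 7. Synthetic-data generator

The simulator builds a compact genome (default 10 chromosomes × 100 Mb,
50 Mb per arm, 1 Mb bins → 1000 bins, 20 arms) and, per model, a PT
truth state plus a single PDX lineage that drifts one step per passage
(engraftment is step 0). Events are drawn on the bin lattice (so that a
clean observation recovers truth exactly): Poisson counts of shared
truncal events (rate 8) and private drift events (rate 1 per step),
each either a whole arm (probability 0.25) or a focal segment (3–20
Mb), gain `log2(1.5)` or loss `−1.0` in log space (copy number 3 or 1).
A fraction of events (default 0.1) is subclonal with prevalence drawn
from (0.05, 0.95).

Observation model per bin:

```
obs = log2( purity · 2^t_eff + (1 − purity) ) + Normal(0, noise_sd)
t_eff = log2( prev · 2^t + (1 − prev) )
```

with defaults PT purity 0.7, PDX purity 0.95, noise 0.05. Ploidy is the
mean truth copy number; tumor fraction equals purity. Randomness uses
`numpy.random.default_rng([seed, model_index])`, so models are
independent and the study is reproducible from one seed. The generator
exposes `GroundTruth`, which scores the planted `t_eff` states with an
independently transcribed copy of the discordance clauses, giving an
oracle for both bin fractions and arm calls.

Scope and limits: the generator plants lattice-aligned events on a
reduced genome — it exercises the calculus, binning, pairing and
statistics end to end, but does not model segmentation error, breakpoint
uncertainty, sex chromosomes, or focal events below bin resolution.

## 8. Validation and problem sizes

`tests/test_acceptance.py` holds the end-to-end criteria; the problem
sizes there are this package's own validation choices:

1. the vectorized discordance call equals a literal clause transcription
   on the full 201 × 201 grid over [−1, 1]² (step 0.01), including
   antisymmetry;
2. with purity 1 and no noise, pipeline discordance equals planted truth
   exactly (20 models); with purity 0.6 and noise 0.05, ≥ 95% of ≥ 200
   pairs are within 0.02 of truth;
3. arm-call boundaries: 75/100 uniform bins call, 74/100 and mixed
   directions do not;
4. strata medians order low < intermediate < high on a seeded drift
   study, and the trio signed-rank test detects planted divergence at
   n = 20 with p < 0.05;
5. `required_n` reproduces 153 and 103 and agrees with the numerical
   power oracle within ±1;
6. ES is 0 at proportionality and `ln 10` for (x, N, g, G) =
   (10, 100, 50, 5000); hypergeometric p-values equal exhaustive
   enumeration on small universes;
7. the integer calculus is invariant to joint cn/ploidy scaling, and
   the 0.5 adjusted-gap boundary behaves as specified.

`scripts/acceptance.py --seed S --out f.json` reruns the same study
from a single seed and writes the headline quantities.

## 9. Design decisions

- Established libraries are used for standard numerics: scipy for
  Mann-Whitney, Wilcoxon, Pearson, hypergeometric and normal quantiles;
  statsmodels for Benjamini-Hochberg. The discordance calculi are
  implemented directly because those definitions *are* the method.
- The fourth discordance clause is the loss-mirror of clause 3
  (`A > −0.1` as the near-neutral condition), completing the symmetry
  of the clause family; antisymmetry of the resulting call is tested
  exhaustively.
- Bin assignment prefers the larger-|value| segment so that focal
  events are not diluted by flanking neutral segments sharing a bin.
- All tables are written as TSV with fixed column orders and a JSON
  manifest, so runs diff cleanly; the pipeline is deterministic given
  its seed.

## 10. Limitations

- The relative calculus compares log-ratio profiles without explicit
  purity/ploidy correction; severe purity differences can masquerade as
  discordance, which is why the low-purity filter exists and why the
  integer calculus is preferred when absolute calls are available.
- Arm calls require ≥ 10 evaluable bins, so heavily masked arms are
  silently unassessed.
- Power analysis assumes the normal approximation to the binomial and a
  fixed 10-point absolute decrease.
- The simulator validates the software, not biology: its event rates
  and effect sizes are stylized, and real segmentation noise is not
  modeled.
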