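# Methods

## The experimental design being modelled

A short-term mutation-accumulation (MA) experiment: two founders (F0)
produce one large F1 clutch; 190 F1 siblings are pooled and sequenced deeply
so that their allele frequencies stand in for the parental genotypes; pairs
of the remaining F1 siblings found MA lines that are propagated by full-sib
matings, one clutch per generation, for five generations; one F5 individual
per line is genome-sequenced.  A de novo mutation (DNM) is a variant present
in exactly one line and absent from the pool.  With ten lines this yields
mutation counts large enough for a direct rate estimate after only five
generations, in a species where parentage cannot be assigned individually.

## DNM identification

Candidates pass three independent stages, in order:

1. **Uniqueness** — the (scaffold, position, ref, alt) key must occur in
   exactly one line's call set and not in the pool's own (tetraploid-style)
   call set.  Two different alternative alleles at one site in one line are
   two candidates; if both are accepted the site is flagged multi-allelic.
2. **Hard quality filters** — GQ strictly above 90; SOR ≤ 4; absolute
   ref/alt length difference ≤ 2; depth within [15, 44] (the upper bound
   guards against collapsed paralogs); alternative allele count ≥ 5.  The
   predicates are pure and order-free; a record missing an annotation fails
   with a `missing:FIELD` reason code rather than being dropped silently.
   Threshold readings ("above 90" strict, depth bounds inclusive, any
   SOR > 4 removed) are recorded in `FilterThresholds` and overridable.
3. **Pool screen** — a single pool read supporting the alternative allele
   removes the candidate (`pool_alt_max = 0`); the tolerance is exposed
   because very deep pools may carry sequencing-error reads.  A candidate
   whose position is missing from the pool table is routed to a
   machine-readable review flag — the programmatic stand-in for manual
   browser curation — and is excluded from rate totals by default.

**Callable sites** (the exposure denominator) are positions where the line's
depth lies in [15, 44] *and* the pool depth is at least 15, so that the pool
screen could have been performed there.  The pool-depth condition is an
assumption of this package (the criterion is not fully specified in the
literature the design follows) and can be switched off
(`require_pool_depth_for_callable=False`).

2-bp indels survive the filter chain (the length cap is 2) but are excluded
from "single-base mutation" totals used for rates.

## Rate estimation

The direct estimator is μ = m / (C · G · k), with m accepted single-base
mutations, C summed callable sites, G generations and k the ploidy factor.
Two conventions coexist and are labelled in all outputs: per-line table
rates use k = 1 (mutations per diploid genome per generation, matching how
per-line tables are usually printed), headline rates use k = 2 (per haploid
genome, the convention for cross-species comparison).

The total count is modelled as Poisson with mean μ·E.  The primary 95% CI is
the exact **Garwood interval**, [½·Q<sub>χ²</sub>(α/2, 2m),
½·Q<sub>χ²</sub>(1−α/2, 2m+2)]/E, with a zero lower bound at m = 0; its
coverage is verified by simulation at λE ∈ {2, 5, 26} (≥ 94% at nominal
95%).  A Wald interval on the per-line mean count (λ̂ ± z·√(λ̂/n)) is
available behind a flag for comparison with legacy analyses; it is
asymptotic and anti-conservative at small counts.  Effective population size
is N<sub>e</sub> = θ/4μ.  Rates are reported at three significant digits;
internal arithmetic is double precision throughout (the quantities involved
are far from the precision floor).

## Mutational spectrum and homopolymer runs

Transitions are A↔G and C↔T; the Ts/Tv ratio counts every accepted
alternative allele separately.  Directional bias (GC→AT vs AT→GC) and
insertion/deletion asymmetry use the equal-expectation one-degree χ²
goodness of fit without continuity correction, unadjusted for multiple
testing (single planned tests).

Maximal monomer runs are counted per scaffold (runs never span scaffolds;
non-ACGT characters break runs and are reported as masked).  Under iid base
draws with per-base probability p, E[maximal runs of length L] =
N·p^L·(1−p)²; edge effects (N−L+1 ≈ N, unterminated boundary runs) are
ignored, which at the genome sizes used is far below counting noise.  CpG
"runs" are maximal forward-strand tandem repeats of the CG dinucleotide
(reverse-complement counting is off by default; the convention is
strand-silent in the field), with E[(CG)ₖ repeats] replacing p by
p_C·p_G.  The expected A/T : G/C run-count ratio at length L follows by
taking within-class bases as equifrequent.

A candidate's **run context** is the longest maximal run overlapping the
affected bases extended by ±1 bp — the breakpoint of a homopolymer indel is
ambiguous, so a run immediately adjacent to the anchored position is still
its mutational context.  Indel/run association is an exact binomial test of
the in-run indel fraction against the genomic fraction of run positions;
per-run-length rates divide indel counts by (runs of length L × generations
× lines × ploidy), and the length trend is summarised by Spearman's rank
correlation.  Genic overlap is an exact binomial test against the supplied
gene-space fraction.

## Pedigree probabilities

A DNM arises heterozygously on a single gamete.  Conditional on origin
generation g, the sequenced F5 individual's carrier state is computed by
seeded Monte Carlo over the full-sib chain: the generation-g breeding pair
starts as (het, non-carrier); each next pair is two independent offspring;
the sequenced individual is one offspring of the final pair.  Reported per
g: P(present), and P(het)/P(hom) conditional on presence, with binomial
Monte-Carlo standard errors.  A mutation arising in the final transmission
cannot be homozygous (P_hom(G) = 0 exactly), and P_hom decreases with later
origin.  The test suite checks the Monte Carlo against an exact
dynamic-programming solution of the same chain (9-state ordered
pair-genotype distribution).

Confirmation design: with one heterozygous carrier parent, at least one of
n Sanger-sequenced full siblings carries the mutation with probability
1 − 2⁻ⁿ (0.999023 at n = 10; computed in exact rational arithmetic).  Under
a uniform prior over origin generation, mutations arising in the final
generation exist only in the sequenced individual, so the expected
confirmable fraction is 1 − 1/G (80% at G = 5; 7.2 of 36 assayed candidates
expected unconfirmable).  The observed homozygote count among confirmed
mutations is compared with the presence-weighted model expectation by a
one-df χ², with the Monte-Carlo uncertainty of the expectation propagated.

## The synthetic-data generator

`simdata` emulates the products of an upstream read-mapping/genotyping
pipeline, not reads themselves (no FASTQ, mapping artifacts or base-quality
modelling — that is out of scope by design).

* **Genome**: iid draws over {A,C,G,T}; the default composition is 69% A+T,
  equifrequent within class.  iid genomes reproduce the run-length law above
  but not the long-range repeat structure of real assemblies; conclusions
  about paralog mismapping therefore cannot be drawn from these fixtures.
* **Pedigree**: explicit haplotype-transmission graph of the full design
  (founders, F1 clutch including the pool members, per-line full-sib chains
  with a random breeding pair per clutch, sequenced F5 individual plus
  confirmation siblings).  A single sire per clutch is assumed — the
  simplest chain consistent with the design; multi-sire swarm breeding is
  deliberately not modelled (a config extension point).  Clutch size
  defaults to 30 reared offspring (real clutches hold hundreds of eggs; 30
  is ample for breeder choice plus 10 confirmation siblings and keeps the
  graph small).  Line extinction and back-up lines are out of scope.
* **Mutation injection**: per line, generation and each of the two gamete
  chains feeding the sequenced F5 individual, the number of new mutations
  per class is Poisson(rate × haploid genome length) — exactly the exposure
  convention (callable × G × 2) used by the estimator, so parameter-recovery
  tests are calibrated.  Two modelling simplifications are deliberate:
  (i) the generator works in the **infinite-sites regime** — every mutation
  hits a distinct site genome-wide; at desk-scale rates (1e-5 per site) the
  same variant would otherwise recur across lines by birthday collision and
  be (correctly) removed by the uniqueness filter, which no realistic
  rate × genome combination produces; (ii) **inbreeding coalescence of the
  two F5 haplotype ancestries is not modelled in the injection step** — under
  sib mating the two lineages share ancestors with appreciable probability,
  which would shrink the number of distinct observable mutations by roughly
  10–15% over five generations.  The direct estimator's exposure convention
  makes the same simplification, so the generator matches the model the
  estimator assumes; zygosity dynamics are handled separately in
  `pedigree`.  Consequently all rendered true variants are heterozygous.
* **Spectrum defaults**: transition probability κ/(κ+1) with κ = 15/11
  (the observed Ts:Tv split of the motivating experiment); indel length 1
  with probability 0.95, else 2 ("single-base" events dominate); inserted
  bases duplicate the neighbouring base (polymerase slippage); indel
  positions are weighted by `run_affinity` inside monomer runs ≥ 5 — the
  default 140 makes ~84% of indels fall in such runs on a 69% AT genome
  (21 of 25 observed in-run), since run positions are only ~3.5% of that
  genome: solving a·f/(a·f + 1 − f) = 21/25 with f = 2·p⁵(5−4p), p = 0.345
  gives a ≈ 140.  `run_affinity` may also be a callable length → weight for
  experiments with length-dependent slippage.
* **Rendering**: depth is piecewise-constant per 500-bp block (Poisson
  around the target coverage when `error_rate > 0`, constant otherwise) —
  real coverage is autocorrelated, and block tracks keep BED outputs
  compact.  With `error_rate = 0` the rendering is fully deterministic
  (alt count = depth/2, GQ 99, SOR 1) and the filter chain must return the
  truth set exactly; with noise, true variants can fall outside the callable
  depth range or below the allele-count minimum, and every such loss is
  attributable in the attrition report.  Contamination channels:
  `fp_shared` (founder standing variation: ≥ 2 lines + pool, expected pool
  frequency 1/4), `fp_error` (low-GQ or low-allele-count singletons), and
  `fp_pool_low` (singletons with 1–4 supporting pool reads, below the pool's
  own calling threshold — removable only by the read-level screen).  The
  truth/contaminant channels exist solely for test oracles.

All randomness flows from explicit seeds through named numpy generators; no
global state.  Identical seeds give byte-identical fixtures and reports.

## Problem sizes used by the test suite

Simulation-based checks run at desk scale, chosen to give tight statistical
bands while keeping the suite fast: 1-Mb genomes for identity/spectrum
checks, twenty 5-Mb replicates at μ = 1e-5 for parameter recovery (the
Garwood CI covers truth in ≥ 18/20 seeds), 2,000 replicates per λ for CI
coverage, and 1e5–2e5 Monte-Carlo replicates for pedigree probabilities.
Statistical invariants tested over many simultaneous bins (the run-length
law across 48 base × length bins per composition) use Šidák-corrected
per-bin bands so the family-wise level matches the intended 3σ tail.

## Known limitations

* The generator does not emulate paralog mismapping, PCR artifacts that
  survive duplicate marking, or mapping bias — the false-positive classes it
  plants are idealised stand-ins with known removal stages; passing tests
  show the filter logic is correct, not that real-data contamination is
  fully captured.
* The uniform-origin prior treats observed mutations as equally likely to
  have arisen in any generation.  Under the full sib-mating model earlier
  mutations are less likely to survive to the sequenced individual, so the
  confirmable-fraction arithmetic (1 − 1/G) is the design expectation under
  that stated assumption, not an exact posterior quantity.
* Wald intervals are provided for comparability only; the Garwood interval
  is the supported method.
* Review-flagged candidates are excluded from rates by default; there is no
  model of what fraction of flagged candidates would survive curation.
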