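# mutlines

Analysis toolkit for **short-term mutation-accumulation (MA) experiments**
that estimate the spontaneous mutation rate of a species directly, by deep
sequencing one individual per MA line and screening candidate de novo
mutations (DNMs) against a large pool of F1 full siblings whose allele
frequencies mirror the unknown parental genotypes.  The design suits
organisms (such as the harlequin fly *Chironomus riparius*) where individual
parentage cannot be determined because of swarm breeding, so classical
parent–offspring trios are impossible and long-term inbred MA panels are
impractical.

The package provides, as both a library and a `mutlines` command line:

* **`simdata`** — a synthetic-experiment generator: iid genomes with
  configurable base composition (default 69% A+T), full-sib pedigrees
  (10 lines × 5 generations founded from one F1 clutch, a 190-individual F1
  pool), germline SNMs and 1–2 bp indels injected per gamete per generation
  with a configurable homopolymer-run affinity, and rendered call sets with
  planted contamination and a hidden truth channel.
* **`dnmcall`** — the DNM filter chain: per-line uniqueness against all other
  lines and the pool call set; hard quality filters (GQ > 90, SOR ≤ 4,
  indel length ≤ 2, depth 15–44, alternative allele count ≥ 5); a read-level
  pool screen (any supporting pool read removes a candidate); callable-site
  accounting; and classification (SNM/INS/DEL, Ts/Tv, GC↔AT direction,
  run context) with a per-stage attrition report.
* **`rates`** — direct rate estimation μ = m / (callable sites × generations
  × ploidy factor) with exact Garwood 95% confidence intervals
  ½·χ²(α/2, 2m) ≤ λ ≤ ½·χ²(1−α/2, 2m+2) on the Poisson count, a Wald
  alternative, and N<sub>e</sub> = θ/4μ.
* **`spectrum`** — Ts/Tv ratio, equal-expectation χ² tests (GC↔AT and
  insertion/deletion bias), maximal-run decomposition of a genome, the iid
  expectation E[runs of length L] = N·p^L·(1−p)², per-run-length indel
  rates, and exact binomial run-enrichment and genic-overlap tests.
* **`pedigree`** — Monte-Carlo transmission probabilities over the full-sib
  chain (presence and zygosity of a mutation in the sequenced F5 individual
  by origin generation), sibling-confirmation probabilities
  (1 − 2⁻ⁿ for one heterozygous carrier parent), and the expected
  confirmable fraction 1 − 1/G under a uniform origin prior.
* **`report`** — one-command orchestration of
  simulate → call → estimate → spectrum → pedigree with byte-reproducible
  outputs, plus a **counts-only mode** that turns a published per-line count
  table into rate estimates without any sequence data.

## Worked example: rates from a published count table

The package ships the per-line counts of a ten-line, five-generation MA
experiment (`mutlines/data/example_counts.tsv`; 51 single-base mutations —
26 SNMs, 8 insertions, 17 deletions — over 1,229,187,450 callable sites).

```sh
mutlines report-counts --counts src/mutlines/data/example_counts.tsv \
    --generations 5 --ts 15 --tv 11
```

prints (abridged):

```json
{
  "per_line_mu_diploid": {"A1": 1.23e-08, "A2": 6.34e-09, "...": "..."},
  "rates": {
    "SNM":     {"count": 26, "rate": 2.115e-09, "ci_low": 1.382e-09, "ci_high": 3.099e-09},
    "overall": {"count": 51, "rate": 4.149e-09, "ci_low": 3.089e-09, "ci_high": 5.455e-09},
    "INS":     {"count": 8,  "rate": 6.508e-10, "ci_low": 2.810e-10, "ci_high": 1.282e-09},
    "DEL":     {"count": 17, "rate": 1.383e-09, "ci_low": 8.057e-10, "ci_high": 2.214e-09}
  },
  "ts_tv": {"ratio": 1.36, "ts": 15, "tv": 11},
  "ins_del_bias": {"chi2": 3.24, "p": 0.0719, "observed": [8, 17]}
}
```

Reading the output: the haploid SNM rate is 2.12 × 10⁻⁹ per site per
generation (95% CI 1.4–3.1 × 10⁻⁹; the total exposure is callable sites ×
5 generations × 2 haploid genomes), the overall single-base rate is
4.15 × 10⁻⁹, and deletions outnumber insertions 17:8 (χ² = 3.24, P = 0.07).
Per-line rates (`per_line_mu_diploid`) divide by callable × generations only,
i.e. they are diploid-genome rates — both conventions are labelled
explicitly.

A full simulated run (synthetic genome → injected truth → rendered calls →
filter chain → estimates, with a consolidated `summary.json`):

```sh
mutlines -v report --config my_run.yaml
```

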