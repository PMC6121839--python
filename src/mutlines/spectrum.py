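"""Mutational-spectrum statistics and homopolymer-run models.

Covers the descriptive spectrum of an MA experiment (Ts/Tv ratio, GC<->AT
directional bias, insertion/deletion asymmetry, genic overlap) and a simple
iid base-composition model for monomer and CpG runs.  Under iid draws with
per-base probability p, the expected number of *maximal* runs of a base with
length exactly L in a genome of N positions is

    E[runs of length L] = N * p^L * (1 - p)^2

(edge effects at sequence ends are ignored, N - L + 1 ~ N), so the expected
density per Mb is 1e6 * p^L * (1-p)^2.  The CpG analogue replaces p by
p_C * p_G per dinucleotide repeat unit.  These closed forms are the reference
against which observed run counts on simulated genomes are checked, and the
basis for the expected A/T : G/C run-count ratio as a function of AT content.

Indel/run association is quantified with an exact binomial test of the
observed in-run indel fraction against the genomic fraction of run positions,
and per-run-length indel rates with a Spearman trend statistic.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dnmcall import MutationRecord
from .simdata import BaseComposition, Genome

__all__ = [
    "RunSpectrum",
    "SpectrumTestResult",
    "RunTrend",
    "ts_tv_ratio",
    "ts_tv_from_counts",
    "gof_equal_chi2",
    "count_runs",
    "expected_run_density",
    "at_gc_run_ratio",
    "run_length_mutation_rate",
    "run_enrichment_test",
    "genic_overlap",
]

_CPG = re.compile(r"(?:CG)+")
_NON_ACGT = re.compile(r"[^ACGT]+")


@dataclass(frozen=True)
class SpectrumTestResult:
    statistic: float
    df: int | None
    p_value: float
    observed: tuple
    expected: tuple

    def __post_init__(self) -> None:
        if self.statistic < 0 or not 0.0 <= self.p_value <= 1.0:
            raise ValueError("invalid test result")


@dataclass(frozen=True)
class RunTrend:
    """Spearman rank correlation of per-run-length rates against length."""

    rho: float
    p_value: float


@dataclass
class RunSpectrum:
    """Counts of maximal monomer (and CpG) runs per class and length."""

    genome_length: int
    counts: dict[str, Counter]  # class ("A".."T", "CpG") -> {length: count}
    masked_positions: int = 0
    composition: BaseComposition | None = None

    CLASS_MEMBERS = {"AT": ("A", "T"), "GC": ("G", "C")}

    def class_counter(self, cls: str) -> Counter:
        if cls in self.counts:
            return self.counts[cls]
        members = self.CLASS_MEMBERS[cls]
        agg: Counter = Counter()
        for m in members:
            agg.update(self.counts.get(m, Counter()))
        return agg

    def runs_of_length(self, cls: str, length: int) -> int:
        return self.class_counter(cls)[length]

    def runs_at_least(self, cls: str, min_len: int) -> int:
        return sum(n for L, n in self.class_counter(cls).items() if L >= min_len)

    def sites_in_runs(self, cls: str, min_len: int) -> int:
        """Total genome positions inside runs of the class with length >= min_len."""
        return sum(
            L * n for L, n in self.class_counter(cls).items() if L >= min_len
        )


def ts_tv_from_counts(ts: int, tv: int) -> tuple[float | None, int, int]:
    """Ts/Tv ratio at 3 significant digits; None when Tv is zero."""
    if ts + tv < 1:
        raise ValueError("need at least one SNM")
    from .rates import round_sig

    ratio = round_sig(ts / tv, 3) if tv > 0 else None
    return ratio, ts, tv


def ts_tv_ratio(mutations: Sequence[MutationRecord]) -> tuple[float | None, int, int]:
    """Ts/Tv over accepted SNMs; each alternative allele counts separately."""
    ts = sum(m.ts_tv == "Ts" for m in mutations if m.mtype == "SNM")
    tv = sum(m.ts_tv == "Tv" for m in mutations if m.mtype == "SNM")
    return ts_tv_from_counts(ts, tv)


def gof_equal_chi2(n1: int, n2: int) -> SpectrumTestResult:
    """1-df goodness of fit of two counts against equal expectation.

    chi2 = sum (O - E)^2 / E with E = (n1 + n2) / 2, no continuity
    correction; p from the chi-square survival function.
    """
    if n1 < 0 or n2 < 0 or n1 + n2 == 0:
        raise ValueError("counts must be >= 0 with positive total")
    expected = (n1 + n2) / 2.0
    chi2, p = stats.chisquare([n1, n2], f_exp=[expected, expected])
    return SpectrumTestResult(
        statistic=float(chi2), df=1, p_value=float(p),
        observed=(n1, n2), expected=(expected, expected),
    )


def count_runs(genome: Genome, min_len: int = 1) -> RunSpectrum:
    """Maximal-run decomposition of every scaffold.

    Runs never span scaffolds.  Non-ACGT characters break runs; the affected
    positions are excluded and reported in ``masked_positions``.  CpG runs
    are maximal tandem repeats of the CG dinucleotide on the forward strand,
    counted in repeat units.
    """
    counts: dict[str, Counter] = {b: Counter() for b in "ACGT"}
    counts["CpG"] = Counter()
    masked = 0
    total = 0
    for seq in genome.scaffolds.values():
        seq = seq.upper()
        total += len(seq)
        masked += sum(len(m.group()) for m in _NON_ACGT.finditer(seq))
        for segment in _NON_ACGT.split(seq):
            if not segment:
                continue
            arr = np.frombuffer(segment.encode("ascii"), dtype=np.uint8)
            change = np.flatnonzero(arr[1:] != arr[:-1])
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [arr.size]])
            lengths = ends - starts
            bases = arr[starts]
            for code, base in zip(b"ACGT", "ACGT"):
                for L, n in zip(*np.unique(lengths[bases == code],
                                           return_counts=True)):
                    if L >= min_len:
                        counts[base][int(L)] += int(n)
            for m in _CPG.finditer(segment):
                counts["CpG"][len(m.group()) // 2] += 1
    comp = None
    if masked == 0 and total > 0:
        base_totals = {
            b: sum(L * n for L, n in counts[b].items()) for b in "ACGT"
        }
        comp = BaseComposition(*(base_totals[b] / total for b in "ACGT"))
    return RunSpectrum(
        genome_length=total, counts=counts, masked_positions=masked,
        composition=comp,
    )


def expected_run_density(
    composition: BaseComposition, cls: str, length: int
) -> float:
    """Expected maximal runs per Mb of length exactly ``length``.

    ``cls`` is a single base, an aggregate class ("AT", "GC") whose member
    bases' expectations are summed, or "CpG" (repeat units of the CG
    dinucleotide).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if cls == "CpG":
        p = composition.p_c * composition.p_g
        return 1e6 * p**length * (1 - p) ** 2
    members = RunSpectrum.CLASS_MEMBERS.get(cls, (cls,))
    dens = 0.0
    for b in members:
        p = composition.prob(b)
        dens += 1e6 * p**length * (1 - p) ** 2
    return dens


def at_gc_run_ratio(at_content: float, length: int) -> float:
    """Expected A/T : G/C maximal-run count ratio at a given run length.

    Assumes equifrequent bases within each class, so the per-class factor 2
    cancels: ratio = [(a/2)^L (1-a/2)^2] / [(g/2)^L (1-g/2)^2] with
    a = AT content and g = 1 - a.
    """
    if not 0.0 < at_content < 1.0:
        raise ValueError("at_content must lie strictly between 0 and 1")
    a = at_content / 2.0
    g = (1.0 - at_content) / 2.0
    return (a / g) ** length * ((1 - a) / (1 - g)) ** 2


def run_length_mutation_rate(
    mutations: Sequence[MutationRecord],
    run_spectrum: RunSpectrum,
    generations: int,
    n_lines: int,
    ploidy_factor: int = 2,
    cls: str = "AT",
    lengths: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, "RunTrend"]:
    """Per-run-length indel rates and a monotone-trend statistic.

    For each run length L the rate is (# indels whose run context has length
    L) / (# genomic runs of length L x generations x lines x ploidy factor),
    i.e. mutations per run site per generation.  Lengths with zero genomic
    runs yield an undefined (NaN) rate and are flagged.  The trend across L
    is summarised by Spearman's rank correlation of rate against L.
    """
    indels = [m for m in mutations if m.mtype in ("INS", "DEL")]
    counter = run_spectrum.class_counter(cls)
    if lengths is None:
        max_ctx = max((m.run_context_length for m in indels), default=0)
        max_run = max(counter, default=0)
        lengths = range(1, max(max_ctx, max_run) + 1)
    ctx = Counter(m.run_context_length for m in indels)
    rows = []
    for L in lengths:
        n_runs = counter.get(L, 0)
        n_mut = ctx.get(L, 0)
        rate = (
            n_mut / (n_runs * generations * n_lines * ploidy_factor)
            if n_runs > 0
            else float("nan")
        )
        rows.append({"run_length": L, "n_runs": n_runs, "n_indels": n_mut,
                     "rate": rate, "undefined": n_runs == 0})
    df = pd.DataFrame(rows)
    defined = df[~df["undefined"]]
    if len(defined) >= 3 and defined["rate"].nunique() > 1:
        rho, p = stats.spearmanr(defined["run_length"], defined["rate"])
        rho = float(rho) if rho == rho else 0.0
        p = float(p) if p == p else 1.0
    else:
        rho, p = 0.0, 1.0
    return df, RunTrend(rho=rho, p_value=p)


def run_enrichment_test(
    mutations: Sequence[MutationRecord],
    run_spectrum: RunSpectrum,
    min_len: int = 5,
    cls: str = "AT",
    alternative: str = "two-sided",
) -> SpectrumTestResult:
    """Exact binomial test of indels inside runs vs. the genomic run fraction.

    The null success probability is the fraction of genome positions lying
    inside runs of the class with length >= ``min_len``; a mutation counts as
    in-run when its recorded run context reaches ``min_len``.
    """
    indels = [m for m in mutations if m.mtype in ("INS", "DEL")]
    if not indels:
        raise ValueError("zero indels")
    frac = run_spectrum.sites_in_runs(cls, min_len) / run_spectrum.genome_length
    in_run = sum(m.run_context_length >= min_len for m in indels)
    res = stats.binomtest(in_run, len(indels), frac, alternative=alternative)
    return SpectrumTestResult(
        statistic=float(in_run), df=None, p_value=float(res.pvalue),
        observed=(in_run, len(indels) - in_run),
        expected=(len(indels) * frac, len(indels) * (1 - frac)),
    )


def genic_overlap(
    mutations: Sequence[MutationRecord],
    intervals: Mapping[str, Sequence[tuple[int, int]]],
    gene_space_fraction: float,
    alternative: str = "two-sided",
) -> SpectrumTestResult:
    """Binomial test of the genic mutation count against the gene-space fraction.

    ``intervals`` maps scaffold -> sorted, non-overlapping 0-based half-open
    annotation intervals.  ``gene_space_fraction`` is the genomic fraction
    covered by gene space (supplied, because the annotated assembly fraction
    may differ from the interval total on the analysed scaffolds).
    """
    import bisect

    if not 0.0 <= gene_space_fraction <= 1.0:
        raise ValueError("gene_space_fraction must lie in [0, 1]")
    starts_by_sc = {}
    ends_by_sc = {}
    for sc, ivs in intervals.items():
        last = -1
        for s, e in ivs:
            if e <= s or s < last:
                raise ValueError(f"malformed intervals on {sc}")
            last = e
        starts_by_sc[sc] = [s for s, _ in ivs]
        ends_by_sc[sc] = [e for _, e in ivs]
    n_genic = 0
    for m in mutations:
        starts = starts_by_sc.get(m.scaffold)
        if not starts:
            continue
        i = bisect.bisect_right(starts, m.pos - 1) - 1
        if i >= 0 and m.pos - 1 < ends_by_sc[m.scaffold][i]:
            n_genic += 1
    n = len(mutations)
    if n == 0:
        raise ValueError("no mutations supplied")
    if gene_space_fraction == 0.0:
        p = 0.0 if n_genic > 0 else 1.0
    else:
        p = float(
            stats.binomtest(n_genic, n, gene_space_fraction,
                            alternative=alternative).pvalue
        )
    return SpectrumTestResult(
        statistic=float(n_genic), df=None, p_value=p,
        observed=(n_genic, n - n_genic),
        expected=(n * gene_space_fraction, n * (1 - gene_space_fraction)),
    )
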