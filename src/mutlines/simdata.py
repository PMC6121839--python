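"""Synthetic mutation-accumulation experiments with a known truth channel.

This module emulates the study design that downstream stages analyse: an iid
genome with configurable base composition (the default mirrors a strongly
AT-biased dipteran genome, ~69% A+T), ten MA lines propagated by full-sib
matings over five generations from a single founding F1 clutch, a large pooled
set of F1 siblings serving as the parental-genotype baseline, germline point
mutations and 1-2 bp indels injected per gamete per generation (indels with a
configurable affinity for homopolymer runs), and rendered call sets with
controllable contamination:

* *shared* false positives — standing variation of the founder pair, present
  in several lines and in the pool (removed by the uniqueness/pool stages),
* *error* false positives — low-quality singleton calls (removed by the
  quality filters).

Every quantity that a test might need to check is kept in a hidden truth
channel (:class:`RenderedCallSets.truth`, ``contaminants``), so the calling
pipeline can be scored for sensitivity and precision without real data.

Mutations are injected along the two gamete chains feeding the sequenced
F5 individual — two haploid transmissions per line and generation, matching
the exposure convention of the rate estimator (callable sites x generations
x 2).  The reduction of distinct ancestral meioses caused by inbreeding
coalescence under sib mating is deliberately not modelled here; zygosity
dynamics live in :mod:`mutlines.pedigree`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dnmcall import PoolSite, VariantCall

__all__ = [
    "BaseComposition",
    "Genome",
    "PedigreeConfig",
    "Pedigree",
    "LineChain",
    "Individual",
    "TrueMutation",
    "RenderedCallSets",
    "generate_genome",
    "simulate_pedigree",
    "haplotype_ancestry",
    "individual_carries",
    "inject_mutations",
    "render_callsets",
    "write_fixture",
    "read_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_ORDER = "ACGT"

#: Default transition/transversion bias of the injected point-mutation
#: spectrum: 15 transitions vs 11 transversions gives kappa = Ts odds 15/11.
DEFAULT_KAPPA = 15.0 / 11.0

#: Default homopolymer affinity of injected indels, chosen so that on a
#: 69% AT iid genome (~3.5% of sites inside runs of length >= 5) about 84%
#: of indels fall inside such runs (21 of 25 observed in-run).
DEFAULT_RUN_AFFINITY = 140.0


@dataclass(frozen=True)
class BaseComposition:
    """Genome-wide base probabilities (order A, C, G, T)."""

    p_a: float
    p_c: float
    p_g: float
    p_t: float

    def __post_init__(self) -> None:
        probs = (self.p_a, self.p_c, self.p_g, self.p_t)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"base probabilities must lie in [0,1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(
                f"base probabilities must sum to 1 (got {sum(probs)!r})"
            )

    @classmethod
    def uniform(cls) -> "BaseComposition":
        return cls(0.25, 0.25, 0.25, 0.25)

    @classmethod
    def from_at_content(cls, at_content: float) -> "BaseComposition":
        """Composition with the given A+T fraction, equifrequent within class."""
        a = at_content / 2.0
        g = (1.0 - at_content) / 2.0
        return cls(a, g, g, a)

    @property
    def at_content(self) -> float:
        return self.p_a + self.p_t

    @property
    def gc_content(self) -> float:
        return self.p_c + self.p_g

    def as_array(self) -> np.ndarray:
        return np.array([self.p_a, self.p_c, self.p_g, self.p_t])

    def prob(self, base: str) -> float:
        return float(self.as_array()[_BASE_ORDER.index(base)])


@dataclass
class Genome:
    """Ordered scaffolds over the {A,C,G,T} alphabet (no ambiguity codes)."""

    scaffolds: dict[str, str]

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    @property
    def composition(self) -> BaseComposition:
        counts = np.zeros(4, dtype=np.int64)
        for seq in self.scaffolds.values():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for i, b in enumerate(_BASES):
                counts[i] += int((arr == b).sum())
        if counts.sum() != self.length:
            raise ValueError("genome contains non-ACGT characters")
        frac = counts / counts.sum()
        return BaseComposition(*(float(f) for f in frac))


def generate_genome(
    length: int,
    composition: BaseComposition | None = None,
    n_scaffolds: int = 1,
    seed: int = 0,
) -> Genome:
    """Draw an iid genome of ``length`` bases with the given composition.

    Scaffold lengths partition ``length`` as evenly as possible; the draw is
    deterministic for a fixed seed.
    """
    comp = composition or BaseComposition.from_at_content(0.69)
    length = int(length)
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(4, size=length, p=comp.as_array())
    seq = _BASES[idx].tobytes().decode("ascii")
    base_len, extra = divmod(length, n_scaffolds)
    scaffolds: dict[str, str] = {}
    offset = 0
    for i in range(n_scaffolds):
        sl = base_len + (1 if i < extra else 0)
        scaffolds[f"scaffold_{i + 1}"] = seq[offset : offset + sl]
        offset += sl
    return Genome(scaffolds=scaffolds)


@dataclass(frozen=True)
class PedigreeConfig:
    """Design of the MA experiment.

    Defaults: 10 lines propagated over 5 generations from one F1 clutch, a
    190-individual F1 pool as parental baseline, and 10 full siblings of each
    sequenced F5 individual retained for confirmation.  ``clutch_size`` is the
    number of reared offspring per clutch (real clutches hold hundreds of
    eggs; 30 is ample for breeder choice plus confirmation siblings).
    """

    n_lines: int = 10
    n_generations: int = 5
    clutch_size: int = 30
    pool_size: int = 190
    n_confirm_siblings: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_generations", "clutch_size", "pool_size",
                     "n_confirm_siblings"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_generations < 2:
            raise ValueError("n_generations must be >= 2")
        if self.clutch_size < self.n_confirm_siblings + 1:
            raise ValueError("clutch_size must exceed n_confirm_siblings")


@dataclass(frozen=True)
class Individual:
    id: int
    line_id: str | None
    generation: int
    haplotypes: tuple[int, int]  # (maternal hap id, paternal hap id)


@dataclass
class LineChain:
    line_id: str
    breeders: list[tuple[int, int]]  # mating pair per generation 1..G-1
    clutches: dict[int, list[int]]  # generation (2..G) -> offspring ids
    sequenced: int
    confirm_siblings: list[int]


@dataclass
class Pedigree:
    cfg: PedigreeConfig
    individuals: dict[int, Individual]
    hap_parent: dict[int, int | None]  # hap id -> parental hap copied from
    founders: tuple[int, int]
    pool_members: list[int]
    lines: dict[str, LineChain]


def simulate_pedigree(cfg: PedigreeConfig) -> Pedigree:
    """Build the haplotype transmission graph of the full design.

    Two diploid F0 founders produce one F1 clutch; the pool and every line's
    founding pair are members of that clutch.  Each subsequent generation is a
    full-sib mating (single sire) producing ``clutch_size`` offspring, of
    which a random pair breeds the next generation; in the final generation
    one random individual is "sequenced" and ``n_confirm_siblings`` of its
    sibs are retained.  Haplotype transmission is a fair coin per gamete.
    """
    rng = np.random.default_rng(cfg.seed)
    individuals: dict[int, Individual] = {}
    hap_parent: dict[int, int | None] = {}
    next_ind = 0
    next_hap = 0

    def new_individual(line_id, generation, hap_m, hap_p) -> int:
        nonlocal next_ind
        ind = Individual(next_ind, line_id, generation, (hap_m, hap_p))
        individuals[next_ind] = ind
        next_ind += 1
        return ind.id

    def founder() -> int:
        nonlocal next_hap
        h0, h1 = next_hap, next_hap + 1
        next_hap += 2
        hap_parent[h0] = None
        hap_parent[h1] = None
        return new_individual(None, 0, h0, h1)

    def child(line_id, generation, mother: int, father: int) -> int:
        nonlocal next_hap
        haps = []
        for parent in (mother, father):
            src = individuals[parent].haplotypes[int(rng.integers(2))]
            hap_parent[next_hap] = src
            haps.append(next_hap)
            next_hap += 1
        return new_individual(line_id, generation, haps[0], haps[1])

    f0_a, f0_b = founder(), founder()
    n_f1 = cfg.pool_size + 2 * cfg.n_lines
    f1_clutch = [child(None, 1, f0_a, f0_b) for _ in range(n_f1)]
    pool_members = f1_clutch[: cfg.pool_size]
    founder_pairs = f1_clutch[cfg.pool_size :]

    lines: dict[str, LineChain] = {}
    for i in range(cfg.n_lines):
        line_id = f"A{i + 1}"
        pair = (founder_pairs[2 * i], founder_pairs[2 * i + 1])
        breeders = [pair]
        clutches: dict[int, list[int]] = {}
        for gen in range(2, cfg.n_generations + 1):
            mother, father = breeders[-1]
            clutch = [
                child(line_id, gen, mother, father) for _ in range(cfg.clutch_size)
            ]
            clutches[gen] = clutch
            if gen < cfg.n_generations:
                picks = rng.choice(cfg.clutch_size, size=2, replace=False)
                breeders.append((clutch[picks[0]], clutch[picks[1]]))
        final = clutches[cfg.n_generations]
        picks = rng.choice(
            cfg.clutch_size, size=cfg.n_confirm_siblings + 1, replace=False
        )
        lines[line_id] = LineChain(
            line_id=line_id,
            breeders=breeders,
            clutches=clutches,
            sequenced=final[picks[0]],
            confirm_siblings=[final[p] for p in picks[1:]],
        )
    return Pedigree(
        cfg=cfg,
        individuals=individuals,
        hap_parent=hap_parent,
        founders=(f0_a, f0_b),
        pool_members=pool_members,
        lines=lines,
    )


def haplotype_ancestry(pedigree: Pedigree, hap_id: int) -> list[int]:
    """Chain of haplotype ids from ``hap_id`` back to a founder haplotype."""
    chain = [hap_id]
    while pedigree.hap_parent[chain[-1]] is not None:
        chain.append(pedigree.hap_parent[chain[-1]])
    return chain


def individual_carries(
    pedigree: Pedigree, individual_id: int, marked_hap: int
) -> int:
    """Number of the individual's haplotypes descending from ``marked_hap``."""
    return sum(
        marked_hap in haplotype_ancestry(pedigree, h)
        for h in pedigree.individuals[individual_id].haplotypes
    )


@dataclass(frozen=True)
class TrueMutation:
    """A germline mutation injected into the pedigree (truth channel)."""

    line_id: str
    origin_generation: int
    scaffold: str
    pos: int  # 1-based, VCF-style anchored for indels
    mtype: str  # "SNM" | "INS" | "DEL"
    ref: str
    alt: str
    carrier_haplotypes: frozenset[int]

    def __post_init__(self) -> None:
        dlen = abs(len(self.alt) - len(self.ref))
        if self.mtype == "SNM":
            if self.ref == self.alt or dlen != 0:
                raise ValueError("SNM must substitute a single base")
        elif dlen not in (1, 2):
            raise ValueError("indel length difference must be 1 or 2")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.scaffold, self.pos, self.ref, self.alt)


def _scaffold_offsets(genome: Genome) -> tuple[list[str], np.ndarray]:
    names = list(genome.scaffolds)
    lengths = np.array([len(genome.scaffolds[n]) for n in names], dtype=np.int64)
    return names, np.concatenate([[0], np.cumsum(lengths)])


def _run_length_per_position(genome: Genome) -> np.ndarray:
    """For every global 0-based position, the length of its maximal monomer run."""
    names, offsets = _scaffold_offsets(genome)
    out = np.empty(int(offsets[-1]), dtype=np.int32)
    for name, off in zip(names, offsets[:-1]):
        arr = np.frombuffer(genome.scaffolds[name].encode("ascii"), dtype=np.uint8)
        if arr.size == 0:
            continue
        change = np.flatnonzero(arr[1:] != arr[:-1])
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [arr.size]])
        lengths = (ends - starts).astype(np.int32)
        out[off : off + arr.size] = np.repeat(lengths, lengths)
    return out


def _locate(names, offsets, gpos: int) -> tuple[str, int]:
    i = int(np.searchsorted(offsets, gpos, side="right")) - 1
    return names[i], int(gpos - offsets[i])


def inject_mutations(
    pedigree: Pedigree,
    genome: Genome,
    mu_snm: float,
    mu_ins: float = 0.0,
    mu_del: float = 0.0,
    ts_tv_kappa: float = DEFAULT_KAPPA,
    run_affinity: float = DEFAULT_RUN_AFFINITY,
    seed: int = 0,
) -> list[TrueMutation]:
    """Inject germline mutations along the sequenced individuals' gamete chains.

    For every line, generation ``1..G`` and each of the two haploid gamete
    chains, the number of new mutations per class is Poisson(rate x haploid
    genome length).  Point-mutation alternative alleles are transitions with
    probability kappa/(kappa+1), the two transversions split equally.  Indel
    positions are drawn with sampling weight multiplied by ``run_affinity``
    inside monomer runs of length >= 5; indel length is 1 with probability
    0.95, otherwise 2, and inserted bases duplicate the neighbouring base
    (polymerase slippage).
    """
    for name, r in (("mu_snm", mu_snm), ("mu_ins", mu_ins), ("mu_del", mu_del)):
        if r < 0:
            raise ValueError(f"{name} must be >= 0")
    total_rate = mu_snm + mu_ins + mu_del
    if total_rate * pedigree.cfg.n_generations > 0.1:
        raise ValueError(
            "expected mutations exceed 10% of sites; the infinite-sites "
            "model breaks down at such rates"
        )
    rng = np.random.default_rng(seed)
    names, offsets = _scaffold_offsets(genome)
    L = int(offsets[-1])
    p_ts = ts_tv_kappa / (ts_tv_kappa + 1.0)

    # Per-position run length, for affinity-weighted indel placement.
    # run_affinity may be a scalar (weight applied inside runs >= 5) or a
    # callable length -> weight (applied at every run length).
    runlen = _run_length_per_position(genome)
    if callable(run_affinity):
        weight_of = run_affinity
    else:
        weight_of = lambda rl: run_affinity if rl >= 5 else 1.0  # noqa: E731
    max_rl = int(runlen.max())
    n_by_len = np.bincount(runlen, minlength=max_rl + 1).astype(float)
    w_by_len = np.array([weight_of(rl) for rl in range(max_rl + 1)])
    if np.any(w_by_len < 0):
        raise ValueError("run_affinity weights must be >= 0")
    group_prob = n_by_len * w_by_len
    group_prob /= group_prob.sum()
    order = np.argsort(runlen, kind="stable")
    group_start = np.concatenate(
        [[0], np.cumsum(n_by_len.astype(np.int64))]
    )

    def draw_indel_gpos() -> int:
        rl = int(rng.choice(max_rl + 1, p=group_prob))
        lo, hi = group_start[rl], group_start[rl + 1]
        return int(order[rng.integers(lo, hi)])

    # Infinite-sites regime: every mutation hits a distinct genomic site,
    # also across lines (recurrent hits are vanishingly rare at realistic
    # rate x genome size, and would be removed by the uniqueness stage).
    used: set[tuple[str, int]] = set()
    muts: list[TrueMutation] = []
    G = pedigree.cfg.n_generations
    for line_id in sorted(pedigree.lines):
        chain = pedigree.lines[line_id]
        f5_haps = pedigree.individuals[chain.sequenced].haplotypes
        for gen in range(1, G + 1):
            for chain_idx in (0, 1):
                carrier = frozenset({f5_haps[chain_idx]})
                for mtype, mu in (("SNM", mu_snm), ("INS", mu_ins), ("DEL", mu_del)):
                    n = int(rng.poisson(mu * L))
                    made = 0
                    while made < n:
                        if mtype == "SNM":
                            g = int(rng.integers(L))
                            scaffold, i = _locate(names, offsets, g)
                            pos = i + 1
                            if (scaffold, pos) in used:
                                continue
                            ref = genome.scaffolds[scaffold][i]
                            if rng.random() < p_ts:
                                alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
                            else:
                                tv = [b for b in "ACGT"
                                      if b != ref and b != {"A": "G", "G": "A",
                                                            "C": "T", "T": "C"}[ref]]
                                alt = tv[int(rng.integers(2))]
                            muts.append(TrueMutation(
                                line_id, gen, scaffold, pos, "SNM", ref, alt, carrier))
                        else:
                            g = draw_indel_gpos()
                            scaffold, i = _locate(names, offsets, g)
                            seq = genome.scaffolds[scaffold]
                            dlen = 1 if rng.random() < 0.95 else 2
                            if i < 1:
                                continue
                            anchor = i - 1
                            pos = anchor + 1  # 1-based anchor
                            if (scaffold, pos) in used:
                                continue
                            if mtype == "DEL":
                                if anchor + 1 + dlen > len(seq):
                                    continue
                                ref = seq[anchor : anchor + 1 + dlen]
                                alt = ref[0]
                            else:
                                ref = seq[anchor]
                                alt = ref + seq[i] * dlen
                            muts.append(TrueMutation(
                                line_id, gen, scaffold, pos, mtype, ref, alt, carrier))
                        used.add((scaffold, pos))
                        made += 1
    muts.sort(key=lambda m: (m.line_id, m.scaffold, m.pos, m.alt))
    return muts


@dataclass
class RenderedCallSets:
    """Upstream-caller products rendered from the truth channel."""

    line_calls: dict[str, list[VariantCall]]
    pool_sites: list[PoolSite]
    pool_calls: set[tuple[str, int, str, str]]
    depth_tracks: dict[str, list[tuple[str, int, int, int]]]
    pool_depth_track: list[tuple[str, int, int, int]]
    truth: list[TrueMutation]
    #: hidden oracle channel: contaminant key -> designed removal stage
    contaminants: dict[tuple[str, str, int, str, str], str]


def _block_track(
    genome: Genome,
    coverage: float,
    rng: np.random.Generator,
    stochastic: bool,
    block_size: int,
) -> tuple[list[tuple[str, int, int, int]], dict[str, np.ndarray]]:
    track: list[tuple[str, int, int, int]] = []
    depths: dict[str, np.ndarray] = {}
    for name, seq in genome.scaffolds.items():
        n_blocks = math.ceil(len(seq) / block_size)
        if stochastic:
            d = rng.poisson(coverage, size=n_blocks).astype(np.int64)
        else:
            d = np.full(n_blocks, int(round(coverage)), dtype=np.int64)
        depths[name] = d
        # merge equal-depth neighbours so the track stays compact
        start = 0
        for b in range(n_blocks):
            end = min((b + 1) * block_size, len(seq))
            if b + 1 < n_blocks and d[b + 1] == d[b]:
                continue
            track.append((name, start, end, int(d[b])))
            start = end
    return track, depths


def _depth_at(depths: Mapping[str, np.ndarray], scaffold: str, pos1: int,
              block_size: int) -> int:
    return int(depths[scaffold][(pos1 - 1) // block_size])


def render_callsets(
    pedigree: Pedigree,
    truth: Sequence[TrueMutation],
    genome: Genome,
    coverage_line: float = 25.0,
    coverage_pool: float = 60.0,
    error_rate: float = 0.0,
    fp_shared: int = 0,
    fp_error: int = 0,
    fp_pool_low: int = 0,
    seed: int = 0,
    block_size: int = 500,
) -> RenderedCallSets:
    """Render per-line call sets, pool allele counts and depth tracks.

    ``error_rate == 0`` produces a fully deterministic, noise-free rendering
    (constant depth, alt count exactly depth/2, GQ 99, SOR 1) under which the
    filter chain recovers the transmitted truth set exactly.  With
    ``error_rate > 0`` depths are Poisson per ``block_size`` window and alt
    counts binomial, so true variants can fall outside the callable depth
    range — losses the attrition report must then explain.  ``fp_shared``
    standing variants are planted in >= 2 lines and the pool; ``fp_error``
    low-quality singletons violate GQ or the minimum allele count;
    ``fp_pool_low`` good-quality singletons carry 1-4 supporting pool reads
    (standing variation below the pool's own calling threshold), so only the
    read-level pool screen can remove them.
    """
    if coverage_line <= 0 or coverage_pool <= 0:
        raise ValueError("coverages must be > 0")
    rng = np.random.default_rng(seed)
    stochastic = error_rate > 0
    cfg = pedigree.cfg

    depth_tracks: dict[str, list[tuple[str, int, int, int]]] = {}
    line_depths: dict[str, dict[str, np.ndarray]] = {}
    for line_id in sorted(pedigree.lines):
        track, depths = _block_track(genome, coverage_line, rng, stochastic,
                                     block_size)
        depth_tracks[line_id] = track
        line_depths[line_id] = depths
    pool_track, pool_depths = _block_track(genome, coverage_pool, rng,
                                           stochastic, block_size)

    names, offsets = _scaffold_offsets(genome)
    L = int(offsets[-1])
    taken = {(m.scaffold, m.pos) for m in truth}

    def fresh_site() -> tuple[str, int, str]:
        while True:
            g = int(rng.integers(1, L))  # skip scaffold-initial base
            scaffold, i = _locate(names, offsets, g)
            if i < 1:
                continue
            pos = i + 1
            if (scaffold, pos) not in taken:
                taken.add((scaffold, pos))
                return scaffold, pos, genome.scaffolds[scaffold][i]

    def het_call(line_id, scaffold, pos, ref, alt) -> VariantCall:
        dp = _depth_at(line_depths[line_id], scaffold, pos, block_size)
        if stochastic:
            alt_n = int(rng.binomial(dp, 0.5)) if dp > 0 else 0
            sor = float(np.round(rng.uniform(0.2, 2.5), 3))
        else:
            alt_n = dp // 2
            sor = 1.0
        return VariantCall(line_id=line_id, scaffold=scaffold, pos=pos,
                           ref=ref, alt=alt, gq=99.0, sor=sor, dp=dp,
                           alt_count=alt_n, genotype="het")

    line_calls: dict[str, list[VariantCall]] = {l: [] for l in sorted(pedigree.lines)}
    pool_alt: dict[tuple[str, int], tuple[str, str, int]] = {}
    contaminants: dict[tuple[str, str, int, str, str], str] = {}

    for m in truth:
        line_calls[m.line_id].append(
            het_call(m.line_id, m.scaffold, m.pos, m.ref, m.alt)
        )

    all_lines = sorted(pedigree.lines)
    for _ in range(fp_shared):
        scaffold, pos, ref = fresh_site()
        alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
        n_present = int(rng.integers(2, cfg.n_lines + 1))
        present = rng.choice(cfg.n_lines, size=n_present, replace=False)
        for li in present:
            line_id = all_lines[li]
            line_calls[line_id].append(het_call(line_id, scaffold, pos, ref, alt))
            contaminants[(line_id, scaffold, pos, ref, alt)] = "shared"
        pd_ = _depth_at(pool_depths, scaffold, pos, block_size)
        # one founder heterozygous -> expected pool allele frequency 1/4
        alt_n = int(rng.binomial(pd_, 0.25)) if stochastic else pd_ // 4
        pool_alt[(scaffold, pos)] = (ref, alt, max(1, alt_n))

    for k in range(fp_error):
        scaffold, pos, ref = fresh_site()
        alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
        line_id = all_lines[int(rng.integers(cfg.n_lines))]
        dp = _depth_at(line_depths[line_id], scaffold, pos, block_size)
        if k % 2 == 0:  # fails the minimum allele count
            call = VariantCall(line_id=line_id, scaffold=scaffold, pos=pos,
                               ref=ref, alt=alt, gq=99.0, sor=1.0, dp=dp,
                               alt_count=min(dp, int(rng.integers(1, 5))),
                               genotype="het")
        else:  # fails the genotype-quality threshold
            call = VariantCall(line_id=line_id, scaffold=scaffold, pos=pos,
                               ref=ref, alt=alt,
                               gq=float(rng.integers(20, 91)), sor=1.0, dp=dp,
                               alt_count=dp // 2, genotype="het")
        line_calls[line_id].append(call)
        contaminants[(line_id, scaffold, pos, ref, alt)] = "error"

    for _ in range(fp_pool_low):
        scaffold, pos, ref = fresh_site()
        alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
        line_id = all_lines[int(rng.integers(cfg.n_lines))]
        line_calls[line_id].append(het_call(line_id, scaffold, pos, ref, alt))
        contaminants[(line_id, scaffold, pos, ref, alt)] = "pool_low"
        pool_alt[(scaffold, pos)] = (ref, alt, int(rng.integers(1, 5)))

    # pool allele-count table at every variant site
    site_keys = sorted(
        {(c.scaffold, c.pos) for calls in line_calls.values() for c in calls}
    )
    pool_sites: list[PoolSite] = []
    for scaffold, pos in site_keys:
        depth = _depth_at(pool_depths, scaffold, pos, block_size)
        ref_base = genome.scaffolds[scaffold][pos - 1]
        counts = {b: 0 for b in "ACGT"}
        counts["INS"] = 0
        counts["DEL"] = 0
        if (scaffold, pos) in pool_alt:
            _, alt, alt_n = pool_alt[(scaffold, pos)]
            alt_n = min(alt_n, depth)
            counts[alt] = alt_n
            counts[ref_base] = depth - alt_n
        else:
            counts[ref_base] = depth
        pool_sites.append(PoolSite(scaffold=scaffold, pos=pos, depth=depth,
                                   allele_counts=counts))

    pool_calls = {
        (scaffold, pos, "*", alt)
        for (scaffold, pos), (_, alt, n) in pool_alt.items()
        if n >= 5
    }
    for calls in line_calls.values():
        calls.sort(key=lambda c: (c.scaffold, c.pos, c.alt))
    return RenderedCallSets(
        line_calls=line_calls,
        pool_sites=pool_sites,
        pool_calls=pool_calls,
        depth_tracks=depth_tracks,
        pool_depth_track=pool_track,
        truth=list(truth),
        contaminants=contaminants,
    )


# ---------------------------------------------------------------------------
# fixture serialization


def write_fixture(out_dir: str | Path, genome: Genome, rcs: RenderedCallSets) -> None:
    """Write a rendered experiment as FASTA / VCF 4.2 / TSV / BED files."""
    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_fasta(out / "genome.fa", genome)
    for line_id, calls in rcs.line_calls.items():
        mio.write_vcf(out / f"line_{line_id}.vcf", calls, genome, sample=line_id)
    mio.write_pool_tsv(out / "pool_sites.tsv", rcs.pool_sites)
    mio.write_pool_calls_tsv(out / "pool_calls.tsv", rcs.pool_calls)
    for line_id, track in rcs.depth_tracks.items():
        mio.write_bed(out / f"depth_{line_id}.bed", track)
    mio.write_bed(out / "depth_pool.bed", rcs.pool_depth_track)
    mio.write_truth_tsv(out / "truth.tsv", rcs.truth)
    mio.write_contaminants_tsv(out / "contaminants.tsv", rcs.contaminants)


def read_fixture(in_dir: str | Path) -> tuple[Genome, RenderedCallSets]:
    """Read back a fixture written by :func:`write_fixture` (lossless)."""
    from . import io as mio

    d = Path(in_dir)
    genome = mio.read_fasta(d / "genome.fa")
    line_calls = {}
    for vcf in sorted(d.glob("line_*.vcf")):
        line_id = vcf.stem.removeprefix("line_")
        line_calls[line_id] = mio.read_vcf(vcf, line_id=line_id)
    depth_tracks = {
        bed.stem.removeprefix("depth_"): mio.read_bed(bed)
        for bed in sorted(d.glob("depth_*.bed"))
        if bed.stem != "depth_pool"
    }
    rcs = RenderedCallSets(
        line_calls=line_calls,
        pool_sites=mio.read_pool_tsv(d / "pool_sites.tsv"),
        pool_calls=mio.read_pool_calls_tsv(d / "pool_calls.tsv"),
        depth_tracks=depth_tracks,
        pool_depth_track=mio.read_bed(d / "depth_pool.bed"),
        truth=mio.read_truth_tsv(d / "truth.tsv"),
        contaminants=mio.read_contaminants_tsv(d / "contaminants.tsv"),
    )
    return genome, rcs
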