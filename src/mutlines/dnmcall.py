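"""De novo mutation identification for mutation-accumulation lines.

The calling strategy assumes one deep-sequenced individual per MA line and a
pooled baseline of many full siblings from the founding clutch, whose allele
frequencies mirror the (unknown) parental genotypes.  A candidate de novo
mutation must be

1. unique to a single line and absent from the pool's own call set
   (:func:`intersect_unique`),
2. a confident call: genotype quality above ``gq_min``, no strand bias
   (``SOR <= sor_max``), indel length at most ``indel_len_max``, depth inside
   ``[dp_min, dp_max]`` (guards against paralog mismapping), and at least
   ``alt_min`` reads on the alternative allele (:func:`quality_filter`),
3. unsupported by any read in the pooled baseline (:func:`pool_screen`).

Surviving candidates are classified (:func:`classify_mutation`) into SNM /
insertion / deletion, transition vs. transversion, GC<->AT direction and
homopolymer-run context.  :func:`count_callable_sites` produces the exposure
denominator for rate estimation: positions where a mutation could have been
called at all, i.e. line depth in range and pool depth sufficient for the
screen.  :func:`run_pipeline` chains the stages and keeps a per-stage
attrition report so that every removed candidate is accounted for.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VariantCall",
    "PoolSite",
    "FilterThresholds",
    "MutationRecord",
    "CallableSummary",
    "DepthTrack",
    "FilterOutcome",
    "PipelineResult",
    "intersect_unique",
    "quality_filter",
    "pool_screen",
    "count_callable_sites",
    "callable_summaries",
    "classify_mutation",
    "run_context_length",
    "run_pipeline",
    "pool_callset_from_sites",
]

PURINES = {"A", "G"}
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
GC = {"G", "C"}
AT = {"A", "T"}


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one MA line (or the pool).

    ``pos`` is 1-based (VCF convention).  ``ref``/``alt`` are VCF-style
    anchored alleles; multi-allelic VCF records are split into one
    :class:`VariantCall` per alternative allele before entering the chain.
    """

    line_id: str
    scaffold: str
    pos: int
    ref: str
    alt: str
    gq: float | None = None
    sor: float | None = None
    dp: int | None = None
    alt_count: int | None = None
    genotype: str = "het"  # "het" | "hom_alt"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.dp is not None and self.alt_count is not None:
            if not (self.dp >= self.alt_count >= 0):
                raise ValueError(
                    f"require DP >= alt_count >= 0, got DP={self.dp}, "
                    f"alt_count={self.alt_count}"
                )
        if self.gq is not None and self.gq < 0:
            raise ValueError("GQ must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the variant irrespective of line: (scaffold, pos, ref, alt)."""
        return (self.scaffold, self.pos, self.ref, self.alt)

    @property
    def is_snm(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass(frozen=True)
class PoolSite:
    """Per-base allele counts in the pooled baseline at one position.

    ``allele_counts`` maps single bases ("A".."T") and the aggregate indel
    alleles ("INS", "DEL") to supporting read counts.
    """

    scaffold: str
    pos: int
    depth: int
    allele_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if sum(self.allele_counts.values()) > self.depth:
            raise ValueError(
                f"allele counts exceed depth at {self.scaffold}:{self.pos}"
            )

    def support_for(self, call: VariantCall) -> int:
        """Reads in the pool supporting the call's alternative allele."""
        if call.is_snm:
            return int(self.allele_counts.get(call.alt, 0))
        if call.length_change > 0:
            return int(self.allele_counts.get("INS", 0))
        return int(self.allele_counts.get("DEL", 0))


@dataclass(frozen=True)
class FilterThresholds:
    """Hard filters applied to raw candidates.

    Defaults encode the reading of the published criteria: "above 90" is
    strict (GQ > 90); calls with SOR > 4 are removed (keep SOR <= 4);
    "between 15 and 44" is inclusive on both ends; allele count is a
    minimum (>= 5); any pool read supporting the alternative allele removes
    a candidate (pool_alt_max = 0).  All are overridable.
    """

    gq_min: float = 90.0  # exclusive
    sor_max: float = 4.0  # inclusive
    indel_len_max: int = 2
    dp_min: int = 15
    dp_max: int = 44
    alt_min: int = 5
    pool_alt_max: int = 0
    require_pool_depth_for_callable: bool = True

    def __post_init__(self) -> None:
        if self.dp_min > self.dp_max:
            raise ValueError("dp_min must be <= dp_max")
        for name in ("gq_min", "sor_max", "indel_len_max", "dp_min", "alt_min",
                     "pool_alt_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class MutationRecord:
    """An accepted de novo mutation with its spectrum classification."""

    line_id: str
    scaffold: str
    pos: int
    ref: str
    alt: str
    mtype: str  # "SNM" | "INS" | "DEL"
    ts_tv: str = "NA"  # "Ts" | "Tv" | "NA"
    gc_at_direction: str = "NA"  # "GCtoAT" | "ATtoGC" | "within_class" | "NA"
    run_context_length: int = 0
    multi_allelic_site: bool = False
    zygosity: str = "het"
    review_flag: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.scaffold, self.pos, self.ref, self.alt)

    @property
    def is_single_base(self) -> bool:
        """True for SNMs and 1-bp indels (the events entering rate totals)."""
        return self.mtype == "SNM" or abs(len(self.alt) - len(self.ref)) == 1


@dataclass(frozen=True)
class CallableSummary:
    line_id: str
    callable_sites: int


# A depth track is a list of 0-based half-open intervals with constant depth.
DepthTrack = Sequence[tuple[str, int, int, int]]


def _validate_track(track: DepthTrack) -> dict[str, list[tuple[int, int, int]]]:
    by_scaffold: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for scaffold, start, end, depth in track:
        if end <= start:
            raise ValueError(f"empty/inverted interval {scaffold}:{start}-{end}")
        by_scaffold[scaffold].append((start, end, depth))
    for scaffold, ivs in by_scaffold.items():
        last_end = -1
        for start, end, _ in ivs:
            if start < last_end:
                raise ValueError(
                    f"depth track unsorted or overlapping on {scaffold} at {start}"
                )
            last_end = end
    return by_scaffold


def intersect_unique(
    line_callsets: Mapping[str, Sequence[VariantCall]],
    pool_callset: Iterable[tuple[str, int, str, str]],
) -> dict[str, list[VariantCall]]:
    """Retain, per line, the variants called in exactly one line and not in the pool.

    Variants are keyed by (scaffold, pos, ref, alt), so two different
    alternative alleles at one site in one line both survive.  Duplicate keys
    within a single line are rejected as malformed input.
    """
    if len(line_callsets) < 2:
        raise ValueError("need call sets for at least two lines")
    pool_keys = set(pool_callset)
    line_count: Counter[tuple[str, int, str, str]] = Counter()
    for line_id, calls in line_callsets.items():
        seen: set[tuple[str, int, str, str]] = set()
        for call in calls:
            if call.key in seen:
                raise ValueError(
                    f"duplicate record in line {line_id} at {call.key}"
                )
            seen.add(call.key)
        line_count.update(seen)
    out: dict[str, list[VariantCall]] = {}
    for line_id, calls in line_callsets.items():
        out[line_id] = [
            c
            for c in calls
            if line_count[c.key] == 1
            and not any(k in pool_keys for k in _pool_key_variants(c))
        ]
    return out


@dataclass
class FilterOutcome:
    passed: list[VariantCall]
    rejected: list[tuple[VariantCall, tuple[str, ...]]]

    def reasons(self) -> Counter[str]:
        c: Counter[str] = Counter()
        for _, reasons in self.rejected:
            c.update(reasons)
        return c


def quality_filter(
    candidates: Sequence[VariantCall], thresholds: FilterThresholds | None = None
) -> FilterOutcome:
    """Apply the hard quality filters; predicates are independent and order-free.

    A record missing an annotation needed by a predicate fails that predicate
    with a ``missing:FIELD`` reason code rather than being silently dropped.
    """
    t = thresholds or FilterThresholds()
    passed: list[VariantCall] = []
    rejected: list[tuple[VariantCall, tuple[str, ...]]] = []
    for c in candidates:
        reasons: list[str] = []
        if c.gq is None:
            reasons.append("missing:GQ")
        elif not c.gq > t.gq_min:
            reasons.append("GQ")
        if c.sor is None:
            reasons.append("missing:SOR")
        elif not c.sor <= t.sor_max:
            reasons.append("SOR")
        if abs(c.length_change) > t.indel_len_max:
            reasons.append("INDEL_LEN")
        if c.dp is None:
            reasons.append("missing:DP")
        elif not t.dp_min <= c.dp <= t.dp_max:
            reasons.append("DP")
        if c.alt_count is None:
            reasons.append("missing:ALT_COUNT")
        elif not c.alt_count >= t.alt_min:
            reasons.append("ALT_COUNT")
        if reasons:
            rejected.append((c, tuple(reasons)))
        else:
            passed.append(c)
    return FilterOutcome(passed=passed, rejected=rejected)


@dataclass
class PoolScreenOutcome:
    passed: list[VariantCall]
    removed: list[VariantCall]
    flagged: list[VariantCall]  # pool coverage gap -> manual-review channel


def pool_screen(
    candidates: Sequence[VariantCall],
    pool_sites: Mapping[tuple[str, int], PoolSite],
    thresholds: FilterThresholds | None = None,
) -> PoolScreenOutcome:
    """Remove candidates whose alternative allele is supported by pool reads.

    With the default ``pool_alt_max = 0`` a single supporting read in the
    pooled baseline removes the candidate (the allele was already present in
    the parents).  A candidate whose position is absent from the pool table is
    routed to the review channel, never auto-accepted.
    """
    t = thresholds or FilterThresholds()
    passed: list[VariantCall] = []
    removed: list[VariantCall] = []
    flagged: list[VariantCall] = []
    for c in candidates:
        site = pool_sites.get((c.scaffold, c.pos))
        if site is None:
            flagged.append(c)
        elif site.support_for(c) > t.pool_alt_max:
            removed.append(c)
        else:
            passed.append(c)
    return PoolScreenOutcome(passed=passed, removed=removed, flagged=flagged)


def pool_callset_from_sites(
    pool_sites: Iterable[PoolSite], min_count: int = 5
) -> set[tuple[str, int, str, str]]:
    """Derive the pool's own variant call set from its allele-count table.

    An allele counts as *called* in the (tetraploid-genotyped) pool when at
    least ``min_count`` reads support it — the same minimum allele count
    applied to the line calls.  Indel alleles cannot be reconstructed from the
    aggregate INS/DEL counters, so they are keyed by a wildcard allele; the
    uniqueness stage treats any indel at that site as pool-called.
    """
    keys: set[tuple[str, int, str, str]] = set()
    for site in pool_sites:
        for allele, n in site.allele_counts.items():
            if n >= min_count and allele in {"A", "C", "G", "T", "INS", "DEL"}:
                keys.add((site.scaffold, site.pos, "*", allele))
    return keys


def _pool_key_variants(call: VariantCall) -> list[tuple[str, int, str, str]]:
    out = [call.key]
    if call.is_snm:
        out.append((call.scaffold, call.pos, "*", call.alt))
    elif call.length_change > 0:
        out.append((call.scaffold, call.pos, "*", "INS"))
    else:
        out.append((call.scaffold, call.pos, "*", "DEL"))
    return out


def count_callable_sites(
    line_track: DepthTrack,
    pool_track: DepthTrack,
    thresholds: FilterThresholds | None = None,
) -> int:
    """Number of positions at which a mutation could have been called.

    Callable means the line's depth lies in ``[dp_min, dp_max]`` and — by
    default — the pool's depth is at least ``dp_min`` so that the pool screen
    could have been performed (toggle with
    ``thresholds.require_pool_depth_for_callable``).
    """
    t = thresholds or FilterThresholds()
    line_by_sc = _validate_track(line_track)
    pool_by_sc = _validate_track(pool_track)
    total = 0
    for scaffold, line_ivs in line_by_sc.items():
        good_line = [
            (s, e) for s, e, d in line_ivs if t.dp_min <= d <= t.dp_max
        ]
        if not t.require_pool_depth_for_callable:
            total += sum(e - s for s, e in good_line)
            continue
        good_pool = [
            (s, e) for s, e, d in pool_by_sc.get(scaffold, []) if d >= t.dp_min
        ]
        # two-pointer overlap of two sorted interval lists
        i = j = 0
        while i < len(good_line) and j < len(good_pool):
            ls, le = good_line[i]
            ps, pe = good_pool[j]
            lo, hi = max(ls, ps), min(le, pe)
            if lo < hi:
                total += hi - lo
            if le <= pe:
                i += 1
            else:
                j += 1
    return total


def callable_summaries(
    depth_tracks: Mapping[str, DepthTrack],
    pool_track: DepthTrack,
    thresholds: FilterThresholds | None = None,
) -> list[CallableSummary]:
    return [
        CallableSummary(line_id, count_callable_sites(track, pool_track, thresholds))
        for line_id, track in sorted(depth_tracks.items())
    ]


def run_context_length(sequence: str, start0: int, end0: int) -> int:
    """Longest maximal monomer run overlapping [start0, end0) extended by 1 bp.

    ``sequence`` is the scaffold string; the window extension captures the
    breakpoint ambiguity of homopolymer indels (a run immediately adjacent to
    the reported position is still its mutational context).
    """
    n = len(sequence)
    lo = max(0, start0 - 1)
    hi = min(n, end0 + 1)
    best = 0
    i = lo
    while i < hi:
        base = sequence[i]
        s = i
        while s > 0 and sequence[s - 1] == base:
            s -= 1
        e = i
        while e + 1 < n and sequence[e + 1] == base:
            e += 1
        best = max(best, e - s + 1)
        i = e + 1
    return best


def classify_mutation(call: VariantCall, genome, review_flag: bool = False) -> MutationRecord:
    """Classify an accepted candidate into a :class:`MutationRecord`.

    ``genome`` is any object with a ``scaffolds`` mapping of name -> sequence
    (see :class:`mutlines.simdata.Genome`).  The multi-allelic flag is set by
    :func:`run_pipeline`, which sees all accepted alts at a site.
    """
    if call.ref == call.alt:
        raise ValueError("alt equal to ref")
    seq = genome.scaffolds[call.scaffold]
    dlen = call.length_change
    if dlen == 0:
        if not call.is_snm:
            raise ValueError("length-preserving multi-base substitution unsupported")
        mtype = "SNM"
        ts_tv = "Ts" if TRANSITION_PARTNER[call.ref] == call.alt else "Tv"
        if call.ref in GC and call.alt in AT:
            direction = "GCtoAT"
        elif call.ref in AT and call.alt in GC:
            direction = "ATtoGC"
        else:
            direction = "within_class"
        span = (call.pos - 1, call.pos)  # 0-based half-open
    else:
        mtype = "INS" if dlen > 0 else "DEL"
        ts_tv = "NA"
        direction = "NA"
        if dlen > 0:
            # inserted bases sit between pos and pos+1; context is the anchor
            # base and its right neighbour
            span = (call.pos - 1, min(len(seq), call.pos + 1))
        else:
            # deleted bases occupy pos+1 .. pos+|dlen| (1-based)
            span = (call.pos, call.pos - dlen)
    return MutationRecord(
        line_id=call.line_id,
        scaffold=call.scaffold,
        pos=call.pos,
        ref=call.ref,
        alt=call.alt,
        mtype=mtype,
        ts_tv=ts_tv,
        gc_at_direction=direction,
        run_context_length=run_context_length(seq, *span),
        zygosity="hom" if call.genotype == "hom_alt" else "het",
        review_flag=review_flag,
    )


@dataclass
class PipelineResult:
    records: list[MutationRecord]
    callable: list[CallableSummary]
    attrition: "pandas.DataFrame"  # noqa: F821 - imported lazily
    removal_stage: dict[tuple[str, str, int, str, str], str]
    quality_reasons: Counter

    def accepted(self, include_review: bool = False) -> list[MutationRecord]:
        return [r for r in self.records if include_review or not r.review_flag]


def run_pipeline(
    line_callsets: Mapping[str, Sequence[VariantCall]],
    pool_callset: Iterable[tuple[str, int, str, str]],
    pool_sites: Mapping[tuple[str, int], PoolSite],
    depth_tracks: Mapping[str, DepthTrack],
    pool_depth_track: DepthTrack,
    genome,
    thresholds: FilterThresholds | None = None,
) -> PipelineResult:
    """Full chain: intersect_unique -> quality_filter -> pool_screen -> classify.

    Returns accepted mutation records (review-flagged ones carry
    ``review_flag=True`` and are excluded from rates by default), per-line
    callable-site summaries, and a per-stage attrition table.
    """
    import pandas as pd

    t = thresholds or FilterThresholds()
    pool_keys = set(pool_callset)

    # stage 1: uniqueness among lines and against the pool call set
    line_count: Counter[tuple[str, int, str, str]] = Counter()
    for line_id, calls in line_callsets.items():
        seen: set[tuple[str, int, str, str]] = set()
        for call in calls:
            if call.key in seen:
                raise ValueError(f"duplicate record in line {line_id} at {call.key}")
            seen.add(call.key)
        line_count.update(seen)

    removal_stage: dict[tuple[str, str, int, str, str], str] = {}
    quality_reasons: Counter = Counter()
    rows = []
    all_records: list[MutationRecord] = []
    for line_id in sorted(line_callsets):
        calls = line_callsets[line_id]
        unique: list[VariantCall] = []
        n_nonunique = n_poolcalled = 0
        for c in calls:
            if line_count[c.key] > 1:
                n_nonunique += 1
                removal_stage[(line_id, *c.key)] = "uniqueness"
            elif any(k in pool_keys for k in _pool_key_variants(c)):
                n_poolcalled += 1
                removal_stage[(line_id, *c.key)] = "uniqueness"
            else:
                unique.append(c)

        qf = quality_filter(unique, t)
        for c, reasons in qf.rejected:
            removal_stage[(line_id, *c.key)] = "quality"
            quality_reasons.update(reasons)

        ps = pool_screen(qf.passed, pool_sites, t)
        for c in ps.removed:
            removal_stage[(line_id, *c.key)] = "pool_screen"

        accepted_calls = ps.passed
        flagged_calls = ps.flagged
        site_alt_count: Counter[tuple[str, int]] = Counter(
            (c.scaffold, c.pos) for c in accepted_calls
        )
        for c in accepted_calls + flagged_calls:
            rec = classify_mutation(c, genome, review_flag=c in flagged_calls)
            rec.multi_allelic_site = site_alt_count[(c.scaffold, c.pos)] > 1
            all_records.append(rec)

        rows.append(
            {
                "line_id": line_id,
                "input": len(calls),
                "removed_uniqueness": n_nonunique + n_poolcalled,
                "removed_quality": len(qf.rejected),
                "removed_pool_screen": len(ps.removed),
                "flagged_review": len(flagged_calls),
                "accepted": len(accepted_calls),
            }
        )

    summaries = callable_summaries(depth_tracks, pool_depth_track, t)
    attrition = pd.DataFrame(rows).set_index("line_id")
    all_records.sort(key=lambda r: (r.line_id, r.scaffold, r.pos, r.alt))
    return PipelineResult(
        records=all_records,
        callable=summaries,
        attrition=attrition,
        removal_stage=removal_stage,
        quality_reasons=quality_reasons,
    )
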