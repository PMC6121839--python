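"""Mutation-rate estimation for MA-line experiments.

The direct estimator is m / (callable sites x generations x ploidy factor):
``m`` accepted single-base mutations over an exposure measured in
site-generations.  Two exposure conventions coexist and are labelled
explicitly: per-line rates divide by callable x generations only
(``ploidy_factor=1``, diploid-genome rates), headline rates divide
additionally by 2 (``ploidy_factor=2``, per haploid genome) because each
sequenced genome accumulates mutations along two gamete chains.

Interval estimation treats the total count as Poisson with mean rate x
exposure.  The primary 95% CI is the exact Garwood interval

    [ chi2.ppf(alpha/2, 2m) / 2,  chi2.ppf(1 - alpha/2, 2m + 2) / 2 ] / E,

with a zero lower bound at m = 0.  An asymptotic Wald alternative on the
per-line mean count (lambda_hat +/- z * sqrt(lambda_hat / n_lines)) is
available behind a flag.

N_e follows from the population mutation parameter as theta / (4 mu).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dnmcall import CallableSummary, MutationRecord

__all__ = [
    "RateEstimate",
    "NeEstimate",
    "point_rate",
    "poisson_ml_ci",
    "wald_ci",
    "rate_table",
    "rate_table_from_counts",
    "counts_from_records",
    "effective_population_size",
    "round_sig",
]


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant digits (reporting convention)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + digits - 1)


@dataclass(frozen=True)
class RateEstimate:
    """Point rate with 95% CI, in mutations per site per generation."""

    category: str  # "overall" | "SNM" | "INS" | "DEL" | line id
    count: int
    exposure: float  # site-generations (x ploidy factor)
    rate: float
    ci_low: float
    ci_high: float
    method: str = "garwood"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.rate <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class NeEstimate:
    theta: float
    mu: float
    ne: float


def point_rate(
    m: int, callable_sum: float, generations: int, ploidy_factor: int = 1
) -> float:
    """Exact m / (callable x generations x ploidy_factor)."""
    if callable_sum <= 0:
        raise ValueError("zero exposure: callable_sum must be > 0")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if ploidy_factor not in (1, 2):
        raise ValueError("ploidy_factor must be 1 or 2")
    if m < 0:
        raise ValueError("negative count")
    return m / (callable_sum * generations * ploidy_factor)


def poisson_ml_ci(
    m: int, exposure: float, alpha: float = 0.05, category: str = "overall"
) -> RateEstimate:
    """Poisson ML point rate with the exact Garwood confidence interval."""
    if m < 0:
        raise ValueError("negative count")
    if exposure <= 0:
        raise ValueError("exposure must be > 0")
    lo = 0.0 if m == 0 else float(stats.chi2.ppf(alpha / 2, 2 * m)) / 2.0
    hi = float(stats.chi2.ppf(1 - alpha / 2, 2 * m + 2)) / 2.0
    return RateEstimate(
        category=category,
        count=m,
        exposure=exposure,
        rate=m / exposure,
        ci_low=lo / exposure,
        ci_high=hi / exposure,
        method="garwood",
    )


def wald_ci(
    per_line_counts: Sequence[int],
    exposure: float,
    alpha: float = 0.05,
    category: str = "overall",
) -> RateEstimate:
    """Asymptotic CI from the per-line mean count (normal approximation).

    ``lambda_hat`` is the mean count per line; its standard error is
    ``sqrt(lambda_hat / n)``.  Bounds are rescaled to rates by the total
    exposure; the lower bound is clipped at zero.
    """
    counts = np.asarray(per_line_counts, dtype=float)
    n = counts.size
    if n < 1:
        raise ValueError("need at least one line")
    lam = float(counts.mean())
    z = float(stats.norm.ppf(1 - alpha / 2))
    se = np.sqrt(lam / n)
    total = lam * n
    return RateEstimate(
        category=category,
        count=int(counts.sum()),
        exposure=exposure,
        rate=total / exposure,
        ci_low=max(0.0, (lam - z * se) * n / exposure),
        ci_high=(lam + z * se) * n / exposure,
        method="wald",
    )


COUNT_COLUMNS = [
    "callable_sites", "mutations", "snms", "alt_snm_sites",
    "insertions", "deletions", "ts", "tv",
]


def counts_from_records(
    mutations: Sequence[MutationRecord],
    callable: Sequence[CallableSummary],
) -> pd.DataFrame:
    """Tabulate per-line category counts from accepted mutation records.

    Only single-base events (SNMs and 1-bp indels) enter the ``mutations``
    total; 2-bp indels survive filtering but are excluded from rate totals.
    Review-flagged records are excluded.  SNM alternative alleles at
    multi-allelic sites are counted individually in ``snms`` but — because a
    site showing both a transition and a transversion belongs to neither
    class — excluded from the per-line ``ts``/``tv`` columns.
    """
    rows = []
    by_line: dict[str, list[MutationRecord]] = {c.line_id: [] for c in callable}
    for m in mutations:
        if m.review_flag:
            continue
        by_line.setdefault(m.line_id, []).append(m)
    callable_by_line = {c.line_id: c.callable_sites for c in callable}
    for line_id in sorted(by_line):
        recs = by_line[line_id]
        single = [m for m in recs if m.is_single_base]
        snms = [m for m in single if m.mtype == "SNM"]
        multi_sites = {
            (m.scaffold, m.pos) for m in snms if m.multi_allelic_site
        }
        biallelic = [m for m in snms if not m.multi_allelic_site]
        rows.append({
            "line_id": line_id,
            "callable_sites": callable_by_line.get(line_id, 0),
            "mutations": len(single),
            "snms": len(snms),
            "alt_snm_sites": len(multi_sites),
            "insertions": sum(m.mtype == "INS" for m in single),
            "deletions": sum(m.mtype == "DEL" for m in single),
            "ts": sum(m.ts_tv == "Ts" for m in biallelic),
            "tv": sum(m.ts_tv == "Tv" for m in biallelic),
        })
    return pd.DataFrame(rows).set_index("line_id")


def rate_table_from_counts(
    counts: pd.DataFrame,
    generations: int = 5,
    alpha: float = 0.05,
    wald: bool = False,
) -> tuple[pd.DataFrame, dict[str, RateEstimate]]:
    """Per-line and headline rates from a per-line category count table.

    ``counts`` must carry the columns of :data:`COUNT_COLUMNS` indexed by
    line id.  Per-line rates use ploidy factor 1 (diploid-genome rates); the
    SUM row and the returned headline estimates use ploidy factor 2 (per
    haploid genome) with Garwood (or Wald) 95% CIs.
    """
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (counts["callable_sites"] <= 0).any():
        raise ValueError("line with zero callable sites")

    table = counts.copy()
    diploid_exposure = table["callable_sites"] * generations
    table["mu"] = table["mutations"] / diploid_exposure
    table["mu_snm"] = table["snms"] / diploid_exposure

    sums = table[COUNT_COLUMNS].sum()
    total_callable = float(sums["callable_sites"])
    haploid_exposure = total_callable * generations * 2

    headline: dict[str, RateEstimate] = {}
    for category, column in (
        ("overall", "mutations"),
        ("SNM", "snms"),
        ("INS", "insertions"),
        ("DEL", "deletions"),
    ):
        m = int(sums[column])
        if wald:
            headline[category] = wald_ci(
                counts[column].to_numpy(), haploid_exposure, alpha, category
            )
        else:
            headline[category] = poisson_ml_ci(
                m, haploid_exposure, alpha, category
            )

    sum_row = sums.to_dict()
    sum_row["mu"] = headline["overall"].rate
    sum_row["mu_snm"] = headline["SNM"].rate
    table = pd.concat([table, pd.DataFrame([sum_row], index=["SUM"])])
    table.index.name = "line_id"
    return table, headline


def rate_table(
    mutations: Sequence[MutationRecord],
    callable: Sequence[CallableSummary],
    generations: int = 5,
    alpha: float = 0.05,
    wald: bool = False,
) -> tuple[pd.DataFrame, dict[str, RateEstimate]]:
    """Classified mutations + callable summaries -> per-line/headline rates."""
    counts = counts_from_records(mutations, callable)
    return rate_table_from_counts(counts, generations, alpha, wald)


def effective_population_size(theta: float, mu: float) -> NeEstimate:
    """N_e = theta / (4 mu) from the population mutation parameter."""
    if theta <= 0 or mu <= 0:
        raise ValueError("theta and mu must be > 0")
    return NeEstimate(theta=theta, mu=mu, ne=theta / (4.0 * mu))
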