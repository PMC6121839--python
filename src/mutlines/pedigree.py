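"""Transmission probabilities in a short full-sib MA pedigree.

A de novo mutation arises heterozygously on a single gamete transmitted to
one member of the generation-``g`` breeding pair (for ``g = G`` it arises on
a gamete forming the sequenced final-generation individual itself).  The line
is then propagated by full-sib matings: each subsequent breeding pair is two
independent offspring of the previous pair, and the sequenced individual is
one offspring of the last pair.  This module computes, by seeded Monte
Carlo over that chain,

* ``P_present(g)`` — the probability the sequenced individual carries the
  mutation at all,
* ``P_het(g)`` / ``P_hom(g)`` — its zygosity conditional on presence
  (``P_hom(G) = 0`` exactly: a mutation arising in the final transmission
  cannot be duplicated),

plus the sibling-confirmation probabilities of the validation design (exact
rational arithmetic) and the expected confirmable fraction under a uniform
prior over the origin generation: mutations arising in the last generation
exist only in the single sequenced individual, so with ``G`` generations a
fraction ``1/G`` of assayed candidates is unconfirmable by sibling
sequencing — 80% confirmable, 7.2 of 36 expected unconfirmable, for the
default five-generation design.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .simdata import PedigreeConfig
from .spectrum import SpectrumTestResult

__all__ = [
    "PedigreeStateProbs",
    "HomozygoteTest",
    "state_probabilities",
    "confirmation_probability",
    "expected_confirmable",
    "homozygote_expectation_test",
]


@dataclass
class PedigreeStateProbs:
    """Per origin generation g = 1..G: presence and zygosity probabilities."""

    n_generations: int
    reps: int
    p_present: np.ndarray
    p_het: np.ndarray  # conditional on presence
    p_hom: np.ndarray
    se_present: np.ndarray
    se_het: np.ndarray
    se_hom: np.ndarray
    prior: np.ndarray  # prior over origin generation (default uniform)

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "origin_generation": np.arange(1, self.n_generations + 1),
            "p_present": self.p_present,
            "p_het": self.p_het,
            "p_hom": self.p_hom,
            "se_present": self.se_present,
            "se_het": self.se_het,
            "se_hom": self.se_hom,
            "prior": self.prior,
        }).set_index("origin_generation")


def _binom_se(p: np.ndarray | float, n: int | np.ndarray) -> np.ndarray:
    n = np.maximum(np.asarray(n, dtype=float), 1.0)
    return np.sqrt(np.asarray(p) * (1.0 - np.asarray(p)) / n)


def state_probabilities(
    cfg: PedigreeConfig | int,
    reps: int = 100_000,
    seed: int = 0,
    prior: Sequence[float] | None = None,
) -> PedigreeStateProbs:
    """Monte-Carlo state probabilities over the full-sib transmission chain.

    ``cfg`` may be a :class:`~mutlines.simdata.PedigreeConfig` or simply the
    number of generations.  ``reps`` replicates are simulated per origin
    generation (at least 1e4 recommended for the reported precision); the
    per-probability Monte-Carlo standard errors are returned alongside.
    """
    G = cfg.n_generations if isinstance(cfg, PedigreeConfig) else int(cfg)
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if G < 2:
        raise ValueError("need at least two generations")
    rng = np.random.default_rng(seed)
    prior_arr = (
        np.full(G, 1.0 / G) if prior is None else np.asarray(prior, dtype=float)
    )
    if prior_arr.shape != (G,) or abs(prior_arr.sum() - 1.0) > 1e-9:
        raise ValueError("prior must be a length-G probability vector")

    p_present = np.zeros(G)
    p_het = np.zeros(G)
    p_hom = np.zeros(G)
    se_present = np.zeros(G)
    se_het = np.zeros(G)
    se_hom = np.zeros(G)

    for g in range(1, G + 1):
        if g == G:
            # arose on a gamete forming the sequenced individual itself
            p_present[g - 1], p_het[g - 1], p_hom[g - 1] = 1.0, 1.0, 0.0
            continue
        # allele counts (0/1/2) of the current breeding pair, per replicate
        a = np.ones(reps, dtype=np.int8)  # the mutant gamete's recipient
        b = np.zeros(reps, dtype=np.int8)

        def gamete(parent: np.ndarray) -> np.ndarray:
            return (rng.random(reps) < parent / 2.0).astype(np.int8)

        for step in range(g, G):
            if step < G - 1:
                a, b = gamete(a) + gamete(b), gamete(a) + gamete(b)
            else:
                f5 = gamete(a) + gamete(b)
        present = f5 > 0
        hom = f5 == 2
        n_present = int(present.sum())
        p_present[g - 1] = n_present / reps
        se_present[g - 1] = float(_binom_se(p_present[g - 1], reps))
        if n_present:
            p_hom[g - 1] = int(hom.sum()) / n_present
            p_het[g - 1] = 1.0 - p_hom[g - 1]
            se_hom[g - 1] = float(_binom_se(p_hom[g - 1], n_present))
            se_het[g - 1] = se_hom[g - 1]
    return PedigreeStateProbs(
        n_generations=G, reps=reps,
        p_present=p_present, p_het=p_het, p_hom=p_hom,
        se_present=se_present, se_het=se_het, se_hom=se_hom,
        prior=prior_arr,
    )


def confirmation_probability(
    n_siblings: int, parent_state: str = "single_het"
) -> Fraction:
    """Probability that >= 1 of ``n_siblings`` full sibs carries the mutation.

    ``parent_state`` describes the mutation in the sibs' parents:
    ``single_het`` (one heterozygous carrier parent; per-sib transmission
    1/2), ``both_het`` (per-sib carriage 3/4), or ``hom`` (a homozygous
    parent transmits always).  Exact rational arithmetic.
    """
    if n_siblings < 1:
        raise ValueError("n_siblings must be >= 1")
    per_sib_miss = {
        "single_het": Fraction(1, 2),
        "both_het": Fraction(1, 4),
        "hom": Fraction(0),
    }
    try:
        q = per_sib_miss[parent_state]
    except KeyError:
        raise ValueError(f"unknown parent_state {parent_state!r}") from None
    return 1 - q**n_siblings


def expected_confirmable(
    n_generations: int, n_assayed: int
) -> tuple[float, float]:
    """(confirmable fraction, expected unconfirmable count) under a uniform
    origin prior: only last-generation mutations are unconfirmable."""
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if n_generations == 1:
        return 0.0, float(n_assayed)
    fraction = 1.0 - 1.0 / n_generations
    return fraction, n_assayed / n_generations


@dataclass(frozen=True)
class HomozygoteTest:
    observed_hom: int
    expected_hom: float
    chi2: float
    p_value: float
    mc_se: float  # Monte-Carlo uncertainty of the expected count


def homozygote_expectation_test(
    observed_hom: int,
    n_confirmed: int,
    probs: PedigreeStateProbs,
    prior: Sequence[float] | None = None,
) -> HomozygoteTest:
    """Compare the observed homozygote count to the pedigree-model expectation.

    The expected homozygous fraction among observed (confirmed) mutations is
    the presence-weighted mixture of ``P_hom(g)`` over the origin prior; a
    one-df chi-square compares the hom/het split.  When the expectation is
    zero and homozygotes were observed, an exact binomial-style p of 0 is
    returned instead of the (undefined) chi-square.
    """
    if observed_hom > n_confirmed:
        raise ValueError("observed_hom cannot exceed n_confirmed")
    from scipy import stats

    w = np.asarray(prior, dtype=float) if prior is not None else probs.prior
    weights = w * probs.p_present
    total = weights.sum()
    p_hom_mean = float((weights * probs.p_hom).sum() / total)
    expected = n_confirmed * p_hom_mean
    var = ((weights / total) ** 2 * probs.se_hom**2).sum() * n_confirmed**2
    mc_se = float(np.sqrt(var))
    if expected == 0.0:
        return HomozygoteTest(
            observed_hom=observed_hom, expected_hom=0.0,
            chi2=float("inf") if observed_hom else 0.0,
            p_value=0.0 if observed_hom else 1.0, mc_se=mc_se,
        )
    exp_vec = np.array([expected, n_confirmed - expected])
    obs_vec = np.array([observed_hom, n_confirmed - observed_hom])
    chi2 = float((((obs_vec - exp_vec) ** 2) / exp_vec).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return HomozygoteTest(
        observed_hom=observed_hom, expected_hom=expected,
        chi2=chi2, p_value=p, mc_se=mc_se,
    )
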