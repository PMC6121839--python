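"""Spectrum tests: Ts/Tv, chi-square goodness of fit, run decomposition and
its iid expectations, indel/run association, genic overlap."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutlines import simdata, spectrum
from mutlines.dnmcall import MutationRecord
from mutlines.simdata import BaseComposition, Genome
from mutlines.spectrum import (
    at_gc_run_ratio,
    count_runs,
    expected_run_density,
    genic_overlap,
    gof_equal_chi2,
    run_enrichment_test,
    run_length_mutation_rate,
    ts_tv_from_counts,
    ts_tv_ratio,
)

from oracles import brute_force_cpg_runs, brute_force_runs, chi2_equal_manual


def indel_rec(pos, run_len, line="A1", mtype="DEL"):
    return MutationRecord(line_id=line, scaffold="s1", pos=pos, ref="GT",
                          alt="G", mtype=mtype, ts_tv="NA",
                          run_context_length=run_len)


class TestTsTv:
    def test_published_counts(self):
        assert ts_tv_from_counts(15, 11)[0] == 1.36

    def test_even_counts(self):
        assert ts_tv_from_counts(10, 10)[0] == 1.0

    def test_zero_tv_undefined_counts_reported(self):
        ratio, ts, tv = ts_tv_from_counts(4, 0)
        assert ratio is None and (ts, tv) == (4, 0)

    def test_records_match_hand_count(self, clean_experiment):
        genome, _, _, rcs = clean_experiment
        from conftest import run_chain

        recs = run_chain(genome, rcs).accepted()
        ratio, ts, tv = ts_tv_ratio(recs)
        hand_ts = sum(
            1 for m in recs if m.mtype == "SNM"
            and (m.ref, m.alt) in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        )
        assert ts == hand_ts
        assert tv == sum(m.mtype == "SNM" for m in recs) - hand_ts


class TestEqualChi2:
    @pytest.mark.parametrize("counts,chi2,p", [
        ((14, 7), 2.333, 0.127),
        ((8, 17), 3.240, 0.072),
        ((10, 10), 0.0, 1.0),
    ])
    def test_reported_statistics(self, counts, chi2, p):
        r = gof_equal_chi2(*counts)
        assert r.statistic == pytest.approx(chi2, abs=5e-4)
        assert r.p_value == pytest.approx(p, abs=5e-4)
        assert r.df == 1

    @given(n1=st.integers(0, 500), n2=st.integers(0, 500))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_textbook_formula(self, n1, n2):
        if n1 + n2 == 0:
            return
        r = gof_equal_chi2(n1, n2)
        assert r.statistic == pytest.approx(chi2_equal_manual(n1, n2))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            gof_equal_chi2(0, 0)


class TestCountRuns:
    def test_hand_decomposition(self):
        spec = count_runs(Genome(scaffolds={"s": "AAAACGT"}))
        assert spec.counts["A"] == Counter({4: 1})
        assert spec.counts["C"] == Counter({1: 1})
        assert spec.counts["G"] == Counter({1: 1})
        assert spec.counts["T"] == Counter({1: 1})

    def test_cpg_tandem_repeat(self):
        spec = count_runs(Genome(scaffolds={"s": "CGCGCG"}))
        assert spec.counts["CpG"] == Counter({3: 1})

    def test_runs_do_not_span_scaffolds(self):
        spec = count_runs(Genome(scaffolds={"a": "AAA", "b": "AAA"}))
        assert spec.counts["A"] == Counter({3: 2})

    def test_non_acgt_masked(self):
        spec = count_runs(Genome(scaffolds={"s": "AANNAA"}))
        assert spec.masked_positions == 2
        assert spec.counts["A"] == Counter({2: 2})

    def test_matches_brute_force_scanner(self):
        g = simdata.generate_genome(
            200_000, BaseComposition.from_at_content(0.69), 1, seed=99)
        spec = count_runs(g)
        seq = g.scaffolds["scaffold_1"]
        assert {b: spec.counts[b] for b in "ACGT"} == brute_force_runs(seq)
        assert spec.counts["CpG"] == brute_force_cpg_runs(seq)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_decomposition_conserves_base_totals(self, seq):
        spec = count_runs(Genome(scaffolds={"s": seq}))
        for b in "ACGT":
            assert sum(L * n for L, n in spec.counts[b].items()) == seq.count(b)


class TestExpectedRunDensity:
    def test_uniform_L5_closed_form(self):
        d = expected_run_density(BaseComposition.uniform(), "A", 5)
        assert d == pytest.approx(1e6 * 0.25**5 * 0.75**2)
        assert d == pytest.approx(549.3, abs=0.1)

    def test_singleton_density_matches_simulation(self):
        comp = BaseComposition.from_at_content(0.6)
        expected = sum(expected_run_density(comp, b, 1) for b in "ACGT")
        obs = []
        for seed in range(5):
            g = simdata.generate_genome(200_000, comp, 1, seed=200 + seed)
            spec = count_runs(g)
            obs.append(sum(spec.counts[b][1] for b in "ACGT") / 0.2)
        assert abs(np.mean(obs) - expected) <= 3 * np.std(obs, ddof=1)

    def test_degenerate_composition_limit(self):
        comp = BaseComposition(0.999999, 1e-6 / 3, 1e-6 / 3, 1e-6 / 3)
        assert expected_run_density(comp, "A", 5) < 1e-5


class TestAtGcRunRatio:
    def test_symmetric_composition(self):
        for L in (1, 3, 8):
            assert at_gc_run_ratio(0.5, L) == pytest.approx(1.0)

    def test_biased_composition_L5(self):
        # (0.345/0.155)^5 * (0.655/0.845)^2
        assert at_gc_run_ratio(0.69, 5) == pytest.approx(32.83, abs=0.05)

    def test_long_run_at_share_band(self, at_genome):
        spec = count_runs(at_genome)
        at = spec.runs_at_least("AT", 5)
        share = at / (at + spec.runs_at_least("GC", 5))
        assert 0.97 <= share <= 0.995


class TestRunEnrichment:
    def spectrum_with_run_fraction(self, frac, genome_length=1_000_000):
        """Synthetic run spectrum whose >= 5 A-run positions cover ``frac``."""
        n_runs = int(genome_length * frac / 5)
        counts = {b: Counter() for b in "ACGT"}
        counts["CpG"] = Counter()
        counts["A"][5] = n_runs
        rest = genome_length - 5 * n_runs
        counts["T"][1] = rest
        return spectrum.RunSpectrum(genome_length=genome_length, counts=counts)

    def test_strong_enrichment_significant(self):
        spec = self.spectrum_with_run_fraction(0.05)
        muts = [indel_rec(i, 6) for i in range(21)] + [
            indel_rec(100 + i, 1) for i in range(4)
        ]
        r = run_enrichment_test(muts, spec, min_len=5, cls="AT")
        assert r.p_value < 1e-6
        assert r.observed == (21, 4)

    def test_null_proportion_not_significant(self):
        spec = self.spectrum_with_run_fraction(0.2)
        muts = [indel_rec(i, 6) for i in range(4)] + [
            indel_rec(100 + i, 1) for i in range(16)
        ]
        r = run_enrichment_test(muts, spec, min_len=5, cls="AT")
        assert r.p_value >= 0.5

    def test_zero_indels_rejected(self):
        with pytest.raises(ValueError):
            run_enrichment_test([], self.spectrum_with_run_fraction(0.05))

    def test_calibration_under_uniform_placement(self, at_genome):
        """P-values are roughly uniform when indels land uniformly."""
        from scipy.stats import kstest

        spec = count_runs(at_genome)
        frac = spec.sites_in_runs("AT", 5) / spec.genome_length
        seq = "".join(at_genome.scaffolds.values())
        runlen = simdata._run_length_per_position(at_genome)
        is_at = np.frombuffer(seq.encode(), dtype=np.uint8)
        at_run = (runlen >= 5) & ((is_at == ord("A")) | (is_at == ord("T")))
        rng = np.random.default_rng(1234)
        pvals = []
        for _ in range(100):
            hits = rng.integers(0, len(seq), size=400)
            k = int(at_run[hits].sum())
            from scipy.stats import binomtest

            pvals.append(binomtest(k, 400, frac).pvalue)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestRunLengthRate:
    def make_spectrum(self):
        counts = {b: Counter() for b in "ACGT"}
        counts["CpG"] = Counter()
        for L, n in [(1, 10000), (2, 5000), (5, 500), (8, 50)]:
            counts["A"][L] = n
        return spectrum.RunSpectrum(genome_length=100_000, counts=counts)

    def test_no_indels_zero_curve(self):
        df, trend = run_length_mutation_rate([], self.make_spectrum(), 5, 10)
        assert (df["n_indels"] == 0).all()
        assert trend.p_value == 1.0

    def test_zero_run_lengths_flagged(self):
        df, _ = run_length_mutation_rate(
            [indel_rec(1, 3)], self.make_spectrum(), 5, 10,
            lengths=[1, 2, 3, 5])
        row = df.set_index("run_length").loc[3]
        assert bool(row["undefined"]) and math.isnan(row["rate"])

    def test_affinity_increasing_in_length_recovered(self, at_genome,
                                                     small_pedigree):
        from conftest import run_chain

        truth = simdata.inject_mutations(
            small_pedigree, at_genome, 0.0, mu_ins=2e-6, mu_del=4e-6,
            run_affinity=lambda L: float(3 ** min(L, 10)), seed=6)
        rcs = simdata.render_callsets(small_pedigree, truth, at_genome, seed=7)
        recs = run_chain(at_genome, rcs).accepted()
        spec = count_runs(at_genome)
        df, trend = run_length_mutation_rate(recs, spec, 5, 10,
                                             lengths=range(1, 11))
        assert trend.rho > 0.8
        assert trend.p_value < 0.05


class TestGenicOverlap:
    def test_published_style_deficit(self):
        muts = [indel_rec(i * 100, 0) for i in range(51)]
        intervals = {"s1": [(0, 10)]}  # only one mutation can be genic
        r = genic_overlap(muts[:1] + muts[1:], intervals, 0.15)
        assert r.observed[0] == 0 or r.observed[0] == 1
        r = genic_overlap(muts, {"s1": [(95, 105)]}, 0.15)
        assert r.observed[0] == 1
        assert r.p_value < 0.01

    def test_interval_scan_matches_manual_count(self):
        muts = [indel_rec(p, 0) for p in (1, 5, 10, 20, 30)]
        intervals = {"s1": [(0, 5), (18, 25)]}
        r = genic_overlap(muts, intervals, 0.4)
        # genic: pos 1 (0-based 0 in [0,5)), pos 5 (4 in [0,5)), pos 20 (19)
        assert r.observed[0] == 3

    def test_zero_fraction_handling(self):
        muts = [indel_rec(1, 0)]
        assert genic_overlap(muts, {"s1": [(0, 5)]}, 0.0).p_value == 0.0
        no_hit = genic_overlap([indel_rec(50, 0)], {"s1": [(0, 5)]}, 0.0)
        assert no_hit.p_value == 1.0

    def test_malformed_intervals_rejected(self):
        with pytest.raises(ValueError):
            genic_overlap([indel_rec(1, 0)], {"s1": [(5, 2)]}, 0.1)
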