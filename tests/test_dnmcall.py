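"""Filter-chain tests: uniqueness, quality predicates, pool screen,
callable-site accounting, classification, and full-pipeline behaviour."""

import dataclasses
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from mutlines import dnmcall, simdata
from mutlines.dnmcall import (
    FilterThresholds,
    PoolSite,
    VariantCall,
    count_callable_sites,
    intersect_unique,
    pool_screen,
    quality_filter,
    run_context_length,
)

from conftest import run_chain
from oracles import brute_force_callable


def vc(line="A1", scaffold="s1", pos=100, ref="G", alt="A", gq=95.0, sor=1.0,
       dp=20, alt_count=8, genotype="het"):
    return VariantCall(line_id=line, scaffold=scaffold, pos=pos, ref=ref,
                       alt=alt, gq=gq, sor=sor, dp=dp, alt_count=alt_count,
                       genotype=genotype)


class TestIntersectUnique:
    def test_shared_variant_removed_from_both(self):
        shared_a = vc(line="A1")
        shared_b = vc(line="A2")
        only_a = vc(line="A1", pos=200)
        out = intersect_unique({"A1": [shared_a, only_a], "A2": [shared_b]},
                               pool_callset=set())
        assert out["A1"] == [only_a]
        assert out["A2"] == []

    def test_pool_called_variant_removed(self):
        a = vc(line="A1")
        out = intersect_unique({"A1": [a], "A2": []},
                               pool_callset={a.key})
        assert out["A1"] == []
        # wildcard pool keys (allele called in pool, ref unknown) also match
        out = intersect_unique({"A1": [a], "A2": []},
                               pool_callset={("s1", 100, "*", "A")})
        assert out["A1"] == []

    def test_two_alts_same_site_both_retained(self):
        g_to_c = vc(line="A2", alt="C")
        g_to_a = vc(line="A2", alt="A")
        out = intersect_unique({"A1": [], "A2": [g_to_c, g_to_a]}, set())
        assert out["A2"] == [g_to_c, g_to_a]

    def test_duplicate_key_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            intersect_unique({"A1": [vc(), vc()], "A2": []}, set())

    def test_needs_two_lines(self):
        with pytest.raises(ValueError):
            intersect_unique({"A1": []}, set())


class TestQualityFilter:
    def test_all_pass(self):
        out = quality_filter([vc(gq=95, sor=1, dp=20, alt_count=6)])
        assert len(out.passed) == 1 and not out.rejected

    @pytest.mark.parametrize("kwargs,reason", [
        (dict(gq=90.0), "GQ"),  # "above 90" is strict
        (dict(sor=4.5), "SOR"),
        (dict(dp=45), "DP"),
        (dict(dp=14), "DP"),
        (dict(alt_count=4), "ALT_COUNT"),
        (dict(ref="G", alt="ACGA"), "INDEL_LEN"),
    ])
    def test_single_predicate_failures(self, kwargs, reason):
        out = quality_filter([vc(**kwargs)])
        assert not out.passed
        assert reason in out.rejected[0][1]

    @pytest.mark.parametrize("kwargs", [
        dict(gq=90.01),
        dict(sor=4.0),  # SOR > 4 removed, 4 kept
        dict(dp=15), dict(dp=44),  # inclusive depth bounds
        dict(alt_count=5),
        dict(ref="G", alt="GTT"),  # 2-bp insertion allowed through
    ])
    def test_boundary_values_pass(self, kwargs):
        assert quality_filter([vc(**kwargs)]).passed

    def test_designed_toy_set(self):
        """Ten records, each tripping exactly one filter (or none)."""
        records = [
            vc(pos=1),                                  # survivor
            vc(pos=2, gq=80),                           # GQ
            vc(pos=3, gq=90),                           # GQ boundary
            vc(pos=4, sor=9.0),                         # SOR
            vc(pos=5, dp=50, alt_count=25),             # DP high
            vc(pos=6, dp=10, alt_count=5),              # DP low
            vc(pos=7, alt_count=2),                     # allele count
            vc(pos=8, ref="A", alt="ATTT"),             # indel length 3
            vc(pos=9, gq=None),                         # missing annotation
            vc(pos=10),                                 # survivor
        ]
        out = quality_filter(records)
        assert [c.pos for c in out.passed] == [1, 10]
        assert out.reasons() == Counter({
            "GQ": 2, "SOR": 1, "DP": 2, "ALT_COUNT": 1, "INDEL_LEN": 1,
            "missing:GQ": 1,
        })

    def test_missing_annotations_counted_not_dropped(self):
        out = quality_filter([vc(sor=None, dp=None)])
        assert out.rejected[0][1] == ("missing:SOR", "missing:DP")

    @given(
        gq=st.one_of(st.none(), st.floats(0, 200)),
        sor=st.one_of(st.none(), st.floats(0, 10)),
        dp=st.integers(0, 60),
        alt_frac=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_partition_and_predicate_soundness(self, gq, sor, dp, alt_frac):
        c = vc(gq=gq, sor=sor, dp=dp, alt_count=int(dp * alt_frac))
        out = quality_filter([c])
        assert len(out.passed) + len(out.rejected) == 1
        if out.passed:
            t = FilterThresholds()
            assert gq > t.gq_min and sor <= t.sor_max
            assert t.dp_min <= dp <= t.dp_max
            assert c.alt_count >= t.alt_min

    def test_tightening_monotonicity(self):
        """Tightening any threshold never increases the surviving count."""
        base = FilterThresholds()
        records = [vc(pos=i, gq=85 + i, sor=i / 4, dp=10 + 2 * i,
                      alt_count=min(10 + 2 * i, i)) for i in range(1, 20)]
        n_base = len(quality_filter(records, base).passed)
        for tighter in [
            dataclasses.replace(base, gq_min=95),
            dataclasses.replace(base, sor_max=2),
            dataclasses.replace(base, dp_min=20),
            dataclasses.replace(base, dp_max=35),
            dataclasses.replace(base, alt_min=8),
            dataclasses.replace(base, indel_len_max=0),
        ]:
            assert len(quality_filter(records, tighter).passed) <= n_base


class TestPoolScreen:
    def site(self, alt_n, pos=100, depth=60, allele="A"):
        counts = {b: 0 for b in "ACGT"} | {"INS": 0, "DEL": 0}
        counts[allele] = alt_n
        counts["G"] = depth - alt_n if allele != "G" else counts["G"]
        return PoolSite(scaffold="s1", pos=pos, depth=depth,
                        allele_counts=counts)

    def test_zero_support_retained(self):
        out = pool_screen([vc()], {("s1", 100): self.site(0)})
        assert out.passed and not out.removed

    def test_single_read_removes(self):
        out = pool_screen([vc()], {("s1", 100): self.site(1)})
        assert out.removed and not out.passed

    def test_missing_site_flagged_for_review(self):
        out = pool_screen([vc()], {})
        assert out.flagged and not out.passed and not out.removed

    def test_indel_support_uses_indel_counters(self):
        ins = vc(ref="A", alt="AT")
        counts = {b: 0 for b in "ACGT"} | {"INS": 2, "DEL": 0, "A": 58}
        site = PoolSite(scaffold="s1", pos=100, depth=60, allele_counts=counts)
        assert pool_screen([ins], {("s1", 100): site}).removed

    def test_configurable_tolerance(self):
        t = FilterThresholds(pool_alt_max=2)
        out = pool_screen([vc()], {("s1", 100): self.site(2)}, t)
        assert out.passed


class TestCallableSites:
    def test_zero_depth_track(self):
        assert count_callable_sites([("s1", 0, 100, 0)],
                                    [("s1", 0, 100, 60)]) == 0

    def test_known_in_range_positions(self):
        line = [("s1", 0, 400, 10), ("s1", 400, 1400, 25), ("s1", 1400, 1500, 50)]
        pool = [("s1", 0, 1500, 60)]
        assert count_callable_sites(line, pool) == 1000

    def test_pool_depth_condition(self):
        line = [("s1", 0, 1000, 25)]
        pool = [("s1", 0, 300, 5), ("s1", 300, 1000, 60)]
        assert count_callable_sites(line, pool) == 700
        t = FilterThresholds(require_pool_depth_for_callable=False)
        assert count_callable_sites(line, pool, t) == 1000

    def test_unsorted_track_rejected(self):
        with pytest.raises(ValueError, match="unsorted|overlap"):
            count_callable_sites([("s1", 100, 200, 20), ("s1", 50, 150, 20)],
                                 [("s1", 0, 300, 60)])

    def test_matches_brute_force_on_noisy_tracks(self, noisy_experiment):
        _, _, _, rcs = noisy_experiment
        t = FilterThresholds()
        for line_id in list(rcs.depth_tracks)[:3]:
            track = [iv for iv in rcs.depth_tracks[line_id]
                     if iv[0] == "scaffold_1" and iv[1] < 30_000]
            pool = [iv for iv in rcs.pool_depth_track
                    if iv[0] == "scaffold_1" and iv[1] < 30_000]
            assert count_callable_sites(track, pool, t) == \
                brute_force_callable(track, pool, t.dp_min, t.dp_max)


class TestClassify:
    @pytest.fixture()
    def toy_genome(self):
        return simdata.Genome(scaffolds={
            "s1": "ACGTACGTGGAAAAAACCGTACGTT",
        })

    def test_transition_gc_to_at(self, toy_genome):
        rec = dnmcall.classify_mutation(vc(scaffold="s1", pos=9, ref="G",
                                           alt="A"), toy_genome)
        assert (rec.mtype, rec.ts_tv, rec.gc_at_direction) == \
            ("SNM", "Ts", "GCtoAT")

    def test_transversion_within_class(self, toy_genome):
        rec = dnmcall.classify_mutation(vc(scaffold="s1", pos=9, ref="G",
                                           alt="C"), toy_genome)
        assert (rec.mtype, rec.ts_tv, rec.gc_at_direction) == \
            ("SNM", "Tv", "within_class")

    def test_deletion_in_homopolymer_context(self, toy_genome):
        # 1-bp deletion of the first A of the AAAAAA stretch (positions 11-16)
        rec = dnmcall.classify_mutation(vc(scaffold="s1", pos=10, ref="GA",
                                           alt="G"), toy_genome)
        assert rec.mtype == "DEL"
        assert rec.run_context_length >= 6

    def test_adjacent_run_counts(self, toy_genome):
        # insertion anchored right before the A-run: run is adjacent (+1)
        rec = dnmcall.classify_mutation(vc(scaffold="s1", pos=10, ref="G",
                                           alt="GA"), toy_genome)
        assert rec.mtype == "INS"
        assert rec.run_context_length == 6

    def test_ref_equal_alt_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            dnmcall.classify_mutation(vc(ref="G", alt="G"), toy_genome)

    def test_run_context_scan(self):
        assert run_context_length("AAAAAACG", 2, 3) == 6
        assert run_context_length("CGAAAAAA", 1, 2) == 6  # adjacent window
        assert run_context_length("ACGT", 1, 2) == 1


class TestPipeline:
    def test_clean_fixture_identity(self, clean_experiment):
        genome, _, truth, rcs = clean_experiment
        result = run_chain(genome, rcs)
        accepted = {(m.line_id, *m.key) for m in result.accepted()}
        assert accepted == {(m.line_id, *m.key) for m in truth}

    def test_contaminants_removed_at_designed_stage(self, noisy_experiment):
        genome, _, truth, rcs = noisy_experiment
        result = run_chain(genome, rcs)
        expected_stage = {"shared": {"uniqueness", "pool_screen"},
                          "error": {"quality"},
                          "pool_low": {"pool_screen"}}
        for key, kind in rcs.contaminants.items():
            assert result.removal_stage.get(key) in expected_stage[kind], \
                (key, kind, result.removal_stage.get(key))

    def test_noisy_losses_all_attributed(self, noisy_experiment):
        genome, _, truth, rcs = noisy_experiment
        result = run_chain(genome, rcs)
        accepted = {(m.line_id, *m.key) for m in result.accepted()}
        for m in truth:
            key = (m.line_id, *m.key)
            assert key in accepted or key in result.removal_stage

    def test_precision_on_noisy_fixture(self, noisy_experiment):
        genome, _, truth, rcs = noisy_experiment
        result = run_chain(genome, rcs)
        accepted = {(m.line_id, *m.key) for m in result.accepted()}
        truth_keys = {(m.line_id, *m.key) for m in truth}
        tp = len(accepted & truth_keys)
        assert tp / len(accepted) >= 0.95

    def test_attrition_bookkeeping_sums(self, noisy_experiment):
        genome, _, _, rcs = noisy_experiment
        result = run_chain(genome, rcs)
        att = result.attrition
        lhs = att["input"]
        rhs = (att["removed_uniqueness"] + att["removed_quality"]
               + att["removed_pool_screen"] + att["flagged_review"]
               + att["accepted"])
        assert (lhs == rhs).all()

    def test_stagewise_equals_pipeline(self, clean_experiment):
        """Applying the stages one by one reproduces run_pipeline's output."""
        genome, _, _, rcs = clean_experiment
        result = run_chain(genome, rcs)
        unique = intersect_unique(rcs.line_calls, rcs.pool_calls)
        pool_map = {(s.scaffold, s.pos): s for s in rcs.pool_sites}
        stagewise = set()
        for line_id, cands in unique.items():
            kept = quality_filter(cands).passed
            kept = pool_screen(kept, pool_map).passed
            stagewise |= {(line_id, *c.key) for c in kept}
        assert stagewise == {(m.line_id, *m.key) for m in result.accepted()}

    def test_predicate_order_invariance(self):
        """One-at-a-time threshold application in any order = joint filter."""
        import itertools

        records = [vc(pos=i, gq=88 + i, sor=i / 3, dp=12 + i,
                      alt_count=min(12 + i, i)) for i in range(1, 15)]
        joint = {c.pos for c in quality_filter(records).passed}
        axes = {
            "gq": dict(sor_max=1e9, indel_len_max=99, dp_min=0, dp_max=10**9,
                       alt_min=0),
            "sor": dict(gq_min=0.0, indel_len_max=99, dp_min=0, dp_max=10**9,
                        alt_min=0),
            "dp": dict(gq_min=0.0, sor_max=1e9, indel_len_max=99, alt_min=0),
            "alt": dict(gq_min=0.0, sor_max=1e9, indel_len_max=99, dp_min=0,
                        dp_max=10**9),
        }
        for order in itertools.permutations(axes):
            kept = records
            for axis in order:
                t = FilterThresholds(**({"gq_min": 90.0, "sor_max": 4.0,
                                         "indel_len_max": 2, "dp_min": 15,
                                         "dp_max": 44, "alt_min": 5}
                                        | axes[axis]))
                kept = quality_filter(kept, t).passed
            assert {c.pos for c in kept} == joint
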