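"""Genotype likelihood models: per-read terms, products, coverage model,
aggregation, decomposition and cohort filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graphsv.genotype import (GENOTYPES, CoverageProfile, GenotypeCall,
                              HighConfidenceFilter, ModelNotApplicable,
                              aggregate_call, breakpoint_genotype,
                              coverage_genotype, coverage_profile,
                              decompose_multiallelic, decompose_supports,
                              filter_calls, lower_median, per_read_likelihood)
from graphsv.graph import SmallVariant
from graphsv.realign import NONE_SUPPORT, AlleleSupport, ExtractedRead


def mk_read(paired=True):
    return ExtractedRead(name="r", sequence="ACGT" * 40, is_paired=paired,
                         is_first=True, mate_mapped_in_region=False)


def sup(alleles, paired=True, mate_on_graph=True):
    return AlleleSupport(read=mk_read(paired), site_id=0,
                         supported_alleles=frozenset(alleles),
                         mate_on_graph=mate_on_graph)


def oracle_likelihoods(supports):
    """Independent direct-product oracle for the three genotypes."""
    out = []
    for x, y in GENOTYPES:
        L = 1.0
        for s in supports:
            nx = x in s.supported_alleles
            ny = y in s.supported_alleles
            if nx and ny:
                L *= 1.0
            elif nx or ny:
                L *= 0.5
            else:
                eps = (2.0 ** -8 if s.read.is_paired and s.mate_on_graph
                       else 2.0 ** -4)
                L *= eps
        out.append(L)
    return out


class TestPerReadLikelihood:
    def test_both_alleles_supported_gives_one(self):
        assert per_read_likelihood(sup({0, 1}), 0, 1) == 1.0
        assert per_read_likelihood(sup({0}), 0, 0) == 1.0

    def test_exactly_one_gives_half(self):
        assert per_read_likelihood(sup({0}), 0, 1) == 0.5
        assert per_read_likelihood(sup({1}), 0, 1) == 0.5

    def test_neither_gives_epsilon_by_pairing(self):
        assert per_read_likelihood(sup({1}, paired=True, mate_on_graph=True),
                                   0, 0) == 2.0 ** -8
        assert per_read_likelihood(sup({1}, paired=True, mate_on_graph=False),
                                   0, 0) == 2.0 ** -4
        assert per_read_likelihood(sup({1}, paired=False,
                                       mate_on_graph=False), 0, 0) == 2.0 ** -4
        assert per_read_likelihood(sup(NONE_SUPPORT), 0, 1) == 2.0 ** -8


class TestBreakpointGenotype:
    def test_three_ref_two_alt_reads_called_het(self):
        supports = [sup({0}) for _ in range(3)] + [sup({1}) for _ in range(2)]
        gl = breakpoint_genotype(supports)
        assert gl.log10 == pytest.approx(
            [math.log10((2.0 ** -8) ** 2), math.log10(0.5 ** 5),
             math.log10((2.0 ** -8) ** 3)])
        assert gl.best_genotype == (0, 1)
        assert (gl.n_ref, gl.n_alt) == (3, 2)

    def test_ref_only_reads_called_homref_with_unit_likelihood(self):
        gl = breakpoint_genotype([sup({0}) for _ in range(10)])
        assert gl.best_genotype == (0, 0)
        assert gl.log10[0] == 0.0

    def test_empty_support_is_uninformative(self):
        gl = breakpoint_genotype([], site_id=3)
        assert gl.log10 == (0.0, 0.0, 0.0)
        assert gl.gq == 0

    def test_mixed_sites_rejected(self):
        a, b = sup({0}), sup({1})
        b.site_id = 7
        with pytest.raises(ValueError, match="multiple sites"):
            breakpoint_genotype([a, b])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.sampled_from([(), (0,), (1,), (0, 1)]),
                  st.booleans(), st.booleans()),
        min_size=0, max_size=12))
    def test_matches_direct_product_oracle(self, pattern):
        supports = [sup(set(a), paired=p, mate_on_graph=m)
                    for a, p, m in pattern]
        gl = breakpoint_genotype(supports)
        expected = oracle_likelihoods(supports)
        for got_log, exp in zip(gl.log10, expected):
            assert got_log == pytest.approx(math.log10(exp), rel=1e-12)

    def test_order_invariance(self, rng):
        opts = [(), (0,), (1,), (0, 1)]
        supports = [sup(set(opts[i])) for i in rng.integers(0, 4, size=10)]
        gl1 = breakpoint_genotype(supports)
        gl2 = breakpoint_genotype(list(reversed(supports)))
        assert gl1.log10 == gl2.log10

    def test_alt_read_monotonicity(self, rng):
        opts = [(0,), (1,), (0, 1)]
        supports = [sup(set(opts[i])) for i in rng.integers(0, 3, size=8)]
        base = breakpoint_genotype(supports)
        more = breakpoint_genotype(supports + [sup({1})])
        assert more.log10[0] <= base.log10[0]       # L00 never increases
        assert more.log10[2] - base.log10[2] >= math.log10(0.5) - 1e-12


class TestCoverageModel:
    def test_het_deletion_example(self):
        gl = coverage_genotype(CoverageProfile(0, c_in=14, c_out=30), "DEL")
        assert (gl.n_alt, gl.n_ref) == (16, 14)
        assert gl.best_genotype == (0, 1)

    def test_hom_deletion_example(self):
        gl = coverage_genotype(CoverageProfile(0, c_in=0, c_out=30), "DEL")
        assert (gl.n_alt, gl.n_ref) == (30, 0)
        assert gl.best_genotype == (1, 1)

    def test_no_coverage_change_is_homref(self):
        gl = coverage_genotype(CoverageProfile(0, c_in=30, c_out=30), "DEL")
        assert gl.n_alt == 0
        assert gl.best_genotype == (0, 0)

    def test_duplication_uses_coverage_increase(self):
        # het DUP: increase c_out/2 supports the extra copy, the
        # non-duplicated allele's share (2·c_out − c_in) supports ref
        gl = coverage_genotype(CoverageProfile(0, c_in=45, c_out=30), "DUP")
        assert (gl.n_alt, gl.n_ref) == (15, 15)
        assert gl.best_genotype == (0, 1)

    def test_homozygous_duplication_called_from_doubled_coverage(self):
        gl = coverage_genotype(CoverageProfile(0, c_in=60, c_out=30), "DUP")
        assert (gl.n_alt, gl.n_ref) == (30, 0)
        assert gl.best_genotype == (1, 1)

    def test_not_applicable_types_signal(self):
        for t in ("INS", "INV", "BND"):
            with pytest.raises(ModelNotApplicable):
                coverage_genotype(CoverageProfile(0, 10, 10), t)

    def test_matches_pseudo_read_oracle(self):
        # every pseudo-read is unambiguous and unpaired (ε = 2⁻⁴)
        prof = CoverageProfile(0, c_in=14, c_out=30)
        gl = coverage_genotype(prof, "DEL")
        pseudo = ([sup({0}, paired=False) for _ in range(14)]
                  + [sup({1}, paired=False) for _ in range(16)])
        ora = breakpoint_genotype(pseudo)
        assert gl.log10 == pytest.approx(ora.log10, rel=1e-12)

    def test_lower_median_for_even_counts(self):
        assert lower_median([1, 2, 3, 4]) == 2
        assert lower_median([5]) == 5
        assert lower_median([]) == 0

    def test_profile_sampling_and_exclusion(self):
        from graphsv.sites import SVSite
        site = SVSite("c", 5000, 6000, "DEL", 1000)
        depth = lambda p: 10 if 5000 <= p < 6000 else 30
        prof = coverage_profile(depth, site)
        assert (prof.c_in, prof.c_out) == (10, 30)
        # positions inside a neighbouring SV are excluded from the median
        prof2 = coverage_profile(lambda p: 0 if p < 5000 else depth(p),
                                 site, exclude_spans=[(4000, 5000)])
        assert prof2.c_out == 30


class TestAggregation:
    def _gl(self, logs, model="BREAKPOINT"):
        from graphsv.genotype import GenotypeLikelihoods
        return GenotypeLikelihoods(0, "s", model, tuple(logs))

    def test_higher_gq_model_wins(self):
        bp = self._gl([-4.5, 0.0, -9.0])          # 0/1, GQ 45
        cov = self._gl([0.0, -1.2, -9.0], "COVERAGE")   # 0/0, GQ 12
        call = aggregate_call(bp, cov)
        assert call.genotype == (0, 1)

    def test_single_model_passthrough(self):
        bp = self._gl([-4.5, 0.0, -9.0])
        call = aggregate_call(bp, None)
        assert call.genotype == (0, 1) and call.model_used == "BREAKPOINT"

    def test_agreement_takes_max_gq(self):
        bp = self._gl([-9.0, -4.0, 0.0])          # 1/1, GQ 40
        cov = self._gl([-9.9, -6.0, 0.0], "COVERAGE")   # 1/1, GQ 60
        call = aggregate_call(bp, cov)
        assert call.genotype == (1, 1)
        assert call.gq == 60

    def test_gq_capped_at_99(self):
        assert self._gl([0.0, -50.0, -99.0]).gq == 99


class TestDecomposition:
    def test_identity_for_biallelic(self):
        from graphsv.sites import SVSite
        s = SVSite("c", 100, 600, "DEL", 500)
        assert decompose_multiallelic(s) == [s]

    def test_triallelic_splits_to_three(self):
        smv = SmallVariant("c", 100, "A", ("C", "G", "T"))
        parts = decompose_multiallelic(smv)
        assert len(parts) == 3
        assert {p.alts[0] for p in parts} == {"C", "G", "T"}

    @given(st.integers(1, 6))
    @settings(deadline=None)
    def test_alt_union_preserved(self, k):
        alts = tuple(f"A{'C' * i}" for i in range(1, k + 1))
        parts = decompose_multiallelic(SmallVariant("c", 10, "A", alts))
        assert {p.alts[0] for p in parts} == set(alts)

    def test_other_alt_support_maps_to_none(self):
        supports = [sup({0}), sup({2}), sup({1, 2}), sup({1})]
        views = decompose_supports(supports, 2)
        v1 = [v.supported_alleles for v in views[0]]
        assert v1 == [frozenset({0}), NONE_SUPPORT, frozenset({1}),
                      frozenset({1})]
        v2 = [v.supported_alleles for v in views[1]]
        assert v2 == [frozenset({0}), frozenset({1}), frozenset({1}),
                      NONE_SUPPORT]


def _call(sample, gt, gq=50):
    logs = [-9.0, -9.0, -9.0]
    logs[GENOTYPES.index(gt)] = 0.0
    return GenotypeCall(0, sample, gt, "BREAKPOINT", gq, tuple(logs))


class TestFilterCalls:
    def test_all_reference_site_dropped(self):
        calls = {0: [_call(f"s{i}", (0, 0)) for i in range(10)]}
        assert filter_calls(calls) == {}

    def test_single_het_retained(self):
        calls = {0: [_call("s0", (0, 1))]}
        kept = filter_calls(calls)
        assert 0 in kept
        assert kept[0][0].passed_filters["nonref_seen"]

    def test_empty_cohort(self):
        assert filter_calls({}) == {}

    def test_high_confidence_flag_configurable(self):
        calls = {0: [_call("s0", (0, 1), gq=50), _call("s1", (0, 0), gq=5)]}
        kept = filter_calls(calls, HighConfidenceFilter(min_gq=10,
                                                        min_call_fraction=0.9))
        assert not kept[0][0].passed_filters["high_confidence"]
        calls = {0: [_call("s0", (0, 1), gq=50), _call("s1", (0, 0), gq=50)]}
        kept = filter_calls(calls, HighConfidenceFilter(min_gq=10,
                                                        min_call_fraction=0.9))
        assert kept[0][0].passed_filters["high_confidence"]
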