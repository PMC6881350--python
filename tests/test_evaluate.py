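"""Benchmark matching, truth extraction and pedigree statistics."""

import subprocess

import numpy as np
import pandas as pd
import pysam
import pytest
from intervaltree import IntervalTree

from graphsv.evaluate import (MatchCriteria, PedigreeTrio, carrier_spectrum,
                              concordance, extract_truth_svs,
                              genotypes_from_vcf, match_pairs, match_sv_sets,
                              mendelian_consistent, mendelian_error_rate,
                              normalize_variant, read_bed_regions,
                              read_pedigree, recall_by_size,
                              transmission_rate)
from graphsv.sites import SVSite


def D(begin, end, sv_type="DEL", contig="c"):
    size = end - begin if sv_type != "INS" else 100
    return SVSite(contig, begin, end, sv_type, size)


def _vcf(path, records, contig=("c", 100_000)):
    header = pysam.VariantHeader()
    header.contigs.add(contig[0], length=contig[1])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for pos, ref, alts in records:
            out.write(out.new_record(contig=contig[0], start=pos - 1,
                                     alleles=(ref, *alts)))
    return str(path)


class TestTruthExtraction:
    def test_fifty_base_insertion_retained(self, tmp_path):
        path = _vcf(tmp_path / "t.vcf", [(100, "A", ["A" + "CG" * 25]),
                                         (500, "T" * 30, ["T"])])
        sites = extract_truth_svs(path)
        assert len(sites) == 1          # 29 bp deletion excluded
        assert sites[0].sv_type == "INS" and sites[0].size == 50

    def test_multiallelic_decomposed_and_classified(self, tmp_path):
        path = _vcf(tmp_path / "t.vcf",
                    [(100, "A" * 81, ["A", "A" * 81 + "C" * 60])])
        sites = extract_truth_svs(path)
        types = sorted(s.sv_type for s in sites)
        assert types == ["DEL", "INS"]
        del_site = next(s for s in sites if s.sv_type == "DEL")
        assert del_site.size == 80

    def test_region_expansion_rescues_nearby_site(self, tmp_path):
        path = _vcf(tmp_path / "t.vcf", [(1000, "A", ["A" + "C" * 60])])
        regions = {"c": IntervalTree()}
        regions["c"].addi(1010, 2000)   # site 10 bp outside the region
        crit25 = MatchCriteria(region_expansion=25)
        crit0 = MatchCriteria(region_expansion=0)
        assert len(extract_truth_svs(path, regions, crit25)) == 1
        assert len(extract_truth_svs(path, regions, crit0)) == 0

    def test_normalization_matches_bcftools_norm(self, tmp_path):
        """Cross-check left-normalization against an independent tool."""
        rng = np.random.default_rng(4)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        fa = tmp_path / "r.fa"
        fa.write_text(">c\n" + ref + "\n")
        pysam.faidx(str(fa))
        # deletion with shared trailing bases: needs left-shifting
        pos = 100
        deleted = ref[pos:pos + 60]
        raw_ref = ref[pos - 1] + deleted + ref[pos + 60]
        raw_alt = ref[pos - 1] + ref[pos + 60]
        path = _vcf(tmp_path / "t.vcf", [(pos, raw_ref, [raw_alt])],
                    contig=("c", 400))
        out = subprocess.run(
            ["bcftools", "norm", "-f", str(fa), str(path)],
            capture_output=True, text=True, check=True)
        exp = [l.split("\t") for l in out.stdout.splitlines()
               if not l.startswith("#")][0]
        got_pos, got_ref, got_alt = normalize_variant(pos, raw_ref, raw_alt,
                                                      ref)
        assert (got_pos, got_ref, got_alt) == (int(exp[1]), exp[3], exp[4])


class TestMatching:
    def test_identity_gives_perfect_recall_and_zero_fdr(self):
        truth = [D(1000 * i, 1000 * i + 300) for i in range(1, 8)]
        table = match_sv_sets(list(truth), truth, range(1, 51))
        assert (table["recall"] == 1.0).all()
        assert (table["fdr"] == 0.0).all()

    def test_threshold_boundary_on_both_breakpoints(self):
        truth = [D(1000, 1500)]
        calls = [D(1049, 1451)]
        assert match_pairs(calls, truth, 50) == [(0, 0)]
        assert match_pairs(calls, truth, 49) == [(0, 0)]
        assert match_pairs(calls, truth, 48) == []

    def test_type_match_required_by_default(self):
        truth = [D(1000, 1500)]
        calls = [D(1000, 1500, "DUP")]
        assert match_pairs(calls, truth, 50) == []
        crit = MatchCriteria(require_type_match=False)
        assert match_pairs(calls, truth, 50, crit) == [(0, 0)]

    def test_one_to_one_matching(self):
        truth = [D(1000, 1500)]
        calls = [D(1001, 1501), D(1002, 1502)]
        pairs = match_pairs(calls, truth, 50)
        assert len(pairs) == 1
        assert pairs[0] == (0, 0)       # nearest call wins

    def test_jittered_recall_equals_empirical_jitter_count(self, rng):
        truth = [D(5000 * i, 5000 * i + 700) for i in range(1, 101)]
        jit = rng.integers(-30, 31, size=(100, 2))
        calls = [D(t.begin + int(a), t.end + int(b))
                 for t, (a, b) in zip(truth, jit)]
        table = match_sv_sets(calls, truth, range(1, 31))
        for t in (5, 10, 20, 30):
            expected = float(np.mean(np.abs(jit).max(axis=1) <= t))
            row = table[table.threshold == t].iloc[0]
            assert row["recall"] == pytest.approx(expected)
        assert table[table.threshold == 30].iloc[0]["recall"] == 1.0

    def test_recall_monotone_fdr_antitone(self, rng):
        truth = [D(3000 * i, 3000 * i + 400) for i in range(1, 60)]
        calls = [D(t.begin + int(rng.integers(-80, 81)),
                   t.end + int(rng.integers(-80, 81))) for t in truth]
        table = match_sv_sets(calls, truth, range(1, 101))
        assert table["recall"].is_monotonic_increasing
        assert (table["fdr"].diff().dropna() <= 1e-12).all()

    def test_size_bins_cover_named_extremes(self):
        truth = [D(1000, 1075), D(5000, 5600), D(9000, 12_000)]
        bins = recall_by_size(list(truth), truth, 50)
        assert bins.iloc[0]["size_bin"] == "50-99"
        assert bins.iloc[-1]["size_bin"] == "2000+"
        by = dict(zip(bins["size_bin"], bins["n_truth"]))
        assert by["50-99"] == 1 and by["500-999"] == 1 and by["2000+"] == 1


class TestConcordance:
    def test_identical_sets_fully_validated(self):
        calls = [D(1000, 1500), D(8000, 8900)]
        validated = [(c, 5) for c in calls]
        assert concordance(calls, validated) == (2, 1.0)

    def test_empty_validation_set(self):
        assert concordance([D(1000, 1500)], []) == (0, 0.0)

    def test_min_support_enforced(self):
        calls = [D(1000, 1500)]
        assert concordance(calls, [(D(1000, 1500), 1)], min_support=2) \
            == (0, 0.0)
        assert concordance(calls, [(D(1030, 1530), 2)], min_support=2) \
            == (1, 1.0)


class TestMendelian:
    def test_impossible_child_flagged(self):
        assert not mendelian_consistent((0, 0), (0, 0), (0, 1))
        assert mendelian_consistent((0, 1), (0, 0), (0, 1))
        assert not mendelian_consistent((1, 1), (1, 1), (0, 1))
        assert mendelian_consistent((0, 1), (0, 1), (1, 1))

    def test_consistency_against_enumeration_oracle(self):
        gts = [(0, 0), (0, 1), (1, 1)]
        for f in gts:
            for m in gts:
                possible = {tuple(sorted((a, b))) for a in f for b in m}
                for c in gts:
                    assert mendelian_consistent(f, m, c) == (c in possible)

    def test_error_free_pedigree_has_zero_rate(self, pedigree_truth,
                                               pedigree_vcf):
        gts = genotypes_from_vcf(pedigree_vcf)
        rate, table = mendelian_error_rate(gts, pedigree_truth.trios)
        assert rate == 0.0
        assert table["n_trios"].sum() == len(pedigree_truth.sites) * 48

    def test_injected_flips_raise_error_count(self, pedigree_truth,
                                              pedigree_vcf, rng):
        gts = genotypes_from_vcf(pedigree_vcf)
        flipped = [(label, dict(g)) for label, g in gts]
        trios = pedigree_truth.trios
        n_broken = 0
        for _ in range(30):
            si = int(rng.integers(len(flipped)))
            trio = trios[int(rng.integers(len(trios)))]
            g = flipped[si][1]
            old = g[trio.offspring]
            new = {(0, 0): (1, 1), (0, 1): (0, 0), (1, 1): (0, 0)}[old]
            if mendelian_consistent(g[trio.father], g[trio.mother], old) \
                    and not mendelian_consistent(g[trio.father],
                                                 g[trio.mother], new):
                n_broken += 1
            g[trio.offspring] = new
        rate, _ = mendelian_error_rate(flipped, trios)
        total = sum(1 for label, g in flipped for t in trios)
        assert rate * len(flipped) * 48 >= n_broken > 0

    def test_missing_trio_member_skipped_with_warning(self, caplog):
        gts = [("s", {"a": (0, 0), "b": (0, 0)})]
        trios = [PedigreeTrio("a", "b", "missing")]
        rate, table = mendelian_error_rate(gts, trios)
        assert rate == 0.0 and table["n_trios"].sum() == 0


class TestTransmission:
    def test_resolvable_cases(self):
        gts = [("site", {"f": (0, 1), "m": (0, 0), "c1": (0, 1),
                         "c2": (0, 0)})]
        trios = [PedigreeTrio("f", "m", "c1"), PedigreeTrio("f", "m", "c2")]
        table = transmission_rate(gts, trios)
        assert table.iloc[0]["n_opportunities"] == 2
        assert table.iloc[0]["n_transmitted"] == 1

    def test_het_het_het_child_ambiguous_skipped(self):
        gts = [("site", {"f": (0, 1), "m": (0, 1), "c": (0, 1)})]
        table = transmission_rate(gts, [PedigreeTrio("f", "m", "c")])
        assert table.iloc[0]["n_opportunities"] == 0

    def test_fair_pedigree_rate_near_half(self, pedigree_truth,
                                          pedigree_vcf):
        gts = genotypes_from_vcf(pedigree_vcf)
        table = transmission_rate(gts, pedigree_truth.trios)
        n = int(table["n_opportunities"].sum())
        k = int(table["n_transmitted"].sum())
        se = 0.5 / np.sqrt(n)
        assert abs(k / n - 0.5) <= 3 * se

    def test_histogram_symmetric_about_half(self, pedigree_truth,
                                            pedigree_vcf):
        gts = genotypes_from_vcf(pedigree_vcf)
        table = transmission_rate(gts, pedigree_truth.trios)
        rates = table["rate"].dropna()
        above = (rates > 0.5).sum()
        below = (rates < 0.5).sum()
        from scipy.stats import binomtest
        assert binomtest(above, above + below, 0.5).pvalue > 0.001


class TestCarrierSpectrum:
    def test_single_het_sample_is_one_carrier(self):
        gts = [("s", {"a": (0, 1), "b": (0, 0)})]
        assert carrier_spectrum(gts) == {1: 1}

    def test_histogram_conserves_site_count(self, pedigree_vcf,
                                            pedigree_truth):
        gts = genotypes_from_vcf(pedigree_vcf)
        hist = carrier_spectrum(gts)
        assert sum(hist.values()) == len(pedigree_truth.sites)


class TestPedParsing:
    def test_trios_from_ped(self, tmp_path):
        ped = tmp_path / "p.ped"
        ped.write_text("fam1\tf\t0\t0\t1\t0\n"
                       "fam1\tm\t0\t0\t2\t0\n"
                       "fam1\tc\tf\tm\t0\t0\n")
        trios = read_pedigree(str(ped))
        assert trios == [PedigreeTrio("f", "m", "c")]

    def test_ped_roundtrip_with_simulator(self, pedigree_truth, tmp_path):
        from graphsv.simulate import write_ped
        path = write_ped(pedigree_truth, str(tmp_path / "x.ped"))
        trios = read_pedigree(path)
        assert set(trios) == set(pedigree_truth.trios)
        assert len(trios) == 48
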