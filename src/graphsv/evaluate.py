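"""Evaluation machinery: truth-set extraction, breakpoint-precision
matching, long-read-style concordance, and pedigree statistics.

A call is *recalled* against a truth SV when both are of the same type
and both breakpoints lie within a chosen precision threshold (bp);
recall/FDR curves over thresholds and per-size-bin recall reproduce the
standard benchmark readout.  Pedigree statistics cover Mendelian
inheritance errors in parent-offspring trios and the per-site allele
transmission rate, which for germline variants is expected to be
distributed symmetrically around 50%.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .sites import MIN_SV_SIZE, SVSite

log = logging.getLogger(__name__)

SIZE_BINS = ((50, 99), (100, 249), (250, 499), (500, 999), (1000, 1999),
             (2000, None))


@dataclass
class MatchCriteria:
    """Breakpoint-precision matching parameters."""

    precision_threshold: int = 50
    require_type_match: bool = True
    region_expansion: int = 25
    dup_as_ins: bool = False   # optionally let DUP calls match INS truth

    def __post_init__(self) -> None:
        if self.precision_threshold < 0:
            raise ValueError("precision threshold must be >= 0")


@dataclass(frozen=True)
class PedigreeTrio:
    father: str
    mother: str
    offspring: str

    def __post_init__(self) -> None:
        if len({self.father, self.mother, self.offspring}) != 3:
            raise ValueError("trio members must be three distinct samples")


# ---------------------------------------------------------------------------
# truth extraction


def normalize_variant(pos: int, ref: str, alt: str,
                      refseq: Optional[str] = None) -> tuple[int, str, str]:
    """Left-normalize a sequence-resolved variant (1-based ``pos``).

    Trims shared leading/trailing bases and, when the contig sequence is
    given, left-aligns the remaining indel.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if refseq is not None:
        while (pos > 1 and len(ref) != len(alt)
               and ref[-1] == alt[-1]):
            prev = refseq[pos - 2].upper()
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
    return pos, ref, alt


def read_bed_regions(path: str) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            trees.setdefault(f[0], IntervalTree()).addi(int(f[1]), int(f[2]))
    return trees


def extract_truth_svs(vcf_path: str,
                      regions: Optional[Mapping[str, IntervalTree]] = None,
                      criteria: Optional[MatchCriteria] = None,
                      reference: Optional[Mapping[str, str]] = None
                      ) -> list[SVSite]:
    """Extract an SV truth set from a sequence-resolved variant VCF.

    Multi-allelic records are decomposed and each alternative allele is
    left-normalized; alleles whose length differs from the reference
    allele by at least 50 bp are kept, classified DEL when the reference
    is longer and INS otherwise, and restricted to the confidence
    regions expanded by ``region_expansion`` bp on each side.
    """
    criteria = criteria or MatchCriteria()
    out: list[SVSite] = []
    with pysam.VariantFile(vcf_path) as vf:
        for rec in vf:
            refseq = reference.get(rec.contig) if reference else None
            for alt in rec.alts or ():
                if alt.startswith("<") or "[" in alt or "]" in alt:
                    continue
                pos, ref_a, alt_a = normalize_variant(rec.pos, rec.ref, alt,
                                                      refseq)
                diff = len(alt_a) - len(ref_a)
                if abs(diff) < MIN_SV_SIZE:
                    continue
                if diff < 0:
                    site = SVSite(rec.contig, pos, pos - diff, "DEL", -diff)
                else:
                    ins = (alt_a[len(ref_a):] if alt_a.startswith(ref_a)
                           else alt_a[1:])
                    site = SVSite(rec.contig, pos, pos, "INS", diff, ins)
                if regions is not None:
                    tree = regions.get(site.contig)
                    exp = criteria.region_expansion
                    if tree is None or not tree.overlap(
                            site.begin - 1 - exp, site.end + exp):
                        continue
                out.append(site)
    return out


# ---------------------------------------------------------------------------
# breakpoint-precision matching


def _type_compatible(a: str, b: str, criteria: MatchCriteria) -> bool:
    if a == b:
        return True
    if not criteria.require_type_match:
        return True
    if criteria.dup_as_ins and {a, b} == {"DUP", "INS"}:
        return True
    return False


def match_pairs(calls: Sequence[SVSite], truth: Sequence[SVSite],
                threshold: int,
                criteria: Optional[MatchCriteria] = None
                ) -> list[tuple[int, int]]:
    """Greedy one-to-one matching, nearest pair first.

    A (call, truth) pair is eligible when the types are compatible and
    both breakpoint distances are within ``threshold``; pairs are taken
    in order of increasing ``max(Δbegin, Δend)``.
    """
    criteria = criteria or MatchCriteria()
    cand = []
    for ti, t in enumerate(truth):
        for ci, c in enumerate(calls):
            if c.contig != t.contig:
                continue
            if not _type_compatible(c.sv_type, t.sv_type, criteria):
                continue
            db, de = abs(c.begin - t.begin), abs(c.end - t.end)
            if db <= threshold and de <= threshold:
                cand.append((max(db, de), db + de, ci, ti))
    cand.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for _, _, ci, ti in cand:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        pairs.append((ci, ti))
    return pairs


def match_sv_sets(calls: Sequence[SVSite], truth: Sequence[SVSite],
                  thresholds: Iterable[int] = range(1, 51),
                  criteria: Optional[MatchCriteria] = None) -> pd.DataFrame:
    """Recall and FDR per breakpoint-precision threshold."""
    rows = []
    for t in thresholds:
        pairs = match_pairs(calls, truth, t, criteria)
        recall = len(pairs) / len(truth) if truth else 0.0
        fdr = (len(calls) - len(pairs)) / len(calls) if calls else 0.0
        rows.append({"threshold": t, "n_matched": len(pairs),
                     "recall": recall, "fdr": fdr})
    return pd.DataFrame(rows)


def size_bin_label(size: int) -> str:
    for lo, hi in SIZE_BINS:
        if hi is None and size >= lo:
            return f"{lo}+"
        if hi is not None and lo <= size <= hi:
            return f"{lo}-{hi}"
    return "<50"


def recall_by_size(calls: Sequence[SVSite], truth: Sequence[SVSite],
                   threshold: int = 50,
                   criteria: Optional[MatchCriteria] = None) -> pd.DataFrame:
    """Per-size-bin recall at one precision threshold (truth sizes)."""
    pairs = match_pairs(calls, truth, threshold, criteria)
    matched_t = {ti for _, ti in pairs}
    rows = []
    for lo, hi in SIZE_BINS:
        label = f"{lo}+" if hi is None else f"{lo}-{hi}"
        idx = [i for i, t in enumerate(truth)
               if t.size >= lo and (hi is None or t.size <= hi)]
        n = len(idx)
        m = sum(1 for i in idx if i in matched_t)
        rows.append({"size_bin": label, "n_truth": n, "n_matched": m,
                     "recall": m / n if n else float("nan")})
    return pd.DataFrame(rows)


def concordance(calls_a: Sequence[SVSite],
                calls_b: Sequence[tuple[SVSite, int]],
                min_support: int = 2, threshold: int = 50
                ) -> tuple[int, float]:
    """Fraction of calls in A validated by a supported record in B.

    A call is validated iff a type-matching record in B with at least
    ``min_support`` supporting reads lies within ``threshold`` bp at
    both breakpoints.  Returns (validated count, fraction).
    """
    b_ok = [s for s, n in calls_b if n >= min_support]
    n_val = 0
    for c in calls_a:
        for b in b_ok:
            if (b.contig == c.contig and b.sv_type == c.sv_type
                    and abs(b.begin - c.begin) <= threshold
                    and abs(b.end - c.end) <= threshold):
                n_val += 1
                break
    return n_val, (n_val / len(calls_a) if calls_a else 0.0)


# ---------------------------------------------------------------------------
# pedigree statistics


def read_pedigree(path: str) -> list[PedigreeTrio]:
    """Parse a PED file (FamID, ID, FatherID, MotherID, sex, phenotype)
    into parent-offspring trios."""
    trios = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 4:
                continue
            fam, iid, fid, mid = f[:4]
            if fid not in ("0", "") and mid not in ("0", ""):
                trios.append(PedigreeTrio(fid, mid, iid))
    return trios


def genotypes_from_vcf(path: str) -> list[tuple[str, dict]]:
    """Per-record sample genotypes: (site label, {sample: (a, b) or None})."""
    out = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            gts = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt) or len(gt) != 2:
                    gts[s] = None
                else:
                    gts[s] = tuple(sorted(int(a) for a in gt))
            out.append((f"{rec.contig}:{rec.pos}:{rec.alts[0] if rec.alts else '.'}",
                        gts))
    return out


def mendelian_consistent(father: tuple, mother: tuple, child: tuple) -> bool:
    """Is the child's biallelic genotype possible under Mendelian
    transmission from the parents?"""
    a, b = child
    return ((a in father and b in mother)
            or (b in father and a in mother))


def mendelian_error_rate(genotypes: Sequence[tuple[str, dict]],
                         trios: Sequence[PedigreeTrio]
                         ) -> tuple[float, pd.DataFrame]:
    """Mendelian inheritance error rate over all (site, trio) pairs.

    Trios with a member absent from the cohort are skipped with a
    warning; (site, trio) pairs with any missing genotype are not
    evaluated.  Returns (rate, per-site table).
    """
    if genotypes:
        present = set(genotypes[0][1])
        usable = []
        for t in trios:
            if {t.father, t.mother, t.offspring} <= present:
                usable.append(t)
            else:
                log.warning("trio %s skipped: member missing from cohort", t)
        trios = usable
    rows = []
    n_err = n_eval = 0
    for label, gts in genotypes:
        site_err = site_eval = 0
        for t in trios:
            gf, gm, gc = gts.get(t.father), gts.get(t.mother), gts.get(t.offspring)
            if gf is None or gm is None or gc is None:
                continue
            site_eval += 1
            if not mendelian_consistent(gf, gm, gc):
                site_err += 1
        n_err += site_err
        n_eval += site_eval
        rows.append({"site": label, "n_trios": site_eval, "n_errors": site_err})
    rate = n_err / n_eval if n_eval else 0.0
    return rate, pd.DataFrame(rows)


def _transmission_status(other: tuple, child: tuple) -> Optional[bool]:
    """Did the heterozygous parent transmit its alternative allele?

    ``other`` is the other parent's genotype.  Returns None when the
    child's allele received from the het parent is not uniquely
    determined (het × het with het child), or when the trio is
    Mendelian-inconsistent.
    """
    if not mendelian_consistent((0, 1), other, child):
        return None
    if child == (0, 0):
        return False
    if child == (1, 1):
        return True
    # child 0/1: the allele received from the het parent must be unique
    if set(other) == {0}:
        return True
    if set(other) == {1}:
        return False
    return None   # other parent het too: ambiguous


def transmission_rate(genotypes: Sequence[tuple[str, dict]],
                      trios: Sequence[PedigreeTrio]
                      ) -> pd.DataFrame:
    """Per-site SV allele transmission rate from heterozygous parents.

    Each (site, trio, heterozygous parent) with a resolvable transmission
    contributes one opportunity; the per-site rate is transmitted /
    opportunities.  Expected to be symmetric around 50% for germline
    variants.
    """
    rows = []
    for label, gts in genotypes:
        n_trans = n_opp = 0
        for t in trios:
            gf, gm, gc = gts.get(t.father), gts.get(t.mother), gts.get(t.offspring)
            if gf is None or gm is None or gc is None:
                continue
            for parent, other in ((gf, gm), (gm, gf)):
                if parent != (0, 1):
                    continue
                status = _transmission_status(other, gc)
                if status is None:
                    continue
                n_opp += 1
                n_trans += int(status)
        rows.append({"site": label, "n_opportunities": n_opp,
                     "n_transmitted": n_trans,
                     "rate": n_trans / n_opp if n_opp else float("nan")})
    return pd.DataFrame(rows)


def carrier_spectrum(genotypes: Sequence[tuple[str, dict]]) -> Counter:
    """Distribution of sites by carrier count (samples with ≥1 alt allele)."""
    hist: Counter = Counter()
    for _label, gts in genotypes:
        carriers = sum(1 for g in gts.values()
                       if g is not None and any(a != 0 for a in g))
        hist[carriers] += 1
    return hist
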