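"""Read extraction and local realignment to a breakpoint graph.

Reads are pulled from a coordinate-sorted linear-reference alignment
file for a window (including clipped reads and unmapped reads whose
mapped mate lies in the window) and re-scored against the local
haplotype sequences of every variant site within reach.  A read
supports an allele if its best alignment overlaps that allele;
equally-scoring alleles are all supported; a read whose best alignment
overlaps the site but clears no allele's match threshold supports
neither (the ``NONE`` outcome that feeds the ε branch of the genotype
likelihood).

The scoring engine is a semi-global local-haplotype alignment (match 1,
mismatch −2, gap open −5, gap extend −1) applied per site, with ties
handled exactly as the graph-alignment contract requires.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pysam
from Bio import Align

from .graph import BreakpointGraph, GraphSite, SmallVariant, START, END
from .sites import SVSite, revcomp

log = logging.getLogger(__name__)

#: Marker for "best alignment overlaps the site but supports no allele".
NONE_SUPPORT: frozenset = frozenset()


@dataclass
class AlignConfig:
    """Realignment thresholds and context geometry.

    A read's best alignment must cover at least ``min_read_cover`` of
    its bases and score at least ``min_score_frac`` of the maximum
    attainable (match score × read length); otherwise the read supports
    neither allele.  ``context_pad`` is the reference flank placed
    around each allele when building local haplotype contexts; it must
    exceed the read length so junction-crossing reads fit.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -1
    min_score_frac: float = 0.65
    min_read_cover: float = 0.90
    context_pad: int = 300
    min_read_len: int = 16
    extraction_padding: int = 1000


@dataclass
class ExtractedRead:
    """One read pulled from the alignment file for realignment."""

    name: str
    sequence: str
    is_paired: bool
    is_first: bool
    mate_mapped_in_region: bool
    is_clipped: bool = False
    was_unmapped: bool = False
    ref_pos: Optional[int] = None        # 0-based linear placement
    mate_ref_pos: Optional[int] = None
    base_qualities: Optional[tuple] = None

    @property
    def approx_span0(self) -> tuple[int, int]:
        """Rough reference interval the read may cover (0-based)."""
        n = len(self.sequence)
        if self.ref_pos is not None:
            return (self.ref_pos - n, self.ref_pos + 2 * n)
        if self.mate_ref_pos is not None:
            # unmapped read: somewhere within a fragment of its mate
            return (self.mate_ref_pos - 1500, self.mate_ref_pos + 1500)
        return (0, 1 << 60)


@dataclass
class AlleleSupport:
    """Which alleles of one site a read's best alignment supports."""

    read: ExtractedRead
    site_id: int
    supported_alleles: frozenset
    mate_on_graph: bool

    @property
    def is_none(self) -> bool:
        return len(self.supported_alleles) == 0


class MissingIndexError(FileNotFoundError):
    pass


def _open_alignment(path: str, reference: Optional[str] = None):
    mode_ref = {"reference_filename": reference} if reference else {}
    af = pysam.AlignmentFile(path, **mode_ref)
    if not af.has_index():
        af.close()
        raise MissingIndexError(
            f"{path} has no index; run `samtools index {path}` first")
    return af


def extract_reads(alignments: str, contig: str, window0: tuple[int, int],
                  padding: int = 1000,
                  reference: Optional[str] = None) -> list[ExtractedRead]:
    """Extract candidate reads for a window from an indexed alignment file.

    Returns primary, non-duplicate alignments overlapping the padded
    window plus unmapped reads whose mapped mate lies in it, deduplicated
    by (name, first/second-of-pair).
    """
    w0, w1 = window0
    lo, hi = max(0, w0 - padding), w1 + padding
    out: dict[tuple, ExtractedRead] = {}
    with _open_alignment(alignments, reference) as af:
        if contig not in af.references:
            return []
        hi = min(hi, af.get_reference_length(contig))
        if lo >= hi:
            return []
        for aln in af.fetch(contig, lo, hi):
            if aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                continue
            if aln.query_sequence is None:
                continue
            if aln.is_unmapped and not (aln.mate_is_mapped if aln.is_paired
                                        else False):
                continue
            key = (aln.query_name, aln.is_read1 or not aln.is_paired)
            if key in out:
                continue
            mate_in_region = bool(
                aln.is_paired and not aln.mate_is_unmapped
                and aln.next_reference_name == contig
                and lo <= (aln.next_reference_start or 0) < hi)
            cig = aln.cigartuples or ()
            clipped = any(op in (4, 5) for op, _ in cig)
            out[key] = ExtractedRead(
                name=aln.query_name,
                sequence=aln.query_sequence.upper(),
                is_paired=aln.is_paired,
                is_first=aln.is_read1 or not aln.is_paired,
                mate_mapped_in_region=mate_in_region,
                is_clipped=clipped,
                was_unmapped=aln.is_unmapped,
                ref_pos=None if aln.is_unmapped else aln.reference_start,
                mate_ref_pos=(aln.next_reference_start
                              if aln.is_paired and not aln.mate_is_unmapped
                              else None),
                base_qualities=(tuple(aln.query_qualities)
                                if aln.query_qualities is not None else None),
            )
    return sorted(out.values(), key=lambda r: (r.name, not r.is_first))


# ---------------------------------------------------------------------------
# realignment


def _make_aligner(config: AlignConfig) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = config.match
    a.mismatch_score = config.mismatch
    a.open_gap_score = config.gap_open
    a.extend_gap_score = config.gap_extend
    return a


@dataclass
class _AlleleContext:
    seq: str
    interval: tuple[int, int]   # allele occupancy within the context


class SiteRealigner:
    """Precomputed per-site allele contexts for one breakpoint graph.

    Each SV allele is scored through its per-junction breakpoint-node
    contexts: the reference flank adjacent to the junction followed
    (START) or preceded (END) by the allele node sequence.  The bounded
    node length keeps reference and alternative evidence footprints
    comparable across SV sizes.  An alignment placed entirely in flank
    sequence — a placement the reference path explains equally well
    elsewhere — makes the read ambiguous rather than allele-supporting,
    which reproduces how ties against the reference path behave in
    whole-graph alignment (breakpoint sequences of deletions and
    duplications are copies of reference sequence from the other
    junction, so a purely positional comparison would otherwise count
    plain reference reads as SV support).
    """

    def __init__(self, graph: BreakpointGraph,
                 config: Optional[AlignConfig] = None) -> None:
        self.graph = graph
        self.config = config or AlignConfig()
        self._aligner = _make_aligner(self.config)
        self._site_contexts: list[tuple[GraphSite, list[list[_AlleleContext]],
                                        list[tuple[int, int]]]] = []
        pad = self.config.context_pad
        for gsite in graph.sites:
            ctxs = self._contexts_for(gsite)
            if ctxs is None:
                continue
            windows = [(sp[0] - pad, sp[1] + pad)
                       for sp, _, _ in gsite.loci]
            self._site_contexts.append((gsite, ctxs, windows))

    # -- context construction ---------------------------------------------
    def _wslice(self, a: int, b: int) -> str:
        w0, w1 = self.graph.window0
        a, b = max(a, w0), min(b, w1)
        if a >= b:
            return ""
        return self.graph._window_seq[a - w0:b - w0]

    def _contexts_for(self, gsite: GraphSite):
        pad = self.config.context_pad
        if not gsite.is_sv:
            smv: SmallVariant = gsite.site
            a, b = smv.span0
            left, right = self._wslice(a - pad, a), self._wslice(b, b + pad)
            ref_ctx = _AlleleContext(left + self._wslice(a, b) + right,
                                     (len(left), len(left) + (b - a)))
            out = [[ref_ctx]]
            for alt in smv.alts:
                out.append([_AlleleContext(left + alt.upper() + right,
                                           (len(left), len(left) + len(alt)))])
            return out

        # SV: one (ref ctx, alt ctx) pair per breakpoint junction.
        # Bounded node length (L_bp) keeps the reference and alternative
        # evidence footprints comparable across SV sizes.
        ref_ctxs: list[_AlleleContext] = []
        alt_ctxs: list[_AlleleContext] = []
        for _span, _alts, bps in gsite.loci:
            bp = bps[0]
            if bp is None:
                continue
            a = bp.anchor_pos
            n = len(bp.alt_sequence)
            if bp.side == START:
                left = self._wslice(a - pad, a)
                ref_node = self._wslice(a, a + n)
                ref_ctxs.append(_AlleleContext(
                    left + ref_node, (len(left), len(left) + len(ref_node))))
                alt_ctxs.append(_AlleleContext(
                    left + bp.alt_sequence,
                    (len(left), len(left) + n)))
            else:
                right = self._wslice(a, a + pad)
                ref_node = self._wslice(a - n, a)
                ref_ctxs.append(_AlleleContext(
                    ref_node + right, (0, len(ref_node))))
                alt_ctxs.append(_AlleleContext(
                    bp.alt_sequence + right, (0, n)))
        if not alt_ctxs:
            return None
        return [ref_ctxs, alt_ctxs]

    # -- scoring ------------------------------------------------------------
    def _best_on_context(self, seq: str, ctx: str) -> float:
        if not ctx:
            return float("-inf")
        if seq in ctx:  # exact-substring fast path
            return self.config.match * len(seq)
        return self._aligner.score(ctx, seq)

    def _traceback(self, seq: str, ctx: str):
        """(score, target intervals of best placements, read coverage)."""
        ivs = []
        start = ctx.find(seq)
        while start >= 0:  # exact placements (possibly several)
            ivs.append((start, start + len(seq)))
            start = ctx.find(seq, start + 1)
        if ivs:
            return self.config.match * len(seq), ivs, 1.0
        alns = self._aligner.align(ctx, seq)
        top = alns[0]
        t_blocks, q_blocks = top.aligned
        t_iv = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
        q_cov = sum(int(b) - int(a) for a, b in q_blocks) / max(1, len(seq))
        return top.score, [t_iv], q_cov

    def support_for_read(self, read: ExtractedRead) -> list[AlleleSupport]:
        cfg = self.config
        seq = read.sequence
        if len(seq) < cfg.min_read_len:
            return []
        seq_rc = revcomp(seq)
        lo_r, hi_r = read.approx_span0
        out: list[AlleleSupport] = []
        max_score = cfg.match * len(seq)
        for gsite, ctxs, windows in self._site_contexts:
            if not any(lo < hi_r and hi > lo_r for lo, hi in windows):
                continue
            # exact-substring shortcut: an exact hit attains the maximum
            # score, so only other exact hits can tie and DP is skipped
            scores: list[tuple[float, int, int, str]] = []
            for ai, allele_ctxs in enumerate(ctxs):
                for ci, actx in enumerate(allele_ctxs):
                    for strand, s in (("+", seq), ("-", seq_rc)):
                        if s and s in actx.seq:
                            scores.append((max_score, ai, ci, strand))
            if not scores:
                for ai, allele_ctxs in enumerate(ctxs):
                    for ci, actx in enumerate(allele_ctxs):
                        for strand, s in (("+", seq), ("-", seq_rc)):
                            scores.append(
                                (self._best_on_context(s, actx.seq),
                                 ai, ci, strand))
            best_score = max(sc for sc, *_ in scores)
            min_score = cfg.min_score_frac * cfg.match * len(seq)
            n_alleles = len(ctxs)
            supported: set[int] = set()
            elsewhere = False
            covered_ok = False
            if best_score >= min_score:
                for sc, ai, ci, strand in scores:
                    if sc != best_score:
                        continue
                    actx = ctxs[ai][ci]
                    s = seq if strand == "+" else seq_rc
                    _, t_ivs, q_cov = self._traceback(s, actx.seq)
                    if q_cov < cfg.min_read_cover:
                        continue
                    covered_ok = True
                    a, b = actx.interval
                    for t_iv in t_ivs:
                        if a == b:  # zero-length allele: require crossing
                            hit = t_iv[0] < a < t_iv[1]
                        else:
                            hit = t_iv[0] < b and t_iv[1] > a
                        if hit:
                            supported.add(ai)
                        else:
                            # equally good placement in flank sequence: the
                            # reference path explains the read elsewhere
                            elsewhere = True
            if covered_ok:
                if elsewhere:
                    supported = set(range(n_alleles))
                if not supported:
                    continue
                out.append(AlleleSupport(
                    read=read, site_id=gsite.site_id,
                    supported_alleles=frozenset(supported),
                    mate_on_graph=read.mate_mapped_in_region))
            else:
                # no acceptable alignment: the read overlaps the site but
                # supports neither allele (the ε branch) if its linear
                # placement covers the site's loci
                sp_lo = min(sp[0] for sp, _, _ in gsite.loci)
                sp_hi = max(sp[1] for sp, _, _ in gsite.loci)
                pos = read.ref_pos
                if (pos is not None and pos < sp_hi
                        and pos + len(seq) > sp_lo):
                    out.append(AlleleSupport(
                        read=read, site_id=gsite.site_id,
                        supported_alleles=NONE_SUPPORT,
                        mate_on_graph=read.mate_mapped_in_region))
        return out


def realign_to_graph(read: ExtractedRead, graph: BreakpointGraph,
                     config: Optional[AlignConfig] = None,
                     realigner: Optional[SiteRealigner] = None
                     ) -> list[AlleleSupport]:
    """Realign one read to a graph, returning per-site allele support."""
    if realigner is None:
        realigner = SiteRealigner(graph, config)
    return realigner.support_for_read(read)


def support_table(by_site: dict) -> "pandas.DataFrame":
    """Tabulate allele support for debugging (one row per read × site)."""
    import pandas as pd
    rows = []
    for site_id, sups in sorted(by_site.items()):
        for s in sups:
            rows.append({
                "read": s.read.name,
                "mate": 1 if s.read.is_first else 2,
                "site_id": site_id,
                "supported_alleles": ",".join(
                    map(str, sorted(s.supported_alleles))) or "NONE",
                "mate_on_graph": s.mate_on_graph,
            })
    return pd.DataFrame(rows)


def realign_all(reads: Iterable[ExtractedRead], graph: BreakpointGraph,
                config: Optional[AlignConfig] = None
                ) -> dict[int, list[AlleleSupport]]:
    """Realign reads to a graph, grouping supports by site id."""
    realigner = SiteRealigner(graph, config)
    by_site: dict[int, list[AlleleSupport]] = {}
    skipped = 0
    for read in reads:
        if len(read.sequence) < realigner.config.min_read_len:
            skipped += 1
            continue
        for sup in realigner.support_for_read(read):
            by_site.setdefault(sup.site_id, []).append(sup)
    if skipped:
        log.info("skipped %d reads shorter than %d bp", skipped,
                 realigner.config.min_read_len)
    return by_site
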