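"""Acyclic breakpoint-aware graphs over a reference window.

A structural variant is encoded by its *breakpoint sequences*: at each
junction where the SV haplotype diverges from or converges to the
reference, an alternative node carries up to ``L_bp`` bases (default
152, the short-read length) of the SV haplotype adjacent to the
junction.  Inserting only breakpoint sequences bounds graph size, keeps
read mapping unbiased across SV lengths and tolerates partially
characterized SV sequences.  Small variants (SNPs, indels) coexist in
the same graph as ordinary allele nodes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .sites import CoordinateError, RejectedSite, SVSite, revcomp

log = logging.getLogger(__name__)

GRAPH_DUMP_VERSION = 1

START = "START"
END = "END"


@dataclass
class GraphConfig:
    """Graph construction parameters.

    L_bp
        Maximum breakpoint-sequence length in bp.  The default follows
        the short-read length (151–152 bp Illumina reads); configurable
        per run from the observed read length.
    small_region
        Tiling window for small-variant graphs (bp, no overlap).
    sv_region, sv_overlap
        SV graphs are larger so that both breakpoints of an SV usually
        fall in one graph; consecutive windows overlap by ``sv_overlap``.
    min_anchor
        Breakpoint sequences truncated (by a contig edge) below this
        length are dropped: a shorter sequence cannot anchor a read.
    """

    L_bp: int = 152
    small_region: int = 50_000
    sv_region: int = 1_200_000
    sv_overlap: int = 200_000
    min_anchor: int = 16

    def __post_init__(self) -> None:
        if self.L_bp < 1:
            raise ValueError("L_bp must be >= 1")
        if self.sv_overlap >= self.sv_region:
            raise ValueError("sv_overlap must be smaller than sv_region")


@dataclass
class Breakpoint:
    """One SV junction with its reference and alternative sequences.

    ``anchor_pos`` is the 1-based reference position where the SV
    haplotype diverges from (START) or converges to (END) the reference.
    START sequences extend rightward from the anchor, END sequences
    leftward; ``ref_sequence`` is the same-length reference segment on
    the same side.
    """

    anchor_pos: int
    side: str
    ref_sequence: str
    alt_sequence: str
    parent_site: SVSite

    @property
    def ref_span0(self) -> tuple[int, int]:
        """Reference interval occupied by the allele node, 0-based half-open."""
        n = len(self.alt_sequence)
        if self.side == START:
            return (self.anchor_pos, self.anchor_pos + n)
        return (self.anchor_pos - n, self.anchor_pos)


def _clip(seq: str, n: int, from_start: bool) -> str:
    if n >= len(seq):
        return seq
    return seq[:n] if from_start else seq[-n:]


def make_breakpoints(site: SVSite, reference: str,
                     config: Optional[GraphConfig] = None) -> list[Breakpoint]:
    """Derive the breakpoint sequences of one SV against a reference contig.

    Returns two breakpoints (START and END) when both junction sequences
    are derivable, one when only a single junction is known (partially
    assembled insertions, breakends).  Each ``alt_sequence`` is the first
    (START) or last (END) ``min(L_bp, available)`` bases of the SV
    haplotype at that junction.

    Raises
    ------
    CoordinateError
        if the site does not fit inside the contig.
    RejectedSite
        if no junction sequence of at least one base can be derived.
    """
    config = config or GraphConfig()
    L = config.L_bp
    b0, e0 = site.span0
    n_ref = len(reference)
    if not (0 <= b0 <= e0 <= n_ref):
        raise CoordinateError(
            f"site {site} outside contig of length {n_ref}")

    bps: list[Breakpoint] = []

    def add(anchor0: int, side: str, alt: str) -> None:
        alt = alt.upper()
        if not alt:
            return
        n = len(alt)
        if side == START:
            ref_seq = reference[anchor0:anchor0 + n]
        else:
            ref_seq = reference[max(0, anchor0 - n):anchor0]
        if len(ref_seq) < n:  # contig edge: truncate both to match
            n = len(ref_seq)
            alt = alt[:n] if side == START else alt[-n:]
        if n < config.min_anchor:
            log.warning("dropping %s breakpoint of %s: only %d bp at contig "
                        "edge (< min_anchor %d)", side, site, n,
                        config.min_anchor)
            return
        bps.append(Breakpoint(anchor0, side, ref_seq.upper(), alt, site))

    t = site.sv_type
    if t == "DEL":
        add(b0, START, _clip(reference[e0:], L, True))
        add(e0, END, _clip(reference[:b0], L, False))
    elif t == "INS":
        ins = site.alt_sequence
        if not ins:
            raise RejectedSite(
                f"insertion {site} has no alternative sequence")
        if site.partial_side == "left":
            add(b0, START, _clip(ins, L, True))
        elif site.partial_side == "right":
            add(b0, END, _clip(ins, L, False))
        else:
            add(b0, START, _clip(ins + reference[b0:], L, True))
            add(b0, END, _clip(reference[:b0] + ins, L, False))
    elif t == "DUP":
        # tandem duplication: after the first copy (ending at `end`) the
        # haplotype continues with the start of the duplicated span
        add(e0, START, _clip(reference[b0:], L, True))
        add(b0, END, _clip(reference[:e0], L, False))
    elif t == "INV":
        span_rc = revcomp(reference[b0:e0])
        add(b0, START, _clip(span_rc + reference[e0:], L, True))
        add(e0, END, _clip(reference[:b0] + span_rc, L, False))
    elif t == "BND":
        if not site.alt_sequence:
            raise RejectedSite(f"breakend {site} has no junction sequence")
        side = END if site.partial_side == "right" else START
        add(b0, side, _clip(site.alt_sequence, L, side == START))
    if not bps:
        raise RejectedSite(f"no usable junction sequence for {site}")
    return bps


# ---------------------------------------------------------------------------
# graph construction


@dataclass
class GraphNode:
    node_id: int
    kind: str               # "ref_segment" | "ref_allele" | "alt_allele"
    seq: str
    span0: tuple[int, int]  # reference interval, 0-based half-open
    site_id: Optional[int] = None
    allele_index: Optional[int] = None  # 0 = ref, >=1 alternative
    breakpoint: Optional[Breakpoint] = None


@dataclass
class GraphSite:
    """One variant site in a graph and its allele loci.

    A small variant occupies a single locus; an SV typically occupies
    two (its START and END breakpoints), which are *linked*: a haplotype
    either carries the SV at both junctions or at neither.
    """

    site_id: int
    site: object                      # SVSite or small-variant tuple
    is_sv: bool
    n_alt: int
    loci: list = field(default_factory=list)   # list[(span0, [alt seqs], [Breakpoint|None])]
    overlay: bool = False
    allele_nodes: list = field(default_factory=list)


@dataclass
class SmallVariant:
    """A sequence-resolved small variant (SNP or indel) for graph insertion."""

    contig: str
    pos: int            # 1-based VCF POS
    ref: str
    alts: tuple

    @property
    def span0(self) -> tuple[int, int]:
        return (self.pos - 1, self.pos - 1 + len(self.ref))


class BreakpointGraph:
    """A serialized DAG over one reference window.

    The reference path (the chain of ``ref_segment``/``ref_allele``
    nodes) concatenates to the window's reference sequence.  Every
    consistent per-site allele assignment splices to a candidate local
    haplotype; the two breakpoints of one SV are a single linked choice.
    """

    def __init__(self, contig: str, window0: tuple[int, int],
                 window_seq: str) -> None:
        self.contig = contig
        self.window0 = window0
        self._window_seq = window_seq.upper()
        self.nodes: dict[int, GraphNode] = {}
        self.edges: list[tuple[int, int]] = []
        self.sites: list[GraphSite] = []
        self._next_id = 0

    # -- construction helpers ---------------------------------------------
    def _new_node(self, **kw) -> GraphNode:
        node = GraphNode(node_id=self._next_id, **kw)
        self.nodes[node.node_id] = node
        self._next_id += 1
        return node

    @property
    def site_index(self) -> dict:
        """Map site_id → list of allele nodes (reference first)."""
        return {s.site_id: s.allele_nodes for s in self.sites}

    def in_graph_sites(self) -> list[GraphSite]:
        return [s for s in self.sites if not s.overlay]

    def overlay_sites(self) -> list[GraphSite]:
        return [s for s in self.sites if s.overlay]

    # -- properties ---------------------------------------------------------
    def reference_path_sequence(self) -> str:
        parts = []
        for node in sorted(self.nodes.values(), key=lambda n: n.span0):
            if node.kind in ("ref_segment", "ref_allele"):
                parts.append(node.seq)
        return "".join(parts)

    def topological_order(self) -> list[int]:
        """Topological sort of node ids; raises ValueError on a cycle."""
        from collections import defaultdict, deque
        indeg: dict[int, int] = {i: 0 for i in self.nodes}
        out = defaultdict(list)
        for a, b in self.edges:
            out[a].append(b)
            indeg[b] += 1
        q = deque(sorted(i for i, d in indeg.items() if d == 0))
        order = []
        while q:
            i = q.popleft()
            order.append(i)
            for j in out[i]:
                indeg[j] -= 1
                if indeg[j] == 0:
                    q.append(j)
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a cycle")
        return order

    def n_haplotypes(self) -> int:
        """Number of candidate local haplotypes (allele combinations)."""
        n = 1
        for s in self.in_graph_sites():
            n *= 1 + s.n_alt
        return n

    def enumerate_haplotypes(self) -> Iterator[str]:
        """Splice every consistent allele assignment into a haplotype string."""
        import itertools
        sites = self.in_graph_sites()
        choices = [range(1 + s.n_alt) for s in sites]
        w0 = self.window0[0]
        for combo in itertools.product(*choices):
            edits = []
            for s, allele in zip(sites, combo):
                if allele == 0:
                    continue
                for span, alts, _bps in s.loci:
                    edits.append((span, alts[allele - 1]))
            edits.sort()
            parts, cur = [], 0
            seq = self._window_seq
            for (a, b), alt in edits:
                a -= w0
                b -= w0
                parts.append(seq[cur:a])
                parts.append(alt)
                cur = b
            parts.append(seq[cur:])
            yield "".join(parts)

    # -- serialization ------------------------------------------------------
    def to_jsonl(self, fh) -> None:
        """Dump nodes and edges as versioned JSON lines (debugging aid)."""
        fh.write(json.dumps({"record": "header",
                             "version": GRAPH_DUMP_VERSION,
                             "contig": self.contig,
                             "window0": list(self.window0)}) + "\n")
        for node in self.nodes.values():
            fh.write(json.dumps({
                "record": "node", "id": node.node_id, "kind": node.kind,
                "span0": list(node.span0), "seq": node.seq,
                "site_id": node.site_id,
                "allele_index": node.allele_index}) + "\n")
        for a, b in self.edges:
            fh.write(json.dumps({"record": "edge", "from": a, "to": b}) + "\n")


def build_graph(contig: str, window0: tuple[int, int], reference: str,
                small_variants: Sequence[SmallVariant] = (),
                sv_sites: Sequence[SVSite] = (),
                config: Optional[GraphConfig] = None) -> BreakpointGraph:
    """Build the breakpoint graph for one reference window.

    ``reference`` is the full contig sequence (SV breakpoints may need
    sequence outside the window).  Variants whose loci overlap an
    earlier-added variant's loci cannot be serialized into the DAG and
    are demoted to biallelic *overlay* records, genotyped against the
    reference-only backbone.
    """
    config = config or GraphConfig()
    w0, w1 = window0
    graph = BreakpointGraph(contig, window0, reference[w0:w1])

    # collect per-site loci
    site_id = 0
    for sv in sv_sites:
        try:
            bps = make_breakpoints(sv, reference, config)
        except RejectedSite:
            log.warning("site %s rejected from graph (no junction sequence); "
                        "coverage-model-only candidate", sv)
            continue
        loci = [(bp.ref_span0, [bp.alt_sequence], [bp]) for bp in bps]
        graph.sites.append(GraphSite(site_id, sv, True, 1, loci))
        site_id += 1
    for smv in small_variants:
        loci = [(smv.span0, list(smv.alts), [None] * len(smv.alts))]
        graph.sites.append(GraphSite(site_id, smv, False, len(smv.alts), loci))
        site_id += 1

    # serialize: accept loci greedily in coordinate order; a site whose
    # locus collides with an accepted locus becomes an overlay record
    accepted: list[tuple[tuple[int, int], GraphSite]] = []

    def collides(span: tuple[int, int]) -> bool:
        a, b = span
        return any(a < y and x < b for (x, y), _ in accepted)

    for s in sorted(graph.sites, key=lambda s: s.loci[0][0]):
        spans = sorted(span for span, _, _ in s.loci)
        self_overlap = any(spans[i][1] > spans[i + 1][0]
                           for i in range(len(spans) - 1))
        if self_overlap or any(collides(sp) for sp in spans) or any(
                x < w0 or y > w1 for x, y in spans):
            s.overlay = True
            continue
        for sp in spans:
            accepted.append((sp, s))

    # build node chain
    accepted.sort(key=lambda t: t[0])
    cur = w0
    prev_layer: list[GraphNode] = []
    for (a, b), s in accepted:
        if a > cur:
            seg = graph._new_node(kind="ref_segment",
                                  seq=reference[cur:a].upper(), span0=(cur, a))
            for p in prev_layer:
                graph.edges.append((p.node_id, seg.node_id))
            prev_layer = [seg]
        locus_idx = [sp for sp, _, _ in s.loci].index((a, b))
        _, alts, bps = s.loci[locus_idx]
        ref_node = graph._new_node(kind="ref_allele",
                                   seq=reference[a:b].upper(), span0=(a, b),
                                   site_id=s.site_id, allele_index=0)
        layer = [ref_node]
        for i, alt in enumerate(alts):
            alt_node = graph._new_node(kind="alt_allele", seq=alt,
                                       span0=(a, b), site_id=s.site_id,
                                       allele_index=i + 1,
                                       breakpoint=bps[i])
            layer.append(alt_node)
        if s.site_id is not None:
            s.allele_nodes.extend(layer)
        for p in prev_layer:
            for n in layer:
                graph.edges.append((p.node_id, n.node_id))
        prev_layer = layer
        cur = b
    if cur < w1 or not graph.nodes:
        seg = graph._new_node(kind="ref_segment",
                              seq=reference[cur:w1].upper(), span0=(cur, w1))
        for p in prev_layer:
            graph.edges.append((p.node_id, seg.node_id))
    return graph


# ---------------------------------------------------------------------------
# genome partitioning


@dataclass(frozen=True)
class Window:
    """A 1-based inclusive genomic window."""

    contig: str
    start: int
    end: int

    @property
    def span0(self) -> tuple[int, int]:
        return (self.start - 1, self.end)


def partition_genome(contig_lengths: dict[str, int],
                     config: Optional[GraphConfig] = None,
                     kind: str = "sv") -> list[Window]:
    """Tile contigs into genotyping windows.

    ``kind="small"`` gives non-overlapping ``small_region`` tiles;
    ``kind="sv"`` gives ``sv_region`` windows stepping by
    ``sv_region - sv_overlap`` so consecutive windows overlap by
    ``sv_overlap`` and both breakpoints of an SV usually share a graph.
    """
    config = config or GraphConfig()
    windows: list[Window] = []
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for contig {contig}")
        if kind == "small":
            size, step = config.small_region, config.small_region
        elif kind == "sv":
            size, step = config.sv_region, config.sv_region - config.sv_overlap
        else:
            raise ValueError(f"unknown window kind {kind!r}")
        start = 1
        while True:
            end = min(start + size - 1, length)
            windows.append(Window(contig, start, end))
            if end >= length:
                break
            start += step
    return windows
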