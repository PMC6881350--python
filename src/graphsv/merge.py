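"""Merging of SV sites discovered independently across samples.

The same SV is often reported with slightly different breakpoints in
each sample.  To avoid populating graphs with near-duplicate sites,
sites of the same type whose sizes differ by at most ``max_size_diff``
and whose begin and end positions each differ by at most
``max_pos_diff`` are clustered in a single left-to-right sweep; a site
joins a group by satisfying those criteria against *any* member
(transitive growth), but never if its begin or end lies more than
``max_group_span`` from any existing member.  Each group elects the
member with the most common (begin, end) pair as its representative,
whose INFO field is carried to the output verbatim.  Genotype columns
of the inputs are never parsed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pysam

from .sites import SVSite, read_sv_sites, sv_header, write_site_record

log = logging.getLogger(__name__)


@dataclass
class MergeConfig:
    max_size_diff: int = 100
    max_pos_diff: int = 200
    max_group_span: int = 10_000

    def __post_init__(self) -> None:
        if min(self.max_size_diff, self.max_pos_diff,
               self.max_group_span) < 0:
            raise ValueError("merge thresholds must be non-negative")
        if self.max_pos_diff > self.max_group_span:
            raise ValueError("max_pos_diff must not exceed max_group_span")


@dataclass
class MergeGroup:
    members: list

    @property
    def sv_type(self) -> str:
        return self.members[0].sv_type

    def representative(self) -> SVSite:
        return elect_representative(self)


def mergeable(a: SVSite, b: SVSite, config: Optional[MergeConfig] = None
              ) -> bool:
    """Pairwise merging criterion: same type, size within
    ``max_size_diff``, begin and end each within ``max_pos_diff``."""
    config = config or MergeConfig()
    return (a.sv_type == b.sv_type
            and abs(a.size - b.size) <= config.max_size_diff
            and abs(a.begin - b.begin) <= config.max_pos_diff
            and abs(a.end - b.end) <= config.max_pos_diff)


def _within_span(site: SVSite, group: MergeGroup, cap: int) -> bool:
    return all(abs(site.begin - m.begin) <= cap
               and abs(site.end - m.end) <= cap for m in group.members)


def group_svs(sites: Sequence[SVSite],
              config: Optional[MergeConfig] = None) -> list[MergeGroup]:
    """Cluster sorted SV sites into merge groups with one sweep.

    ``sites`` must be sorted by (contig, begin).  A site joins a
    qualifying open group (mergeable with at least one member, within
    ``max_group_span`` of every member); among several qualifying groups
    the one whose current most-common endpoint pair is nearest by
    |Δbegin| + |Δend| wins.  Otherwise the site founds a new group.
    """
    config = config or MergeConfig()
    order = [(s.contig, s.begin) for s in sites]
    if order != sorted(order):
        raise ValueError("sites must be sorted by (contig, begin)")
    groups: list[MergeGroup] = []
    open_groups: list[MergeGroup] = []
    contig = None
    for site in sites:
        if site.contig != contig:
            contig = site.contig
            open_groups = []
        # retire groups that can never be joined again
        open_groups = [g for g in open_groups
                       if site.begin - max(m.begin for m in g.members)
                       <= config.max_group_span]
        candidates = [
            g for g in open_groups
            if any(mergeable(site, m, config) for m in g.members)
            and _within_span(site, g, config.max_group_span)]
        if candidates:
            def dist(g: MergeGroup) -> tuple:
                rb, re = _most_common_pair(g)
                return (abs(site.begin - rb) + abs(site.end - re),
                        rb, re)
            best = min(candidates, key=dist)
            best.members.append(site)
        else:
            g = MergeGroup([site])
            groups.append(g)
            open_groups.append(g)
    return groups


def _most_common_pair(group: MergeGroup) -> tuple[int, int]:
    counts = Counter((m.begin, m.end) for m in group.members)
    top = max(counts.values())
    return min(pair for pair, n in counts.items() if n == top)


def elect_representative(group: MergeGroup) -> SVSite:
    """The member whose (begin, end) pair is most common in the group.

    Ties break to the smallest begin, then end, then first-seen member.
    """
    if not group.members:
        raise ValueError("empty merge group")
    pair = _most_common_pair(group)
    for m in group.members:
        if (m.begin, m.end) == pair:
            return m
    raise AssertionError("unreachable")


def merge_sites(sites: Iterable[SVSite],
                config: Optional[MergeConfig] = None
                ) -> list[tuple[SVSite, int]]:
    """Group sites per contig and return (representative, group size) pairs
    in coordinate order."""
    config = config or MergeConfig()
    ordered = sorted(sites, key=lambda s: (s.contig, s.begin, s.end,
                                           s.sv_type, s.size))
    out = []
    for g in group_svs(ordered, config):
        out.append((elect_representative(g), len(g.members)))
    out.sort(key=lambda t: (t[0].contig, t[0].begin, t[0].end))
    return out


def merge_vcfs(paths: Sequence[str], out_path: str,
               config: Optional[MergeConfig] = None) -> int:
    """Merge single-sample SV VCFs into one site-only VCF.

    Sites are streamed (genotype columns never parsed); FILTER values of
    the inputs are ignored, so non-PASS records are included.  Writes one
    record per group carrying the representative's coordinates, INFO and
    a ``NUM_MERGED_SVS`` annotation.  Returns the number of records
    written; malformed records are skipped with a logged warning.
    """
    config = config or MergeConfig()
    sites: list[SVSite] = []
    contigs: dict[str, int] = {}
    info_defs: dict[str, tuple] = {}
    for path in paths:
        with pysam.VariantFile(path) as vf:
            for name, rec in vf.header.contigs.items():
                contigs.setdefault(name, rec.length or (1 << 29))
            for key, meta in vf.header.info.items():
                info_defs.setdefault(
                    key, (meta.number, meta.type,
                          meta.description or "From input VCF"))
        for site in read_sv_sites(path, skip_malformed=True):
            sites.append(site)
    merged = merge_sites(sites, config)
    header = sv_header(
        sorted(contigs.items()),
        extra_info=[("NUM_MERGED_SVS", "1", "Integer",
                     "Number of SV sites merged into this record"),
                    ("SVMODEL", "1", "String", "SV merging model")]
        + [(k, n, t, d) for k, (n, t, d) in info_defs.items()
           if k not in ("SVTYPE", "SVLEN", "END")])
    header.add_line(f"##graphsv_mergeConfig=max_size_diff={config.max_size_diff},"
                    f"max_pos_diff={config.max_pos_diff},"
                    f"max_group_span={config.max_group_span}")
    with pysam.VariantFile(out_path, "w", header=header) as out:
        for rep, n in merged:
            write_site_record(out, header, rep,
                              extra_info={"NUM_MERGED_SVS": n,
                                          "SVMODEL": "AGGREGATED"})
    return len(merged)
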