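"""End-to-end SV genotyping: windows → graphs → realignment → calls.

For each SV window the pipeline builds a breakpoint graph from the merged
site list, extracts each sample's reads, realigns them, computes the
breakpoint- and coverage-model likelihoods and emits the aggregated
per-sample calls as a multi-sample VCF.  Sites falling in the overlap of
consecutive windows are genotyped twice and deduplicated by keeping the
higher-quality record (ties go to the earlier window).
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from typing import Optional

import numpy as np
import pysam

from . import __version__
from .genotype import (MIN_COVERAGE_MODEL_SPAN, GenotypeCall,
                       HighConfidenceFilter, ModelNotApplicable,
                       aggregate_call, breakpoint_genotype, coverage_genotype,
                       coverage_profile, filter_calls)
from .graph import BreakpointGraph, GraphConfig, Window, build_graph, \
    partition_genome
from .realign import AlignConfig, extract_reads, realign_all
from .sites import SVSite, read_sv_sites

log = logging.getLogger(__name__)


class DataError(RuntimeError):
    """Unreadable or inconsistent input data."""


def _depth_array(bam_path: str, contig: str, span0: tuple[int, int],
                 reference: Optional[str] = None) -> np.ndarray:
    lo, hi = span0
    kw = {"reference_filename": reference} if reference else {}
    with pysam.AlignmentFile(bam_path, **kw) as af:
        if contig not in af.references:
            return np.zeros(hi - lo, dtype=np.int32)
        hi = min(hi, af.get_reference_length(contig))
        if lo >= hi:
            return np.zeros(0, dtype=np.int32)
        cov = af.count_coverage(contig, lo, hi)
    return np.asarray(cov).sum(axis=0).astype(np.int32)


def genotype_window(window: Window, sites: list[SVSite], reference: str,
                    bams: dict[str, str], fasta_path: Optional[str],
                    graph_config: GraphConfig, align_config: AlignConfig
                    ) -> dict[tuple, dict[str, GenotypeCall]]:
    """Genotype one window's SV sites across all samples."""
    w0, w1 = window.span0
    graph = build_graph(window.contig, (w0, w1), reference,
                        sv_sites=sites, config=graph_config)
    id_to_site = {gs.site_id: gs.site for gs in graph.sites if gs.is_sv}
    spans = {sid: s.span0 for sid, s in id_to_site.items()}
    calls: dict[tuple, dict[str, GenotypeCall]] = {}
    for sample, bam in bams.items():
        reads = extract_reads(bam, window.contig, (w0, w1),
                              padding=align_config.extraction_padding,
                              reference=fasta_path)
        by_site = realign_all(reads, graph, align_config)
        depth_lo = max(0, w0 - 1100)
        depth = _depth_array(bam, window.contig,
                             (depth_lo, w1 + 1100), fasta_path)

        def depth_at(p: int, _d=depth, _lo=depth_lo) -> int:
            i = p - _lo
            return int(_d[i]) if 0 <= i < len(_d) else 0

        for sid, site in id_to_site.items():
            bp_gl = breakpoint_genotype(by_site.get(sid, []),
                                        site_id=sid, sample=sample)
            cov_gl = None
            span = site.end - site.begin
            if (site.sv_type in ("DEL", "DUP")
                    and span >= MIN_COVERAGE_MODEL_SPAN):
                exclude = [sp for osid, sp in spans.items() if osid != sid]
                prof = coverage_profile(depth_at, site,
                                        exclude_spans=exclude, site_id=sid)
                try:
                    cov_gl = coverage_genotype(prof, site.sv_type, sample)
                except ModelNotApplicable:  # pragma: no cover
                    cov_gl = None
            call = aggregate_call(bp_gl, cov_gl)
            call.sample = sample
            calls.setdefault(site.key, {})[sample] = call
    return calls


def genotype_sv(bams: dict[str, str], sv_vcf: str, reference_fasta: str,
                out_vcf: str,
                graph_config: Optional[GraphConfig] = None,
                align_config: Optional[AlignConfig] = None,
                hc_filter: Optional[HighConfidenceFilter] = None,
                drop_allref: bool = True) -> dict:
    """Genotype the SV sites of ``sv_vcf`` in every sample and write a
    multi-sample VCF.  Returns {site key: {sample: GenotypeCall}} for the
    retained sites."""
    graph_config = graph_config or GraphConfig()
    align_config = align_config or AlignConfig()
    try:
        fa = pysam.FastaFile(reference_fasta)
    except OSError as e:
        raise DataError(f"cannot read reference {reference_fasta}: {e}")
    sites = list(read_sv_sites(sv_vcf))
    by_contig: dict[str, list[SVSite]] = {}
    for s in sites:
        by_contig.setdefault(s.contig, []).append(s)

    merged: dict[tuple, dict[str, GenotypeCall]] = {}
    win_of: dict[tuple, int] = {}
    contig_lengths = {c: fa.get_reference_length(c)
                      for c in by_contig if c in fa.references}
    windows = partition_genome(contig_lengths, graph_config, kind="sv")
    for wi, window in enumerate(windows):
        w0, w1 = window.span0
        contig_sites = by_contig.get(window.contig, [])
        in_win = [s for s in contig_sites
                  if w0 <= s.begin and s.end <= w1]
        # a site too large for any single window is genotyped in the
        # window holding its start breakpoint (less accurate, logged)
        stray = [s for s in contig_sites
                 if w0 <= s.begin < w1 and s.end > w1
                 and not any(v.span0[0] <= s.begin and s.end <= v.span0[1]
                             for v in windows if v.contig == s.contig)]
        for s in stray:
            log.warning("SV %s spans beyond its window; breakpoints may be "
                        "on different graphs", s)
        use = in_win + stray
        if not use:
            continue
        reference = fa.fetch(window.contig)
        try:
            wcalls = genotype_window(window, use, reference, bams,
                                     reference_fasta, graph_config,
                                     align_config)
        except Exception as e:
            raise DataError(
                f"genotyping failed in window {window.contig}:"
                f"{window.start}-{window.end}: {e}") from e
        for key, per_sample in wcalls.items():
            if key not in merged:
                merged[key] = per_sample
                win_of[key] = wi
            else:
                old = max(c.gq for c in merged[key].values())
                new = max(c.gq for c in per_sample.values())
                if new > old:
                    merged[key] = per_sample
                    win_of[key] = wi

    site_by_key = {s.key: s for s in sites}
    calls_by_site = {k: list(v.values()) for k, v in merged.items()}
    if drop_allref:
        kept = filter_calls(calls_by_site, hc_filter)
    else:
        kept = calls_by_site
        for calls in kept.values():
            hc = (hc_filter or HighConfidenceFilter()).site_passes(calls)
            for c in calls:
                c.passed_filters["high_confidence"] = hc
    _write_calls_vcf(out_vcf, fa, site_by_key, merged, kept,
                     sorted(bams), graph_config, align_config)
    fa.close()
    return {k: merged[k] for k in kept}


def _write_calls_vcf(out_vcf, fa, site_by_key, merged, kept, samples,
                     graph_config, align_config) -> None:
    header = pysam.VariantHeader()
    for c in fa.references:
        header.contigs.add(c, length=fa.get_reference_length(c))
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", ".", "Integer", "Length of structural variant")
    header.filters.add("LOW_CONFIDENCE", None, None,
                       "Did not pass the aggregate high-confidence filter")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("PL", "G", "Integer",
                       "Phred-scaled genotype likelihoods of chosen model")
    header.formats.add("MOD", 1, "String",
                       "Genotype model used (BREAKPOINT/COVERAGE/AGGREGATED)")
    header.add_line(f"##graphsv_version={__version__}")
    header.add_line("##graphsv_graphConfig=" + ",".join(
        f"{k}={v}" for k, v in asdict(graph_config).items()))
    header.add_line("##graphsv_alignConfig=" + ",".join(
        f"{k}={v}" for k, v in asdict(align_config).items()))
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(out_vcf, "w", header=header) as out:
        for key in sorted(kept, key=lambda k: (k[0], k[1], k[2])):
            site = site_by_key[key]
            per_sample = merged[key]
            ref_base = fa.fetch(site.contig, site.begin - 1, site.begin) or "N"
            rec = out.new_record(contig=site.contig, start=site.begin - 1,
                                 alleles=(ref_base, f"<{site.sv_type}>"),
                                 stop=site.end)
            rec.info["SVTYPE"] = site.sv_type
            rec.info["SVLEN"] = (-site.size if site.sv_type == "DEL"
                                 else site.size,)
            hc = any(c.passed_filters.get("high_confidence")
                     for c in per_sample.values())
            rec.filter.add("PASS" if hc else "LOW_CONFIDENCE")
            for s in samples:
                call = per_sample.get(s)
                if call is None:
                    rec.samples[s]["GT"] = (None, None)
                    continue
                rec.samples[s]["GT"] = call.genotype
                rec.samples[s]["GQ"] = call.gq
                rec.samples[s]["PL"] = list(call.pl())
                rec.samples[s]["MOD"] = call.model_used
            out.write(rec)
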