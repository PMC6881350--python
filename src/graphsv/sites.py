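"""Structural-variant site records and their VCF representation.

An :class:`SVSite` is one structural variant — a deletion, insertion,
duplication, inversion or single breakend — with 1-based anchor
coordinates as they appear in VCF.  ``begin`` is the last reference base
before the event and ``end`` the last reference base of the event, so the
affected reference span in 0-based half-open coordinates is numerically
``[begin, end)``.  For insertions ``end == begin`` (point events).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

SV_TYPES = ("DEL", "INS", "DUP", "INV", "BND")

#: Minimum size for a variant to count as structural.
MIN_SV_SIZE = 50

_DNA_RE = re.compile(r"^[ACGTRYSWKMBDHVNacgtryswkmbdhvn]*$")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """A site's coordinates do not fit the reference contig."""


class RejectedSite(ValueError):
    """A site cannot be encoded (e.g. zero-length alternative haplotype)."""


@dataclass
class SVSite:
    """One structural variant site.

    Parameters
    ----------
    contig : str
        Reference contig name.
    begin : int
        1-based position of the last reference base before the event
        (VCF POS convention for symbolic SV alleles).
    end : int
        1-based position of the last reference base of the event; equals
        ``begin`` for insertions.
    sv_type : str
        One of ``DEL``, ``INS``, ``DUP``, ``INV``, ``BND``.
    size : int
        Event size in bp: inserted-sequence length for INS, reference span
        for DEL/DUP/INV.
    alt_sequence : str
        The alternative sequence where known (inserted bases for INS);
        possibly partial or empty for imprecise sites.
    info : dict
        INFO key→value pairs carried verbatim from the source VCF.
    sample_of_origin : str or None
        Sample the site was discovered in, when known.
    partial_side : str or None
        For an insertion whose sequence is only partially assembled:
        ``"left"`` if ``alt_sequence`` is the fragment adjacent to the
        start junction, ``"right"`` for the end junction. ``None`` means
        the sequence is complete (or absent).
    """

    contig: str
    begin: int
    end: int
    sv_type: str
    size: int
    alt_sequence: str = ""
    info: dict = field(default_factory=dict)
    sample_of_origin: Optional[str] = None
    partial_side: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.begin > self.end:
            raise ValueError(
                f"begin {self.begin} > end {self.end} for {self.sv_type} site")
        if self.size < 0:
            raise ValueError("size must be non-negative")
        if self.alt_sequence and not _DNA_RE.match(self.alt_sequence):
            raise ValueError("alt_sequence contains non-IUPAC characters")

    # -- coordinate helpers ------------------------------------------------
    @property
    def span0(self) -> tuple[int, int]:
        """Affected reference interval, 0-based half-open."""
        return (self.begin, self.end)

    @property
    def key(self) -> tuple:
        return (self.contig, self.begin, self.end, self.sv_type, self.size)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.sv_type}:{self.contig}:{self.begin}-{self.end}({self.size}bp)"


def _first(v):
    """INFO values from pysam arrive as tuples for Number!=1 fields."""
    if isinstance(v, (tuple, list)):
        return v[0] if v else None
    return v


def site_from_record(rec, alt_index: int = 0,
                     sample_of_origin: Optional[str] = None) -> Optional[SVSite]:
    """Build an :class:`SVSite` from a pysam VariantRecord alternative allele.

    Recognizes symbolic alleles (``<DEL>``, ``<INS>``, ``<DUP>``, ``<INV>``,
    ``<DUP:TANDEM>`` ...), breakend notation, and sequence-resolved alleles
    whose length difference from the reference is at least ``MIN_SV_SIZE``.
    Returns ``None`` for alleles that are not structural.
    """
    if rec.alts is None or alt_index >= len(rec.alts):
        return None
    alt = rec.alts[alt_index]
    ref = rec.ref or ""
    info = dict(rec.info)
    pos = rec.pos  # 1-based

    svtype = _first(info.get("SVTYPE"))
    svlen = _first(info.get("SVLEN"))
    end = info.get("END", rec.stop)  # rec.stop is 0-based end -> equals END

    if alt.startswith("<"):
        base = alt.strip("<>").split(":")[0]
        if svtype is None:
            svtype = base
        if base in ("DUP", "CNV"):
            svtype = "DUP"
        if svtype not in SV_TYPES:
            return None
        if svtype == "INS":
            size = abs(int(svlen)) if svlen is not None else 0
            return SVSite(rec.contig, pos, pos, "INS", size, "", info,
                          sample_of_origin)
        end = int(end)
        if end <= pos and svlen is not None:
            end = pos + abs(int(svlen))
        return SVSite(rec.contig, pos, end, svtype, end - pos, "", info,
                      sample_of_origin)

    if "[" in alt or "]" in alt:
        return SVSite(rec.contig, pos, pos, "BND", 0, "", info,
                      sample_of_origin)

    # sequence-resolved
    if abs(len(alt) - len(ref)) < MIN_SV_SIZE:
        return None
    if len(ref) > len(alt):
        # deletion: POS anchors the base before the deleted run
        return SVSite(rec.contig, pos, pos + len(ref) - len(alt), "DEL",
                      len(ref) - len(alt), "", info, sample_of_origin)
    inserted = alt[len(ref):] if alt.startswith(ref) else alt[1:]
    return SVSite(rec.contig, pos, pos, "INS", len(alt) - len(ref),
                  inserted, info, sample_of_origin)


def read_sv_sites(path: str, sample_of_origin: Optional[str] = None,
                  skip_malformed: bool = False) -> Iterator[SVSite]:
    """Yield SV sites from a VCF/BCF file, decomposing multi-allelic records."""
    with pysam.VariantFile(path) as vf:
        origin = sample_of_origin
        if origin is None and list(vf.header.samples):
            origin = list(vf.header.samples)[0]
        for rec in vf:
            try:
                for i in range(len(rec.alts or ())):
                    site = site_from_record(rec, i, origin)
                    if site is not None:
                        yield site
            except (ValueError, KeyError):
                if not skip_malformed:
                    raise


def sv_header(contigs: Iterable[tuple[str, int]],
              extra_info: Iterable[tuple[str, str, str, str]] = (),
              samples: Iterable[str] = ()) -> pysam.VariantHeader:
    """A VCF header with the standard SV INFO keys and given contigs."""
    h = pysam.VariantHeader()
    for name, length in contigs:
        h.contigs.add(name, length=length)
    h.info.add("SVTYPE", 1, "String", "Type of structural variant")
    h.info.add("SVLEN", ".", "Integer", "Length of structural variant")
    for key, number, vtype, descr in extra_info:
        if key not in h.info:
            h.info.add(key, number, vtype, descr)
    for s in samples:
        h.add_sample(s)
    return h


def write_site_record(vcf_out, header, site: SVSite, ref_base: str = "N",
                      gt=None, extra_info: Optional[dict] = None) -> None:
    """Append one SV site to an open pysam VariantFile."""
    if site.sv_type == "INS" and site.alt_sequence and not site.partial_side:
        # sequence-resolved insertions keep their sequence in the ALT
        alleles = (ref_base, ref_base + site.alt_sequence)
    else:
        alleles = (ref_base, f"<{site.sv_type}>")
    rec = vcf_out.new_record(
        contig=site.contig, start=site.begin - 1, alleles=alleles,
        stop=site.end)
    rec.info["SVTYPE"] = site.sv_type
    rec.info["SVLEN"] = (-site.size if site.sv_type == "DEL" else site.size,)
    for k, v in site.info.items():
        if k in ("SVTYPE", "SVLEN", "END"):
            continue
        if k in header.info:
            try:
                rec.info[k] = v
            except (TypeError, ValueError):
                pass
    if extra_info:
        for k, v in extra_info.items():
            rec.info[k] = v
    if gt is not None:
        rec.samples[0]["GT"] = gt
    vcf_out.write(rec)
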