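"""Synthetic diploid and pedigree fixtures with planted SVs.

Generates a random reference contig, plants non-overlapping deletions,
insertions, tandem duplications and inversions with known phased diploid
genotypes across a multi-family pedigree, and simulates paired short
reads with naive linear-reference placements (soft-clipping read bases
that cross planted junctions, and emitting reads wholly inside inserted
sequence as unmapped with a mapped mate) — the same conventions a linear
aligner produces, so the extraction and realignment machinery sees
realistic input without any external downloads.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .evaluate import PedigreeTrio
from .sites import SVSite, revcomp, sv_header, write_site_record

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults emulate a 30× Illumina run with 151 bp paired reads over a
    contig large enough to hold 20 SVs of each type at the enforced
    ≥ 2 kb spacing (spacing keeps the 1000 bp coverage-model windows of
    neighbouring SVs from colliding).  Founder alternative-allele
    frequencies are drawn uniformly from a low range, mirroring the
    rare-variant-skewed site frequency spectrum of real SV callsets.
    The pedigree is four families with 8 parents and 48 offspring.
    """

    seed: int = 1
    contig_name: str = "sim1"
    contig_length: int = 600_000
    n_sv_per_type: dict = field(default_factory=lambda: {
        "DEL": 20, "INS": 20, "DUP": 20, "INV": 20})
    sv_size_range: tuple = (100, 1000)
    min_sv_spacing: int = 2000
    edge_margin: int = 5000
    coverage: float = 30.0
    read_length: int = 151
    fragment_mean: int = 420
    fragment_sd: int = 50
    base_error_rate: float = 0.01
    alt_freq_range: tuple = (0.05, 0.5)
    families: tuple = (10, 10, 11, 17)
    breakpoint_jitter: int = 30
    dropout: float = 0.0

    def rng(self, *stream) -> np.random.Generator:
        return np.random.default_rng([self.seed % (1 << 31), *stream])


@dataclass
class Segment:
    """Mapping of a haplotype interval back to the reference.

    kind: ``ref`` colinear forward; ``dup`` second tandem copy (maps
    forward onto the duplicated span); ``inv`` reverse-complemented
    span; ``ins`` inserted sequence with no reference projection.
    """

    hap_start: int
    hap_end: int
    kind: str
    ref_start: int
    ref_end: int


@dataclass
class Haplotype:
    sequence: str
    segments: list


@dataclass
class SimTruth:
    """All ground truth of one simulation."""

    config: SimConfig
    reference: str
    sites: list                       # list[SVSite], coordinate order
    samples: list                     # ordered sample names
    genotypes: dict                   # sample -> (n_sites, 2) int8, phased
    trios: list                       # list[PedigreeTrio]
    allele_freqs: np.ndarray
    transmissions: list               # (site_idx, offspring, parent, bool)

    def genotype(self, sample: str, site_idx: int) -> tuple[int, int]:
        return tuple(sorted(int(a) for a in self.genotypes[sample][site_idx]))

    def haplotype(self, sample: str, hap: int) -> Haplotype:
        return splice_haplotype(self.reference, self.sites,
                                self.genotypes[sample][:, hap])


def simulate_reference(length: int, rng: np.random.Generator) -> str:
    """Uniform-random DNA contig of the given length."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def plant_svs(reference: str, config: SimConfig) -> SimTruth:
    """Plant SVs with phased pedigree genotypes on a reference contig.

    SVs are non-overlapping and at least ``min_sv_spacing`` bp apart.
    Offspring haplotypes obey Mendelian transmission (haplotype 0 from
    the father, 1 from the mother) and every transmission from a
    heterozygous parent is recorded.
    """
    rng = config.rng(2)
    L = len(reference)
    types = [t for t, n in config.n_sv_per_type.items() for _ in range(n)]
    order = rng.permutation(len(types))
    types = [types[i] for i in order]
    lo, hi = config.sv_size_range
    sizes = rng.integers(lo, hi + 1, size=len(types))
    ref_spans = [0 if t == "INS" else int(s)
                 for t, s in zip(types, sizes)]
    n = len(types)
    need = (2 * config.edge_margin + sum(ref_spans)
            + (n - 1) * config.min_sv_spacing)
    if need > L:
        raise ValueError(
            f"contig of {L} bp cannot hold {n} SVs "
            f"({need} bp required with spacing)")
    free = L - need
    cuts = np.sort(rng.integers(0, free + 1, size=n))
    increments = np.diff(np.concatenate([[0], cuts]))

    sites: list[SVSite] = []
    cursor = config.edge_margin
    for i, (t, size, span) in enumerate(zip(types, sizes, ref_spans)):
        cursor += int(increments[i]) + (config.min_sv_spacing if i else 0)
        begin = cursor
        end = begin + span
        alt = _random_dna(int(size), rng) if t == "INS" else ""
        sites.append(SVSite(config.contig_name, begin, end, t, int(size), alt,
                            info={"SIM_INDEX": i}))
        cursor = end
    sites.sort(key=lambda s: s.begin)

    # pedigree
    samples: list[str] = []
    trios: list[PedigreeTrio] = []
    families = []
    for fi, n_off in enumerate(config.families, start=1):
        father, mother = f"fam{fi}_father", f"fam{fi}_mother"
        offspring = [f"fam{fi}_child{ci:02d}" for ci in range(1, n_off + 1)]
        samples.extend([father, mother] + offspring)
        trios.extend(PedigreeTrio(father, mother, c) for c in offspring)
        families.append((father, mother, offspring))

    n_sites = len(sites)
    grng = config.rng(3)
    f_lo, f_hi = config.alt_freq_range
    freqs = grng.uniform(f_lo, f_hi, size=n_sites)
    genotypes: dict[str, np.ndarray] = {}
    for father, mother, offspring in families:
        for parent in (father, mother):
            genotypes[parent] = (grng.random((n_sites, 2))
                                 < freqs[:, None]).astype(np.int8)
    transmissions = []
    for father, mother, offspring in families:
        for child in offspring:
            g = np.zeros((n_sites, 2), dtype=np.int8)
            for hap, parent in ((0, father), (1, mother)):
                pick = grng.integers(0, 2, size=n_sites)
                g[:, hap] = genotypes[parent][np.arange(n_sites), pick]
                pg = genotypes[parent]
                for si in np.nonzero(pg[:, 0] != pg[:, 1])[0]:
                    transmissions.append(
                        (int(si), child, parent, bool(g[si, hap])))
            genotypes[child] = g
    return SimTruth(config, reference, sites, samples, genotypes, trios,
                    freqs, transmissions)


def splice_haplotype(reference: str, sites: Sequence[SVSite],
                     alleles: Sequence[int]) -> Haplotype:
    """Realize one haplotype by splicing the carried SV alleles."""
    parts: list[str] = []
    segments: list[Segment] = []
    cur = 0
    hp = 0

    def emit(seq: str, kind: str, ref_start: int, ref_end: int) -> None:
        nonlocal hp
        if not seq:
            return
        segments.append(Segment(hp, hp + len(seq), kind, ref_start, ref_end))
        parts.append(seq)
        hp += len(seq)

    for site, allele in zip(sites, alleles):
        if not allele:
            continue
        b0, e0 = site.span0
        emit(reference[cur:b0], "ref", cur, b0)
        if site.sv_type == "DEL":
            pass
        elif site.sv_type == "INS":
            emit(site.alt_sequence, "ins", b0, b0)
        elif site.sv_type == "DUP":
            emit(reference[b0:e0], "ref", b0, e0)
            emit(reference[b0:e0], "dup", b0, e0)
        elif site.sv_type == "INV":
            emit(revcomp(reference[b0:e0]), "inv", b0, e0)
        else:
            emit(reference[b0:e0], "ref", b0, e0)
        cur = e0
    emit(reference[cur:], "ref", cur, len(reference))
    return Haplotype("".join(parts), segments)


# ---------------------------------------------------------------------------
# read simulation


def _project(segments: Sequence[Segment], s: int, e: int, min_anchor: int = 16):
    """Project a haplotype interval to its best linear placement.

    Returns (ref_pos, clip_left, n_match, strand_flip), where
    ``clip_left`` counts soft-clipped bases in haplotype orientation,
    or None when no mappable piece of at least ``min_anchor`` bp exists
    (read inside an insertion, or junction fragments too short).
    """
    best = None
    for seg in segments:
        ps, pe = max(s, seg.hap_start), min(e, seg.hap_end)
        if pe - ps < min_anchor or seg.kind == "ins":
            continue
        if best is None or (pe - ps) > best[0]:
            if seg.kind == "inv":
                ref_pos = seg.ref_start + (seg.hap_end - pe)
            else:
                ref_pos = seg.ref_start + (ps - seg.hap_start)
            best = (pe - ps, ref_pos, ps - s, seg.kind == "inv")
    if best is None:
        return None
    n_match, ref_pos, clip_left, flip = best
    return ref_pos, clip_left, n_match, flip


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    arr = bytearray(seq, "ascii")
    lut = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
    for p in pos:
        cur = arr[p]
        arr[p] = lut.get(cur, b"ACG")[rng.integers(0, 3)]
    return arr.decode()


def simulate_reads(truth: SimTruth, sample: str, out_bam: str,
                   min_anchor: int = 16) -> str:
    """Simulate paired reads for one sample and write a sorted, indexed
    alignment file with naive linear-reference placements."""
    cfg = truth.config
    rl = cfg.read_length
    rng = cfg.rng(4, truth.samples.index(sample))
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": cfg.contig_name, "LN": len(truth.reference)}],
        "RG": [{"ID": sample, "SM": sample}],
    })
    quals = pysam.qualitystring_to_array("?" * rl)  # constant Q30
    records = []
    for hap_i in (0, 1):
        hap = truth.haplotype(sample, hap_i)
        hlen = len(hap.sequence)
        n_frags = int(hlen * (cfg.coverage / 2.0) / (2 * rl))
        flens = np.clip(
            rng.normal(cfg.fragment_mean, cfg.fragment_sd, n_frags),
            rl, None).astype(int)
        starts = (rng.random(n_frags) * (hlen - flens)).astype(int)
        for fi in range(n_frags):
            s, flen = int(starts[fi]), int(flens[fi])
            r1_iv = (s, s + rl)
            r2_iv = (s + flen - rl, s + flen)
            name = f"sim:{sample}:{hap_i}:{fi}"
            mates = []
            for ri, (a, b) in enumerate((r1_iv, r2_iv)):
                seq = _apply_errors(hap.sequence[a:b], rng,
                                    cfg.base_error_rate)
                proj = _project(hap.segments, a, b, min_anchor)
                mates.append((ri, seq, proj))
            if all(m[2] is None for m in mates):
                continue
            for (ri, hap_seq, proj), (_, _, mproj) in (
                    (mates[0], mates[1]), (mates[1], mates[0])):
                rec = pysam.AlignedSegment(header)
                rec.query_name = name
                rec.is_paired = True
                rec.is_read1 = ri == 0
                rec.is_read2 = ri == 1
                # read2 was sequenced from the other fragment strand
                seq_strand_rev = ri == 1
                if proj is None:
                    # inside inserted sequence: unmapped, placed at mate
                    rec.is_unmapped = True
                    rec.reference_id = 0
                    rec.reference_start = mproj[0]
                    rec.query_sequence = (revcomp(hap_seq) if seq_strand_rev
                                          else hap_seq)
                    rec.query_qualities = quals
                    rec.mapping_quality = 0
                else:
                    ref_pos, clip_left, n_match, flip = proj
                    # SEQ is stored reference-forward: for a piece inside an
                    # inverted span that is the reverse complement of the
                    # haplotype-forward read
                    if flip:
                        rec.query_sequence = revcomp(hap_seq)
                        cl = len(hap_seq) - clip_left - n_match
                    else:
                        rec.query_sequence = hap_seq
                        cl = clip_left
                    cig = []
                    if cl:
                        cig.append((4, cl))
                    cig.append((0, n_match))
                    cr = len(hap_seq) - cl - n_match
                    if cr:
                        cig.append((4, cr))
                    rec.reference_id = 0
                    rec.reference_start = ref_pos
                    rec.mapping_quality = 60
                    rec.cigartuples = cig
                    rec.is_reverse = seq_strand_rev != flip
                    rec.query_qualities = quals
                rec.next_reference_id = 0
                if mproj is None:
                    rec.mate_is_unmapped = True
                    rec.next_reference_start = rec.reference_start
                else:
                    rec.next_reference_start = mproj[0]
                rec.set_tag("RG", sample)
                records.append(rec)
    tmp = out_bam + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for rec in sorted(records, key=lambda r: r.reference_start):
            bam.write(rec)
    pysam.sort("-o", out_bam, tmp)
    os.remove(tmp)
    pysam.index(out_bam)
    return out_bam


# ---------------------------------------------------------------------------
# writers


def write_reference_fasta(truth: SimTruth, path: str) -> str:
    with open(path, "w") as fh:
        fh.write(f">{truth.config.contig_name}\n")
        seq = truth.reference
        for i in range(0, len(seq), 60):
            fh.write(seq[i:i + 60] + "\n")
    pysam.faidx(path)
    return path


def write_truth_vcf(truth: SimTruth, path: str,
                    samples: Optional[Sequence[str]] = None) -> str:
    """Cohort truth VCF with per-sample genotypes for all planted SVs."""
    samples = list(samples) if samples is not None else truth.samples
    header = sv_header([(truth.config.contig_name, len(truth.reference))],
                       samples=samples)
    header.formats.add("GT", 1, "String", "Genotype")
    with pysam.VariantFile(path, "w", header=header) as out:
        for si, site in enumerate(truth.sites):
            ref_base = truth.reference[site.begin - 1]
            if site.sv_type == "INS" and site.alt_sequence:
                alleles = (ref_base, ref_base + site.alt_sequence)
            else:
                alleles = (ref_base, f"<{site.sv_type}>")
            rec = out.new_record(contig=site.contig, start=site.begin - 1,
                                 alleles=alleles, stop=site.end)
            rec.info["SVTYPE"] = site.sv_type
            rec.info["SVLEN"] = (-site.size if site.sv_type == "DEL"
                                 else site.size,)
            for s in samples:
                rec.samples[s]["GT"] = tuple(
                    int(a) for a in truth.genotypes[s][si])
                rec.samples[s].phased = True
            out.write(rec)
    return path


def write_ped(truth: SimTruth, path: str) -> str:
    lines = []
    fam_of = {}
    for t in truth.trios:
        fam = t.offspring.split("_")[0]
        fam_of[t.father] = fam
        fam_of[t.mother] = fam
        fam_of[t.offspring] = fam
    for s in truth.samples:
        fam = fam_of.get(s, s.split("_")[0])
        trio = next((t for t in truth.trios if t.offspring == s), None)
        father = trio.father if trio else "0"
        mother = trio.mother if trio else "0"
        sex = "1" if s.endswith("father") else ("2" if s.endswith("mother")
                                                else "0")
        lines.append(f"{fam}\t{s}\t{father}\t{mother}\t{sex}\t0")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def write_manifest(truth: SimTruth, path: str) -> str:
    doc = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(truth.config).items()},
        "sites": [{"index": i, "contig": s.contig, "begin": s.begin,
                   "end": s.end, "type": s.sv_type, "size": s.size}
                  for i, s in enumerate(truth.sites)],
        "samples": truth.samples,
        "genotypes": {s: truth.genotypes[s].tolist()
                      for s in truth.samples},
        "transmissions": [
            {"site": si, "offspring": c, "parent": p, "transmitted": tr}
            for si, c, p, tr in truth.transmissions],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return path


def degrade_callset(truth: SimTruth, out_dir: str,
                    samples: Optional[Sequence[str]] = None,
                    jitter: Optional[int] = None,
                    dropout: Optional[float] = None) -> list[str]:
    """Re-emit the truth SVs per sample with breakpoint jitter/dropout,
    as valid single-sample VCFs (emulating independent discovery)."""
    cfg = truth.config
    jitter = cfg.breakpoint_jitter if jitter is None else jitter
    dropout = cfg.dropout if dropout is None else dropout
    samples = list(samples) if samples is not None else truth.samples
    paths = []
    os.makedirs(out_dir, exist_ok=True)
    for s in samples:
        rng = cfg.rng(5, truth.samples.index(s))
        header = sv_header([(cfg.contig_name, len(truth.reference))],
                           samples=[s])
        header.formats.add("GT", 1, "String", "Genotype")
        path = os.path.join(out_dir, f"{s}.sv.vcf")
        with pysam.VariantFile(path, "w", header=header) as out:
            for si, site in enumerate(truth.sites):
                if dropout > 0 and rng.random() < dropout:
                    continue
                db = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                de = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                begin = max(1, site.begin + db)
                alt_seq = ""
                if site.sv_type == "INS":
                    end = begin
                    if site.alt_sequence:
                        # keep the discovered sequence; jitter position only
                        alt_seq = site.alt_sequence
                        size = site.size
                    else:
                        size = max(50, site.size + de)
                else:
                    end = max(begin + 50, site.end + de)
                    size = end - begin
                jsite = SVSite(site.contig, begin, end, site.sv_type, size,
                               alt_seq, info=dict(site.info))
                gt = tuple(sorted(int(a) for a in truth.genotypes[s][si]))
                write_site_record(out, header, jsite,
                                  ref_base=truth.reference[begin - 1],
                                  gt=gt)
        paths.append(path)
    return paths


def simulate_all(config: SimConfig, out_dir: str,
                 read_samples: Optional[Sequence[str]] = None) -> dict:
    """Run the full simulation and write every artifact to ``out_dir``.

    ``read_samples`` limits alignment-file generation (the expensive
    step) to the given samples; truth VCF, PED, FASTA and manifest always
    cover the whole pedigree.
    """
    os.makedirs(out_dir, exist_ok=True)
    reference = simulate_reference(config.contig_length, config.rng(1))
    truth = plant_svs(reference, config)
    paths = {
        "fasta": write_reference_fasta(truth,
                                       os.path.join(out_dir, "ref.fa")),
        "truth_vcf": write_truth_vcf(truth,
                                     os.path.join(out_dir, "truth.vcf")),
        "ped": write_ped(truth, os.path.join(out_dir, "pedigree.ped")),
        "manifest": write_manifest(truth,
                                   os.path.join(out_dir, "manifest.json")),
        "bams": {},
    }
    for s in (read_samples or ()):
        paths["bams"][s] = simulate_reads(
            truth, s, os.path.join(out_dir, f"{s}.bam"))
    return {"truth": truth, "paths": paths}
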