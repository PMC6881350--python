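"""Genotype likelihood models for structural variants.

Two models are computed per biallelic SV and sample:

* the **breakpoint model**, from counts of realigned reads supporting the
  reference vs the SV breakpoint allele.  The relative likelihood of a
  genotype ``G_xy`` is the product over overlapping reads of a per-read
  term: 1 if the read supports both ``x`` and ``y``, 1/2 if it supports
  exactly one, and ``ε_r`` if it supports neither, where ``ε_r = 2⁻⁸``
  for a paired read whose mate also aligned to the graph and ``2⁻⁴``
  otherwise;
* the **coverage model** (deletions and duplications, including inverted
  duplications), from the median alignment coverage inside the SV
  (``c_in``) versus two 1000 bp flanking windows (``c_out``), sampled
  every 20 bp.  The coverage decrease ``max(0, c_out − c_in)`` acts as
  the number of pseudo-reads supporting a deletion and ``c_in`` as the
  number supporting the reference; duplications use the coverage
  increase instead.  Pseudo-reads are unambiguous and unpaired, so
  ``ε = 2⁻⁴``.

The aggregated call is the call of whichever model has the higher
genotyping quality (phred-scaled ratio of best to second-best
likelihood, capped at 99).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .realign import AlleleSupport
from .sites import SVSite

log = logging.getLogger(__name__)

EPS_PAIRED_LOG2 = -8    # ε_r = 2⁻⁸: paired read, mate aligned on the graph
EPS_UNPAIRED_LOG2 = -4  # ε_r = 2⁻⁴: otherwise (and all coverage pseudo-reads)

BREAKPOINT = "BREAKPOINT"
COVERAGE = "COVERAGE"
AGGREGATED = "AGGREGATED"

GENOTYPES = ((0, 0), (0, 1), (1, 1))

#: Below this SV span the coverage model has too few sampled positions
#: inside the SV to give a stable median and is not applied.
MIN_COVERAGE_MODEL_SPAN = 100


class ModelNotApplicable(ValueError):
    """The coverage model does not apply to this SV type."""


def per_read_likelihood(support: AlleleSupport, x: int, y: int) -> float:
    """Relative likelihood of one read given genotype alleles ``x, y``."""
    s = support.supported_alleles
    x_in, y_in = x in s, y in s
    if x_in and y_in:
        return 1.0
    if x_in or y_in:
        return 0.5
    eps_log2 = (EPS_PAIRED_LOG2
                if support.read.is_paired and support.mate_on_graph
                else EPS_UNPAIRED_LOG2)
    return 2.0 ** eps_log2


@dataclass
class GenotypeLikelihoods:
    """Relative genotype likelihoods (log10) for one site and sample."""

    site_id: int
    sample: str
    model: str
    log10: tuple[float, float, float]   # L00, L01, L11
    n_ref: int = 0
    n_alt: int = 0
    n_ambiguous: int = 0
    n_neither: int = 0

    @property
    def best_genotype(self) -> tuple[int, int]:
        return GENOTYPES[int(np.argmax(self.log10))]

    @property
    def gq(self) -> int:
        """Phred-scaled ratio of best to second-best likelihood, cap 99."""
        a = sorted(self.log10, reverse=True)
        return min(99, int(round(10.0 * (a[0] - a[1]))))

    def pl(self) -> tuple[int, int, int]:
        """Phred-scaled likelihoods normalized to the best genotype."""
        m = max(self.log10)
        return tuple(min(255, int(round(-10.0 * (l - m))))
                     for l in self.log10)


def _counts(supports: Sequence[AlleleSupport]) -> tuple[int, int, int, int]:
    n_ref = n_alt = n_amb = n_none = 0
    for s in supports:
        has0, has1 = 0 in s.supported_alleles, 1 in s.supported_alleles
        if has0 and has1:
            n_amb += 1
        elif has0:
            n_ref += 1
        elif has1:
            n_alt += 1
        else:
            n_none += 1
    return n_ref, n_alt, n_amb, n_none


def breakpoint_genotype(supports: Sequence[AlleleSupport],
                        site_id: Optional[int] = None,
                        sample: str = "") -> GenotypeLikelihoods:
    """Breakpoint-model likelihoods from per-read allele support.

    All supports must belong to one biallelic site; an empty support
    list gives equal (uninformative) likelihoods.
    """
    sids = {s.site_id for s in supports}
    if len(sids) > 1:
        raise ValueError(f"supports from multiple sites: {sorted(sids)}")
    if site_id is None:
        site_id = next(iter(sids), -1)
    logs = [0.0, 0.0, 0.0]
    for s in supports:
        for gi, (x, y) in enumerate(GENOTYPES):
            logs[gi] += math.log10(per_read_likelihood(s, x, y))
    n_ref, n_alt, n_amb, n_none = _counts(supports)
    return GenotypeLikelihoods(site_id, sample, BREAKPOINT, tuple(logs),
                               n_ref, n_alt, n_amb, n_none)


# ---------------------------------------------------------------------------
# coverage model


def lower_median(values: Sequence[float]) -> int:
    """Median taking the lower of the two central values for even counts,
    so pseudo-read counts stay integral."""
    v = sorted(values)
    if not v:
        return 0
    return int(v[(len(v) - 1) // 2])


@dataclass
class CoverageProfile:
    """Median alignment coverage inside an SV and in its flanks.

    Medians are computed over coverage sampled every ``step`` bp; the
    two flanking windows are ``window_len`` bp each and their sampled
    positions are pooled into one median, ``c_out``.
    """

    site_id: int
    c_in: int
    c_out: int
    window_len: int = 1000
    step: int = 20

    def __post_init__(self) -> None:
        if self.c_in < 0 or self.c_out < 0:
            raise ValueError("coverage medians must be non-negative")


def coverage_profile(depth, site: SVSite,
                     exclude_spans: Iterable[tuple[int, int]] = (),
                     window_len: int = 1000, step: int = 20,
                     site_id: Optional[int] = None) -> CoverageProfile:
    """Build a :class:`CoverageProfile` from a per-base depth accessor.

    ``depth`` maps a 0-based reference position to an integer coverage
    (callable, or an indexable array).  Sampled positions inside any
    ``exclude_spans`` interval (other SVs of the window) are skipped so
    neighbouring SVs do not contaminate the medians.
    """
    get = depth if callable(depth) else (lambda p: int(depth[p])
                                         if 0 <= p < len(depth) else 0)
    b0, e0 = site.span0
    excl = sorted(exclude_spans)

    def excluded(p: int) -> bool:
        return any(a <= p < b for a, b in excl)

    inside = [get(p) for p in range(b0, e0, step) if not excluded(p)]
    flank = [get(p) for p in range(max(0, b0 - window_len), b0, step)
             if not excluded(p)]
    flank += [get(p) for p in range(e0, e0 + window_len, step)
              if not excluded(p)]
    return CoverageProfile(site_id if site_id is not None else -1,
                           lower_median(inside), lower_median(flank),
                           window_len, step)


def coverage_genotype(profile: CoverageProfile, sv_type: str,
                      sample: str = "") -> GenotypeLikelihoods:
    """Coverage-model likelihoods for a deletion or duplication.

    Raises :class:`ModelNotApplicable` for SV types without a copy-number
    signature (insertions, inversions, breakends).
    """
    if sv_type == "DEL":
        n_alt = max(0, profile.c_out - profile.c_in)
        n_ref = profile.c_in
    elif sv_type == "DUP":
        # mirror of the deletion case: the coverage increase counts the
        # extra copies, and the coverage attributable to the
        # non-duplicated allele, 2·c_out − c_in, supports the reference
        # (0 for a homozygous duplication, c_out/2-scale for a het)
        n_alt = max(0, profile.c_in - profile.c_out)
        n_ref = max(0, 2 * profile.c_out - profile.c_in)
    else:
        raise ModelNotApplicable(
            f"coverage model does not apply to {sv_type}")
    eps_log10 = EPS_UNPAIRED_LOG2 * math.log10(2.0)
    half = math.log10(0.5)
    logs = (n_alt * eps_log10,                 # G00: alt pseudo-reads miss
            (n_ref + n_alt) * half,            # G01: every read hits one allele
            n_ref * eps_log10)                 # G11: ref pseudo-reads miss
    return GenotypeLikelihoods(profile.site_id, sample, COVERAGE, logs,
                               n_ref=n_ref, n_alt=n_alt)


# ---------------------------------------------------------------------------
# call aggregation and filtering


@dataclass
class GenotypeCall:
    """Aggregated per-sample biallelic genotype call."""

    site_id: int
    sample: str
    genotype: tuple[int, int]
    model_used: str
    gq: int
    log10: tuple[float, float, float]
    breakpoint: Optional[GenotypeLikelihoods] = None
    coverage: Optional[GenotypeLikelihoods] = None
    passed_filters: dict = field(default_factory=dict)

    @property
    def is_nonref(self) -> bool:
        return any(a != 0 for a in self.genotype)

    def pl(self) -> tuple[int, int, int]:
        m = max(self.log10)
        return tuple(min(255, int(round(-10.0 * (l - m))))
                     for l in self.log10)


def aggregate_call(breakpoint_gl: Optional[GenotypeLikelihoods],
                   coverage_gl: Optional[GenotypeLikelihoods] = None
                   ) -> GenotypeCall:
    """Select the call of the model with the higher genotyping quality.

    Ties (and agreement on genotype) go to the breakpoint model; with a
    single model present its call is returned unchanged.
    """
    if breakpoint_gl is None and coverage_gl is None:
        raise ValueError("at least one model must produce likelihoods")
    candidates = [gl for gl in (breakpoint_gl, coverage_gl) if gl is not None]
    best = max(candidates, key=lambda gl: gl.gq)
    if (breakpoint_gl is not None and coverage_gl is not None
            and breakpoint_gl.gq == coverage_gl.gq):
        best = breakpoint_gl
    gq = best.gq
    if (breakpoint_gl is not None and coverage_gl is not None
            and breakpoint_gl.best_genotype == coverage_gl.best_genotype):
        gq = max(breakpoint_gl.gq, coverage_gl.gq)
    return GenotypeCall(best.site_id, best.sample, best.best_genotype,
                        AGGREGATED if len(candidates) > 1 else best.model,
                        gq, best.log10,
                        breakpoint=breakpoint_gl, coverage=coverage_gl)


def decompose_multiallelic(site) -> list:
    """Decompose a multi-allelic site into one biallelic site per alt.

    ``site`` may be an :class:`SVSite` (already biallelic → identity) or
    any object with an ``alts`` tuple (e.g. a small variant), which is
    split into ``len(alts)`` single-alt copies.
    """
    from dataclasses import replace
    alts = getattr(site, "alts", None)
    if alts is None:
        return [site]
    return [replace(site, alts=(alt,)) for alt in alts]


def decompose_supports(supports: Sequence[AlleleSupport], k: int
                       ) -> list[list[AlleleSupport]]:
    """Re-index multi-allelic read support into k biallelic views.

    In the view for alt ``i`` (1-based allele index in the original
    site), support for any other alternative maps to the NONE marker.
    """
    from dataclasses import replace
    views: list[list[AlleleSupport]] = []
    for i in range(1, k + 1):
        view = []
        for s in supports:
            mapped = set()
            if 0 in s.supported_alleles:
                mapped.add(0)
            if i in s.supported_alleles:
                mapped.add(1)
            view.append(replace(s, supported_alleles=frozenset(mapped)))
        views.append(view)
    return views


@dataclass
class HighConfidenceFilter:
    """Configurable aggregate high-confidence site filter.

    This is a package-level knob (thresholds below are this package's
    documented defaults, not values from any published filter): a site
    is flagged high-confidence when it has at least ``min_carriers``
    carriers, at least ``min_call_fraction`` of samples called with
    GQ ≥ ``min_gq``.
    """

    min_gq: int = 20
    min_carriers: int = 1
    min_call_fraction: float = 0.9

    def site_passes(self, calls: Sequence[GenotypeCall]) -> bool:
        if not calls:
            return False
        carriers = sum(1 for c in calls if c.is_nonref)
        frac_hq = sum(1 for c in calls if c.gq >= self.min_gq) / len(calls)
        return (carriers >= self.min_carriers
                and frac_hq >= self.min_call_fraction)


def filter_calls(calls_by_site: dict,
                 hc_filter: Optional[HighConfidenceFilter] = None) -> dict:
    """Drop sites where no sample has a non-reference genotype.

    Surviving sites are annotated with the (configurable) high-confidence
    flag in each call's ``passed_filters``.
    """
    hc_filter = hc_filter or HighConfidenceFilter()
    out = {}
    for site_id, calls in calls_by_site.items():
        if not any(c.is_nonref for c in calls):
            continue
        hc = hc_filter.site_passes(calls)
        for c in calls:
            c.passed_filters["nonref_seen"] = True
            c.passed_filters["high_confidence"] = hc
        out[site_id] = calls
    return out
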