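# Methods

`graphsv` genotypes structural variants (SVs, sequence changes of ≥50 bp)
in short-read data by local realignment against acyclic breakpoint
graphs, following the population-scale pangenome-genotyping approach:
SVs are *discovered* elsewhere (per-sample callers, long-read
assemblies), merged into one non-redundant site list, and then
*genotyped* in every sample by re-scoring that sample's reads against
the reference and SV-breakpoint alleles.

## Breakpoint encoding

A breakpoint is the reference position where an SV haplotype diverges
from (START) or converges to (END) the reference; most SVs contribute
two. Rather than inserting whole alternative sequences, the graph
carries only the *breakpoint sequences* — the first (START) or last
(END) `L_bp` bases of the SV haplotype at each junction, with `L_bp` =
152 bp by default (one short-read length, configurable from observed
read length). This bounds graph size, treats short and long SVs
uniformly during mapping, and tolerates partially characterized
sequences (a left-assembled insertion fragment yields a single START
breakpoint). The exact splice rules per type, with `b0, e0` the 0-based
affected span, flanks written `L = ref[:b0]`, `R = ref[e0:]`, and `S =
ref[b0:e0]`:

| type | alternative haplotype | START window | END window |
|------|----------------------|--------------|------------|
| DEL  | `L + R`              | first 152 of `R` | last 152 of `L` |
| INS (seq `I`) | `L + I + R` | first 152 of `I + R` | last 152 of `L + I` |
| DUP (tandem) | `L + S + S + R` | first 152 of `S + R` anchored at `e0` | last 152 of `L + S` anchored at `b0` |
| INV  | `L + rc(S) + R`      | first 152 of `rc(S) + R` | last 152 of `L + rc(S)` |

Breakpoints truncated by a contig edge below 16 bp (one read anchor)
are dropped with a warning. Insertions with no sequence at all
(imprecise discovery records) cannot be encoded and are rejected from
the graph; deletion/duplication candidates of this kind still receive a
coverage-model genotype.

The serialized graph is a DAG: reference segments chained left to
right, with allele nodes (reference vs alternative) at each accepted
locus. The two breakpoints of one SV are a single *linked* choice — a
local haplotype either carries the SV at both junctions or at neither —
so haplotype enumeration multiplies allele counts per site, not per
node. Variants whose loci cannot be serialized (overlapping or nested
alleles, including SVs shorter than about twice `L_bp` whose own
breakpoint loci collide) are demoted to independent biallelic overlay
records genotyped against the reference-only backbone; they are still
realigned and genotyped identically.

Genotyping runs per window: small-variant graphs tile the genome in
50 kbp windows; SV graphs use 1.2 Mbp windows overlapping by 200 kbp so
both breakpoints of an SV almost always share a graph. Sites genotyped
twice in an overlap keep the higher-GQ record (tie → earlier window).
An SV too large for any window is genotyped in the window holding its
start breakpoint, with a warning (less accurate, as its junctions are
then scored on different graphs).

## Read extraction and realignment

For each window the pipeline extracts all primary, non-duplicate
alignments overlapping the window padded by 1 kbp, plus unmapped reads
whose mapped mate lies there (junction-spanning reads are often clipped
or unmapped by a linear aligner), deduplicated by (name,
first/second-of-pair).

The original tool's k-mer graph index and alignment engine are replaced
by a documented per-site local realignment. Each allele of each site is
represented by *contexts*: for small variants, flank + allele + flank;
for SV breakpoints, the 300 bp reference flank adjacent to the junction
followed (START) or preceded (END) by the 152 bp allele node. Reads are
scored against every context in both orientations with a local
affine-gap alignment (match +1, mismatch −2, gap open −5, gap extend
−1; exact substring hits shortcut the dynamic program). A read supports
the allele(s) achieving the best score, provided the best alignment
covers ≥90% of the read and scores ≥0.65× the maximum attainable;
below that the read overlaps the site but supports *neither* allele.
Ties support all tied alleles. Two deliberate consequences:

* a best alignment placed wholly in flank sequence means the reference
  path explains the read equally well elsewhere, so the read is
  recorded as ambiguous (supports both alleles) rather than
  allele-supporting — this reproduces tie behavior of whole-graph
  alignment, where breakpoint sequences of deletions and duplications
  are copies of reference sequence from the other junction;
* the bounded node length keeps the reference and alternative evidence
  footprints comparable across SV sizes. Scoring against full spliced
  haplotypes instead makes reference support scale with SV span (every
  interior read counts) while SV support stays junction-bounded, which
  empirically drives large heterozygous deletions toward 0/0; the
  node-bounded design is not just a compute optimization.

The score and coverage thresholds are package configuration, not claims
about the original tool, which does not publish its cutoff.

## Genotype likelihood models

**Breakpoint model.** For a biallelic site with alleles x, y and the
multiset R of overlapping best-aligned reads, the relative genotype
likelihood is the product over reads of: 1 if the read supports both x
and y; 1/2 if exactly one; ε_r otherwise, with ε_r = 2⁻⁸ for a paired
read whose mate also aligned in the region and 2⁻⁴ otherwise. Computed
in log10 space; an empty R gives equal likelihoods. Multi-allelic sites
are genotyped as two or more biallelic sites (reference vs one
alternative; support for other alternatives maps to "neither").

**Coverage model** (deletions and duplications, including inverted
duplications, with span ≥100 bp — below that, fewer than five sampled
positions make the inside-median unstable). Alignment coverage is
sampled every 20 bp; `c_in` is the lower median inside the SV and
`c_out` the lower median over two 1000 bp flanking windows (positions
inside any other SV of the window are excluded; the simulator plants
SVs ≥2 kb apart for the same reason). Lower medians keep pseudo-read
counts integral. For deletions, `max(0, c_out − c_in)` pseudo-reads
support the SV and `c_in` support the reference. For duplications, the
coverage *increase* `max(0, c_in − c_out)` supports the extra copy and
`max(0, 2·c_out − c_in)` — the share attributable to the
non-duplicated allele — supports the reference. (Counting the whole
baseline `c_out` as reference support instead would make a homozygous
duplication, `c_in ≈ 2·c_out`, mathematically impossible to call: it
would require `c_in > 4·c_out`. The chosen form is the exact mirror of
the deletion case, where the inside coverage *is* the reference-allele
share, and is 0 for a homozygous duplication.) All pseudo-reads are
unambiguous and unpaired, so ε = 2⁻⁴.

**Aggregation.** Per model, GQ is the phred-scaled ratio of best to
second-best likelihood, rounded and capped at 99 (the quality formula
is this package's convention). The call of the model with the larger GQ
is emitted; ties go to the breakpoint model; when both models agree the
larger GQ is kept. Cohort post-filtering drops sites with no
non-reference genotype. A separate, explicitly configurable
high-confidence flag (defaults: ≥1 carrier, ≥90% of samples with
GQ ≥20) is this package's own aggregate filter, not a reproduction of
any published one.

**Known limitation — tandem duplications.** The copy-boundary sequences
of a tandem duplication exist on *every* carrier haplotype, so
breakpoint-node reference support is flooded for carriers and the
breakpoint model cannot separate 0/1 from 1/1 (it confidently reports
0/1); the coverage model carries the dosage signal but its GQ rarely
beats a capped breakpoint GQ under max-GQ aggregation. Homozygous
tandem duplications are therefore typically emitted as 0/1. Carrier
status for duplications remains reliable. Deletions, insertions and
inversions have asymmetric junction sequences and are genotype-resolved
by the breakpoint model; recovery statistics are quoted on those
("breakpoint-resolvable") sites, with duplication carrier concordance
reported separately.

## Cross-sample merging

Independently discovered per-sample SV lists are merged by a single
left-to-right sweep per contig: a site joins an open group if it is
*mergeable* with at least one member — same type, size difference
≤100 bp, and both begin and end within 200 bp — and lies within
10,000 bp (begin and end) of every member; otherwise it founds a new
group. Transitive growth is intentional (A–B and B–C mergeable pulls in
C even if A–C is not); the 10 kbp cap stops unbounded chains. When
several open groups qualify, the site joins the one whose most common
endpoint pair so far is nearest by |Δbegin|+|Δend| (deterministic,
locality-preserving; the grouping order among qualifying groups is
otherwise unspecified in the field). Each group's representative is a
member with the most common (begin, end) pair, ties to the smallest
pair; its INFO field is written verbatim, plus a `NUM_MERGED_SVS`
count. Genotype columns are never parsed and input FILTER values are
ignored (non-PASS records are included). Insertions use end = begin and
compare SVLEN as size. Merging is idempotent and partitions its input;
site count is non-increasing in the position threshold.

## Evaluation statistics

*Truth extraction:* sequence-resolved VCFs are decomposed, left
normalized (shared-base trimming, plus reference-guided left-alignment
— cross-checked against `bcftools norm` in the tests), alleles with
|len(alt) − len(ref)| ≥ 50 kept and classified DEL/INS, and restricted
to high-confidence regions expanded by 25 bp.

*Breakpoint-precision matching:* a call matches a truth SV if types
match and both breakpoint distances are within the threshold; matching
is greedy nearest-first (by max breakpoint distance), one-to-one.
Recall = matched truth / all truth; FDR = unmatched calls / all calls.
Curves are produced over thresholds 1–50 bp and recall per size bin
(50–99, 100–249, 250–499, 500–999, 1000–1999, ≥2000 bp). Greedy
matching is deterministic; at 50 bp thresholds on SV-scale spacing it
is indistinguishable from optimal bipartite matching. One truth SV may
validate only one call (the one-to-many alternative would inflate
recall).

*Long-read-style concordance:* a call is validated if a type-matching
record with ≥2 supporting reads lies within 50 bp at both breakpoints.

*Trio statistics:* Mendelian errors are offspring genotypes impossible
under biallelic transmission, rated over all evaluable (site, trio)
pairs. The transmission rate counts, per site and heterozygous parent,
whether the SV allele reached the offspring; opportunities where the
transmitted allele is not uniquely determined (het × het with het
child) are skipped rather than given half credit. For germline variants
the per-site rates are expected to distribute symmetrically around 50%.
The carrier spectrum is the distribution of sites by number of
carriers.

## Synthetic study design

The simulator generates the full study the tests and the acceptance
script run on: a uniform-random contig; planted DEL/INS/DUP/INV with
phased genotypes across a pedigree; paired reads; and jittered
single-sample discovery VCFs for the merge/benchmark paths.

Defaults (the study conditions): 600 kb contig; 20 SVs per type of
100–1000 bp, non-overlapping, ≥2 kb apart (so 1000 bp coverage windows
never collide; 80 SVs at that spacing need more than 160 kb, which is
why the contig is 600 kb); 30× coverage in 151 bp paired reads
(fragments 420 ± 50 bp), 1% uniform base error, constant Q30 qualities
(the models are quality-blind); four families with 8 parents and 48
offspring (10/10/11/17); founder alternative-allele frequencies uniform
on 0.05–0.5, mirroring the rare-skewed site frequency spectrum of real
SV callsets; breakpoint jitter ±30 bp for degraded callsets. Offspring
haplotypes follow Mendelian transmission with every transmission from a
het parent recorded, so trio statistics have exact expectations.

Reads carry naive linear placements rather than an external aligner's:
each read maps to the longest reference-colinear piece of its fragment
(soft-clipping bases across planted junctions, reverse-strand placement
inside inversions, second tandem copies mapped onto the duplicated
span), and reads wholly inside insertions are emitted unmapped with a
mapped mate. This reproduces the extraction-relevant behavior of a real
aligner (clipped junction reads, unmapped-with-mapped-mate) without
network downloads. What the simulator does *not* model — and what
passing tests therefore do not demonstrate — includes empirical error
profiles, GC and mapping-quality bias, repeat structure (segmental
duplications are the hard case for real SV genotyping), nested and
overlapping SVs, and imprecise discovery breakpoints beyond uniform
jitter. Everything is byte-deterministic under the configured seed;
per-purpose random streams are derived from (seed, stream-id) so adding
one output does not reshuffle others.

## Numerical and edge-case choices

Likelihoods accumulate in log10; products of ≤12 reads agree with a
direct-product oracle to 1e-12 relative tolerance. Genotype argmax ties
resolve in the order 0/0, 0/1, 1/1 (an empty read set yields 0/0 with
GQ 0). VCF I/O is 1-based; all internal intervals are 0-based
half-open. Coverage medians take the lower central value for even
counts. Reads shorter than 16 bp are skipped and logged. Unsorted input
to the merge sweep is an error, not silently reordered.

## Problem sizes used

The recovery study genotypes one 30× sample over 80 SVs on a 600 kb
contig (about two minutes end to end); trio statistics use the full
56-sample pedigree's truth genotypes at those 80 sites (3,840 trio-site
evaluations, ~2,300 transmission opportunities); the coverage-model
recovery check forces 12 deletions of 500–1000 bp to a known genotype.
These sizes make the binomial error of every asserted proportion small
against its margin while keeping the whole suite and the acceptance
script each within a few minutes on one CPU.
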