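# graphsv

Population-scale genotyping of structural variants (SVs) from short
reads using acyclic breakpoint graphs.

Short-read SV *discovery* is noisy and caller-dependent: the same
deletion is reported with slightly different breakpoints in every
sample, and genotypes from joint discovery callers are biased toward
the reference. `graphsv` addresses the *genotyping* half of the
problem: given SV sites discovered elsewhere (per-sample callers,
long-read assemblies), it merges them into one non-redundant site list,
encodes each SV's breakpoint sequences (up to 152 bp per junction) as
alternative alleles in a local variation graph, realigns each sample's
reads — including clipped reads and unmapped reads with a mapped mate —
to that graph, and calls genotypes from two models whose higher-quality
call wins:

* **breakpoint model** — with x, y the genotype's alleles and R the
  reads whose best graph alignment overlaps the site,

  L(R | G_xy) = ∏_{r∈R} L(r | G_xy),
  L(r | G_xy) = 1 if r supports both x and y; 1/2 if exactly one;
  ε_r otherwise, where ε_r = 2⁻⁸ for a paired read with its mate
  aligned on the graph and 2⁻⁴ otherwise;

* **coverage model** (deletions/duplications ≥100 bp) — alignment depth
  sampled every 20 bp gives the median inside the SV, c_in, and in two
  1 kbp flanking windows, c_out; the coverage decrease
  max(0, c_out − c_in) acts as deletion-supporting pseudo-reads against
  c_in reference-supporting ones (duplications use the increase), fed
  through the same likelihood with ε = 2⁻⁴.

Genotype quality (GQ) is the phred-scaled ratio of best to second-best
likelihood, capped at 99. The toolkit also ships the evaluation
machinery used to validate such callsets — breakpoint-precision
recall/FDR curves, size-binned recall, long-read-style concordance,
trio Mendelian-error and allele-transmission rates, carrier spectra —
and a fully deterministic simulator (reference, planted SVs with phased
pedigree genotypes, paired reads with realistic clipping) so everything
is testable offline. See `docs/methods.md` for the model details and
design rationale.

## Worked example

Simulate a study (600 kb contig, 80 planted SVs of 100–1000 bp, four
families, 30× paired 151 bp reads for one sample), emulate per-sample
discovery with ±30 bp breakpoint jitter, merge, genotype and benchmark:

```sh
graphsv simulate --seed 11 --out sim --read-samples fam1_father
python - <<'EOF'
from graphsv.simulate import SimConfig, simulate_reference, plant_svs, degrade_callset
cfg = SimConfig(seed=11)
truth = plant_svs(simulate_reference(cfg.contig_length, cfg.rng(1)), cfg)
degrade_callset(truth, "disc", samples=truth.samples[:6])
EOF

graphsv merge --out merged.vcf disc/*.vcf
# wrote 80 merged SV sites to merged.vcf

graphsv genotype-sv --bam fam1_father=sim/fam1_father.bam \
    --vcf merged.vcf --ref sim/ref.fa --out calls.vcf
# wrote 27 genotyped SV sites to calls.vcf

graphsv evaluate --calls merged.vcf --truth sim/truth.vcf --out-prefix eval
# "recall_at_max_threshold": 1.0,
# "fdr_at_max_threshold": 0.0,
```

The merge step collapsed 6 × 80 jittered discovery records back to the
80 distinct sites (each sample reports every SV with independent
breakpoint noise; same type, size within 100 bp, begin/end within
200 bp cluster together). Genotyping kept the 27 sites at which the one
genotyped sample carries a non-reference allele — sites with no carrier
are filtered, mirroring cohort practice. The benchmark matched every
merged site to a truth SV within the 50 bp breakpoint-precision
threshold (recall 1.0) with no unmatched calls (FDR 0.0);
`eval.recall_fdr.tsv` holds the full 1–50 bp threshold curve and
`eval.recall_by_size.tsv` the per-size-bin recall.

Trio statistics on the pedigree's truth genotypes:

```sh
graphsv evaluate --calls sim/truth.vcf --ped sim/pedigree.ped --out-prefix ped
# "mendelian_error_rate": 0.0,
# "mean_transmission_rate": 0.5064602941842643
```

Zero Mendelian errors across the 48 parent-offspring trios, and
heterozygous parents transmitted their SV allele in 50.6% of resolvable
opportunities — consistent with the 50% expected for germline alleles.

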