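# smvkit

Somatic microsatellite variation (SMV) from aligned sequencing reads —
without a matched normal.

Microsatellites (MSTs) are tandem repeats of 1–6 nt motifs and mutate
10–1000× faster than surrounding DNA, mostly through polymerase slippage
that inserts or deletes whole repeat units. In a heterogeneous cell
population this produces *minor alleles*: repeat variants carried by cell
subpopulations, visible in deep sequencing as read groups that pass
support filters but do not belong to the one- or two-allele haplotype.
The fraction of loci carrying minor alleles, and the SNP : expansion :
contraction make-up of those alleles, form an instability profile that
differs between DNA-repair-proficient and repair-defective samples.

smvkit implements the full workflow for exome-scale data:

- **catalogue** — scan a reference FASTA for repeat loci (motif length
  1–6, length ≥ 8 nt, ≥ 3 copies, purity ≥ 0.85) and sample non-repeat
  control segments;
- **call** — for each locus, tally allele sequences from reads that span
  the repeat plus flanking anchors (MAPQ ≥ 10, base quality ≥ 28 inside
  the repeat, exact anchor match), call an allele at ≥ 3 supporting reads
  on both strands, and genotype with the heterozygote rule: the second
  allele joins the haplotype if its support exceeds 25% of locus depth,
  or 50% of the major allele's support; everything else called is a
  minor allele;
- **classify** — type each minor allele against the major allele as SNP
  (same length), expansion or contraction, flagging in-phase changes
  (multiples of the motif length);
- **profile / compare** — zygosity and minor-allele percentages, 1-Mb
  bin fractions with chi-square hotspot flags, pairwise concordance with
  an analytic + Monte-Carlo random null, between-sample regression,
  second-allele read fractions, exon/untranslated and gene-level reports;
- **simulate / evaluate** — a paired-end read simulator with planted
  diploid genotypes and subclonal minor alleles, used to characterize how
  per-base error (0.5–5%) creates false alleles and why 3 supporting
  reads is the working threshold.

## Worked example

Simulate 40 microsatellite loci at 1% per-base error with subclonal minor
alleles planted at 10% of loci, call, and score against the planted truth:

```
$ smvkit simulate -o sim --n-loci 40 --per-base-error 0.01 \
      --minor-planting-rate 0.1 --seed 5
simulated 40 loci -> sim/sim.bam

$ smvkit call sim/sim.bam sim/catalogue.tsv \
      --reference sim/reference.fasta -o calls.tsv
called 40 loci -> calls.tsv

$ smvkit evaluate calls.tsv sim/truth.tsv
loci evaluated      40
loci genotyped      39
zygosity accuracy   100.000%
false-allele-free   97.44%
minor sensitivity   80.00%
  alleles=1: mean depth 47.2 (n=33)
  alleles=2: mean depth 51.7 (n=6)
```

Reading the output: 39 of 40 loci reached the depth-15 genotyping cutoff;
every called genotype matched the planted one; at 97.44% of genotyped
loci every called allele was a true (haplotype or planted) allele — the
remaining locus carries a false allele assembled from recurrent
sequencing errors; 80% of planted subclonal alleles were recovered (the
rest fell below the 3-read both-strand rule at their drawn read
fraction). Mean depth rises with allele count, as expected when extra
alleles need extra supporting reads.

`smvkit classify` then types the minor alleles, and `smvkit profile` /
`smvkit compare` produce the sample-level tables (zygosity percentages,
minor-allele fractions per chromosome and 1-Mb bin, hotspot flags,
concordance against a second sample).

The same operations are available as a library:

```python
from smvkit import SimulationConfig, CallerConfig, simulate_sample, call_sample
```

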