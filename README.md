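# lesionevo

Genomic analysis of matched multi-lesion cohorts along a precursor-to-carcinoma
axis. The package targets study designs in which several lesions are
microdissected from the same patient — normal myometrium (**Nm**, the germline
reference), normal glandular epithelium (**N**), a benign precursor lesion
(**L**, e.g. lobular endocervical glandular hyperplasia, LEGH) and a carcinoma
(**G**, e.g. gastric-type cervical adenocarcinoma, GAS) — and asks whether the
carcinoma evolved *through* the precursor, using somatic variants, copy-number
alterations and mutational signatures.

It is aimed at cancer-genomics analysts who already have per-sample annotated
variant calls and copy-ratio segments (e.g. downstream of Mutect2/ANNOVAR and
GATK ModelSegments) and want the *downstream* inference layer: filtering,
event calling, phylogenies and driver prioritization. A bundled
clonal-evolution simulator with a full truth ledger makes every stage testable
without access to controlled patient data.

## What it computes

* **Somatic filtering** — variants present in the matched Nm sample are
  subtracted as germline (keyed on chrom/pos/ref/alt); remaining calls are
  filtered on mean base quality, depth and VAF, and unplaced/mitochondrial
  contigs dropped.
* **CNA and CN-LOH calling** — per segment: copy ratio > 1.1 → gain,
  < 0.9 → loss; within the neutral band [0.9, 1.1], a segment is
  copy-neutral LOH when its minor allele fraction *b* falls below a cutoff
  derived from the cohort's normal samples:

  `cutoff = mean(p10_i) − 3 · SD(p10_i)`,

  where `p10_i` is the 10th percentile of sample *i*'s minor-allele
  fractions. Phased heterozygous variants inside each event vote on the
  affected haplotype (alleles with VAF < 0.5 mark the lost haplotype).
* **Signature refitting** — SNVs are tallied into the standard 96
  trinucleotide-context spectrum **m** and refit against a reference
  signature matrix **S** by non-negative least squares,
  min‖**m** − **S e**‖₂ s.t. **e** ≥ 0; normalized exposures are the
  per-sample signature proportions (SBS1, the clock-like CpG deamination
  signature, dominates this lesion type).
* **Parsimony phylogeny** — binary presence/absence characters over samples,
  exhaustive search of all unrooted topologies with exact Fitch scoring,
  branch lengths = per-branch change counts, rooted at Nm. Each case is
  classified **Type 1** ({L,G} share a branch: precursor-to-carcinoma
  transition), **Type 2** ({N,L}) or **Type 3** ({N,G}); a binary-model
  maximum-likelihood scorer reports concordance.
* **Candidate-driver scoring** — per gene, one point per case with a rare
  (gnomAD-EAS AF < 0.01 or unregistered) exonic non-synonymous variant in the
  carcinoma, plus one point per case with a biologically plausible CNA
  (oncogene gain, tumor-suppressor loss, or CN-LOH with a loss-of-function
  variant on the retained haplotype). Genes with ≥ 2 points are candidates;
  sensitivity sets at thresholds 2/3/4/5 are nested. Candidate lists can be
  tested for gene-set over-representation (hypergeometric + BH).
* **Statistics** — Kruskal–Wallis across the three lesion groups, gated
  pairwise Wilcoxon rank-sum tests (exact for small tie-free samples) with
  multiplicity correction.

## Worked example

Simulate a seven-case cohort (the defaults mirror the intended study
conditions: binomial read noise at 100× depth, a +0.06 carcinoma VAF shift on
shared variants, SBS1 weight 0.7, five planted driver genes among 200
passengers) and run the full pipeline:

```sh
lesionevo run --out demo --seed 1
```

The run writes `somatic.tsv`, `events.tsv`, `exposures.tsv`, `scores.tsv`,
per-case Newick trees and `summary.json`. Selected output from the run above:

```
cutoff:      0.4620          # derived CN-LOH minor-allele-fraction cutoff
topologies:  case1 TYPE1, case2 TYPE2, case3 TYPE1, case4 TYPE1,
             case5 TYPE1, case6 TYPE3, case7 TYPE2
shared VAF:  L 0.203 vs G 0.257 (difference 0.054, p < 1e-10)
candidates:  SYNG001 SYNG002 SYNG007 SYNG009 SYNG011
```

Every case is classified to its planted topology; the shared-variant VAF
comparison recovers the planted +0.06 carcinoma shift; and the five candidate
genes are exactly the five planted drivers — the three with a plausible CNA
or CN-LOH on top of recurrent variants score 3, the rest 2 (see
`scores.tsv`). `case1_variants.nwk` reads

```
(Nm:40,(N:10,(L:10,G:32):50):0);
```

i.e. 40 trunk variants, a 50-variant branch shared by L and G (the Type 1
signal) and private terminal branches.

Individual stages are available as `lesionevo simulate | filter | cna |
signatures | phylo | score`, and programmatically via `lesionevo.*` modules.

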