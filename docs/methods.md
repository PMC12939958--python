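# Methods

This note documents the models and procedures implemented in `lesionevo`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Study design and data model

Each case (patient) contributes up to four microdissected samples: normal
myometrium (Nm), normal glandular epithelium (N), a benign precursor lesion
(L) and a carcinoma (G). Nm carries the germline and defines the somatic
baseline; N, L and G are related by a clonal genealogy. All tables are
tab-separated; genomic intervals are **1-based, inclusive at both ends, in
files and in memory alike**. A single coordinate convention end-to-end was
preferred over an internal half-open representation: it removes a whole class
of off-by-one defects, at the cost of `+1` terms localized in two interval
helpers (`interval_overlap`, `interval_length`).

Variant tables carry one row per variant per sample (depth, alt reads, VAF,
functional class, East-Asian population allele frequency, haplotype phase,
trinucleotide context); segment tables carry copy ratio (tumor/normal, 1.0 =
two copies) and minor allele fraction (MAF ∈ [0, 0.5], ≈ 0.5 when the two
parental haplotypes are balanced) per interval.

## Somatic filtering

Germline subtraction removes every lesion variant whose (chrom, pos, ref,
alt) key occurs in the same case's Nm sample; the subtraction is genotype-
and phase-blind by design (the matched normal defines the germline
operationally, not through a genotype model). Cross-case subtraction is an
error, not a warning. Quality filtering applies three per-record floors —
mean base quality ≥ 20 (Phred), depth ≥ 10 reads, VAF ≥ 0.05 — and drops
mitochondrial and unplaced contigs. The constants are conventional FFPE-WES
floor values, exposed in `FilterConfig`; the tests exercise the predicates,
not the constants. Records lacking a base-quality annotation pass that
criterion rather than being discarded.

For burden statistics the exonic class set is {nonsynonymous, synonymous,
stopgain, frameshift, nonframeshift}; splicing, intronic, intergenic and UTR
records are non-exonic. Mutation rate is count / target size (Mb).

## CNA and CN-LOH calling

Per-segment decision rule, sensitive to events clonal in roughly ≥ 20 % of
cells: copy ratio > 1.1 → GAIN (strict); < 0.9 → LOSS (strict); inside the
closed band [0.9, 1.1] a segment is CN-LOH when its MAF falls below the
cohort-derived cutoff. Adjacent (bookended or overlapping) same-type calls on
a chromosome merge into one event. Segmentation itself is upstream and out of
scope.

The CN-LOH cutoff is derived from the normal samples: for each normal, the
10th percentile of its MAF values (linear interpolation between order
statistics, the "type 7" convention — the ubiquitous default; the choice is
configurable); the cutoff is the mean of these per-sample percentiles minus
three times their sample standard deviation (n − 1 denominator), clamped to
[0, 0.5]. Two normals are the minimum for the SD to exist. The per-sample
values are taken per segment; on the simulated cohorts the derived cutoff
lands in the 0.44–0.46 range.

Haplotype assignment uses phased heterozygous variants inside an event: a
phase-*h* allele observed below 50 % VAF votes that haplotype *h* was lost
(for gains, above 50 % votes *h* gained); the majority wins and ties or
uninformative events stay unknown. The pipeline feeds this step from the
*unfiltered* variant tables on purpose — the informative phased sites are
germline heterozygotes that germline subtraction would have removed.

Mutual events between two lesions are same-type event pairs with reciprocal
interval overlap ≥ 0.5 (configurable).

## Mutational signatures

SNVs map to the 96 classes (6 pyrimidine-strand substitutions × 16 flanking
combinations, alphabetical within substitution); purine-reference records are
reverse-complemented. Contexts come from the generator's emitted context
column (or any user callable), avoiding a reference-genome dependency.

Exposures are obtained by supervised refitting — non-negative least squares
of the observed spectrum on a reference matrix whose columns sum to one —
rather than de-novo extraction: cohorts of this size cannot support stable
NMF, and the quantity of interest is the proportion of *named* signatures.
Proportions are exposures normalized to one; an all-zero spectrum is flagged
degenerate. The packaged reference (`sbs_reference_synthetic.tsv`) contains
**synthetic** SBS1-, SBS2-, SBS5- and SBS13-like profiles plus a flat
background: SBS1-like mass sits on N[C>T]G contexts (CpG deamination),
SBS2/13-like on T[C>T/G]A and T[C>T/G]T (APOBEC-style), SBS5-like is a broad
T>C-tilted profile. These reproduce the *support structure* of the COSMIC
signatures for testing; a real COSMIC matrix in the same TSV layout can be
supplied instead.

## Phylogeny

Characters are binary presence/absence of variant keys (or of clustered CNA
events, same-type events linked at ≥ 50 % reciprocal overlap) across samples;
Nm is the all-absent outgroup. Presence means "passed somatic filtering in
that sample" with no extra VAF floor. With at most six taxa the unrooted
topology space (3, 15, 105 trees for 4, 5, 6 taxa) is enumerated exhaustively
and each topology scored by exact Fitch parsimony — exactness was preferred
over fidelity to any particular heuristic search. Score ties are reported as
unresolved, never broken silently.

Branch counts place each character's minimal changes by a top-down refinement
that keeps the parent state whenever the Fitch set allows it, i.e. changes go
to the most terminal admissible branch (this affects branch labels only,
never the score). For change placement the tree is re-rooted at a leaf so
every internal node is binary; trees are rooted at Nm for Newick output, with
branch lengths equal to change counts.

Topology classes: TYPE1 iff {L, G} form a cherry against {N, Nm} (consistent
with precursor-to-carcinoma transition), TYPE2 iff {N, L}, TYPE3 iff {N, G}.
Cases without an N sample, empty matrices, and ties with conflicting splits
are UNRESOLVED. A maximum-likelihood cross-check (two-state symmetric model,
one shared branch length optimized per topology by bounded scalar
minimization, Felsenstein pruning, uniform root) reports concordance with the
parsimony tree; it never overrides it.

The shared-variant VAF comparison pairs variants present in both L and G of a
case (pooled over cases), reporting per-lesion means and a two-sided Wilcoxon
rank-sum test.

## Driver scoring

Evidence is restricted to carcinoma (G) samples. Short-variant points: one
per distinct case with ≥ 1 qualifying variant in the gene — exonic,
non-synonymous, and rare (population AF < 0.01) or absent from the population
annotation; multiple hits in one case never add points. CNA points: one per
case with a plausible event over the gene — gain of an oncogene, loss of a
tumor suppressor ("both"-role genes score either way), or CN-LOH with a
loss-of-function variant (stopgain/frameshift/splicing; missense is "function
unclear" and never scores) phased to the retained haplotype. CN-LOH with an
unresolved haplotype never scores. CNA points are capped at one per case per
gene, parallel to the short-variant rule. Gene–event overlap is any base
overlap (full containment available as an option). Totals sort candidates
(ties alphabetical); candidate sets at thresholds 2/3/4/5 are nested by
construction. Enrichment of a candidate list in user-supplied gene sets (GMT)
is a one-sided hypergeometric tail with BH correction across sets — a
deliberate, transparent replacement for web-service pathway tools.

## Statistics

Kruskal–Wallis (midrank ties, chi-square approximation, k − 1 df) for ≥ 3
groups; Wilcoxon rank-sum for 2, exact when the pooled sample is tie-free
and ≤ 20 observations, otherwise normal approximation with continuity and
tie corrections; an all-identical pooled sample yields H = 0, p = 1. Pairwise
tests run only when the omnibus test passes the 0.05 gate, with BH correction
by default (Bonferroni available) — the correction method is a free choice
here and is recorded in the output metadata. All tests are two-sided. BH
adjustment is the standard step-up with monotonicity enforcement, input order
preserved.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, on an
artificial diploid genome of 22 × 10 Mb chromosomes with a packaged synthetic
gene table (220 intervals, 50 kb each, with oncogene/TSG/both/unknown roles).

Defaults (the intended study conditions): 7 cases; topology mix of four
TYPE1, two TYPE2, one TYPE3 case; per case 120 germline variants (80 % het at
VAF 0.5, 20 % hom at 1.0, common population AFs), 40 trunk variants (N∩L∩G),
50 topology-shared variants, 10 private per lesion; Poisson depth at mean
100×, binomial alt reads; lesion purity 0.4 so clonal heterozygous somatic
VAF ≈ 0.2. Carcinoma copies of variants carried by both L and G get an
additive expected-VAF shift of +0.06 (higher carcinoma clonality), so the
pooled shared-variant comparison recovers means near 0.20 vs 0.26. Contexts
follow a 0.7 : 0.3 mixture of the SBS1-like profile and flat background;
half the SNVs are emitted in purine-strand representation to exercise strand
normalization.

CNA events: one topology-shared 2 Mb event per case plus private events per
lesion (defaults N:0, L:1, G:4, mirroring the expectation that carcinomas
carry most events and normal glands none); gains draw ratios in 1.2–1.5,
losses 0.6–0.85, CN-LOH ratio ≈ 1.0 with MAF = 0.30. Each event carries a
known affected haplotype and eight planted phased germline heterozygotes so
haplotype assignment is informative; inside events those heterozygotes' VAFs
shift accordingly (CN-LOH: MAF / 1 − MAF by haplotype; loss 0.35/0.65; gain
0.4/0.6 — matching the emitted segment MAFs). Neutral segments draw MAF
0.5 − |N(0, 0.02)|, which is what places the derived CN-LOH cutoff near
0.44. Segment-mean copy-ratio noise scales with probe support,
σ_seg = 0.03 · min(1, √(200 / n_probes)): the configured σ applies at the
2 Mb / 200-probe reference scale and a whole-chromosome segment mean is
correspondingly tighter, as averaging implies. Phase-switch errors can be
injected per emitted row at a configurable rate (default 0).

Driver recovery is well-posed by construction: five planted drivers carry
qualifying carcinoma variants in ≥ 2 cases (three of them additionally a
CN-LOH-with-phased-LoF, an oncogene gain, or a TSG loss), 200 planted
passengers carry at most one qualifying case each, background somatic
variants never receive qualifying functional classes, and background CNA
events fall in the gene-free 6–10 Mb tail of each chromosome. Genes occupy
the first 6 Mb. A truth ledger labels every emitted variant (branch,
carriers, planted status, true phase) and segment (true event type and
haplotype); a fixed seed reproduces all outputs byte for byte
(`numpy` Generator seeded per case from (seed, case index)).

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: read-level artifacts (FFPE damage, strand bias,
alignment error), subclonal population structure within a lesion (all somatic
variants are clonal at their branch), realistic gene/exon structure and
mutation hotspots, segmentation error (segment boundaries are exact),
recurrent CNA breakpoints, and inter-sample contamination. Results on
simulated cohorts certify the *rules and algorithms*, not caller performance
on real sequencing data.

## Numerical and scale choices

* The acceptance script and tests use desk-scale problem sizes chosen as the
  package's own verification budget: 300 simulated cases for topology
  accuracy, 200 random matrices (4–5 taxa, ≤ 60 characters) against the
  brute-force parsimony oracle, 20 replicates of n = 10,000 multinomial
  spectra, 10,000 null simulations for rank-test calibration (Wilcoxon at
  n = 10 + 10 where the exact test achieves a level close to 0.05; KW at
  3 × 15).
* NNLS is solved by `scipy.optimize.nnls` (active-set; exact mixtures are
  recovered to < 1e-6). Exposures of an all-zero spectrum are zero with NaN
  proportions and a degenerate flag.
* JSON summaries round floats to 10 decimals and sort keys, making reruns
  byte-identical; file outputs use `%.6g` floats and `NA` for missing.
* Degenerate inputs have defined behavior throughout: empty variant tables
  flow through every stage; single-character matrices give honest ties;
  zero-depth configurations are rejected at construction.

## Known limitations

Exhaustive topology search is capped at six taxa by design. The CNA tree
uses binary event characters, not a minimum-event (distance-based) copy-number
evolution model, so it measures event sharing rather than amplitude paths.
Haplotype assignment is a per-event majority vote without a phasing-error
model. The scoring system is a transparent point heuristic — it ranks
recurrently altered known cancer genes; it does not estimate selection.
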