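# Methods

This note documents the models behind each module, the defaults and why
they hold, what the synthetic generator does and does not emulate, and
the numerical conventions a maintainer needs.

## Study design being modeled

One bacterial species (think E. coli in a healthy adult gut) is sampled
at three intestinal sites — terminal ileum (TI), cecum, descending colon
(DC) — plus feces.  Each site yields a metagenome from which a draft
genome (MAG) is assembled and against which reads are mapped, giving a
per-position allele-count table per site.  The working hypothesis the
pipeline quantifies: all sites carry descendants of a single founder
strain that diversified in place (sympatric diversification), possibly
alongside a nondominant co-resident lineage.

## Synthetic data generator

The generator replaces raw metagenomes with a fully ground-truthed
emulation of that design.

**Founder.**  Random contigs populated with alternating intergenic gaps
and complete ORFs (ATG start, sense codons, one stop; random strand;
translation table 11).  Gene lengths are normal around
`mean_gene_length` (floored at 30 codons), gaps gamma-distributed so
that coding bases cover `gene_fraction` of the genome in expectation.
Defaults: 100 kb over 2 contigs, 85% coding, 900 b genes — a scaled-down
MAG that keeps every per-base computation fast while preserving coding
density.  The genome size used by each analysis is stated in the test or
script that runs it (100–200 kb here); all rates are per-base, so
conclusions transfer to full-size genomes.

**Diversification.**  Each site genome is founder + shared substitutions
(pre-split) + site-private substitutions.  Candidate changes are uniform
over (position, alternative base); changes creating a premature stop are
always rejected, and nonsynonymous candidates are accepted with
probability `omega_true` (synonymous with probability 1/omega when
omega > 1).  Because the synonymous fraction of candidate paths equals
S/(3·codons), this rejection scheme makes the realized
(N_d/N)/(S_d/S) of implanted changes target `omega_true` — the property
the dN/dS recovery tests rely on.  Defaults: 10 shared + 20 private
substitutions per site, omega 0.2 (tens of fixed differences and strong
purifying selection, the within-host scale over a few years at
~7×10⁻⁷ per base per year).

**Minor lineage.**  One SNP set (default 25 SNPs at frequency 0.3),
identical across all sites and placed only at positions untouched by the
major lineage, so that minor-lineage evidence is never confounded with
major-strain divergence.  It exists only in the read pools, never in the
emitted site genomes — exactly the situation the shared-SNP intersection
detector is built for.

**Coverage and reads.**  Expected depth is piecewise log-linear between
log₂(ptr·d_ter) at the origin (position 0 of contig 1) and log₂(d_ter)
at the terminus (genome midpoint), symmetric on both replichores
(bidirectional replication), with d_ter normalized so the genome-wide
mean equals `mean_depth`; realized depth is Poisson.  Read bases mix
major lineage (1−f), minor lineage (f) and uniform miscalls
(`error_rate`, default 0.2%).  Read summaries draw uniform read starts
(100 b reads), with mismatches = implanted differences in the interval +
binomial sequencing errors; deleted genes (per-individual gene content)
produce no reads and no coverage.  Since the sample's total read count
is needed for relative abundance, the read-summary TSV carries it in a
`# total_reads=` header line rather than emitting millions of unmapped
rows; the mapped fraction defaults to 0.3 (a high-abundance gut
species).

**What is not emulated.**  No FASTQ/alignment level (mapping bias,
indels, strand artifacts, base-quality structure), no chimeric or
recombinant strains, no GC-dependent coverage bias, no within-site
polymorphism of the major lineage beyond sequencing error (exposed as
`error_rate` rather than asserting a spectrum).  Passing recovery tests
therefore validates the estimators' logic and calibration under the
stated noise model — not robustness to alignment artifacts in real
metagenomes.

## Variant calling and heterogeneity

Filters are inclusive at the quoted thresholds: depth ≥ 8 and best
non-reference allele ≥ 20% to call; VAF ≥ 80% for dominant/fixed status.
Only the single most frequent non-reference allele is reported; ties
break lexicographically.  The heterogeneity rule is deliberately
different in strictness: a callable position is *non*polymorphic only
when its dominant allele exceeds 80% (so 80.0% exactly counts as
polymorphic), and > 5 SNPs/kb flags a probable mixture.  With zero
callable bases the rate is NaN and the flag false.  Indels are out of
scope throughout.

## Minor-lineage detection

Per site, calls with 20% ≤ VAF ≤ 50% are retained (> 50% is attributed
to the major lineage; exactly 50% is kept), and the shared set is the
exact (contig, position, variant base) intersection across all sites;
≥ 20 shared SNPs declares the lineage present.  At depth 100 and
frequency 0.3 the per-site retention probability is ≈ 0.99, so ≥ 95% of
implanted SNPs survive a three-site intersection; at depth 50 the 20%
cutoff starts to clip the binomial tail, which is why the recovery
condition is stated at depth ≥ 100.

## ANI

A is cut into non-overlapping 1 kb fragments; each fragment is aligned
by infix edit distance (edlib) against the colinear window of B
(±max(50, fragment/10) margin) when a same-named contig exists, with a
16-mer-seeded search over an index of B as fallback for renamed or
rearranged contigs.  Identity = 1 − edits/fragment-length; fragments
under 80% identity do not count.  On colinear genomes with substitution
divergence this reduces to Hamming identity, so a 1% substitution
simulation calibrates to 99.0 ± 0.1 and identical genomes give exactly
100.  Fecal-to-lumen assignment is the argmin of total SNP distances;
ties are reported as ambiguous, never broken.

## Gene flux and content dissimilarity

Read-to-gene overlap counts any shared base, once per gene per read.
Missing = target < 3 reads and reference ≥ 10 reads (both bounds as
stated, target bound exclusive).  Presence for dissimilarity uses the
same ≥ 10-read evidence bound.  PERMANOVA uses the standard
distance-based decomposition (SS_total from all squared pairwise
distances / n, SS_within per group / group size), pseudo-F with (a−1),
(n−a) degrees of freedom, and the +1-corrected permutation p-value; it
matches scikit-bio's statistic on the same matrix (asserted in tests)
but is computed independently.  PCoA is classical Torgerson scaling;
negative eigenvalues are dropped and each axis's sign is fixed by making
its largest-magnitude loading positive so plots are reproducible.

## Selection

The quasi-CDS concatenates the codons of coding SNPs passing depth ≥ 10
and VAF ≥ 50%.  Counting dN/dS follows Nei–Gojobori (1986) with equal
path weighting: expected sites from the reference codons only (each pair
differs at one base, so ref/variant averaging is immaterial), mutation
paths to stop codons excluded from both site classes, observed
differences classified by translation (a variant stop counts as
nonsynonymous).  No multiple-hit correction is applied — codon pairs
differ at ≤ 1 position by construction, making corrections moot.  This
counting estimator deliberately replaces likelihood-based site-specific
ω machinery: on quasi-CDS input (one substitution per codon, no
phylogeny) counting is the appropriate estimator, at the cost of bias at
extreme ω, which is why recovery tolerances are relative (±50%) rather
than absolute.  ω is undefined (NaN, no interpretation) when S_d = 0; no
pseudocount is used.

Divergence time is m/(μG) with μ defaulting to 7×10⁻⁷ per base per year
and G the analyzed genome length (5×10⁶ in the typical-genome worked
example, giving 3.5 mutations per genome-year).  Fixed-mutation counts
include intergenic positions.  Note that with a co-resident minor
lineage at frequency f, major-lineage substitutions appear at VAF ≈ 1−f;
at f > 0.2 they drop below the 80% fixed threshold, so the divergence
clock should be read from samples without a substantial minor lineage.

QRDR typing translates gyrA and parC and compares residues 83/87 and 80
against Ser/Asp/Ser (E. coli numbering).  The wild-type map is a plain
argument, overridable for other species or numbering conventions.
Frameshifts are never inferred; if provided as annotations they pass
through reports untouched.

## Replication index

5 kb windows every 100 b (the established convention for this family of
coverage-gradient estimators), sorted ascending, 5% trimmed from each
tail.  The fitted line uses each retained window's quantile rank from
the *untrimmed* ordering, so the fit extrapolates over the full [0, 1]
genome fraction and trimming does not shrink the slope — the estimator
is unbiased for the simulated gradient (recovery within ±0.15 at depth
50, RMSE ≤ 0.1 over 20 replicates at PTR 1.75).  Sorting before fitting
removes any dependence on knowing the origin's location; the cost is
that any non-replication coverage heterogeneity also ends up in the
sorted profile (GC bias is not corrected — a stated limitation).  Flat
coverage yields index 1 with fit r² fixed at 1.0 by convention (the
zero-variance fit is perfect).  Undefined cases (track shorter than one
window, fewer than 20 windows, a retained zero-coverage window) return a
NaN index with a reason string rather than raising.

## Orchestration

`run_individual` executes variants → tracking/flux/selection/growth with
stage and per-site isolation: failures record skipped-with-reason
sections and never abort sibling analyses, because partially covered
individuals are the norm in this design.  Reports serialize to JSON
losslessly (NaN → null) and are byte-identical for identical
scenario+seed.  All randomness flows from `numpy.random.default_rng`
seeded by the scenario seed plus fixed per-stage tags, so every emitted
artifact is deterministic.

## Known limitations

- The generator's substitution process is uniform across the genome; no
  mutational hotspots, no recombination.
- ANI is asymmetric in principle (fragments of A against B); symmetry
  holds within tolerance on colinear genomes, and the matrix helper
  computes both directions explicitly.
- The dN/dS estimator is a polymorphism-based ratio (pN/pS in spirit);
  segregating slightly-deleterious variants can depress it relative to a
  long-term substitution dN/dS.
- Relative abundance requires the caller to supply the sample's total
  read count (or a read summary carrying it); the package does not model
  the non-target fraction of a metagenome.
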