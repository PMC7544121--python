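# Methods

This note documents the models, parameter choices and numerical decisions
behind `mendelmap`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Study design assumed

The pipeline targets the smallest informative design for a fully
penetrant autosomal-recessive (AR) trait in a closed population: `c`
affected offspring (default 2), their `k` unaffected obligate-carrier
dams (default 2), and `u` unrelated unaffected controls (default 4),
jointly genotyped from WGS into one multi-sample VCF. Two assumptions are
load-bearing: full penetrance with no phenocopies (so the AR genotype
pattern is a hard filter, not a score), and a recent common ancestor for
the affecteds (so the causal locus sits in a long shared autozygous
tract). Violating either silently empties the funnel rather than
producing wrong candidates — the report's stage counts make this visible.

## Pipeline stages and parameters

All defaults are exposed on `PruneParams`, `ROHParams` and
`PipelineConfig`.

| parameter | default | units | role |
|---|---|---|---|
| `min_qual` | 30 | Phred | site QUAL floor, boundary inclusive |
| `PruneParams.window` / `step` | 50 / 50 | variants | LD-pruning window geometry |
| `PruneParams.r2_threshold` | 0.2 | — | genotype-r² cutoff (strictly above offends) |
| `ROHParams.window_bp` | 50,000 | bp | physical span of ROH windows |
| `ROHParams.max_het` | 3 | calls | heterozygote allowance per window per individual |
| `ROHParams.min_markers` | 25 | markers | minimum run length for a segment |
| `p_threshold` | 0.02 | — | allelic-test cutoff, strictly below passes |
| `impact_floor` | MODERATE | tier | minimum reported impact |
| flank in `check_candidate_genes` | 1000 | bp | candidate-gene window extension |

The cascade branches after the QUAL filter. The homozygosity branch
prunes for local LD and calls ROH on the pruned grid; the association
branch applies the AR pattern filter and the exact allelic test to the
*unpruned* QUAL-filtered callset and is then intersected with the
affected-shared ROH regions. Pruning is deliberately kept out of the
association branch: its purpose is to de-correlate the marker grid for
autozygosity detection, and applying it before association could delete
the causal variant itself in favour of a linked neighbour.

### LD pruning

Genotype r² is the squared Pearson correlation of 0/1/2 dosages with
exact pairwise deletion of missing calls (all per-pair sums are assembled
from matrix products of the zero-filled dosage matrix and the validity
mask, so the window r² matrix is bit-identical to per-pair computation).
The sweep visits fixed windows of `window` consecutive sites advancing by
`step` per chromosome; within a window, while any retained pair exceeds
the threshold, one member is removed — higher missingness first, then
lower MAF (keeping the more informative, more polymorphic site), then the
later position. Re-pruning the output of a single window is a no-op;
global re-application after re-indexing is not meaningful for
variant-count windows and is not claimed. With only 8 samples the
sampling noise of r² is large (≈ 0.25 probability that two truly
independent sites exceed 0.2), so pruning retains roughly 10% of sites —
this matches how aggressive such pruning is on real tiny cohorts and is
why the simulator's marker density is chosen as it is (below).

Greedy pairwise pruning is *not* monotone in the threshold: raising the
cutoff can change the removal order and occasionally drop a site that a
stricter run kept. This is a property of the procedure itself, shared
with the standard tools, not a defect of this implementation.

### ROH calling

A marker supports autozygosity iff **every** window of `window_bp` base
pairs anchored at a marker and covering it contains at most `max_het`
heterozygous calls for that individual; missing calls neither support nor
interrupt. Maximal runs of at least `min_markers` supporting markers
become segments, spanning first to last supporting marker. Two
consequences of the every-window rule are worth knowing:

- **Edge erosion.** Windows anchored just outside a true autozygous
  tract include het-dense flanking markers, so detected boundaries sit up
  to one window span (50 kb) inside the true tract on each side. Tract
  recovery is therefore asserted to within one window span plus one
  inter-marker spacing, not to the marker.
- **Interior hets.** A run may contain more than `max_het` hets in
  total, as long as no single covering window exceeds the allowance.

Pooling takes the transitive overlap closure of segments across samples.
A group's consensus is the intersection of all member intervals (possibly
empty for a staggered chain, in which case it is recorded as absent). The
affected-shared filter reports the intersection of the *case* segments:
every case must contribute a segment, the cases' homozygous alleles must
agree at every marker where two of them are informative, and no non-case
member may carry the identical homozygous signature over that span. Using
the case intersection rather than the pooled consensus matters: a chance
homozygous run in a control that overlaps the tract with a different
haplotype must not narrow the region the affecteds demonstrably share.

### Exact allelic test

Alleles are counted two per diploid sample, missing calls excluded;
obligate carriers are counted on the control side by default (matching
the carrier-inclusive case/control design such studies use), with
`include_carriers=False` available for unrelated-only controls. The
two-sided p is the point-probability tail of the hypergeometric
distribution at fixed margins. Because the point probabilities at fixed
margins are proportional to products of binomial coefficients, the tail
is assembled by comparing exact integers and reduced with
`fractions.Fraction` — there is no floating-point tolerance anywhere in
the test itself. For the default design the analytic floor is
`p = 15/1820 ≈ 0.00824`; a threshold of 0.02 therefore admits at most one
control heterozygote (`35/1820 ≈ 0.0192`).

No multiple-testing correction is applied; the funnel records how many
tests were run. Structural variants are outside scope and the report
metadata says so.

### Consequence annotation

One transcript per gene is annotated (the first mRNA in the GFF3; the
choice is explicit in the output, never silent). CDS offsets count 5'→3'
along the coding strand; minus-strand models count from the genomically
rightmost coding base and complement the alleles before substitution.
Codons translate under the standard genetic code (via Biopython); the
independent all-64-codon table in the test suite guards the mapping.
HGVS protein notation uses three-letter residue names with `*` for stop
(`p.Ser875*`); synonymous changes render as `p.Xxx123Xxx`. SNVs only:
indels and splice-region effects are out of scope, and any non-coding
position degrades to MODIFIER with its Sequence Ontology region term.

## The synthetic cohort generator

The generator (`mendelmap.simulate`) emulates the statistical structure
the pipeline assumes, not sequencing itself.

- **Genome.** Two 1 Mb chromosomes with 4,000 markers each (1 per
  250 bp, typical of a WGS SNV callset). After pruning this leaves ~1
  marker per 2.5 kb — about 20 markers per 50 kb ROH window, enough for
  the het allowance of 3 to discriminate autozygous from outbred
  sequence. At several-fold sparser grids the ROH stage degenerates
  (every genome looks homozygous at the window scale), which is an
  artifact of marker sparsity, not a harder test.
- **Allele frequencies and LD.** Per-site MAF is uniform on
  [0.05, 0.5]. Haplotypes realize block-wise LD by copying the previous
  marker's latent uniform with probability 0.8 within 10-marker blocks —
  a stylized copula-style model that preserves each site's marginal
  frequency while inducing strong local r², sufficient to exercise
  pruning; it is not a coalescent and carries no recombination map.
- **Ascertainment.** Only sites with at least one called alternate
  allele among the 8 cohort samples are emitted, as a joint variant
  caller would. The MAF test therefore checks convergence to the
  segregation-ascertained density ∝ 1 − (1−p)¹⁶ − p¹⁶ on the configured
  support, with the analytic 95% Kolmogorov–Smirnov band as the frozen
  bound.
- **Planted signal.** A founder haplotype spans the 600 kb tract
  (chr4:200,000–800,000); both affected haplotypes copy it there (fully
  homozygous, identical by descent), each dam carries one copy, controls
  none. The causal G>T site at chr4:500,000 is added with genotypes
  hom-alt/het/hom-ref by role. Its QUAL is drawn from the same
  distribution as background sites but truncated at 30, and it is never
  masked missing: the generator emulates a confidently called causal
  variant, which is the premise of the design being emulated.
- **Noise.** QUAL ~ Gamma(shape 3, scale 40), putting ≈ 4–5% of sites
  below the Q30 floor so the filter is exercised; genotypes go missing
  independently at rate 0.02.
- **Panel.** 12 breeds × 10 samples. Each background variant segregates
  in the panel with probability 0.85 at its own MAF; the causal allele is
  absent from the panel by construction (breed-private).
- **Gene fixture.** A three-exon minus-strand gene (2,700 nt CDS, 900
  codons) is written into the reference so that the causal position is
  spliced-CDS offset 2624, inside reference codon TCA at codon 875 — the
  coding C>A change creates a TAA stop. The reference codon is a fixture
  choice among the serine codons that a C>A at codon position 2 converts
  to a stop. A mirrored plus-strand variant of the fixture (with
  complementary genomic alleles) and an intron-placement variant support
  the strand-symmetry and non-coding tests.

**What passing on this generator does and does not show.** It shows the
procedure is internally correct: filters implement their definitions
(verified against brute-force oracles), the exact test matches
enumeration, and the cascade recovers a planted recessive variant under
realistic marker density, LD, missingness and QC noise. It does not show
robustness to features the generator omits: population structure and
cryptic relatedness among controls, variant-calling artifacts correlated
along the genome, indels and multi-nucleotide variants, reference bias,
or phenocopies and reduced penetrance.

## Numerical and degenerate-input decisions

- Coordinates are 1-based inclusive at VCF/GFF boundaries, 0-based
  half-open internally and in BED; every emitted file is deterministic
  (sorted by chromosome then position) and byte-stable across reruns.
- Multiallelic records are decomposed per alternate allele (other
  alternates count as reference); phased separators are accepted and
  treated as unphased; missing genotypes are a first-class state, never
  imputed, and a missing call in any MOI-required sample fails the site.
- r² is undefined (never "offending") for pairs monomorphic after
  pairwise deletion; a site's pairwise r² exactly at the threshold does
  not offend (strict inequality); oracle tests skip knife-edge draws
  where float noise makes the strict comparison implementation-defined.
- An all-zero contingency table, a group contributing zero alleles, an
  empty genotype survey and a pedigree without affected samples are
  errors; an empty candidate list is a valid pipeline result.
- Fisher p-values are reported to 3 decimals; full precision is kept
  internally. Phenotype-count tables wider than 2×2 are collapsed to
  first-category-vs-rest before testing; comparisons of more than two
  groups must be made pairwise.
- All randomness lives in the simulator, derived from one master seed by
  fixed sub-seeding order; pipeline stages are pure functions of their
  inputs.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run on 2 × 1 Mb chromosomes
with 4,000 markers each (≈ 7,500 segregating sites), a 120-sample panel,
and 20 independently seeded cohorts for the end-to-end recovery rate;
oracle sweeps use chromosomes up to 500 markers (ROH, 200 trials), all
2×2 tables with margins ≤ 12 (exact test), and five-site windows
(pruning). These sizes keep every property at full strength while the
whole suite runs in well under a minute of compute per component.

## Known limitations

- The ROH caller's every-window rule erodes tract edges by up to one
  window span; boundary-precise autozygosity mapping would need a
  hit-proportion rule or HMM smoothing.
- Greedy LD pruning is order-dependent and threshold-non-monotone (as in
  the standard tools).
- One transcript per gene; no splice-region, UTR-regulatory or indel
  consequences; standard genetic code only.
- The allelic test is unadjusted for relatedness between cases and
  carriers — appropriate for hypothesis screening in a known pedigree,
  not for population-scale association.
- The breed-panel screen operates on genotype calls; absence from the
  panel is evidence of breed exclusivity only up to the panel's depth
  and breed coverage.
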