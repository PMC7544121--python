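# mendelmap

Homozygosity mapping and recessive-variant prioritization for small family
cohorts.

## The problem

Rare, fully penetrant recessive diseases in closed breeding populations
(livestock breeds, isolated human communities) are often mapped with only a
handful of genomes: a couple of affected offspring, their unaffected
obligate-carrier parents, and a few unrelated controls. Two complementary
signals make this feasible despite the tiny sample:

1. **Autozygosity.** Affected individuals inherit the causal haplotype
   identically by descent from a common ancestor, so they share a long run
   of homozygosity (ROH) around the causal locus — a tract their carrier
   parents and unrelated controls do not share.
2. **Genotype pattern.** Under an autosomal-recessive (AR) model, every
   affected must be homozygous for the alternate allele and every obligate
   carrier heterozygous; an exact allelic test then ranks the survivors.

`mendelmap` implements the full cascade as a reusable library and CLI:

```
multi-sample VCF + PED pedigree
        │  QUAL ≥ 30
        ├────────────── homozygosity branch ──────────────┐
        │   LD pruning (r² > 0.2 in 50-variant windows)   │
        │   per-sample ROH (50 kb windows, ≤ 3 hets,      │
        │     ≥ 25 markers per segment)                   │
        │   cross-sample pooling → regions homozygous for │
        │     the same allele in all affecteds only       │
        └────────────── association branch ───────────────┘
            AR genotype-pattern filter (cases hom-alt, carriers het)
            two-sided exact allelic test, keep P < 0.02
            intersect with the affected-shared ROH regions
            consequence annotation (HGVS c./p., impact tiers)
            cross-breed panel screen (exclusive alleles)
        → Table-shaped report: variant, impact, HGVS, P_allelic, breeds
```

Because real cohorts of this kind are rarely redistributable, the package
ships a first-class synthetic-data generator that emulates the study
design: two affected foals homozygous for a planted nonsense allele inside
a shared 600 kb identity-by-descent tract, two heterozygous dams, four
homozygous-reference controls, and a 12-breed genotype panel that does not
carry the planted allele.

## The statistics at the core

**Exact allelic test.** For a site with case/control allele counts
arranged as a 2×2 table, the two-sided p-value is the point-probability
Fisher tail: with fixed margins, `P(k) ∝ C(r₁,k)·C(r₂,c₁−k)`, and
`p = Σ_{k: P(k) ≤ P(obs)} P(k)`, evaluated in exact integer arithmetic.
For the design above (2 cases hom-alt, 2 carriers het, 4 controls hom-ref,
carriers counted on the control side) the causal table is
`[[4,0],[2,10]]`, giving `p = 15/1820 = 0.008`; one extra control
heterozygote gives `[[4,0],[3,9]]`, `p = 35/1820 = 0.019` — which is why a
`P < 0.02` threshold admits exactly one control heterozygote.

**ROH calling.** A marker supports autozygosity iff every 50 kb window
anchored at a marker and covering it contains ≤ 3 heterozygous calls;
maximal runs of ≥ 25 supporting markers become segments. Segments are
pooled across samples by transitive overlap, and a region is kept when all
affecteds are homozygous for the same allele over it and no unaffected
sample carries the same homozygous signature.

**Consequence projection.** Genomic SNVs are projected onto strand-aware
transcript models: spliced CDS offset → codon index/offset → codon
substitution under the standard genetic code → HGVS (`c.2624C>A`,
`p.Ser875*`) and impact tier (stop_gained/stop_lost/start_lost → HIGH,
missense → MODERATE, synonymous → LOW, non-coding → MODIFIER).

## Worked example

```bash
mendelmap run --simulate --seed 1 --out-dir demo/
```

generates a synthetic cohort (VCF/PED/GFF3/FASTA/panel), runs the cascade
and prints the report:

```
CHROM	POS	REF	ALT	EFFECT	SO_TERM	P_ALLELIC	BREEDS
chr4	500000	G	T	HIGH (geneA c.2624C>A,p.Ser875*)	stop_gained	0.008	None

#FUNNEL	stage	sites
#FUNNEL	sites_total	7442
#FUNNEL	qual_ge_30	7155
#FUNNEL	moi_recessive	281
#FUNNEL	allelic_p_lt_0.02	93
#FUNNEL	in_shared_roh_region	81
#FUNNEL	impact_ge_MODERATE	1
```

Reading: of 7,442 emitted sites, 7,155 pass `QUAL ≥ 30`; 281 match the
recessive genotype pattern; 93 associate at `P < 0.02`; 81 of those fall
in the single region the two affecteds share homozygously (the recovered
planted tract); and exactly one is coding with impact ≥ MODERATE — the
planted nonsense variant, reported with `p = 0.008` and `BREEDS = None`
(absent from every panel breed, i.e. exclusive to the cohort's own breed).
Background variants riding the same haplotype are intergenic MODIFIERs or
panel-shared and drop out. `demo/` also receives `report.md`,
`report.json`, `roh_consensus.bed` and the simulated inputs themselves.

Each stage is also exposed separately (`mendelmap simulate | prune | roh |
filter | assoc | annotate | screen | report`) and as library functions
(`mendelmap.ld_prune`, `mendelmap.call_roh_sample`,
`mendelmap.fisher_exact_2x2`, `mendelmap.annotate_site`, ...).

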