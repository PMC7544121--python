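"""Quality and mode-of-inheritance filtering, the exact allelic test,
region intersection, breed-panel screening and allele-frequency estimation.

The two-sided Fisher test uses the point-probability definition — the sum
of hypergeometric probabilities, at fixed margins, not exceeding that of
the observed table — evaluated in exact integer arithmetic, which
reproduces printed values such as 15/1820 = 0.008 without rounding error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np

from .errors import StageError
from .model import (
    HET,
    HOM_ALT,
    AssocResult,
    CohortGenotypes,
    GenomicInterval,
    Pedigree,
    ScreenResult,
    VariantSite,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MoiModel:
    """Mode-of-inheritance genotype requirements.

    Only the autosomal-recessive model is defined: affected samples must be
    homozygous for the alternate allele and obligate-carrier parents must
    be heterozygous.
    """

    name: str = "autosomal-recessive"
    case_genotype: int = HOM_ALT
    carrier_genotype: int = HET

    def __post_init__(self) -> None:
        if self.name != "autosomal-recessive":
            raise StageError(f"unsupported inheritance model {self.name!r}")


AR_MODEL = MoiModel()


# ---------------------------------------------------------------------------
# site-wise filters
# ---------------------------------------------------------------------------

def filter_quality(cohort: CohortGenotypes, min_qual: float = 30.0) -> CohortGenotypes:
    """Retain sites with QUAL >= ``min_qual`` (boundary inclusive)."""
    if np.any(np.isnan(cohort.qual)):
        raise StageError("filter_quality requires QUAL on every site")
    return cohort.subset(cohort.qual >= min_qual)


def filter_moi(
    cohort: CohortGenotypes, ped: Pedigree, model: MoiModel = AR_MODEL
) -> CohortGenotypes:
    """Retain sites matching the recessive genotype pattern.

    Every case must carry the case genotype and every obligate-carrier
    parent the carrier genotype; a missing call in any required sample
    fails the site (missingness is never rescued).
    """
    if not ped.cases:
        raise StageError("filter_moi requires >= 1 affected sample")
    case_cols = [cohort.sample_index(s) for s in ped.cases]
    carrier_cols = [cohort.sample_index(s) for s in ped.obligate_carriers]
    mask = np.all(cohort.gt[:, case_cols] == model.case_genotype, axis=1)
    if carrier_cols:
        mask &= np.all(cohort.gt[:, carrier_cols] == model.carrier_genotype, axis=1)
    return cohort.subset(mask)


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Exact integer arithmetic: at fixed margins the hypergeometric point
    probability of a table is proportional to C(r1,k)·C(r2,c1−k), so the
    two-sided tail is assembled by comparing integer numerators — no
    floating-point tolerance is needed.
    """
    ((a, b), (c, d)) = [[int(x) for x in row] for row in table]
    if min(a, b, c, d) < 0:
        raise StageError("contingency counts must be non-negative")
    if a + b + c + d == 0:
        raise StageError("fisher_exact_2x2: all-zero table")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    observed = comb(r1, a) * comb(r2, c1 - a)
    tail = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        numer = comb(r1, k) * comb(r2, c1 - k)
        if numer <= observed:
            tail += numer
    return float(Fraction(tail, comb(n, c1)))


def allelic_table(
    site: VariantSite,
    samples: Sequence[str],
    ped: Pedigree,
    include_carriers: bool = True,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Case/control x alt/ref allele counts (two alleles per diploid call,
    missing calls excluded)."""
    index = {name: i for i, name in enumerate(samples)}
    controls = ped.controls + (ped.obligate_carriers if include_carriers else [])

    def count(group: list[str]) -> tuple[int, int]:
        alt = ref = 0
        for name in group:
            if name not in index:
                raise StageError(f"pedigree sample {name!r} absent from genotypes")
            g = site.genotypes[index[name]]
            if g < 0:
                continue
            alt += g
            ref += 2 - g
        return alt, ref

    case_alt, case_ref = count(ped.cases)
    ctrl_alt, ctrl_ref = count(controls)
    if case_alt + case_ref == 0 or ctrl_alt + ctrl_ref == 0:
        raise StageError(
            f"allelic test at {site.chrom}:{site.pos}: a group contributes "
            "zero alleles"
        )
    return ((case_alt, case_ref), (ctrl_alt, ctrl_ref))


def allelic_test(
    site: VariantSite,
    samples: Sequence[str],
    ped: Pedigree,
    include_carriers: bool = True,
) -> AssocResult:
    """Exact allelic association of one site; controls include obligate
    carriers by default, as in a carrier-inclusive case/control design."""
    if not ped.cases:
        raise StageError("allelic_test requires >= 1 affected sample")
    table = allelic_table(site, samples, ped, include_carriers)
    return AssocResult(
        chrom=site.chrom,
        pos=site.pos,
        ref=site.ref,
        alt=site.alt,
        table=table,
        p_allelic=fisher_exact_2x2(table),
    )


def allelic_test_cohort(
    cohort: CohortGenotypes, ped: Pedigree, include_carriers: bool = True
) -> list[AssocResult]:
    return [
        allelic_test(cohort.site(i), cohort.samples, ped, include_carriers)
        for i in range(cohort.n_sites)
    ]


# ---------------------------------------------------------------------------
# region intersection and panel screen
# ---------------------------------------------------------------------------

def merge_intervals(regions: list[GenomicInterval]) -> list[GenomicInterval]:
    merged: list[GenomicInterval] = []
    for iv in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            merged[-1] = GenomicInterval(
                iv.chrom, merged[-1].start, max(merged[-1].end, iv.end)
            )
        else:
            merged.append(iv)
    return merged


def restrict_to_regions(
    cohort: CohortGenotypes, regions: list[GenomicInterval]
) -> CohortGenotypes:
    """Retain sites whose 1-based position falls inside any region."""
    merged = merge_intervals(regions)
    mask = np.zeros(cohort.n_sites, dtype=bool)
    for iv in merged:
        mask |= (
            (cohort.chrom == iv.chrom)
            & (cohort.pos - 1 >= iv.start)
            & (cohort.pos - 1 < iv.end)
        )
    return cohort.subset(mask)


def screen_breed_panel(
    sites: CohortGenotypes,
    panel: CohortGenotypes,
    breed_of: dict[str, str],
) -> list[ScreenResult]:
    """List, per site, the panel breeds carrying >= 1 alternate allele.

    A site absent from the panel is recorded as unobserved (no breeds) and
    logged; an empty breed list marks the variant as exclusive to the
    cohort's breed.
    """
    unknown = [s for s in panel.samples if s not in breed_of]
    if unknown:
        raise StageError(f"panel samples missing breed labels: {unknown[:5]}")
    lookup = {
        (str(panel.chrom[i]), int(panel.pos[i]), str(panel.ref[i]), str(panel.alt[i])): i
        for i in range(panel.n_sites)
    }
    results: list[ScreenResult] = []
    for i in range(sites.n_sites):
        key = (str(sites.chrom[i]), int(sites.pos[i]), str(sites.ref[i]), str(sites.alt[i]))
        if key not in lookup:
            log.info("site %s:%s %s>%s absent from breed panel", *key)
            results.append(
                ScreenResult(*key, breeds=(), in_panel=False)
            )
            continue
        row = panel.gt[lookup[key]]
        breeds = sorted(
            {breed_of[panel.samples[j]] for j in np.flatnonzero(row > 0)}
        )
        results.append(ScreenResult(*key, breeds=tuple(breeds), in_panel=True))
    return results


# ---------------------------------------------------------------------------
# allele frequency and phenotype-count comparison
# ---------------------------------------------------------------------------

def allele_frequency(counts: tuple[int, int, int]) -> float:
    """Alternate-allele frequency q from (hom-ref, het, hom-alt) genotype
    counts: q = (2·hom-alt + het) / (2n)."""
    n_rr, n_het, n_aa = (int(c) for c in counts)
    if min(n_rr, n_het, n_aa) < 0:
        raise StageError("genotype counts must be non-negative")
    n = n_rr + n_het + n_aa
    if n == 0:
        raise StageError("allele_frequency requires >= 1 genotype")
    return (2 * n_aa + n_het) / (2 * n)


def compare_phenotype_counts(table) -> float:
    """Fisher comparison of phenotype-category counts between two groups.

    Tables wider than two categories are collapsed to 2x2 (first category,
    e.g. normal, versus the pooled remainder) before testing.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise StageError(
            "compare_phenotype_counts expects a 2 x c table (compare groups "
            "pairwise); got shape " + str(arr.shape)
        )
    if arr.shape[1] > 2:
        arr = np.column_stack([arr[:, 0], arr[:, 1:].sum(axis=1)])
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise StageError("compare_phenotype_counts: degenerate margins")
    return fisher_exact_2x2(arr)
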