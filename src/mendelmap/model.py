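"""Internal data model shared by all pipeline stages.

Genotypes are stored as an ``int8`` matrix of allele-dosage codes
(0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing), one row per biallelic
site and one column per cohort sample.  Coordinates are 1-based inclusive
wherever they touch VCF/GFF3 and 0-based half-open internally and in BED;
:class:`GenomicInterval` is always the internal convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, StageError

#: genotype codes
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_ALLELE_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise StageError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int) -> "GenomicInterval":
        """Build from 1-based inclusive bounds (VCF/GFF convention)."""
        return cls(chrom, start1 - 1, end1)

    def contains_pos1(self, chrom: str, pos1: int) -> bool:
        """Membership of a 1-based genomic position."""
        return chrom == self.chrom and self.start <= pos1 - 1 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


@dataclass(frozen=True)
class VariantSite:
    """One biallelic site with per-sample dosage codes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    genotypes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not _ALLELE_RE.match(allele):
                raise FormatError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} is not a "
                    "non-empty string over A,C,G,T"
                )
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


class CohortGenotypes:
    """Sites x samples genotype matrix with site metadata.

    Parameters
    ----------
    samples : sequence of sample names (column order).
    chrom, pos, ref, alt, qual : per-site metadata arrays.
    gt : ``(n_sites, n_samples)`` int8 matrix of dosage codes.
    """

    def __init__(self, samples, chrom, pos, ref, alt, qual, gt) -> None:
        self.samples = list(samples)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.qual = np.asarray(qual, dtype=np.float64)
        self.gt = np.asarray(gt, dtype=np.int8)
        n = len(self.pos)
        if not (
            len(self.chrom) == len(self.ref) == len(self.alt) == len(self.qual) == n
        ):
            raise StageError("site metadata arrays have inconsistent lengths")
        if self.gt.shape != (n, len(self.samples)):
            raise StageError(
                f"genotype matrix shape {self.gt.shape} does not match "
                f"{n} sites x {len(self.samples)} samples"
            )

    # -- basic container protocol -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return self.n_sites

    def site(self, i: int) -> VariantSite:
        return VariantSite(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref=str(self.ref[i]),
            alt=str(self.alt[i]),
            qual=float(self.qual[i]),
            genotypes=tuple(int(g) for g in self.gt[i]),
        )

    def subset(self, index) -> "CohortGenotypes":
        """New cohort restricted to the given site indices / boolean mask."""
        index = np.asarray(index)
        if index.size == 0:
            index = np.array([], dtype=np.int64)
        return CohortGenotypes(
            self.samples,
            self.chrom[index],
            self.pos[index],
            self.ref[index],
            self.alt[index],
            self.qual[index],
            self.gt[index],
        )

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise StageError(f"sample {name!r} not in cohort") from None

    def sort_key(self) -> np.ndarray:
        """Indices sorting sites by (chrom, pos)."""
        return np.lexsort((self.pos, self.chrom))

    def is_sorted(self) -> bool:
        key = self.sort_key()
        return bool(np.all(key == np.arange(self.n_sites)))

    def to_frame(self):
        """Site metadata plus per-sample dosage codes as a DataFrame."""
        import pandas as pd

        data = {
            "chrom": self.chrom,
            "pos": self.pos,
            "ref": self.ref,
            "alt": self.alt,
            "qual": self.qual,
        }
        for j, name in enumerate(self.samples):
            data[name] = self.gt[:, j]
        return pd.DataFrame(data)

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-site MAF from non-missing dosages (NaN when all missing)."""
        g = np.ma.masked_less(self.gt, 0)
        p = g.mean(axis=1).filled(np.nan) / 2.0
        return np.minimum(p, 1.0 - p)

    def missingness(self) -> np.ndarray:
        return (self.gt == MISSING).mean(axis=1)


@dataclass(frozen=True)
class PedigreeSample:
    sample_id: str
    family: str
    sire: str | None
    dam: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    status: str  # "affected" | "unaffected" | "unknown"
    sire_external: bool = False
    dam_external: bool = False


@dataclass
class Pedigree:
    """Cohort samples with parental links and derived analysis roles.

    Roles: *cases* are affected samples; *obligate carriers* are listed
    parents of cases (unaffected under an AR model); *controls* are the
    remaining unaffected samples.
    """

    samples: list[PedigreeSample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample id(s) in pedigree: {dupes}")
        listed = set(ids)
        resolved = []
        for s in self.samples:
            resolved.append(
                replace(
                    s,
                    sire_external=s.sire is not None and s.sire not in listed,
                    dam_external=s.dam is not None and s.dam not in listed,
                )
            )
        self.samples = resolved

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def cases(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.status == "affected"]

    @property
    def obligate_carriers(self) -> list[str]:
        listed = {s.sample_id: s for s in self.samples}
        carriers: list[str] = []
        for s in self.samples:
            if s.status != "affected":
                continue
            for parent in (s.sire, s.dam):
                if parent in listed and listed[parent].status != "affected":
                    if parent not in carriers:
                        carriers.append(parent)
        return carriers

    @property
    def controls(self) -> list[str]:
        carriers = set(self.obligate_carriers)
        return [
            s.sample_id
            for s in self.samples
            if s.status == "unaffected" and s.sample_id not in carriers
        ]


@dataclass
class GeneModel:
    """Strand-aware transcript model with exon/CDS structure.

    ``exons`` are 1-based inclusive genomic intervals sorted by genomic
    position and non-overlapping; ``cds_start``/``cds_end`` delimit the
    genomic span of the coding region; ``cds_parts`` are the coding
    sub-intervals of exons.  ``cds_seq`` is the spliced coding sequence on
    the coding strand (reverse-complemented for minus-strand models).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_parts: list[tuple[int, int]]
    cds_seq: str | None = None
    usable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"overlapping exons in {self.transcript_id}: "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        self.cds_parts = sorted(self.cds_parts)

    @property
    def cds_start(self) -> int:
        return self.cds_parts[0][0]

    @property
    def cds_end(self) -> int:
        return self.cds_parts[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval.from_1based(
            self.chrom, self.exons[0][0], self.exons[-1][1]
        )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_parts)


@dataclass(frozen=True)
class ScreenResult:
    """Breed-panel screen outcome for one site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    breeds: tuple[str, ...]
    in_panel: bool

    @property
    def exclusive(self) -> bool:
        return len(self.breeds) == 0


@dataclass(frozen=True)
class AssocResult:
    """Allelic association outcome for one site.

    ``table`` rows are (case, control), columns are (alt, ref) allele counts.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_allelic: float


@dataclass
class Consequence:
    """Transcript-level consequence of one SNV."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None
    transcript: str | None
    region: str  # CDS | intron | UTR | intergenic
    effect: str
    impact: str
    so_term: str
    hgvs_c: str | None = None
    hgvs_p: str | None = None


@dataclass
class CandidateRow:
    """One Table-1-shaped report row."""

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    assoc: AssocResult
    screen: ScreenResult | None


@dataclass
class PrioritizationReport:
    """Final report: ordered candidates plus the stage-count funnel."""

    candidates: list[CandidateRow]
    funnel: list[tuple[str, int]]
    metadata: dict = field(default_factory=dict)

    def high_candidates(self) -> list[CandidateRow]:
        return [c for c in self.candidates if c.consequence.impact == "HIGH"]
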