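"""Synthetic cohort generator.

Emulates the statistical structure of a small recessive-disease mapping
study: two affected offspring homozygous for a planted causal nonsense
allele inside a shared identity-by-descent tract, their heterozygous dams,
unrelated homozygous-reference controls, plus a breed-labelled genotype
panel that does not carry the causal allele.  Background variation is
drawn per-site from a uniform MAF distribution with local LD realized by
block-wise copying of latent uniforms between neighbouring markers — a
stylized model, sufficient to exercise r² pruning, not a coalescent.

All randomness derives from a single master seed through a fixed
sub-seeding order, so every emitted file is byte-identical across runs.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import StageError
from .model import CohortGenotypes, GenomicInterval, Pedigree, PedigreeSample
from . import io as mio

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOP_CODONS = {"TAA", "TAG", "TGA"}

# fixed synthetic gene geometry (bp): 60 nt UTRs, a 2,700 nt CDS split over
# three exons (1000 / 1100 / 600 coding bases) separated by 500 nt introns.
_UTR5, _UTR3 = 60, 60
_CDS_EXON_LENGTHS = (1000, 1100, 600)
_INTRON = 500
_CDS_LEN = sum(_CDS_EXON_LENGTHS)  # 2700 = 900 codons
_CAUSAL_CDS_OFFSET = 2624  # codon 875, position 2 — the planted nonsense site


@dataclass(frozen=True)
class CausalSpec:
    chrom: str = "chr4"
    pos: int = 500_000
    ref: str = "G"
    alt: str = "T"


@dataclass(frozen=True)
class TractSpec:
    """Planted IBD tract, 1-based inclusive bounds."""

    chrom: str = "chr4"
    start: int = 200_000
    end: int = 800_000


@dataclass(frozen=True)
class SimConfig:
    seed: int = 17
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 1_000_000), ("chr4", 1_000_000))
    markers_per_chrom: int = 4000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_markers: int = 10
    ld_copy_prob: float = 0.8
    causal: CausalSpec = field(default_factory=CausalSpec)
    tract: TractSpec = field(default_factory=TractSpec)
    n_affected: int = 2
    n_carriers: int = 2
    n_controls: int = 4
    qual_shape: float = 3.0
    qual_scale: float = 40.0
    min_causal_qual: float = 30.0
    missing_rate: float = 0.02
    panel_breeds: tuple[str, ...] = (
        "AT", "FM", "FD", "GWB", "HF", "ICE", "KWB", "QH", "SH", "STBD", "SWB", "YH",
    )
    panel_samples_per_breed: int = 10
    panel_share_prob: float = 0.85

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if self.tract.chrom not in lengths:
            raise StageError(f"tract chromosome {self.tract.chrom!r} not simulated")
        if not 1 <= self.tract.start < self.tract.end <= lengths[self.tract.chrom]:
            raise StageError("ROH tract must lie inside its chromosome")
        if not (
            self.causal.chrom == self.tract.chrom
            and self.tract.start <= self.causal.pos <= self.tract.end
        ):
            raise StageError("causal locus must lie inside the ROH tract")
        for rate in (self.ld_copy_prob, self.missing_rate, self.panel_share_prob):
            if not 0.0 <= rate <= 1.0:
                raise StageError(f"rate {rate} outside [0, 1]")
        if not 0.0 < self.maf_range[0] < self.maf_range[1] <= 0.5:
            raise StageError("maf_range must satisfy 0 < lo < hi <= 0.5")

    @property
    def sample_names(self) -> list[str]:
        return (
            [f"foal{i+1}" for i in range(self.n_affected)]
            + [f"dam{i+1}" for i in range(self.n_carriers)]
            + [f"ctrl{i+1}" for i in range(self.n_controls)]
        )


@dataclass
class TruthRecord:
    """What the generator planted, for downstream verification."""

    causal_chrom: str
    causal_pos: int
    causal_ref: str
    causal_alt: str
    genotypes: dict[str, int]
    tracts: dict[str, GenomicInterval]
    maf: dict[str, np.ndarray]
    positions: dict[str, np.ndarray]


def _rngs(config: SimConfig) -> dict[str, np.random.Generator]:
    names = ("positions", "maf", "haplotypes", "qual", "missing", "panel",
             "reference", "alts")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# gene fixture geometry
# ---------------------------------------------------------------------------

def _gene_layout(config: SimConfig, strand: str, causal_placement: str) -> dict:
    """Exon/CDS genomic intervals plus the transcript→genome position map.

    The anchor is chosen so that spliced CDS offset 2624 lands exactly on
    the configured causal genomic position (or, for the intronic variant of
    the fixture, so the causal position falls between two exons).
    """
    if causal_placement not in {"cds", "intron"}:
        raise StageError(f"causal_placement must be 'cds' or 'intron', got {causal_placement!r}")
    if strand == "-":
        # genomic offsets relative to anchor a (gene's leftmost base)
        causal_cds_offset_from_anchor = (
            _UTR3 + _CDS_EXON_LENGTHS[2] - 1 - (_CAUSAL_CDS_OFFSET - 2101)
        )  # = 136 for the default geometry
        anchor = (
            config.causal.pos - causal_cds_offset_from_anchor
            if causal_placement == "cds"
            else config.causal.pos - 900
        )
        e3 = (anchor, anchor + _UTR3 + _CDS_EXON_LENGTHS[2] - 1)
        e2s = e3[1] + _INTRON + 1
        e2 = (e2s, e2s + _CDS_EXON_LENGTHS[1] - 1)
        e1s = e2[1] + _INTRON + 1
        e1 = (e1s, e1s + _CDS_EXON_LENGTHS[0] + _UTR5 - 1)
        exons = [e3, e2, e1]
        cds_parts = [
            (e3[0] + _UTR3, e3[1]),
            e2,
            (e1[0], e1[1] - _UTR5),
        ]
        # transcript coordinates run genomically right -> left
        tx_positions = np.concatenate(
            [np.arange(e[1], e[0] - 1, -1) for e in (e1, e2, e3)]
        )
    elif strand == "+":
        # genomic offset of spliced CDS base 2624 from the gene's left end
        offset_2624 = (
            _UTR5
            + _CDS_EXON_LENGTHS[0] + _INTRON
            + _CDS_EXON_LENGTHS[1] + _INTRON
            + (_CAUSAL_CDS_OFFSET - 2101)
        )
        anchor = (
            config.causal.pos - offset_2624
            if causal_placement == "cds"
            # otherwise drop the causal position into the intron between
            # exon 2 and exon 3
            else config.causal.pos - (offset_2624 - 523 - _INTRON // 2)
        )
        e1 = (anchor, anchor + _UTR5 + _CDS_EXON_LENGTHS[0] - 1)
        e2s = e1[1] + _INTRON + 1
        e2 = (e2s, e2s + _CDS_EXON_LENGTHS[1] - 1)
        e3s = e2[1] + _INTRON + 1
        e3 = (e3s, e3s + _CDS_EXON_LENGTHS[2] + _UTR3 - 1)
        exons = [e1, e2, e3]
        cds_parts = [
            (e1[0] + _UTR5, e1[1]),
            e2,
            (e3[0], e3[1] - _UTR3),
        ]
        tx_positions = np.concatenate(
            [np.arange(e[0], e[1] + 1) for e in (e1, e2, e3)]
        )
    else:
        raise StageError(f"strand must be + or -, got {strand!r}")
    lengths = dict(config.chromosomes)
    chrom_len = lengths[config.causal.chrom]
    lo, hi = exons[0][0], exons[-1][1]
    if lo < 1 or hi > chrom_len:
        raise StageError(
            f"chromosome {config.causal.chrom} (length {chrom_len}) is too "
            f"short for the gene span {lo}-{hi}"
        )
    return {
        "strand": strand,
        "exons": exons,
        "cds_parts": cds_parts,
        "tx_positions": tx_positions,
        "chrom": config.causal.chrom,
    }


def _transcript_sequence(config: SimConfig) -> str:
    """UTR5 + CDS + UTR3 on the coding strand; codon 875 is TCA so the
    planted C>A coding change creates a TAA stop."""
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(8)[6].spawn(1)[0]
    )
    non_stop = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in _STOP_CODONS
    ]
    n_codons = _CDS_LEN // 3
    codons = ["ATG"] + list(rng.choice(non_stop, size=n_codons - 2)) + ["TAA"]
    codons[874] = "TCA"  # codon 875
    cds = "".join(codons)
    utr5 = "".join(rng.choice(_BASES, size=_UTR5))
    utr3 = "".join(rng.choice(_BASES, size=_UTR3))
    return utr5 + cds + utr3


def _reference_sequences(
    config: SimConfig, strand: str = "-", causal_placement: str = "cds"
) -> dict[str, np.ndarray]:
    """Per-chromosome reference as arrays of single characters, with the
    synthetic gene written into the causal chromosome."""
    rng = _rngs(config)["reference"]
    ref = {
        name: _BASES[rng.integers(0, 4, size=length)]
        for name, length in config.chromosomes
    }
    layout = _gene_layout(config, strand, causal_placement)
    tx = _transcript_sequence(config)
    seq = ref[layout["chrom"]]
    genomic = tx if strand == "+" else tx.translate(_COMPLEMENT)
    seq[layout["tx_positions"] - 1] = list(genomic)
    causal = config.causal
    observed = str(seq[causal.pos - 1])
    in_exon = any(s <= causal.pos <= e for s, e in layout["exons"])
    if causal_placement == "cds" and in_exon:
        # the mirrored plus-strand fixture carries the complementary
        # genomic alleles at the same coding position
        expected = causal.ref if strand == "-" else causal.ref.translate(_COMPLEMENT)
        if observed != expected:
            raise StageError(
                f"gene geometry places base {observed!r} at the causal "
                f"position but the config implies {expected!r}"
            )
    else:
        seq[causal.pos - 1] = causal.ref
    return ref


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _ld_haplotypes(
    rng: np.random.Generator, maf: np.ndarray, n_haps: int, config: SimConfig
) -> np.ndarray:
    """(markers x haplotypes) 0/1 alleles with block-wise LD.

    Within an LD block each marker copies the previous marker's latent
    uniform with probability ``ld_copy_prob``; alleles are thresholded
    against each site's own MAF, so marginal frequencies are preserved
    while neighbouring sites correlate."""
    m = len(maf)
    alleles = np.empty((m, n_haps), dtype=np.int8)
    u_prev = rng.random(n_haps)
    for i in range(m):
        fresh = rng.random(n_haps)
        if i % config.ld_block_markers == 0:
            u = fresh
        else:
            copy = rng.random(n_haps) < config.ld_copy_prob
            u = np.where(copy, u_prev, fresh)
        alleles[i] = (u < maf[i]).astype(np.int8)
        u_prev = u
    return alleles


@dataclass
class _SimCore:
    """Deterministic intermediate state shared by all emitters."""

    cohort: CohortGenotypes
    pedigree: Pedigree
    truth: TruthRecord
    panel: CohortGenotypes
    breed_of: dict[str, str]


def build_cohort(config: SimConfig) -> _SimCore:
    """Generate the full synthetic dataset in memory (deterministic)."""
    rngs = _rngs(config)
    names = config.sample_names
    n_ind = len(names)
    n_aff, n_car = config.n_affected, config.n_carriers
    panel_names = [
        f"{breed}_{i+1}"
        for breed in config.panel_breeds
        for i in range(config.panel_samples_per_breed)
    ]
    breed_of = {s: s.rsplit("_", 1)[0] for s in panel_names}
    reference = _reference_sequences(config)

    chrom_col: list[str] = []
    pos_col: list[int] = []
    ref_col: list[str] = []
    alt_col: list[str] = []
    gt_rows: list[np.ndarray] = []
    panel_rows: list[np.ndarray] = []
    causal_flags: list[bool] = []
    truth_maf: dict[str, np.ndarray] = {}
    truth_pos: dict[str, np.ndarray] = {}

    for chrom, length in config.chromosomes:
        spacing = length // (config.markers_per_chrom + 1)
        grid = spacing * np.arange(1, config.markers_per_chrom + 1)
        jitter = rngs["positions"].integers(
            -spacing // 3, spacing // 3 + 1, size=config.markers_per_chrom
        )
        pos = np.unique(np.clip(grid + jitter, 1, length))
        maf = rngs["maf"].uniform(*config.maf_range, size=len(pos))

        is_causal_chrom = chrom == config.causal.chrom
        if is_causal_chrom:
            collide = pos == config.causal.pos
            if collide.any():
                log.info(
                    "displacing %d background marker(s) colliding with the "
                    "causal locus at %s:%d",
                    int(collide.sum()), chrom, config.causal.pos,
                )
                pos, maf = pos[~collide], maf[~collide]

        haps = _ld_haplotypes(rngs["haplotypes"], maf, 2 * n_ind + 1, config)
        founder = haps[:, -1]
        if is_causal_chrom:
            in_tract = (pos >= config.tract.start) & (pos <= config.tract.end)
            for k in range(n_aff):  # both haplotypes IBD from the founder
                haps[in_tract, 2 * k] = founder[in_tract]
                haps[in_tract, 2 * k + 1] = founder[in_tract]
            for k in range(n_car):  # dams transmit one founder haplotype
                col = 2 * (n_aff + k)
                haps[in_tract, col] = founder[in_tract]
        gt = (haps[:, 0 : 2 * n_ind : 2] + haps[:, 1 : 2 * n_ind : 2]).astype(np.int8)

        miss = rngs["missing"].random(gt.shape) < config.missing_rate
        gt[miss] = -1

        # a variant caller only emits sites where the alternate allele was
        # observed: drop background sites with no called alternate allele
        segregating = gt.max(axis=1) > 0
        pos, maf, gt = pos[segregating], maf[segregating], gt[segregating]
        if is_causal_chrom:
            in_tract = in_tract[segregating]

        refs = np.array([str(reference[chrom][p - 1]) for p in pos])
        alt_choice = rngs["alts"].integers(0, 3, size=len(pos))
        alts = np.array(
            [
                [b for b in "ACGT" if b != r][c]
                for r, c in zip(refs, alt_choice)
            ]
        )

        # breed panel: a background variant segregates in the panel with
        # probability panel_share_prob, at its own MAF
        shared = rngs["panel"].random(len(pos)) < config.panel_share_prob
        panel_gt = rngs["panel"].binomial(
            2, np.repeat(maf[:, None], len(panel_names), axis=1)
        ).astype(np.int8)
        panel_gt[~shared] = 0

        if is_causal_chrom:
            at = int(np.searchsorted(pos, config.causal.pos))
            causal_gt = np.array(
                [2] * n_aff + [1] * n_car + [0] * config.n_controls, dtype=np.int8
            )
            pos = np.insert(pos, at, config.causal.pos)
            maf = np.insert(maf, at, np.nan)
            refs = np.insert(refs, at, config.causal.ref)
            alts = np.insert(alts, at, config.causal.alt)
            gt = np.insert(gt, at, causal_gt, axis=0)
            panel_gt = np.insert(
                panel_gt, at, np.zeros(len(panel_names), dtype=np.int8), axis=0
            )
            flags = np.zeros(len(pos), dtype=bool)
            flags[at] = True
        else:
            flags = np.zeros(len(pos), dtype=bool)

        chrom_col.extend([chrom] * len(pos))
        pos_col.extend(int(p) for p in pos)
        ref_col.extend(refs)
        alt_col.extend(alts)
        gt_rows.append(gt)
        panel_rows.append(panel_gt)
        causal_flags.extend(bool(f) for f in flags)
        truth_maf[chrom] = maf
        truth_pos[chrom] = pos

    gt = np.vstack(gt_rows)
    panel_gt = np.vstack(panel_rows)
    causal_mask = np.array(causal_flags)
    n_sites = len(pos_col)

    qual = rngs["qual"].gamma(config.qual_shape, config.qual_scale, size=n_sites)
    qual = np.round(qual, 2)
    ci = int(np.flatnonzero(causal_mask)[0])
    while qual[ci] < config.min_causal_qual:  # causal site passed QC in the design
        qual[ci] = round(
            rngs["qual"].gamma(config.qual_shape, config.qual_scale), 2
        )

    cohort = CohortGenotypes(names, chrom_col, pos_col, ref_col, alt_col, qual, gt)
    panel = CohortGenotypes(
        panel_names, chrom_col, pos_col, ref_col, alt_col,
        np.full(n_sites, np.nan), panel_gt,
    )
    pedigree = _pedigree(config)
    tract_iv = GenomicInterval.from_1based(
        config.tract.chrom, config.tract.start, config.tract.end
    )
    truth = TruthRecord(
        causal_chrom=config.causal.chrom,
        causal_pos=config.causal.pos,
        causal_ref=config.causal.ref,
        causal_alt=config.causal.alt,
        genotypes={
            name: int(g) for name, g in zip(names, gt[causal_mask][0])
        },
        tracts={f"foal{i+1}": tract_iv for i in range(n_aff)},
        maf=truth_maf,
        positions=truth_pos,
    )
    return _SimCore(cohort, pedigree, truth, panel, breed_of)


def _pedigree(config: SimConfig) -> Pedigree:
    samples = []
    for i in range(config.n_affected):
        dam = f"dam{min(i, config.n_carriers - 1) + 1}" if config.n_carriers else None
        samples.append(
            PedigreeSample(
                sample_id=f"foal{i+1}", family="FAM1", sire=None, dam=dam,
                sex=1 + i % 2, status="affected",
            )
        )
    for i in range(config.n_carriers):
        samples.append(
            PedigreeSample(
                sample_id=f"dam{i+1}", family="FAM1", sire=None, dam=None,
                sex=2, status="unaffected",
            )
        )
    for i in range(config.n_controls):
        samples.append(
            PedigreeSample(
                sample_id=f"ctrl{i+1}", family="FAM1", sire=None, dam=None,
                sex=1 + i % 2, status="unaffected",
            )
        )
    return Pedigree(samples)


# ---------------------------------------------------------------------------
# file emitters
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimConfig, out_dir: str | os.PathLike
) -> tuple[Path, Path, TruthRecord]:
    """Write cohort VCF + PED (+ truth TSV); returns their paths and the
    in-memory truth record."""
    core = build_cohort(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vcf_path = out / "cohort.vcf"
    ped_path = out / "cohort.ped"
    mio.write_vcf(core.cohort, vcf_path)
    mio.write_pedigree(core.pedigree, ped_path)
    _write_truth(core.truth, out / "truth.tsv")
    return vcf_path, ped_path, core.truth


def simulate_panel(
    config: SimConfig, out_dir: str | os.PathLike
) -> tuple[Path, Path]:
    """Write the breed-labelled panel VCF and the sample→breed map."""
    core = build_cohort(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel_path = out / "panel.vcf"
    map_path = out / "panel_breeds.tsv"
    mio.write_vcf(core.panel, panel_path)
    with open(map_path, "w") as fh:
        for name in core.panel.samples:
            fh.write(f"{name}\t{core.breed_of[name]}\n")
    return panel_path, map_path


def make_gene_fixture(
    config: SimConfig,
    out_dir: str | os.PathLike,
    strand: str = "-",
    causal_placement: str = "cds",
) -> tuple[Path, Path]:
    """Write the synthetic gene model (GFF3) and reference (FASTA).

    The default minus-strand gene is built so the planted genomic
    substitution projects to spliced CDS offset 2624 inside reference
    codon TCA at codon 875; ``causal_placement="intron"`` shifts the gene
    so the same genomic position falls between two exons.
    """
    layout = _gene_layout(config, strand, causal_placement)
    reference = _reference_sequences(config, strand, causal_placement)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gff_path = out / "genes.gff3"
    fasta_path = out / "reference.fa"

    chrom = layout["chrom"]
    exons = sorted(layout["exons"])
    cds_parts = sorted(layout["cds_parts"])
    gene_lo, gene_hi = exons[0][0], exons[-1][1]
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        base = f"{chrom}\tmendelmap_sim"
        attrs_gene = "ID=geneA;Name=geneA"
        fh.write(
            f"{base}\tgene\t{gene_lo}\t{gene_hi}\t.\t{strand}\t.\t{attrs_gene}\n"
        )
        fh.write(
            f"{base}\tmRNA\t{gene_lo}\t{gene_hi}\t.\t{strand}\t.\t"
            "ID=geneA.t1;Parent=geneA\n"
        )
        for k, (s, e) in enumerate(exons, 1):
            fh.write(
                f"{base}\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID=geneA.t1.exon{k};Parent=geneA.t1\n"
            )
        tx_order = cds_parts if strand == "+" else cds_parts[::-1]
        phase, cum = 0, 0
        phased = {}
        for s, e in tx_order:
            phased[(s, e)] = phase
            cum += e - s + 1
            phase = (3 - cum % 3) % 3
        for k, (s, e) in enumerate(cds_parts, 1):
            fh.write(
                f"{base}\tCDS\t{s}\t{e}\t.\t{strand}\t{phased[(s, e)]}\t"
                f"ID=geneA.t1.cds{k};Parent=geneA.t1\n"
            )

    with open(fasta_path, "w") as fh:
        for name, _length in config.chromosomes:
            fh.write(f">{name}\n")
            seq = "".join(reference[name])
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    return gff_path, fasta_path


def _write_truth(truth: TruthRecord, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#section\tfields...\n")
        fh.write(
            f"causal\t{truth.causal_chrom}\t{truth.causal_pos}\t"
            f"{truth.causal_ref}\t{truth.causal_alt}\n"
        )
        for name, code in truth.genotypes.items():
            fh.write(f"genotype\t{name}\t{code}\n")
        for name, iv in truth.tracts.items():
            fh.write(f"tract\t{name}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
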