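"""Readers and writers for the standard formats the pipeline touches.

VCF parsing is delegated to :mod:`cyvcf2`, FASTA access to :mod:`pyfaidx`
and GFF3 parsing to :mod:`gffutils`; the emitters (VCF, BED, TSV report)
write plain text deterministically so repeated runs on identical inputs are
byte-identical.  Multiallelic VCF records are decomposed into one internal
site per alternate allele, with the remaining alternates recoded as
reference; phased separators are accepted and treated as unphased.
"""

from __future__ import annotations

import logging
import os
import warnings
from pathlib import Path

import gffutils
import numpy as np
from Bio.Seq import Seq
from pyfaidx import Fasta

from .errors import FormatError
from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CohortGenotypes,
    GeneModel,
    GenomicInterval,
    Pedigree,
    PedigreeSample,
    PrioritizationReport,
)

log = logging.getLogger(__name__)

_PHENOTYPE_CODES = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> CohortGenotypes:
    """Read a multi-sample VCF into a :class:`CohortGenotypes`.

    One internal site is produced per (record, alternate allele) pair; for a
    decomposed alternate, sample dosage counts copies of that allele and any
    other alternate is treated as reference.  A genotype with any missing
    allele becomes the missing code.
    """
    import cyvcf2

    path = os.fspath(path)
    if os.path.getsize(path) == 0:
        raise FormatError(f"{path}: empty VCF file")
    try:
        vcf = cyvcf2.VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"{path}: malformed VCF header ({exc})") from exc
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")

    chrom, pos, ref, alt, qual, rows = [], [], [], [], [], []
    for rec_no, rec in enumerate(vcf, start=1):
        if "GT" not in (rec.FORMAT or ""):
            raise FormatError(
                f"{path}: record {rec_no} ({rec.CHROM}:{rec.POS}) has no GT field"
            )
        alleles = rec.genotypes  # [[a1, a2, phased], ...]
        for alt_index, alt_allele in enumerate(rec.ALT, start=1):
            codes = np.empty(len(samples), dtype=np.int8)
            for j, call in enumerate(alleles):
                a = call[:-1]
                if len(a) != 2 or min(a) < 0:
                    codes[j] = MISSING
                else:
                    codes[j] = (a[0] == alt_index) + (a[1] == alt_index)
            _validate_alleles(path, rec_no, rec.CHROM, rec.POS, rec.REF, alt_allele)
            chrom.append(rec.CHROM)
            pos.append(rec.POS)
            ref.append(rec.REF)
            alt.append(alt_allele)
            # htslib stores QUAL as float32; recover the shortest decimal
            qual.append(
                np.nan
                if rec.QUAL is None
                else float(np.format_float_positional(np.float32(rec.QUAL), unique=True))
            )
            rows.append(codes)
    vcf.close()
    if not rows:
        raise FormatError(f"{path}: VCF contains no variant records")
    return CohortGenotypes(samples, chrom, pos, ref, alt, qual, np.vstack(rows))


def _validate_alleles(path, rec_no, chrom, pos, ref, alt) -> None:
    for allele in (ref, alt):
        if not allele or any(base not in "ACGT" for base in allele):
            raise FormatError(
                f"{path}: record {rec_no} ({chrom}:{pos}) has non-ACGT "
                f"allele {allele!r}"
            )
    if ref == alt:
        raise FormatError(f"{path}: record {rec_no} ({chrom}:{pos}) has ref == alt")


_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def format_qual(q: float) -> str:
    if np.isnan(q):
        return "."
    if float(q) == int(q):
        return str(int(q))
    return repr(float(q))


def write_vcf(cohort: CohortGenotypes, path: str | os.PathLike) -> None:
    """Write the cohort as a minimal VCF 4.2, sorted by (chrom, pos)."""
    order = cohort.sort_key()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mendelmap\n")
        for name in sorted(set(map(str, cohort.chrom))):
            fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        for i in order:
            calls = "\t".join(_GT_STRINGS[int(g)] for g in cohort.gt[i])
            fh.write(
                f"{cohort.chrom[i]}\t{cohort.pos[i]}\t.\t{cohort.ref[i]}\t"
                f"{cohort.alt[i]}\t{format_qual(float(cohort.qual[i]))}\t.\t.\tGT\t"
                f"{calls}\n"
            )


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read a whitespace-delimited 6-column PED file.

    Columns: family, id, sire, dam, sex, phenotype (1 unaffected,
    2 affected, 0/-9 unknown).  A parent id that is not itself a listed
    sample is recorded as external rather than rejected.
    """
    samples: list[PedigreeSample] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(
                    f"{path}: line {line_no} has {len(fields)} fields, expected 6"
                )
            family, sid, sire, dam, sex, pheno = fields[:6]
            if pheno not in _PHENOTYPE_CODES:
                raise FormatError(
                    f"{path}: line {line_no}: phenotype code {pheno!r} not in "
                    "{0, 1, 2, -9}"
                )
            if sex not in {"0", "1", "2"}:
                raise FormatError(
                    f"{path}: line {line_no}: sex code {sex!r} not in {{0, 1, 2}}"
                )
            samples.append(
                PedigreeSample(
                    sample_id=sid,
                    family=family,
                    sire=None if sire == "0" else sire,
                    dam=None if dam == "0" else dam,
                    sex=int(sex),
                    status=_PHENOTYPE_CODES[pheno],
                )
            )
    if not samples:
        raise FormatError(f"{path}: pedigree file contains no samples")
    return Pedigree(samples)


def write_pedigree(ped: Pedigree, path: str | os.PathLike) -> None:
    status_codes = {"unaffected": "1", "affected": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for s in ped.samples:
            fh.write(
                f"{s.family}\t{s.sample_id}\t{s.sire or 0}\t{s.dam or 0}\t"
                f"{s.sex}\t{status_codes[s.status]}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 + FASTA
# ---------------------------------------------------------------------------

def read_annotation(
    gff_path: str | os.PathLike, fasta_path: str | os.PathLike
) -> list[GeneModel]:
    """Read gene models from GFF3 and attach spliced CDS sequences.

    One transcript per gene is kept (the first mRNA in file order).  The
    spliced CDS is reconstructed from the FASTA, reverse-complemented for
    minus-strand models, and checked for a length divisible by three; a
    failing model is flagged unusable with a warning rather than dropped.
    """
    db = gffutils.create_db(
        os.fspath(gff_path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    fasta = Fasta(os.fspath(fasta_path), rebuild=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            continue
        mrna = mrnas[0]  # one transcript per gene: first model in the GFF3
        exons = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype="CDS", order_by="start")
        ]
        if not exons or not cds:
            continue
        if gene.seqid not in fasta:
            raise FormatError(
                f"{gff_path}: chromosome {gene.seqid!r} absent from {fasta_path}"
            )
        model = GeneModel(
            gene_id=gene.id,
            transcript_id=mrna.id,
            chrom=gene.seqid,
            strand=gene.strand,
            exons=exons,
            cds_parts=cds,
        )
        pieces = [str(fasta[gene.seqid][s - 1 : e]).upper() for s, e in model.cds_parts]
        seq = "".join(pieces)
        if model.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        model.cds_seq = seq
        if len(seq) % 3 != 0:
            warnings.warn(
                f"transcript {model.transcript_id}: CDS length {len(seq)} not "
                "divisible by 3; model flagged unusable",
                stacklevel=2,
            )
            model.usable = False
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# BED / report
# ---------------------------------------------------------------------------

def write_bed(
    intervals: list[tuple[GenomicInterval, str]], path: str | os.PathLike
) -> None:
    """Write named intervals as 4-column BED (0-based half-open)."""
    rows = sorted(intervals, key=lambda it: (it[0].chrom, it[0].start, it[0].end))
    with open(path, "w") as fh:
        for iv, name in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


REPORT_COLUMNS = (
    "CHROM",
    "POS",
    "REF",
    "ALT",
    "EFFECT",
    "SO_TERM",
    "P_ALLELIC",
    "BREEDS",
)


def report_rows(report: PrioritizationReport) -> list[tuple[str, ...]]:
    """Render candidates into Table-1-shaped string tuples."""
    rows = []
    for cand in report.candidates:
        cons = cand.consequence
        if cons.hgvs_c:
            detail = f"{cons.gene} {cons.hgvs_c},{cons.hgvs_p}"
            effect = f"{cons.impact} ({detail})"
        else:
            effect = cons.impact
        if cand.screen is None:
            breeds = "NA"
        elif cand.screen.breeds:
            breeds = ",".join(cand.screen.breeds)
        else:
            breeds = "None"
        rows.append(
            (
                cand.chrom,
                str(cand.pos),
                cand.ref,
                cand.alt,
                effect,
                cons.so_term,
                f"{cand.assoc.p_allelic:.3f}",
                breeds,
            )
        )
    return rows


def write_outputs(
    report: PrioritizationReport,
    consensus_regions: list[GenomicInterval],
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Write the Table-1-shaped TSV and the ROH consensus BED.

    Output is deterministic: candidate rows arrive pre-sorted by
    (impact rank, p, chrom, pos) and BED lines are sorted by coordinate.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "report_tsv": out / "report.tsv",
            "roh_bed": out / "roh_consensus.bed",
        }
        with open(paths["report_tsv"], "w") as fh:
            fh.write("\t".join(REPORT_COLUMNS) + "\n")
            for row in report_rows(report):
                fh.write("\t".join(row) + "\n")
        write_bed(
            [(iv, f"shared_roh_{k}") for k, iv in enumerate(consensus_regions, 1)],
            paths["roh_bed"],
        )
    except OSError as exc:
        raise OSError(f"cannot write outputs under {out}: {exc}") from exc
    return paths
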