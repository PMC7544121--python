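"""Projection of genomic SNVs onto transcript models: HGVS c./p. notation
and SnpEff-style impact tiers.

CDS offsets are counted 5'→3' along the coding strand, so a minus-strand
model counts from its genomically rightmost coding base and the genomic
alleles are complemented before substitution.  Only single-nucleotide
substitutions under the standard genetic code are handled; splice-region
positions fall back to the intron MODIFIER class with a logged caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .errors import StageError
from .model import Consequence, GeneModel

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: effect -> (impact tier, Sequence Ontology term)
EFFECT_TABLE = {
    "stop_gained": ("HIGH", "stop_gained"),
    "stop_lost": ("HIGH", "stop_lost"),
    "start_lost": ("HIGH", "start_lost"),
    "missense": ("MODERATE", "missense_variant"),
    "synonymous": ("LOW", "synonymous_variant"),
}

IMPACT_RANK = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}


@dataclass(frozen=True)
class CdsPosition:
    """1-based offset within a spliced CDS, with codon arithmetic."""

    transcript_id: str
    cds_offset: int

    @property
    def codon_index(self) -> int:
        return (self.cds_offset + 2) // 3

    @property
    def codon_offset(self) -> int:
        return (self.cds_offset - 1) % 3 + 1


@dataclass(frozen=True)
class CodonChange:
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    codon_index: int


def map_genomic_to_cds(pos: int, model: GeneModel) -> CdsPosition | str:
    """Project a genomic position onto the spliced CDS.

    Returns a :class:`CdsPosition` for coding positions, otherwise one of
    the region tags ``"intergenic"``, ``"intron"``, ``"UTR"``.
    """
    if pos < 1:
        raise StageError(f"genomic position must be >= 1, got {pos}")
    span = model.span
    if not span.contains_pos1(model.chrom, pos):
        return "intergenic"
    if not any(s <= pos <= e for s, e in model.exons):
        return "intron"
    part = next(((s, e) for s, e in model.cds_parts if s <= pos <= e), None)
    if part is None:
        return "UTR"
    if model.strand == "+":
        before = sum(e - s + 1 for s, e in model.cds_parts if e < part[0])
        offset = before + (pos - part[0] + 1)
    else:
        before = sum(e - s + 1 for s, e in model.cds_parts if s > part[1])
        offset = before + (part[1] - pos + 1)
    return CdsPosition(transcript_id=model.transcript_id, cds_offset=offset)


def cds_to_genomic(cds: CdsPosition, model: GeneModel) -> int:
    """Inverse projection (bijection on the CDS)."""
    remaining = cds.cds_offset
    parts = model.cds_parts if model.strand == "+" else model.cds_parts[::-1]
    for s, e in parts:
        length = e - s + 1
        if remaining <= length:
            return s + remaining - 1 if model.strand == "+" else e - remaining + 1
        remaining -= length
    raise StageError(
        f"CDS offset {cds.cds_offset} beyond CDS length {model.cds_length} "
        f"of {model.transcript_id}"
    )


def apply_snv(
    cds: CdsPosition, genomic_ref: str, genomic_alt: str, model: GeneModel
) -> CodonChange:
    """Substitute one base in the coding sequence and translate the codon.

    Genomic alleles are complemented for minus-strand models; a mismatch
    between the genomic reference allele and the transcript sequence
    signals inconsistent inputs and raises.
    """
    if model.cds_seq is None:
        raise StageError(f"model {model.transcript_id} has no attached CDS sequence")
    if len(genomic_ref) != 1 or len(genomic_alt) != 1:
        raise StageError("apply_snv handles single-nucleotide substitutions only")
    if model.strand == "-":
        coding_ref = genomic_ref.translate(_COMPLEMENT)
        coding_alt = genomic_alt.translate(_COMPLEMENT)
    else:
        coding_ref, coding_alt = genomic_ref, genomic_alt
    idx = cds.cds_offset - 1
    if not 0 <= idx < len(model.cds_seq):
        raise StageError(
            f"CDS offset {cds.cds_offset} outside CDS of {model.transcript_id}"
        )
    if model.cds_seq[idx] != coding_ref:
        raise StageError(
            f"reference mismatch at c.{cds.cds_offset} of {model.transcript_id}: "
            f"transcript has {model.cds_seq[idx]}, VCF implies {coding_ref}"
        )
    codon_start = (cds.codon_index - 1) * 3
    ref_codon = model.cds_seq[codon_start : codon_start + 3]
    within = cds.codon_offset - 1
    alt_codon = ref_codon[:within] + coding_alt + ref_codon[within + 1 :]
    return CodonChange(
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=str(Seq(ref_codon).translate()),
        alt_aa=str(Seq(alt_codon).translate()),
        codon_index=cds.codon_index,
    )


def _aa3(aa: str) -> str:
    return "*" if aa == "*" else seq3(aa)


def _coding_effect(change: CodonChange) -> str:
    if change.ref_aa == change.alt_aa:
        return "synonymous"
    if change.alt_aa == "*":
        return "stop_gained"
    if change.ref_aa == "*":
        return "stop_lost"
    if change.codon_index == 1 and change.ref_aa == "M":
        return "start_lost"
    return "missense"


def _utr_side(pos: int, model: GeneModel) -> str:
    """5' vs 3' UTR from position relative to the CDS span and strand."""
    upstream = pos < model.cds_start
    five_prime = upstream if model.strand == "+" else not upstream
    return "5_prime_UTR_variant" if five_prime else "3_prime_UTR_variant"


def classify_consequence(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    model: GeneModel | None,
    mapped: CdsPosition | str | None = None,
    change: CodonChange | None = None,
) -> Consequence:
    """Assemble the final consequence record for one SNV.

    With ``model=None`` the variant is intergenic.  For coding positions a
    :class:`CodonChange` must be supplied; the effect→impact mapping is
    stop_gained/stop_lost/start_lost → HIGH, missense → MODERATE,
    synonymous → LOW and every non-coding region → MODIFIER.
    """
    if model is None or mapped == "intergenic":
        return Consequence(
            chrom, pos, ref, alt,
            gene=None, transcript=None, region="intergenic",
            effect="noncoding", impact="MODIFIER", so_term="intergenic_variant",
        )
    if isinstance(mapped, str):
        so = "intron_variant" if mapped == "intron" else _utr_side(pos, model)
        return Consequence(
            chrom, pos, ref, alt,
            gene=model.gene_id, transcript=model.transcript_id, region=mapped,
            effect="noncoding", impact="MODIFIER", so_term=so,
        )
    if change is None:
        raise StageError("coding position requires an applied codon change")
    effect = _coding_effect(change)
    impact, so_term = EFFECT_TABLE[effect]
    if model.strand == "-":
        coding_ref = ref.translate(_COMPLEMENT)
        coding_alt = alt.translate(_COMPLEMENT)
    else:
        coding_ref, coding_alt = ref, alt
    hgvs_c = f"c.{mapped.cds_offset}{coding_ref}>{coding_alt}"
    hgvs_p = f"p.{_aa3(change.ref_aa)}{change.codon_index}{_aa3(change.alt_aa)}"
    return Consequence(
        chrom, pos, ref, alt,
        gene=model.gene_id, transcript=model.transcript_id, region="CDS",
        effect=effect, impact=impact, so_term=so_term,
        hgvs_c=hgvs_c, hgvs_p=hgvs_p,
    )


def annotate_site(
    chrom: str, pos: int, ref: str, alt: str, models: list[GeneModel]
) -> Consequence:
    """Annotate one SNV against the first usable gene model spanning it."""
    model = next(
        (
            m
            for m in models
            if m.usable and m.chrom == chrom and m.span.contains_pos1(chrom, pos)
        ),
        None,
    )
    if model is None:
        return classify_consequence(chrom, pos, ref, alt, model=None)
    mapped = map_genomic_to_cds(pos, model)
    if isinstance(mapped, str):
        return classify_consequence(chrom, pos, ref, alt, model, mapped)
    change = apply_snv(mapped, ref, alt, model)
    return classify_consequence(chrom, pos, ref, alt, model, mapped, change)
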