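"""End-to-end orchestration of the prioritization cascade.

Two branches start from the quality-filtered callset, mirroring how such
mapping studies are run: a homozygosity branch (LD pruning → per-sample
ROH → cross-sample pooling → affected-only shared-allele regions) and an
association branch (recessive genotype-pattern filter → exact allelic test
→ intersection with the shared ROH regions → consequence annotation →
breed-panel screen).  All stages are pure functions of their inputs;
randomness lives exclusively in the simulator, so identical configuration
and inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import io as mio
from .associate import (
    AR_MODEL,
    MoiModel,
    allelic_test_cohort,
    filter_moi,
    filter_quality,
    restrict_to_regions,
    screen_breed_panel,
)
from .consequence import IMPACT_RANK, annotate_site
from .errors import FormatError, StageError
from .model import (
    CandidateRow,
    CohortGenotypes,
    GenomicInterval,
    Pedigree,
    PrioritizationReport,
    ScreenResult,
)
from .popgen import (
    PruneParams,
    ROHParams,
    affected_shared_regions,
    call_roh_cohort,
    ld_prune,
    pool_roh,
)
from .simulate import SimConfig, make_gene_fixture, simulate_cohort, simulate_panel

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and parameters for one run.

    Either the four+ input paths are given, or ``sim`` is set and the
    pipeline generates its own inputs under ``out_dir``.
    """

    vcf: str | os.PathLike | None = None
    ped: str | os.PathLike | None = None
    gff: str | os.PathLike | None = None
    fasta: str | os.PathLike | None = None
    panel_vcf: str | os.PathLike | None = None
    breed_map: str | os.PathLike | None = None
    sim: SimConfig | None = None
    prune: PruneParams = field(default_factory=PruneParams)
    roh: ROHParams = field(default_factory=ROHParams)
    min_qual: float = 30.0
    moi: MoiModel = AR_MODEL
    p_threshold: float = 0.02
    impact_floor: str = "MODERATE"
    include_carriers_as_controls: bool = True
    out_dir: str | os.PathLike | None = None

    def __post_init__(self) -> None:
        if self.sim is None and (self.vcf is None or self.ped is None):
            raise StageError("PipelineConfig needs input paths or a SimConfig")
        if not 0.0 < self.p_threshold <= 1.0:
            raise StageError("p_threshold must lie in (0, 1]")
        if self.impact_floor not in IMPACT_RANK:
            raise StageError(f"unknown impact floor {self.impact_floor!r}")


@dataclass
class CandidateGeneCheck:
    """Known candidate gene vs the shared ROH regions."""

    gene: str
    interval: GenomicInterval
    flank: int = 1000
    overlaps_roh: bool = False


def _stage(funnel, name, count):
    funnel.append((name, int(count)))
    log.info("stage %-28s %d sites", name, count)


def run_pipeline(config: PipelineConfig) -> PrioritizationReport:
    """Execute the full cascade; returns the Table-1-shaped report.

    Stage errors propagate with the stage name attached; an empty
    candidate list is a valid result.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if config.sim is not None:
        workdir = out_dir if out_dir is not None else Path(".")
        vcf, ped_path, _truth = simulate_cohort(config.sim, workdir)
        gff, fasta = make_gene_fixture(config.sim, workdir)
        panel_vcf, breed_map = simulate_panel(config.sim, workdir)
    else:
        vcf, ped_path = config.vcf, config.ped
        gff, fasta = config.gff, config.fasta
        panel_vcf, breed_map = config.panel_vcf, config.breed_map

    funnel: list[tuple[str, int]] = []
    meta: dict = {
        "version": __version__,
        "parameters": {
            "min_qual": config.min_qual,
            "p_threshold": config.p_threshold,
            "impact_floor": config.impact_floor,
            "moi": config.moi.name,
            "prune": vars(config.prune),
            "roh": vars(config.roh),
            "controls_include_carriers": config.include_carriers_as_controls,
        },
        "notes": [
            "structural variants are not assessed",
            "no multiple-testing correction applied; "
            "the allelic test count is recorded in the funnel",
        ],
    }
    if config.sim is not None:
        meta["parameters"]["seed"] = config.sim.seed

    def run_stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (StageError, FormatError) as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    cohort: CohortGenotypes = run_stage("read_vcf", mio.read_vcf, vcf)
    pedigree: Pedigree = run_stage("read_pedigree", mio.read_pedigree, ped_path)
    _stage(funnel, "sites_total", cohort.n_sites)

    qc = run_stage("filter_quality", filter_quality, cohort, config.min_qual)
    _stage(funnel, f"qual_ge_{config.min_qual:g}", qc.n_sites)

    # homozygosity branch
    retained = run_stage("ld_prune", ld_prune, qc, config.prune)
    pruned = qc.subset(retained)
    segments = run_stage("call_roh", call_roh_cohort, pruned, config.roh)
    groups = run_stage("pool_roh", pool_roh, segments)
    regions = run_stage(
        "affected_shared_regions", affected_shared_regions, groups, pedigree
    )
    meta["roh"] = {
        "pruned_sites": int(pruned.n_sites),
        "segments": len(segments),
        "groups": len(groups),
        "affected_shared_regions": [
            f"{iv.chrom}:{iv.start + 1}-{iv.end}" for iv in regions
        ],
    }
    log.info(
        "ROH branch: %d pruned sites, %d segments, %d groups, %d shared regions",
        pruned.n_sites, len(segments), len(groups), len(regions),
    )

    # association branch
    moi = run_stage("filter_moi", filter_moi, qc, pedigree, config.moi)
    _stage(funnel, "moi_recessive", moi.n_sites)

    assoc = run_stage(
        "allelic_test", allelic_test_cohort, moi, pedigree,
        config.include_carriers_as_controls,
    )
    keep = [i for i, a in enumerate(assoc) if a.p_allelic < config.p_threshold]
    sig = moi.subset(keep)
    assoc = [assoc[i] for i in keep]
    _stage(funnel, f"allelic_p_lt_{config.p_threshold:g}", sig.n_sites)

    in_roh = run_stage("restrict_to_regions", restrict_to_regions, sig, regions)
    kept_keys = {
        (str(in_roh.chrom[i]), int(in_roh.pos[i])) for i in range(in_roh.n_sites)
    }
    assoc = [a for a in assoc if (a.chrom, a.pos) in kept_keys]
    _stage(funnel, "in_shared_roh_region", in_roh.n_sites)

    models = (
        run_stage("read_annotation", mio.read_annotation, gff, fasta)
        if gff is not None and fasta is not None
        else []
    )
    floor = IMPACT_RANK[config.impact_floor]
    candidates: list[CandidateRow] = []
    screened: list[ScreenResult | None]
    if panel_vcf is not None and breed_map is not None:
        panel = run_stage("read_panel", mio.read_vcf, panel_vcf)
        breed_of = _read_breed_map(breed_map)
        screened = run_stage("screen_breed_panel", screen_breed_panel, in_roh, panel, breed_of)
    else:
        screened = [None] * in_roh.n_sites
    for i in range(in_roh.n_sites):
        cons = run_stage(
            "annotate", annotate_site,
            str(in_roh.chrom[i]), int(in_roh.pos[i]),
            str(in_roh.ref[i]), str(in_roh.alt[i]), models,
        )
        if IMPACT_RANK[cons.impact] > floor:
            continue
        candidates.append(
            CandidateRow(
                chrom=cons.chrom, pos=cons.pos, ref=cons.ref, alt=cons.alt,
                consequence=cons, assoc=assoc[i], screen=screened[i],
            )
        )
    _stage(funnel, f"impact_ge_{config.impact_floor}", len(candidates))

    candidates.sort(
        key=lambda c: (
            IMPACT_RANK[c.consequence.impact],
            c.assoc.p_allelic,
            c.chrom,
            c.pos,
        )
    )
    report = PrioritizationReport(candidates=candidates, funnel=funnel, metadata=meta)
    if out_dir is not None:
        paths = mio.write_outputs(report, regions, out_dir)
        (out_dir / "report.md").write_text(render_report(report, "markdown"))
        (out_dir / "report.json").write_text(report_to_json(report))
        log.info("wrote %s", ", ".join(str(p) for p in paths.values()))
    return report


def _read_breed_map(path) -> dict[str, str]:
    breed_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}: breed map lines need 'sample<TAB>breed'")
            breed_of[fields[0]] = fields[1]
    return breed_of


def check_candidate_genes(
    genes: list[CandidateGeneCheck], regions: list[GenomicInterval]
) -> list[CandidateGeneCheck]:
    """Flag each gene (± flank) that intersects any shared ROH region."""
    out = []
    for g in genes:
        if g.flank < 0:
            raise StageError(f"negative flank for {g.gene}")
        flanked = GenomicInterval(
            g.interval.chrom,
            max(0, g.interval.start - g.flank),
            g.interval.end + g.flank,
        )
        hit = any(flanked.overlaps(r) for r in regions)
        out.append(CandidateGeneCheck(g.gene, g.interval, g.flank, overlaps_roh=hit))
    return out


# ---------------------------------------------------------------------------
# rendering / serialization
# ---------------------------------------------------------------------------

def render_report(report: PrioritizationReport, fmt: str = "tsv") -> str:
    """Render candidates plus the stage-count funnel as tsv or markdown."""
    rows = mio.report_rows(report)
    if fmt == "tsv":
        lines = ["\t".join(mio.REPORT_COLUMNS)]
        lines += ["\t".join(r) for r in rows]
        lines.append("")
        lines.append("#FUNNEL\tstage\tsites")
        lines += [f"#FUNNEL\t{name}\t{count}" for name, count in report.funnel]
        return "\n".join(lines) + "\n"
    if fmt == "markdown":
        lines = ["# Variant prioritization report", "", "## Candidates", ""]
        lines.append("| " + " | ".join(mio.REPORT_COLUMNS) + " |")
        lines.append("|" + "---|" * len(mio.REPORT_COLUMNS))
        lines += ["| " + " | ".join(r) + " |" for r in rows]
        lines += ["", "## Stage funnel", "", "| stage | sites |", "|---|---|"]
        lines += [f"| {name} | {count} |" for name, count in report.funnel]
        lines += ["", "## Notes", ""]
        lines += [f"- {n}" for n in report.metadata.get("notes", [])]
        return "\n".join(lines) + "\n"
    raise StageError(f"unknown report format {fmt!r} (use 'tsv' or 'markdown')")


def report_from_json(text: str) -> PrioritizationReport:
    """Rebuild a report from the JSON emitted by :func:`report_to_json`
    (enough structure to re-render; run metadata is carried verbatim)."""
    from .consequence import EFFECT_TABLE
    from .model import AssocResult, CandidateRow, Consequence, ScreenResult

    payload = json.loads(text)
    candidates = []
    for c in payload.get("candidates", []):
        so = c.get("so_term") or EFFECT_TABLE.get(c["effect"], ("MODIFIER", "."))[1]
        cons = Consequence(
            chrom=c["chrom"], pos=c["pos"], ref=c["ref"], alt=c["alt"],
            gene=c.get("gene"), transcript=None,
            region="CDS" if c.get("hgvs_p") else "intergenic",
            effect=c["effect"], impact=c["impact"], so_term=so,
            hgvs_c=c.get("hgvs_c"), hgvs_p=c.get("hgvs_p"),
        )
        assoc = AssocResult(
            chrom=c["chrom"], pos=c["pos"], ref=c["ref"], alt=c["alt"],
            table=tuple(tuple(row) for row in c["table"]),
            p_allelic=c["p_allelic"],
        )
        screen = None
        if c.get("breeds") is not None:
            screen = ScreenResult(
                c["chrom"], c["pos"], c["ref"], c["alt"],
                breeds=tuple(c["breeds"]), in_panel=bool(c.get("in_panel")),
            )
        candidates.append(
            CandidateRow(
                chrom=c["chrom"], pos=c["pos"], ref=c["ref"], alt=c["alt"],
                consequence=cons, assoc=assoc, screen=screen,
            )
        )
    funnel = [(name, int(count)) for name, count in payload.get("funnel", [])]
    return PrioritizationReport(
        candidates=candidates, funnel=funnel, metadata=payload.get("metadata", {})
    )


def report_to_json(report: PrioritizationReport) -> str:
    payload = {
        "metadata": report.metadata,
        "funnel": [[name, count] for name, count in report.funnel],
        "candidates": [
            {
                "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                "impact": c.consequence.impact,
                "effect": c.consequence.effect,
                "so_term": c.consequence.so_term,
                "gene": c.consequence.gene,
                "hgvs_c": c.consequence.hgvs_c,
                "hgvs_p": c.consequence.hgvs_p,
                "table": c.assoc.table,
                "p_allelic": c.assoc.p_allelic,
                "breeds": list(c.screen.breeds) if c.screen else None,
                "in_panel": c.screen.in_panel if c.screen else None,
            }
            for c in report.candidates
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
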