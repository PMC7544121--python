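"""LD pruning and runs-of-homozygosity (ROH) detection.

The ROH caller uses physical-span sliding windows anchored at each marker:
a marker supports autozygosity only if *every* window covering it contains
at most ``max_het`` heterozygous calls, and maximal runs of supporting
markers of at least ``min_markers`` become segments.  Pooling groups
segments across samples by transitive overlap; the consensus of a group is
the intersection of its member intervals, so every member covers the whole
consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import StageError, UndefinedLDError
from .model import CohortGenotypes, GenomicInterval, Pedigree

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PruneParams:
    """PLINK-style ``--indep-pairwise`` parameters (variant-count windows)."""

    window: int = 50
    step: int = 50
    r2_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.window < 2:
            raise StageError("prune window must be >= 2 variants")
        if not 1 <= self.step <= self.window:
            raise StageError("prune step must satisfy 1 <= step <= window")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise StageError("r2 threshold must lie in [0, 1]")


@dataclass(frozen=True)
class ROHParams:
    window_bp: int = 50_000
    max_het: int = 3
    min_markers: int = 25

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise StageError("ROH window span must be positive")
        if self.max_het < 0:
            raise StageError("max het per window must be >= 0")
        if self.min_markers < 1:
            raise StageError("min markers per segment must be >= 1")


@dataclass
class ROHSegment:
    """One per-sample homozygous tract.

    ``positions``/``codes`` carry the (non-missing) marker coordinates and
    dosage codes over the segment — the homozygous-allele signature used
    when pooling across samples.
    """

    sample_id: str
    interval: GenomicInterval
    positions: np.ndarray
    codes: np.ndarray

    @property
    def marker_count(self) -> int:
        return len(self.positions)

    @property
    def het_count(self) -> int:
        return int(np.sum(self.codes == 1))

    def signature_in(self, region: GenomicInterval) -> dict[int, int]:
        """pos -> dosage code for markers inside ``region``."""
        mask = (self.positions - 1 >= region.start) & (self.positions - 1 < region.end)
        return {
            int(p): int(c)
            for p, c in zip(self.positions[mask], self.codes[mask])
        }


@dataclass
class ROHGroup:
    """Segments pooled by transitive overlap, with their consensus region."""

    members: list[ROHSegment]
    consensus: GenomicInterval | None = None
    shared_allele: bool = field(default=False)

    @property
    def samples(self) -> list[str]:
        seen: list[str] = []
        for seg in self.members:
            if seg.sample_id not in seen:
                seen.append(seg.sample_id)
        return seen


# ---------------------------------------------------------------------------
# genotype r^2 and LD pruning
# ---------------------------------------------------------------------------

def genotype_r2(a, b) -> float:
    """Squared Pearson correlation of dosage codings with pairwise
    exclusion of missing calls."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StageError("genotype vectors differ in length")
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    if len(a) < 2 or a.std() == 0.0 or b.std() == 0.0:
        raise UndefinedLDError(
            "r2 undefined: vector monomorphic after missing-call exclusion"
        )
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def _window_r2(gt: np.ndarray) -> np.ndarray:
    """Pairwise r^2 matrix for a window (sites x samples) with exact
    pairwise deletion of missing calls; NaN where LD is undefined.

    All per-pair sums over pairwise-complete samples reduce to matrix
    products of the zero-filled dosage matrix and the validity mask.
    """
    valid = (gt >= 0).astype(np.float64)
    x = np.where(gt >= 0, gt, 0).astype(np.float64)
    x2 = x * x
    n = valid @ valid.T
    sx = x @ valid.T          # sum of site-i dosages over pair-complete calls
    sxx = x2 @ valid.T
    sxy = x @ x.T
    cov = n * sxy - sx * sx.T
    var_i = n * sxx - sx * sx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (cov * cov) / (var_i * var_i.T)
        r2[(n < 2) | (var_i <= 0) | (var_i.T <= 0)] = np.nan
    return np.minimum(r2, 1.0)


def ld_prune(cohort: CohortGenotypes, params: PruneParams | None = None) -> np.ndarray:
    """Greedy within-window LD pruning; returns retained site indices.

    Of an offending pair (r^2 strictly above threshold) the removed member
    is the one with higher missingness, then lower MAF (keeping the more
    informative site), then the later genomic position.  One sweep of
    variant-count windows advances by ``step`` over each chromosome's site
    list, and each window is reduced until no offending pair remains, so
    the retained set is stable — and re-pruning is a no-op — within every
    window the sweep visited.
    """
    params = params or PruneParams()
    if not cohort.is_sorted():
        raise StageError("ld_prune requires sites sorted by (chrom, pos)")
    missing = cohort.missingness()
    maf = cohort.minor_allele_frequency()
    retained_all: list[np.ndarray] = []
    for chrom in sorted(set(map(str, cohort.chrom))):
        idx = list(np.flatnonzero(cohort.chrom == chrom))
        dropped: set[int] = set()
        for start in range(0, len(idx), params.step):
            win = [i for i in idx[start : start + params.window] if i not in dropped]
            dropped |= _prune_window(cohort, win, params, missing, maf)
        retained_all.append(
            np.array([i for i in idx if i not in dropped], dtype=np.int64)
        )
    return np.sort(np.concatenate(retained_all))


def _prune_window(cohort, win, params, missing, maf) -> set[int]:
    removed: set[int] = set()
    win = list(win)
    r2 = _window_r2(cohort.gt[win])
    alive = list(range(len(win)))
    while True:
        offender = None
        for ai, i in enumerate(alive):
            for j in alive[ai + 1 :]:
                v = r2[i, j]
                if np.isfinite(v) and v > params.r2_threshold:
                    offender = (i, j)
                    break
            if offender:
                break
        if offender is None:
            return removed
        i, j = offender
        si, sj = win[i], win[j]
        victim = _pick_victim(si, sj, missing, maf, cohort.pos)
        removed.add(victim)
        alive.remove(i if victim == si else j)


def _pick_victim(si, sj, missing, maf, pos) -> int:
    """Deterministic removal rule: higher missingness, then lower MAF
    (keep the more informative member, as PLINK does), then the later
    position."""
    if missing[si] != missing[sj]:
        return si if missing[si] > missing[sj] else sj
    mi = -1.0 if np.isnan(maf[si]) else maf[si]
    mj = -1.0 if np.isnan(maf[sj]) else maf[sj]
    if mi != mj:
        return si if mi < mj else sj
    return si if pos[si] > pos[sj] else sj


# ---------------------------------------------------------------------------
# ROH calling
# ---------------------------------------------------------------------------

def call_roh_sample(
    chrom: str,
    positions,
    genotypes,
    params: ROHParams | None = None,
    sample_id: str = "sample",
) -> list[ROHSegment]:
    """Call ROH segments for one sample on one chromosome.

    Missing calls are dropped up front (they neither support nor interrupt
    a run).  Windows span ``window_bp`` base pairs, anchored at every
    marker; a marker is ROH-supporting iff no covering window holds more
    than ``max_het`` heterozygous calls.
    """
    params = params or ROHParams()
    positions = np.asarray(positions, dtype=np.int64)
    genotypes = np.asarray(genotypes, dtype=np.int8)
    if len(positions) != len(genotypes):
        raise StageError("positions and genotypes differ in length")
    if np.any(np.diff(positions) < 0):
        raise StageError("call_roh_sample requires positions sorted ascending")
    keep = genotypes >= 0
    positions, genotypes = positions[keep], genotypes[keep]
    m = len(positions)
    if m == 0:
        return []

    het_pos = positions[genotypes == 1]
    # het count of the window [p_j, p_j + window_bp) anchored at marker j
    lo = np.searchsorted(het_pos, positions, side="left")
    hi = np.searchsorted(het_pos, positions + params.window_bp, side="left")
    bad_anchor = (hi - lo) > params.max_het

    # a marker is non-supporting iff covered by any bad window
    cover = np.zeros(m + 1, dtype=np.int64)
    for j in np.flatnonzero(bad_anchor):
        top = np.searchsorted(positions, positions[j] + params.window_bp, side="left")
        cover[j] += 1
        cover[top] -= 1
    supporting = np.cumsum(cover[:-1]) == 0

    segments: list[ROHSegment] = []
    run_start = None
    for i in range(m + 1):
        if i < m and supporting[i]:
            if run_start is None:
                run_start = i
            continue
        if run_start is not None:
            if i - run_start >= params.min_markers:
                seg_pos = positions[run_start:i]
                segments.append(
                    ROHSegment(
                        sample_id=sample_id,
                        interval=GenomicInterval.from_1based(
                            chrom, int(seg_pos[0]), int(seg_pos[-1])
                        ),
                        positions=seg_pos.copy(),
                        codes=genotypes[run_start:i].copy(),
                    )
                )
            run_start = None
    return segments


def call_roh_cohort(
    cohort: CohortGenotypes, params: ROHParams | None = None
) -> list[ROHSegment]:
    """ROH segments for every sample on every chromosome."""
    segments: list[ROHSegment] = []
    for chrom in sorted(set(map(str, cohort.chrom))):
        idx = np.flatnonzero(cohort.chrom == chrom)
        pos = cohort.pos[idx]
        for col, sample in enumerate(cohort.samples):
            segments.extend(
                call_roh_sample(chrom, pos, cohort.gt[idx, col], params, sample)
            )
    return segments


# ---------------------------------------------------------------------------
# pooling and the affected-only shared-allele filter
# ---------------------------------------------------------------------------

def pool_roh(segments: list[ROHSegment]) -> list[ROHGroup]:
    """Partition segments by transitive overlap; consensus = intersection.

    A chain of overlaps can have an empty common intersection; such a group
    keeps ``consensus=None`` and is ignored by downstream region filters.
    """
    groups: list[ROHGroup] = []
    by_chrom: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.interval.chrom, []).append(seg)
    for chrom in sorted(by_chrom):
        segs = sorted(by_chrom[chrom], key=lambda s: (s.interval.start, s.interval.end))
        cluster: list[ROHSegment] = []
        reach = -1
        for seg in segs:
            if cluster and seg.interval.start >= reach:
                groups.append(_finish_group(cluster))
                cluster = []
                reach = -1
            cluster.append(seg)
            reach = max(reach, seg.interval.end)
        if cluster:
            groups.append(_finish_group(cluster))
    return groups


def _finish_group(members: list[ROHSegment]) -> ROHGroup:
    start = max(s.interval.start for s in members)
    end = min(s.interval.end for s in members)
    if start >= end:
        return ROHGroup(members=members, consensus=None, shared_allele=False)
    consensus = GenomicInterval(members[0].interval.chrom, start, end)
    return ROHGroup(
        members=members,
        consensus=consensus,
        shared_allele=_signatures_agree(members, consensus),
    )


def _signatures_agree(members: list[ROHSegment], region: GenomicInterval) -> bool:
    """True iff no two members are homozygous for different alleles at any
    marker inside ``region`` (het / missing calls are uninformative)."""
    seen: dict[int, int] = {}
    for seg in members:
        for p, c in seg.signature_in(region).items():
            if c == 1:
                continue
            if p in seen and seen[p] != c:
                return False
            seen.setdefault(p, c)
    return True


def affected_shared_regions(
    groups: list[ROHGroup], ped: Pedigree
) -> list[GenomicInterval]:
    """Consensus regions homozygous for the same allele in *all* affected
    samples and in no unaffected sample.

    A group is kept when (a) every case contributes a member segment,
    (b) the cases' homozygous-allele signatures agree over their shared
    span, and (c) no non-case member matches that signature there.  The
    reported region is the intersection of the *case* segments: an
    overlapping, differently-haplotyped segment from an unaffected sample
    narrows the pooled group consensus but must not narrow the region the
    affected samples demonstrably share.
    """
    cases = set(ped.cases)
    if not cases:
        raise StageError("affected_shared_regions requires >= 1 affected sample")
    regions: list[GenomicInterval] = []
    for group in groups:
        case_members = [s for s in group.members if s.sample_id in cases]
        if {s.sample_id for s in case_members} != cases:
            continue
        case_iv = _case_span_intersection(case_members)
        if case_iv is None:
            continue
        if not _signatures_agree(case_members, case_iv):
            continue
        signature = _hom_signature(case_members, case_iv)
        if not signature:
            continue
        if any(
            _matches_signature(seg, signature, case_iv)
            for seg in group.members
            if seg.sample_id not in cases
        ):
            continue
        regions.append(case_iv)
    return sorted(regions, key=lambda iv: (iv.chrom, iv.start, iv.end))


def _case_span_intersection(case_members: list[ROHSegment]) -> GenomicInterval | None:
    """Intersection over each case's span of member segments."""
    spans: dict[str, list[int]] = {}
    for seg in case_members:
        span = spans.setdefault(seg.sample_id, [seg.interval.start, seg.interval.end])
        span[0] = min(span[0], seg.interval.start)
        span[1] = max(span[1], seg.interval.end)
    start = max(s for s, _ in spans.values())
    end = min(e for _, e in spans.values())
    if start >= end:
        return None
    chrom = case_members[0].interval.chrom
    return GenomicInterval(chrom, start, end)


def _hom_signature(members: list[ROHSegment], region: GenomicInterval) -> dict[int, int]:
    signature: dict[int, int] = {}
    for seg in members:
        for p, c in seg.signature_in(region).items():
            if c in (0, 2):
                signature.setdefault(p, c)
    return signature


def _matches_signature(
    seg: ROHSegment, signature: dict[int, int], region: GenomicInterval
) -> bool:
    """A non-case segment carries "the same homozygous allele" iff at every
    signature marker it covers it is homozygous for the identical allele."""
    own = seg.signature_in(region)
    compared = 0
    for p, want in signature.items():
        if p not in own:
            continue
        if own[p] != want:
            return False
        compared += 1
    return compared > 0
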