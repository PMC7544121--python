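"""LD pruning and ROH detection against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mendelmap import (
    GenomicInterval,
    PruneParams,
    ROHParams,
    StageError,
    UndefinedLDError,
    affected_shared_regions,
    call_roh_sample,
    genotype_r2,
    ld_prune,
    pool_roh,
)
from mendelmap.popgen import ROHSegment

from conftest import make_cohort, study_pedigree


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_roh_oracle(positions, genotypes, params):
    """Literal re-statement: a marker supports ROH iff every physical-span
    window anchored at a marker and covering it has <= max_het hets; runs of
    >= min_markers supporting markers are segments."""
    positions = list(positions)
    genotypes = list(genotypes)
    keep = [(p, g) for p, g in zip(positions, genotypes) if g >= 0]
    positions = [p for p, _ in keep]
    genotypes = [g for _, g in keep]
    m = len(positions)
    supporting = []
    for i in range(m):
        ok = True
        for j in range(m):  # all windows anchored at marker j
            if not (positions[j] <= positions[i] < positions[j] + params.window_bp):
                continue
            hets = sum(
                1
                for k in range(m)
                if genotypes[k] == 1
                and positions[j] <= positions[k] < positions[j] + params.window_bp
            )
            if hets > params.max_het:
                ok = False
                break
        supporting.append(ok)
    segments = []
    start = None
    for i in range(m + 1):
        if i < m and supporting[i]:
            start = i if start is None else start
            continue
        if start is not None and i - start >= params.min_markers:
            segments.append((positions[start], positions[i - 1]))
        start = None
    return segments


def has_knife_edge_pair(cohort, params):
    """True when some pairwise r^2 sits within float noise of the
    threshold, where a strict comparison is not well defined across
    implementations."""
    for i in range(cohort.n_sites):
        for j in range(i + 1, cohort.n_sites):
            try:
                r2 = genotype_r2(cohort.gt[i], cohort.gt[j])
            except UndefinedLDError:
                continue
            if abs(r2 - params.r2_threshold) < 1e-9:
                return True
    return False


def naive_prune_oracle(cohort, params):
    """Direct restatement of the window sweep with the same removal rule,
    built on per-pair scipy correlations."""
    missing = cohort.missingness()
    maf = cohort.minor_allele_frequency()
    removed = set()
    idx = list(range(cohort.n_sites))
    for start in range(0, len(idx), params.step):
        window = [i for i in idx[start : start + params.window] if i not in removed]
        while True:
            offender = None
            for a in range(len(window)):
                for b in range(a + 1, len(window)):
                    i, j = window[a], window[b]
                    x, y = cohort.gt[i].astype(float), cohort.gt[j].astype(float)
                    ok = (x >= 0) & (y >= 0)
                    x, y = x[ok], y[ok]
                    if len(x) < 2 or x.std() == 0 or y.std() == 0:
                        continue
                    if stats.pearsonr(x, y).statistic ** 2 > params.r2_threshold:
                        offender = (i, j)
                        break
                if offender:
                    break
            if offender is None:
                break
            i, j = offender

            def badness(s):
                m = maf[s] if np.isfinite(maf[s]) else -1.0
                return (missing[s], -m, cohort.pos[s])

            victim = i if badness(i) > badness(j) else j
            removed.add(victim)
            window.remove(victim)
    return sorted(set(idx) - removed)


# ---------------------------------------------------------------------------
# genotype r^2
# ---------------------------------------------------------------------------

class TestGenotypeR2:
    def test_identical_vectors_give_one(self):
        v = [0, 1, 2, 0, 1, 2]
        assert genotype_r2(v, v) == pytest.approx(1.0)

    def test_perfect_anticorrelation_squares_to_one(self):
        assert genotype_r2([0, 0, 1, 1, 2, 2], [2, 2, 1, 1, 0, 0]) == pytest.approx(1.0)

    def test_matches_independent_pearson_squared(self):
        a, b = [0, 1, 2, 2, 1, 0], [0, 0, 1, 2, 2, 1]
        expected = stats.pearsonr(a, b).statistic ** 2
        assert genotype_r2(a, b) == pytest.approx(expected, rel=1e-12)

    def test_monomorphic_after_missing_exclusion_is_undefined(self):
        with pytest.raises(UndefinedLDError):
            genotype_r2([0, 0, 0, 1], [-1, 1, 2, -1])

    @given(
        st.lists(
            st.tuples(st.integers(-1, 2), st.integers(-1, 2)),
            min_size=4,
            max_size=30,
        )
    )
    def test_agrees_with_pairwise_deleted_pearson(self, pairs):
        a = np.array([p[0] for p in pairs], dtype=float)
        b = np.array([p[1] for p in pairs], dtype=float)
        ok = (a >= 0) & (b >= 0)
        x, y = a[ok], b[ok]
        if len(x) < 2 or x.std() == 0 or y.std() == 0:
            with pytest.raises(UndefinedLDError):
                genotype_r2(a, b)
        else:
            expected = stats.pearsonr(x, y).statistic ** 2
            assert genotype_r2(a, b) == pytest.approx(min(expected, 1.0), abs=1e-9)


# ---------------------------------------------------------------------------
# ld_prune
# ---------------------------------------------------------------------------

class TestLdPrune:
    def test_mutually_independent_sites_all_retained(self):
        rng = np.random.default_rng(3)
        # orthogonal-ish patterns over 12 samples, all pairwise r2 < 0.2
        while True:
            gt = rng.integers(0, 3, size=(6, 12)).astype(np.int8)
            c = make_cohort(gt)
            r2 = [
                genotype_r2(gt[i], gt[j])
                for i in range(6)
                for j in range(i + 1, 6)
            ]
            if max(r2) < 0.2:
                break
        retained = ld_prune(c, PruneParams(window=6, step=6, r2_threshold=0.2))
        assert retained.tolist() == [0, 1, 2, 3, 4, 5]

    def test_duplicated_genotype_column_loses_exactly_one_member(self):
        row = [0, 1, 2, 0, 1, 2, 0, 1]
        c = make_cohort([row, row])
        retained = ld_prune(c, PruneParams(window=2, step=2, r2_threshold=0.2))
        assert len(retained) == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle_on_five_site_windows(self, seed):
        rng = np.random.default_rng(seed)
        gt = rng.integers(0, 3, size=(5, 8)).astype(np.int8)
        gt[rng.random(gt.shape) < 0.1] = -1
        c = make_cohort(gt)
        params = PruneParams(window=5, step=5, r2_threshold=0.2)
        if has_knife_edge_pair(c, params):
            return  # strict > at the threshold is float-noise territory
        assert ld_prune(c, params).tolist() == naive_prune_oracle(c, params)

    @pytest.mark.parametrize("seed", range(10))
    def test_repruning_a_pruned_window_changes_nothing(self, seed):
        rng = np.random.default_rng(100 + seed)
        gt = rng.integers(0, 3, size=(5, 8)).astype(np.int8)
        c = make_cohort(gt)
        params = PruneParams(window=5, step=5, r2_threshold=0.2)
        once = ld_prune(c, params)
        twice = ld_prune(c.subset(once), params)
        assert twice.tolist() == list(range(len(once)))

    def test_unsorted_input_rejected(self):
        c = make_cohort([[0, 1, 2, 0], [1, 1, 0, 2]], pos=[500, 100])
        with pytest.raises(StageError, match="sorted"):
            ld_prune(c)


# ---------------------------------------------------------------------------
# ROH calling
# ---------------------------------------------------------------------------

class TestCallRoh:
    def test_all_homozygous_chromosome_is_one_full_segment(self):
        pos = np.arange(1000, 201_000, 1000)
        gts = np.zeros(200, dtype=np.int8)
        gts[::2] = 2
        segs = call_roh_sample("chr1", pos, gts)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.marker_count == 200 and seg.het_count == 0
        assert (seg.interval.start + 1, seg.interval.end) == (1000, 200_000)

    def test_alternating_het_hom_at_1kb_yields_no_segments(self):
        pos = np.arange(1000, 201_000, 1000)
        gts = np.tile([1, 0], 100).astype(np.int8)
        assert call_roh_sample("chr1", pos, gts) == []

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_naive_window_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 300))
        pos = np.sort(rng.choice(np.arange(1, 400_000), size=m, replace=False))
        gts = rng.choice([-1, 0, 1, 2], size=m, p=[0.05, 0.35, 0.25, 0.35]).astype(np.int8)
        params = ROHParams(window_bp=50_000, max_het=2, min_markers=5)
        got = [
            (s.interval.start + 1, s.interval.end)
            for s in call_roh_sample("chr1", pos, gts, params)
        ]
        assert got == naive_roh_oracle(pos, gts, params)

    def test_planted_tract_with_het_dense_flanks_matches_oracle(self):
        rng = np.random.default_rng(5)
        flank = rng.choice([0, 1], size=60, p=[0.4, 0.6])
        core = np.zeros(100, dtype=np.int64)
        core[50] = 1  # one interior het, within the allowance
        gts = np.concatenate([flank, core, flank]).astype(np.int8)
        # 5 kb spacing: each 50 kb window covers ~10 markers, so the
        # het-dense flanks erode but do not consume the 100-marker core
        pos = np.arange(1, len(gts) + 1) * 5000
        params = ROHParams(window_bp=50_000, max_het=3, min_markers=25)
        got = [
            (s.interval.start + 1, s.interval.end)
            for s in call_roh_sample("chr1", pos, gts, params)
        ]
        assert got == naive_roh_oracle(pos, gts, params)
        assert len(got) == 1  # the planted run survives its interior het

    def test_raising_het_allowance_never_shortens_segments(self):
        rng = np.random.default_rng(11)
        pos = np.arange(1, 301) * 777
        gts = rng.choice([0, 1, 2], size=300, p=[0.4, 0.25, 0.35]).astype(np.int8)
        spans = {}
        for max_het in (0, 1, 2, 4, 8):
            segs = call_roh_sample(
                "c", pos, gts, ROHParams(window_bp=30_000, max_het=max_het, min_markers=5)
            )
            spans[max_het] = sum(s.marker_count for s in segs)
        assert sorted(spans.values()) == [spans[k] for k in (0, 1, 2, 4, 8)]

    def test_unsorted_positions_rejected(self):
        with pytest.raises(StageError, match="sorted"):
            call_roh_sample("c", [5, 1], [0, 0])


# ---------------------------------------------------------------------------
# pooling and the affected-only filter
# ---------------------------------------------------------------------------

def _seg(sample, start1, end1, positions, codes, chrom="chr1"):
    return ROHSegment(
        sample_id=sample,
        interval=GenomicInterval.from_1based(chrom, start1, end1),
        positions=np.asarray(positions, dtype=np.int64),
        codes=np.asarray(codes, dtype=np.int8),
    )


class TestPoolRoh:
    def test_identical_segments_pool_to_their_own_consensus(self):
        a = _seg("s1", 100, 500, [100, 300, 500], [2, 2, 0])
        b = _seg("s2", 100, 500, [100, 300, 500], [2, 2, 0])
        groups = pool_roh([a, b])
        assert len(groups) == 1
        g = groups[0]
        assert (g.consensus.start + 1, g.consensus.end) == (100, 500)
        assert g.shared_allele and g.samples == ["s1", "s2"]

    def test_disjoint_segments_form_singleton_groups(self):
        a = _seg("s1", 100, 200, [100, 200], [0, 0])
        b = _seg("s2", 500, 600, [500, 600], [2, 2])
        assert len(pool_roh([a, b])) == 2

    def test_staggered_overlaps_intersect_like_interval_oracle(self):
        segs = [
            _seg("s1", 100, 900, [100, 500, 900], [2, 2, 2]),
            _seg("s2", 400, 1200, [500, 900, 1200], [2, 2, 0]),
            _seg("s3", 700, 1500, [900, 1200, 1500], [2, 0, 0]),
        ]
        groups = pool_roh(segs)
        assert len(groups) == 1
        start = max(s.interval.start for s in segs)
        end = min(s.interval.end for s in segs)
        assert (groups[0].consensus.start, groups[0].consensus.end) == (start, end)

    def test_conflicting_homozygous_alleles_clear_shared_flag(self):
        a = _seg("s1", 100, 500, [100, 300], [2, 2])
        b = _seg("s2", 100, 500, [100, 300], [2, 0])
        assert pool_roh([a, b])[0].shared_allele is False


class TestAffectedSharedRegions:
    ped = study_pedigree()

    def test_affected_identical_hom_alt_tract_with_het_dams_is_kept(self):
        groups = pool_roh(
            [
                _seg("foal1", 100, 900, [100, 500, 900], [2, 2, 2]),
                _seg("foal2", 100, 900, [100, 500, 900], [2, 2, 2]),
            ]
        )
        regions = affected_shared_regions(groups, self.ped)
        assert [(r.start + 1, r.end) for r in regions] == [(100, 900)]

    def test_affecteds_homozygous_for_different_alleles_excluded(self):
        groups = pool_roh(
            [
                _seg("foal1", 100, 900, [100, 500], [2, 2]),
                _seg("foal2", 100, 900, [100, 500], [2, 0]),
            ]
        )
        assert affected_shared_regions(groups, self.ped) == []

    def test_control_with_identical_signature_excludes_region(self):
        groups = pool_roh(
            [
                _seg("foal1", 100, 900, [100, 500], [2, 2]),
                _seg("foal2", 100, 900, [100, 500], [2, 2]),
                _seg("ctrl1", 100, 900, [100, 500], [2, 2]),
            ]
        )
        assert affected_shared_regions(groups, self.ped) == []

    def test_control_with_different_signature_does_not_exclude(self):
        groups = pool_roh(
            [
                _seg("foal1", 100, 900, [100, 500], [2, 2]),
                _seg("foal2", 100, 900, [100, 500], [2, 2]),
                _seg("ctrl1", 100, 900, [100, 500], [0, 0]),
            ]
        )
        assert len(affected_shared_regions(groups, self.ped)) == 1

    def test_missing_affected_member_excludes_group(self):
        groups = pool_roh([_seg("foal1", 100, 900, [100], [2])])
        assert affected_shared_regions(groups, self.ped) == []

    def test_no_affected_samples_is_an_error(self):
        from mendelmap import Pedigree, PedigreeSample

        ped = Pedigree([PedigreeSample("x", "F", None, None, 1, "unaffected")])
        with pytest.raises(StageError, match="affected"):
            affected_shared_regions([], ped)
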