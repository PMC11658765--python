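import numpy as np
import pytest

from exoload import methylation as meth
from exoload import synthetic_data as sd
from exoload.formats_io import IntervalSet, UnionBed


def _unionbed(fractions, coverage, pos=None, context="CG", chrom="Chr1"):
    fractions = np.asarray(fractions, dtype=float)
    coverage = np.asarray(coverage, dtype=np.int64)
    r, n = fractions.shape
    return UnionBed(
        chrom=np.asarray([chrom] * r, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(r) * 50 + 100),
        context=np.asarray([context] * r, dtype=object),
        fractions=np.where(coverage > 0, fractions, np.nan),
        coverage=coverage,
        samples=[f"s{i:02d}" for i in range(n)])


class TestSelectExtremes:
    def test_ranks(self):
        ids = [f"s{i:02d}" for i in range(40)]
        loads = np.arange(1.0, 41.0)
        high, low = meth.select_extreme_samples(loads, ids, n=20)
        assert set(high) == set(ids[20:]) and set(low) == set(ids[:20])

    def test_order_invariance(self):
        ids = [f"s{i:02d}" for i in range(30)]
        rng = np.random.default_rng(1)
        loads = rng.normal(size=30)
        perm = rng.permutation(30)
        a = meth.select_extreme_samples(loads, ids, n=10)
        b = meth.select_extreme_samples(loads[perm], [ids[i] for i in perm], n=10)
        assert a == b

    def test_tie_resolution_by_id(self):
        ids = ["b", "a", "c", "d"]
        loads = np.array([1.0, 1.0, 0.0, 2.0])
        high, low = meth.select_extreme_samples(loads, ids, n=2)
        assert high == ["b", "d"] and low == ["a", "c"]

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            meth.select_extreme_samples(np.arange(5.0), list("abcde"), n=3)


class TestFilterUnion:
    def test_presence_rule(self):
        n = 100
        cov = np.full((1, n), 5)
        cov[0, :6] = 0  # 94% covered < 95%
        frac = np.tile(np.linspace(0, 1, n), (1, 1))
        ub = _unionbed(frac, cov)
        assert meth.filter_union(ub).n_sites == 0

    def test_no_difference_dropped(self):
        cov = np.full((1, 40), 10)
        frac = np.full((1, 40), 0.5)
        assert meth.filter_union(_unionbed(frac, cov)).n_sites == 0

    def test_hand_counted_pass_set(self):
        # 20 samples, 3 sites: site0 passes, site1 fails presence,
        # site2 fails the 5%-difference rule (one deviant only)
        n = 20
        cov = np.full((3, n), 6)
        cov[1, :2] = 0  # 90% presence
        frac = np.full((3, n), 0.5)
        frac[0, 0] = 0.8
        frac[0, 1] = 0.1
        frac[2, 0] = 0.8  # single deviant
        ub = _unionbed(frac, cov)
        out = meth.filter_union(ub, min_cov=4, presence=0.95, min_diff=0.05,
                                min_diff_samples=2)
        assert out.n_sites == 1 and out.pos[0] == ub.pos[0]


def _two_group_ub(n_sites=60, delta=0.0, seed=0, pos=None):
    rng = np.random.default_rng(seed)
    n = 40
    base = rng.uniform(0.4, 0.6, size=(n_sites, 1))
    frac = np.clip(base + rng.normal(0, 0.03, size=(n_sites, n)), 0, 1)
    frac[:, :20] = np.clip(frac[:, :20] + delta, 0, 1)
    cov = np.full((n_sites, n), 10)
    return _unionbed(frac, cov, pos=pos)


class TestCallDmrs:
    def test_identical_groups_no_dmrs(self):
        ub = _two_group_ub(delta=0.0, seed=3)
        high = ub.samples[:20]
        low = ub.samples[20:]
        assert meth.call_dmrs(ub, high, low) == []

    def test_spiked_region_called_with_direction(self, methylation_fixture):
        ub, truth, samples = methylation_fixture
        dmrs = meth.call_dmrs(ub, samples[:20], samples[20:])
        assert len(dmrs) >= len(truth.spiked) - 1
        for chrom, start, end, ctx in truth.spiked:
            hits = [d for d in dmrs if d.chrom == chrom and d.context == ctx
                    and d.start < end and start < d.end]
            if hits:
                assert all(d.direction == "hyper" for d in hits)

    def test_gap_rule_boundary(self):
        # two 5-site seed clusters 301 bp apart -> two regions
        pos = np.r_[np.arange(5) * 50, 200 + 301 + np.arange(5) * 50]
        ub = _two_group_ub(n_sites=10, delta=0.4, seed=4, pos=pos)
        dmrs = meth.call_dmrs(ub, ub.samples[:20], ub.samples[20:],
                              min_sites=5, max_gap=300)
        assert len(dmrs) == 2
        pos2 = np.r_[np.arange(5) * 50, 200 + 300 + np.arange(5) * 50]
        ub2 = _two_group_ub(n_sites=10, delta=0.4, seed=4, pos=pos2)
        dmrs2 = meth.call_dmrs(ub2, ub2.samples[:20], ub2.samples[20:],
                               min_sites=5, max_gap=300)
        assert len(dmrs2) == 1

    def test_disjoint_within_context(self, methylation_fixture):
        ub, truth, samples = methylation_fixture
        dmrs = meth.call_dmrs(ub, samples[:20], samples[20:])
        by_ctx: dict = {}
        for d in dmrs:
            by_ctx.setdefault(d.context, []).append((d.start, d.end))
        for spans in by_ctx.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_seed_diff_monotonicity(self, methylation_fixture):
        ub, truth, samples = methylation_fixture
        n_loose = len(meth.call_dmrs(ub, samples[:20], samples[20:], seed_diff=0.05,
                                     fdr=1.01))
        n_tight = len(meth.call_dmrs(ub, samples[:20], samples[20:], seed_diff=0.2,
                                     fdr=1.01))
        assert n_loose >= n_tight

    def test_overlapping_groups_error(self, methylation_fixture):
        ub, truth, samples = methylation_fixture
        with pytest.raises(ValueError, match="overlap"):
            meth.call_dmrs(ub, samples[:20], samples[10:30])

    def test_invariants(self, methylation_fixture):
        ub, truth, samples = methylation_fixture
        for d in meth.call_dmrs(ub, samples[:20], samples[20:]):
            assert d.n_sites >= 5
            assert d.q >= d.p
            assert d.direction == ("hyper" if d.delta > 0 else "hypo")


class TestDmrFeatureDensity:
    def _dmrs(self, spans):
        return [meth.DMR(chrom="Chr1", start=s, end=e, context="CG", n_sites=5,
                         delta=0.2, p=0.01, q=0.05, direction="hyper")
                for s, e in spans]

    def test_division(self):
        feats = IntervalSet(
            chrom=np.asarray(["Chr1"], dtype=object), start=np.array([0]),
            end=np.array([2_000_000]),
            feature_class=np.asarray(["TE"], dtype=object),
            name=np.asarray(["te1"], dtype=object))
        dmrs = self._dmrs([(i * 1000, i * 1000 + 100) for i in range(10)])
        dens = meth.dmr_feature_density(dmrs, feats, {"TE": 2.0})
        assert dens["TE"] == pytest.approx(5.0)

    def test_no_dmrs(self):
        feats = IntervalSet(
            chrom=np.asarray(["Chr1"], dtype=object), start=np.array([0]),
            end=np.array([100]),
            feature_class=np.asarray(["gene"], dtype=object),
            name=np.asarray(["g"], dtype=object))
        assert meth.dmr_feature_density([], feats, {"gene": 1.0}) == {"gene": 0.0}

    def test_brute_force_overlap_oracle(self):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 100_000, 30)
        feats = IntervalSet(
            chrom=np.asarray(["Chr1"] * 30, dtype=object),
            start=starts, end=starts + rng.integers(100, 5000, 30),
            feature_class=np.asarray(rng.choice(["gene", "TE"], 30), dtype=object),
            name=np.asarray([f"f{i}" for i in range(30)], dtype=object))
        dmrs = self._dmrs([(int(s), int(s) + 200)
                           for s in rng.integers(0, 100_000, 20)])
        dens = meth.dmr_feature_density(dmrs, feats, {"gene": 1.0, "TE": 1.0})
        for fc in ("gene", "TE"):
            want = sum(
                any(feats.chrom[i] == d.chrom and feats.start[i] < d.end
                    and d.start < feats.end[i]
                    and feats.feature_class[i] == fc for i in range(30))
                for d in dmrs)
            assert dens[fc] == pytest.approx(want)

    def test_zero_mb_nan(self):
        assert np.isnan(meth.dmr_feature_density(
            [], IntervalSet(
                chrom=np.asarray(["Chr1"], dtype=object), start=np.array([0]),
                end=np.array([10]),
                feature_class=np.asarray(["gene"], dtype=object),
                name=np.asarray(["g"], dtype=object)),
            {"gene": 0.0})["gene"])


class TestEwaSites:
    def _dmr(self, start, end, context="CG"):
        return meth.DMR(chrom="Chr1", start=start, end=end, context=context,
                        n_sites=5, delta=0.2, p=0.01, q=0.05, direction="hyper")

    def test_site_inside_retained(self):
        ub = _two_group_ub(n_sites=10)
        sites, thr = meth.ewa_sites(ub, [self._dmr(0, 10_000)])
        assert sites.n_sites == 10 and thr == pytest.approx(0.05)

    def test_context_mismatch_excluded(self):
        ub = _two_group_ub(n_sites=10)
        sites, _ = meth.ewa_sites(ub, [self._dmr(0, 10_000, context="CHH")])
        assert sites.n_sites == 0

    def test_bonferroni_162(self):
        ub = _two_group_ub(n_sites=5)
        dmrs = [self._dmr(i * 10, i * 10 + 5) for i in range(162)]
        _, thr = meth.ewa_sites(ub, dmrs)
        assert thr == pytest.approx(0.05 / 162)
        assert thr == pytest.approx(3.086e-4, rel=1e-3)

    def test_zero_dmrs_empty(self):
        ub = _two_group_ub(n_sites=5)
        sites, thr = meth.ewa_sites(ub, [])
        assert sites.n_sites == 0 and np.isnan(thr)
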