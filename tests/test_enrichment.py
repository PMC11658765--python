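import numpy as np
import pytest

from exoload import enrichment as enr
from exoload.formats_io import IntervalSet


def _genes(rows):
    chrom, start, end, name = zip(*rows)
    return IntervalSet(
        chrom=np.asarray(chrom, dtype=object), start=np.asarray(start),
        end=np.asarray(end),
        feature_class=np.asarray(["gene"] * len(rows), dtype=object),
        name=np.asarray(name, dtype=object))


class TestMarkCandidates:
    def test_within_window(self):
        genes = _genes([("Chr1", 50_000, 51_000, "g")])
        # gene start 50_000 (0-based); variant 19_999 bp upstream
        flags = enr.mark_candidates(np.array(["Chr1"]),
                                    np.array([50_000 - 19_999 + 1]), genes)
        assert flags[0]

    def test_outside_window(self):
        genes = _genes([("Chr1", 50_000, 51_000, "g")])
        flags = enr.mark_candidates(np.array(["Chr1"]),
                                    np.array([50_000 - 20_001 + 1]), genes)
        assert not flags[0]

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        genes = _genes([("Chr1", int(s), int(s) + 500, f"g{i}")
                        for i, s in enumerate(rng.integers(0, 900_000, 15))]
                       + [("Chr2", 1000, 3000, "g99")])
        chroms = np.array(["Chr1" if r < 0.8 else "Chr2" for r in rng.random(3000)],
                          dtype=object)
        pos = rng.integers(1, 1_000_000, 3000)
        flags = enr.mark_candidates(chroms, pos, genes, window=20_000)
        for i in rng.integers(0, 3000, 400):  # spot-check by direct scan
            p0 = pos[i] - 1
            want = any(
                genes.chrom[j] == chroms[i]
                and genes.start[j] - 20_000 <= p0 < genes.end[j] + 20_000
                for j in range(len(genes)))
            assert flags[i] == want

    def test_chrom_mismatch_error(self):
        genes = _genes([("Chr9", 0, 100, "g")])
        with pytest.raises(ValueError, match="Chr1"):
            enr.mark_candidates(np.array(["Chr1"]), np.array([10]), genes)


class TestEnrichmentCurve:
    def test_hand_example(self):
        # S=100, A=10, s(1.0)=10, a(1.0)=5 -> E = (5/10)/(10/100) = 5.0
        p = np.full(100, 0.5)
        p[:10] = 0.05  # -log10 = 1.3 >= 1.0
        flags = np.zeros(100, dtype=bool)
        flags[:5] = True  # 5 significant candidates
        flags[95:] = True  # 5 non-significant candidates -> A = 10
        res = enr.enrichment_curve(p, flags)
        i = np.flatnonzero(res.thresholds == 1.0)[0]
        assert res.n_significant[i] == 10 and res.n_candidate_significant[i] == 5
        assert res.enrichment[i] == pytest.approx(5.0)
        # FDR_ub = ((10-5) * 10/90) / 5 = 0.1111
        assert res.fdr_upper[i] == pytest.approx(5 * (10 / 90) / 5, abs=1e-10)
        assert res.fdr_upper[i] == pytest.approx(0.111111, abs=1e-5)

    def test_null_enrichment_near_one(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=20_000)
        flags = rng.random(20_000) < 0.1
        res = enr.enrichment_curve(p, flags)
        low_t = res.thresholds <= 1.0
        assert np.all(np.abs(res.enrichment[low_t] - 1.0) < 0.25)

    def test_monotone_counts(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        flags = rng.random(500) < 0.2
        res = enr.enrichment_curve(p, flags)
        assert np.all(np.diff(res.n_significant) <= 0)
        assert np.all(np.diff(res.n_candidate_significant) <= 0)
        assert np.all(res.n_candidate_significant <= res.n_significant)

    def test_naive_recount_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=800) ** 2
        flags = rng.random(800) < 0.15
        res = enr.enrichment_curve(p, flags)
        logp = -np.log10(p)
        for i, t in enumerate(res.thresholds):
            assert res.n_significant[i] == int((logp >= t).sum())
            assert res.n_candidate_significant[i] == int((flags & (logp >= t)).sum())

    def test_degenerate_error(self):
        p = np.full(10, 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            enr.enrichment_curve(p, np.zeros(10, dtype=bool))
        with pytest.raises(ValueError, match="degenerate"):
            enr.enrichment_curve(p, np.ones(10, dtype=bool))


class TestRotationTest:
    def test_all_flags_true_is_degenerate(self):
        p = np.full(10, 0.01)
        with pytest.raises(ValueError):
            enr.rotation_test(p, np.ones(10, dtype=bool),
                              np.array(["c"] * 10), 1.0, n_perm=100)

    def test_identity_rotation_reproduces_observed(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        flags = rng.random(200) < 0.2
        chroms = np.array(["Chr1"] * 100 + ["Chr2"] * 100)
        logp = -np.log10(p)
        A, S = int(flags.sum()), 200
        obs_direct = enr._enrichment_at(logp, flags, 0.5, A, S)
        rot = enr.rotation_test(p, flags, chroms, 0.5, n_perm=200, seed=1)
        assert rot.observed == obs_direct  # bit-exact

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=300)
        flags = rng.random(300) < 0.2
        chroms = np.array(["Chr1"] * 300)
        a = enr.rotation_test(p, flags, chroms, 1.0, n_perm=300, seed=9)
        b = enr.rotation_test(p, flags, chroms, 1.0, n_perm=300, seed=9)
        np.testing.assert_array_equal(a.null_enrichments, b.null_enrichments)
        assert a.empirical_p == b.empirical_p

    def test_empirical_p_bounds(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=300)
        flags = rng.random(300) < 0.3
        rot = enr.rotation_test(p, flags, np.array(["c"] * 300), 0.5,
                                n_perm=500, seed=2)
        assert 1 / 501 <= rot.empirical_p <= 1.0

    def test_small_nperm_warns(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        flags = np.zeros(50, dtype=bool)
        flags[:10] = True
        with pytest.warns(UserWarning, match="coarse"):
            enr.rotation_test(p, flags, np.array(["c"] * 50), 0.5, n_perm=50)


class TestFeatureEnrichment:
    def test_single_feature_identity(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200)
        res = enr.feature_enrichment(p, np.array(["gene"] * 200))
        vals = res["enrichment"].dropna()
        assert np.allclose(vals, 1.0)

    def test_two_equal_features_near_one(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=10_000)
        labels = np.array(["a", "b"] * 5000)
        res = enr.feature_enrichment(p, labels)
        low = res[(res["threshold"] <= 1.0)]
        assert np.all(np.abs(low["enrichment"] - 1.0) < 0.2)

    def test_background_weighted_mean_is_one(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=2000) ** 3
        labels = rng.choice(["gene", "TE", "intergenic"], size=2000,
                            p=[0.2, 0.3, 0.5])
        res = enr.feature_enrichment(p, labels)
        for t, sub in res.groupby("threshold"):
            if sub["enrichment"].isna().any():
                continue
            wm = float((sub["enrichment"] * sub["background_fraction"]).sum())
            assert wm == pytest.approx(1.0, abs=1e-9)

    def test_concentrated_signal(self):
        p = np.full(300, 0.5)
        labels = np.array(["X"] * 100 + ["Y"] * 200)
        p[:50] = 1e-4  # all strong signal in X
        res = enr.feature_enrichment(p, labels)
        top = res[(res["threshold"] == 3.5)]
        ex = top[top["feature"] == "X"]["enrichment"].iloc[0]
        ey = top[top["feature"] == "Y"]["enrichment"].iloc[0]
        assert ex == pytest.approx(3.0) and ey == 0.0
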