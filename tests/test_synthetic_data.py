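import numpy as np
import pytest
from scipy import stats

from exoload import synthetic_data as sd


class TestMakeGenomes:
    def test_zero_divergence_identical_block(self):
        seqs, t = sd.make_genomes(5000, {"p": 3000}, 800, 0.0, 3)
        host_block = seqs["host"][t.block_start:t.block_end]
        ps = t.pest_block_start["p"]
        assert seqs["p"][ps:ps + 800] == host_block

    def test_divergence_hamming_matches_recorded_sites(self):
        # oracle: count mismatches directly between the two block copies
        seqs, t = sd.make_genomes(5000, {"p": 3000}, 1000, 0.05, 4)
        host_block = seqs["host"][t.block_start:t.block_end]
        ps = t.pest_block_start["p"]
        pest_block = seqs["p"][ps:ps + 1000]
        hamming = sum(a != b for a, b in zip(host_block, pest_block))
        assert hamming == len(t.divergent_sites["p"])
        # binomial(1000, 0.05): within a generous band
        assert 20 <= hamming <= 85

    def test_seed_determinism(self):
        a, _ = sd.make_genomes(2000, {"p": 1000}, 500, 0.1, 9)
        b, _ = sd.make_genomes(2000, {"p": 1000}, 500, 0.1, 9)
        assert a == b

    def test_block_too_long_error(self):
        with pytest.raises(ValueError, match="conserved_len"):
            sd.make_genomes(1000, {"p": 2000}, 1000, 0.05, 1)


class TestMakePopulation:
    def test_fst_zero_no_differentiation(self):
        # simulation oracle: chi-square test of pop vs allele count table
        table, pops = sd.make_population(200, 2, 0.0, 300, seed=21)
        sig = 0
        for j in range(table.n_variants):
            cells = []
            for p in ("pop0", "pop1"):
                g = table.dosages[pops == p, j]
                cells.append([np.sum(g == k) for k in (0, 1, 2)])
            obs = np.array(cells)
            obs = obs[:, obs.sum(axis=0) > 0]
            if obs.shape[1] < 2:
                continue
            _, pval, _, _ = stats.chi2_contingency(obs)
            sig += pval < 0.05
        assert sig / table.n_variants <= 0.05 + 0.03

    def test_single_pop_labels_equal(self):
        _, pops = sd.make_population(10, 1, 0.0, 5, seed=1)
        assert len(set(pops)) == 1

    def test_seed_determinism(self):
        a, _ = sd.make_population(30, 2, 0.2, 50, seed=5)
        b, _ = sd.make_population(30, 2, 0.2, 50, seed=5)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_positions_sorted_within_chrom(self):
        table, _ = sd.make_population(10, 1, 0.0, 100, seed=2)
        for c in set(table.chrom):
            pos = table.pos[table.chrom == c]
            assert np.all(np.diff(pos) > 0)

    def test_errors(self):
        with pytest.raises(ValueError):
            sd.make_population(10, 1, 0.0, 0, seed=1)
        with pytest.raises(ValueError):
            sd.make_population(10, 1, 1.0, 10, seed=1)


class TestSimulateLoads:
    def test_h2_bounds_error(self, population_small):
        table, pops = population_small
        with pytest.raises(ValueError, match="h2"):
            sd.simulate_loads(table, 10, 1.5, seed=1)

    def test_constant_fraction_slope_one(self):
        # OLS oracle: log(c+1) on log(d) has slope ~ 1 when f is constant.
        # h2=1 with a zero kinship forces liability == 0 for every sample.
        table, _ = sd.make_population(400, 1, 0.0, 10, seed=3)
        n = table.n_samples
        counts, depths, truth = sd.simulate_loads(
            table, 0, 1.0, seed=4, genetic_model="kinship",
            kinship=np.zeros((n, n)), f_scale=0.05,
            depth_lognorm_params=(np.log(50_000.0), 0.6))
        assert np.ptp(truth.fraction) == 0
        slope = np.polyfit(np.log(depths), np.log(counts + 1.0), 1)[0]
        assert abs(slope - 1.0) < 0.05

    def test_seed_determinism(self, population_small):
        table, pops = population_small
        a = sd.simulate_loads(table, 20, 0.4, seed=8, pop_labels=pops)[0]
        b = sd.simulate_loads(table, 20, 0.4, seed=8, pop_labels=pops)[0]
        np.testing.assert_array_equal(a, b)

    def test_truth_record_fields(self, population_small):
        table, pops = population_small
        counts, depths, truth = sd.simulate_loads(table, 20, 0.4, seed=8,
                                                  pop_labels=pops)
        assert truth.h2_true == 0.4
        assert len(truth.causal_idx) == 20
        assert np.all(truth.fraction > 0)
        assert len(counts) == len(depths) == table.n_samples

    def test_pop_effect_exceeding_budget_error(self, population_small):
        table, pops = population_small
        with pytest.raises(ValueError, match="pop_effect_sd"):
            sd.simulate_loads(table, 10, 0.9, pop_effect_sd=0.5, seed=1,
                              pop_labels=pops)


class TestSimulateAlignments:
    def test_zero_ambiguous_fraction(self, genomes_small, tmp_path):
        seqs, gtruth = genomes_small
        truth = sd.simulate_alignments(
            seqs, gtruth, {"s0": {"aphid": 5, "mildew": 0}},
            ambiguous_fraction=0.0, out_dir=tmp_path, seed=3, n_host_pairs=50)
        assert all(v != "ambiguous" for v in truth.labels["s0"].values())

    def test_zero_pest_reads(self, genomes_small, tmp_path):
        seqs, gtruth = genomes_small
        truth = sd.simulate_alignments(
            seqs, gtruth, {"s0": {"aphid": 0, "mildew": 0}},
            ambiguous_fraction=0.1, out_dir=tmp_path, seed=3, n_host_pairs=50)
        assert truth.pest_counts["s0"] == {"aphid": 0, "mildew": 0}
        assert all(v != "exogenous" for v in truth.labels["s0"].values())

    def test_counts_consistent_with_labels(self, alignment_fixture):
        truth = alignment_fixture
        for s, lab in truth.labels.items():
            n_exo = sum(v == "exogenous" for v in lab.values())
            assert n_exo == sum(truth.pest_counts[s].values())

    def test_manifest_round_trip(self, alignment_fixture, tmp_path):
        path = tmp_path / "truth.tsv"
        sd.write_truth_manifest(alignment_fixture, path)
        lines = path.read_text().splitlines()
        assert lines[0] == f"#seed\t{alignment_fixture.seed}"
        n = sum(len(v) for v in alignment_fixture.labels.values())
        assert len(lines) == n + 2


class TestSimulateMethylation:
    def test_seed_determinism(self):
        samples = [f"s{i}" for i in range(10)]
        loads = np.arange(10.0)
        a, _ = sd.simulate_methylation(100, samples, loads, 2, -0.2, seed=6)
        b, _ = sd.simulate_methylation(100, samples, loads, 2, -0.2, seed=6)
        np.testing.assert_allclose(a.fractions, b.fractions)
        np.testing.assert_array_equal(a.coverage, b.coverage)

    def test_negative_effect_hypomethylates_high_load(self):
        # compare group means directly inside spiked intervals
        samples = [f"s{i:02d}" for i in range(40)]
        loads = np.r_[np.ones(20), -np.ones(20)]
        ub, truth = sd.simulate_methylation(800, samples, loads, 4, -0.3,
                                            seed=7, contexts=("CG",))
        for chrom, start, end, ctx in truth.spiked:
            mask = (ub.pos >= start) & (ub.pos < end) & (ub.context == ctx)
            hi = np.nanmean(ub.fractions[mask][:, :20])
            lo = np.nanmean(ub.fractions[mask][:, 20:])
            assert hi < lo

    def test_context_means_ordered(self):
        samples = [f"s{i}" for i in range(20)]
        ub, _ = sd.simulate_methylation(400, samples, np.zeros(20), 0, 0.0, seed=8)
        m = {c: np.nanmean(ub.fractions[ub.context == c]) for c in ("CG", "CHG", "CHH")}
        assert m["CG"] > m["CHG"] > m["CHH"]

    def test_effect_bound_error(self):
        with pytest.raises(ValueError, match="dmr_effect"):
            sd.simulate_methylation(10, ["a"], np.zeros(1), 1, 1.5, seed=1)
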