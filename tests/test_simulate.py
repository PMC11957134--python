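"""Generative-model tests: tree/genotype truth, WGA distortion, UMI, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import clonescope as cs
from clonescope.simulate import WgaProfile, default_family_size_dist
from clonescope.trees import root_to_tip_lengths


class TestCloneTree:
    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="mutations_per_day"):
            cs.simulate_clone_tree(4, 2, mutations_per_day=0.0, seed=0)

    def test_more_clones_than_cells_rejected(self):
        with pytest.raises(ValueError):
            cs.simulate_clone_tree(3, 5, mutations_per_day=1.0, seed=0)

    def test_cells_map_to_one_clone_and_times_match_schedule(self, benchmark_truth):
        truth, G = benchmark_truth
        assert sorted(truth.clone_of_cell) == sorted(G.index)
        design = cs.invitro_benchmark_design()
        for cell, clone in truth.clone_of_cell.items():
            assert truth.culture_time_of_cell[cell] == design["sampling_schedule"][clone]

    def test_clone_pairs_share_clone_private_mutations(self, benchmark_truth):
        """Both cells of a clone carry every mutation older than their split."""
        truth, G = benchmark_truth
        cells_of = {}
        for c, k in truth.clone_of_cell.items():
            cells_of.setdefault(k, []).append(c)
        for clone, cells in cells_of.items():
            a, b = sorted(cells)
            shared = (G.loc[a] == 1) & (G.loc[b] == 1)
            # shared mutations = those not on the two private tip edges
            private_a = (G.loc[a] == 1) & (G.loc[b] == 0)
            private_b = (G.loc[b] == 1) & (G.loc[a] == 0)
            assert shared.sum() + private_a.sum() == G.loc[a].sum()
            assert shared.sum() + private_b.sum() == G.loc[b].sum()
            # the clone's two cells agree at every non-tip mutation
            for var in G.columns[private_a | private_b]:
                assert truth.mutation_assignments[var] in (a, b)

    def test_branch_lengths_equal_culture_time(self, benchmark_truth):
        truth, _ = benchmark_truth
        d = root_to_tip_lengths(truth.tree)
        for cell, t in truth.culture_time_of_cell.items():
            assert d[cell] == pytest.approx(t, abs=1e-4)

    def test_poisson_branch_mutation_mean(self):
        """rate=2/day over a 10-day branch: Monte-Carlo mean ~ Poisson(20)."""
        n_rep = 2000
        counts = []
        for s in range(n_rep):
            truth, G = cs.simulate_clone_tree(
                1, 1, mutations_per_day=2.0, sampling_schedule=[10.0],
                within_clone_days=0.0, seed=s)
            counts.append(G.shape[1])
        se = np.sqrt(20.0 / n_rep)
        assert abs(np.mean(counts) - 20.0) < 3 * se

    def test_seed_determinism_byte_identical(self):
        a = cs.simulate_clone_tree(8, 4, 3.0, seed=42)
        b = cs.simulate_clone_tree(8, 4, 3.0, seed=42)
        assert a[1].to_csv() == b[1].to_csv()
        assert a[0].tree.as_string(schema="newick") == b[0].tree.as_string(schema="newick")

    def test_truth_matrix_tree_compatible(self, benchmark_truth):
        """No homoplasy: every truth variant maps cleanly onto one branch."""
        truth, G = benchmark_truth
        pf = cs.phylogeny_filter(G.astype(float), truth.tree)
        assert not pf["homoplasic"].any()


class TestWgaReadcounts:
    def test_no_distortion_limit(self, het_snps):
        """ado=0, dispersion~0, no errors: both alleles at ~0.5 BAF everywhere."""
        G = pd.DataFrame(np.zeros((1, 1)), index=["cellA"], columns=["m0"])
        prof = WgaProfile(ado_rate=0.0, amp_error_rate=0.0,
                          imbalance_dispersion=0.0, mean_depth=40.0)
        d = cs.simulate_wga_readcounts(G, prof, het_snp_positions=het_snps, seed=1)
        covered = d[(d.ref_depth + d.alt_depth) >= 10]
        assert (covered.ref_depth > 0).all() and (covered.alt_depth > 0).all()
        baf = covered.alt_depth / (covered.ref_depth + covered.alt_depth)
        assert abs(baf.mean() - 0.5) < 0.01
        assert baf.std() < 0.12  # pure binomial noise at depth ~40

    def test_ado_estimator_recovers_generating_rate(self):
        """50k sites at the PTA dropout rate: estimate within +/-0.01."""
        het = cs.simulate_het_snp_positions(50000, seed=3)
        G = pd.DataFrame(np.zeros((1, 1)), index=["cellA"], columns=["m0"])
        d = cs.simulate_wga_readcounts(G, cs.PTA_PROFILE,
                                       het_snp_positions=het, seed=4)
        est = cs.estimate_ado(d)
        assert abs(est - 0.057) < 0.01

    def test_mda_baf_density_wider_than_pta(self, het_snps):
        G = pd.DataFrame(np.zeros((1, 1)), index=["cellA"], columns=["m0"])
        bafs = {}
        for name, prof in (("pta", cs.PTA_PROFILE), ("mda", cs.MDA_PROFILE)):
            d = cs.simulate_wga_readcounts(G, prof, het_snp_positions=het_snps,
                                           seed=5)
            tot = d.ref_depth + d.alt_depth
            keep = (tot >= 10) & (d.ref_depth > 0) & (d.alt_depth > 0)
            bafs[name] = (d.alt_depth / tot)[keep]
        assert bafs["mda"].var() > bafs["pta"].var()

    def test_empty_genotypes_rejected(self, het_snps):
        with pytest.raises(ValueError, match="empty"):
            cs.simulate_wga_readcounts(pd.DataFrame(), cs.PTA_PROFILE,
                                       het_snp_positions=het_snps)

    def test_duplicate_positions_rejected(self):
        G = pd.DataFrame(np.zeros((1, 1)), index=["cellA"], columns=["m0"])
        dup = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [5, 5]})
        with pytest.raises(ValueError, match="unique"):
            cs.simulate_wga_readcounts(G, cs.PTA_PROFILE, het_snp_positions=dup)


class TestInjectCnv:
    @pytest.fixture()
    def carriers_setup(self, benchmark_truth, het_snps):
        truth, G = benchmark_truth
        depths = cs.simulate_wga_readcounts(G, cs.PTA_PROFILE,
                                            het_snp_positions=het_snps, seed=9)
        event = cs.CnvEvent(clone=7, chrom="chr13", start=0, end=300_000)
        out = cs.inject_cnv(depths, truth, event, seed=10)
        return truth, depths, out, event

    def test_carrier_baf_hemizygous(self, carriers_setup):
        truth, _, out, event = carriers_setup
        carriers = [c for c, k in truth.clone_of_cell.items() if k == event.clone]
        sub = out[(out.cell.isin(carriers)) & (out.pos < event.end)]
        tot = sub.ref_depth + sub.alt_depth
        baf = (sub.alt_depth / tot)[tot >= 10]
        assert ((baf < 0.1) | (baf > 0.9)).mean() > 0.95

    def test_noncarriers_and_outside_unchanged(self, carriers_setup):
        truth, before, out, event = carriers_setup
        carriers = {c for c, k in truth.clone_of_cell.items() if k == event.clone}
        untouched = ~(out.cell.isin(carriers) & (out.pos < event.end))
        pd.testing.assert_frame_equal(out[untouched], before[untouched])
        # KS test: carrier BAF outside the interval looks like non-carrier BAF
        cell = sorted(carriers)[0]
        outside = out[(out.cell == cell) & (out.pos >= event.end)]
        tot = outside.ref_depth + outside.alt_depth
        baf_carrier = (outside.alt_depth / tot)[tot >= 10]
        other = out[(out.cell == "cell_0_0") & (out.pos >= event.end)]
        tot2 = other.ref_depth + other.alt_depth
        baf_other = (other.alt_depth / tot2)[tot2 >= 10]
        assert stats.ks_2samp(baf_carrier, baf_other).pvalue > 0.01

    def test_interval_without_het_sites_warns_noop(self, benchmark_truth, het_snps):
        truth, G = benchmark_truth
        depths = cs.simulate_wga_readcounts(G, cs.PTA_PROFILE,
                                            het_snp_positions=het_snps, seed=9)
        event = cs.CnvEvent(clone=7, chrom="chr99", start=0, end=100)
        with pytest.warns(UserWarning, match="no het site"):
            out = cs.inject_cnv(depths, truth, event)
        pd.testing.assert_frame_equal(out, depths)


class TestUmiFamilies:
    def test_zero_error_reads_identical(self):
        fs = cs.simulate_umi_families(0.5, 30, per_read_error=0.0, seed=0)[0]
        for fam in fs:
            assert len(set(fam.reads)) == 1

    def test_alt_molecule_fraction_binomial(self):
        """VAF=0.005 over 100k molecules: alt fraction within 3 binomial SE."""
        n = 100_000
        fs = cs.simulate_umi_families(
            0.005, n, reads_per_family_dist=lambda r, k: np.ones(k, int),
            per_read_error=0.0, seed=1)[0]
        frac = np.mean([f.true_allele == fs.alt_base for f in fs])
        se = np.sqrt(0.005 * 0.995 / n)
        assert abs(frac - 0.005) < 3 * se

    def test_negative_error_rejected(self):
        with pytest.raises(ValueError):
            cs.simulate_umi_families(0.1, 10, per_read_error=-0.1)

    def test_family_size_distribution_minimum_one(self, rng):
        sizes = default_family_size_dist(rng, 5000)
        assert sizes.min() >= 1


class TestPhenotypes:
    def test_zero_rate_zero_noise_constant(self, benchmark_truth):
        truth, _ = benchmark_truth
        ph = cs.simulate_phenotypes(truth.tree, 2, bm_rate=0.0, noise_sd=0.0,
                                    seed=0, root_value=3.5)
        assert np.allclose(ph.to_numpy(), 3.5)

    def test_bm_trait_covariance_tracks_shared_path(self, benchmark_truth):
        """Within-clone pairs (long shared path) correlate more than across."""
        truth, _ = benchmark_truth
        reps = [cs.simulate_phenotypes(truth.tree, 1, bm_rate=1.0, noise_sd=0.0,
                                       seed=s)["marker0"] for s in range(150)]
        X = pd.concat(reps, axis=1)
        same = X.loc["cell_7_0"].corr(X.loc["cell_7_1"])
        far = X.loc["cell_7_0"].corr(X.loc["cell_0_0"])
        assert same > far
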