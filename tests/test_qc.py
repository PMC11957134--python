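"""Per-cell QC estimators, clonal calling, hard filters, burden correction."""

import numpy as np
import pandas as pd
import pytest

import clonescope as cs
from clonescope.qc import DEFAULT_HARD_FILTER, HardFilterExpression


def depth_frame(ref, alt, chrom="chr1"):
    n = len(ref)
    return pd.DataFrame({"chrom": chrom, "pos": np.arange(n),
                         "ref_depth": ref, "alt_depth": alt})


class TestEstimateAdo:
    def test_six_of_hundred_single_allele(self):
        ref = [10] * 100
        alt = [10] * 94 + [0] * 6
        assert cs.estimate_ado(depth_frame(ref, alt)) == pytest.approx(0.06)

    def test_all_biallelic_zero(self):
        assert cs.estimate_ado(depth_frame([10] * 50, [8] * 50)) == 0.0

    def test_no_qualifying_sites_flagged_nan(self):
        with pytest.warns(UserWarning, match="ADO undefined"):
            out = cs.estimate_ado(depth_frame([1, 2], [1, 0]), min_depth=5)
        assert np.isnan(out)


class TestRecall:
    def test_fraction_of_het_sites_detected(self):
        het = pd.DataFrame({"chrom": "chr1", "pos": np.arange(100)})
        calls = depth_frame([10] * 100, [5] * 84 + [0] * 16)
        assert cs.estimate_recall_germline(calls, het) == pytest.approx(0.84)

    def test_no_dropout_no_filters_full_recall(self):
        het = cs.simulate_het_snp_positions(500, seed=0)
        G = pd.DataFrame(np.zeros((1, 1)), index=["c"], columns=["m"])
        prof = cs.WgaProfile(ado_rate=0.0, amp_error_rate=0.0,
                             imbalance_dispersion=0.0, mean_depth=40.0)
        d = cs.simulate_wga_readcounts(G, prof, het_snp_positions=het, seed=1)
        assert cs.estimate_recall_germline(d, het) == 1.0

    def test_empty_het_list_rejected(self):
        with pytest.raises(ValueError):
            cs.estimate_recall_germline(depth_frame([1], [1]),
                                        pd.DataFrame(columns=["chrom", "pos"]))


def phased_pairs(candidates):
    """Build a spanning-read table; candidates = {name: list of (het, snv) reads}."""
    rows = []
    for cand, reads in candidates.items():
        for h, s in reads:
            rows.append({"candidate": cand, "het_allele": h, "snv_allele": s})
    return pd.DataFrame(rows)


class TestPrecisionLinked:
    def test_all_two_haplotype_gives_one(self):
        good = [(0, 0)] * 5 + [(1, 1)] * 5
        df = phased_pairs({f"v{i}": good for i in range(10)})
        assert cs.estimate_precision_linked(df) == 1.0

    def test_nine_of_ten(self):
        good = [(0, 0)] * 5 + [(1, 1)] * 5
        bad = [(0, 0)] * 3 + [(0, 1)] * 3 + [(1, 1)] * 3 + [(1, 0)] * 3
        cands = {f"v{i}": good for i in range(9)}
        cands["v9"] = bad
        assert cs.estimate_precision_linked(phased_pairs(cands)) == pytest.approx(0.9)

    def test_synthetic_mixture_recovers_truth_within_3_points(self, rng):
        """92% true sSNVs + 8% WGA errors on both haplotypes."""
        n_cand, depth = 600, 20
        truth_frac = 0.92
        cands = {}
        for i in range(n_cand):
            is_true = rng.random() < truth_frac
            reads = []
            for _ in range(depth):
                h = int(rng.random() < 0.5)
                if is_true:
                    s = int(h == 1)  # alt rides haplotype 1 only
                else:
                    s = int(rng.random() < 0.4)  # error on both haplotypes
                reads.append((h, s))
            cands[f"v{i}"] = reads
        est = cs.estimate_precision_linked(phased_pairs(cands))
        assert abs(est - truth_frac) < 0.03

    def test_no_assessable_flagged(self):
        df = phased_pairs({"v0": [(0, 1)] * 2})  # one het allele only
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(cs.estimate_precision_linked(df))


class TestFalseHet:
    def test_zero_and_small_counts(self):
        calls = depth_frame([20] * 3000, [0] * 3000, chrom="chr21")
        rate, baf = cs.estimate_false_het(calls, ("chr21", 0, 3000))
        assert rate == 0.0 and len(baf) == 0
        calls.loc[:2, "alt_depth"] = 5
        rate, baf = cs.estimate_false_het(calls, ("chr21", 0, 3000))
        assert rate == pytest.approx(3 / 3000)

    def test_amp_error_false_hets_concentrate_at_low_baf(self):
        """Polymerase-error het calls sit well below BAF 0.5."""
        het = cs.simulate_het_snp_positions(30000, chrom="chr21", seed=2)
        # hemizygous/homozygous region: hom-ref genotypes with high error
        prof = cs.WgaProfile(ado_rate=0.0, amp_error_rate=0.01,
                             imbalance_dispersion=0.01, mean_depth=60.0)
        geno = pd.DataFrame(np.zeros((1, len(het))), index=["c"],
                            columns=[f"s{i}" for i in range(len(het))])
        d = cs.simulate_wga_readcounts(geno, prof, seed=3)
        calls = pd.DataFrame({"chrom": "chr21", "pos": het["pos"].to_numpy(),
                              "ref_depth": d["ref_depth"].to_numpy(),
                              "alt_depth": d["alt_depth"].to_numpy()})
        rate, baf = cs.estimate_false_het(calls, ("chr21", 0, int(het.pos.max()) + 1))
        assert rate > 0
        assert baf.median() < 0.2

    def test_absent_region_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            cs.estimate_false_het(depth_frame([1], [1]), ("chrX", 0, 10))


class TestClonalCalling:
    def test_two_of_three_retained_one_dropped(self):
        calls = {"c1": {"A", "B"}, "c2": {"A"}, "c3": {"C"}}
        out = cs.call_clonal_mutations(calls)
        assert out == {"A"}

    def test_germline_and_normal_cells_removed(self):
        calls = {"c1": {"A", "B", "C"}, "c2": {"A", "B", "C"}}
        out = cs.call_clonal_mutations(calls, bulk_germline={"B"},
                                       normal_cell_calls={"n1": {"C"}})
        assert out == {"A"}

    def test_single_cell_clone_rejected(self):
        with pytest.raises(ValueError):
            cs.call_clonal_mutations({"c1": {"A"}})

    def test_extremes_reduce_to_intersection_and_union(self, rng):
        """min_concordant = clone size -> intersection; 1 -> union."""
        universe = list("ABCDEFGHIJ")
        for _ in range(20):
            cells = {f"c{i}": {v for v in universe if rng.random() < 0.5}
                     for i in range(4)}
            inter = set.intersection(*cells.values())
            union = set.union(*cells.values())
            assert cs.call_clonal_mutations(cells, min_concordant=4) == inter
            assert cs.call_clonal_mutations(cells, min_concordant=1) == union


class TestHardFilters:
    def test_boundary_strictness(self):
        rec = pd.DataFrame({"QD": [1.9, 2.0, 30.0], "FS": [0.0, 0.0, 80.0]})
        out = cs.apply_hard_filters(rec, "QD < 2.0 || FS > 60.0")
        assert list(out.index) == [1]  # QD=2.0 kept (strict <); FS=80 removed

    def test_round_trip_on_canonical_expression(self):
        s = ("QD < 2.0 || FS > 60.0 || MQ < 40.0 || HaplotypeScore > 13.0 || "
             "MQRankSum < -12.5 || ReadPosRankSum < -8.0")
        assert str(HardFilterExpression.parse(s)) == s
        assert str(DEFAULT_HARD_FILTER) == s

    def test_missing_metric_clause_skipped_with_warning(self):
        rec = pd.DataFrame({"QD": [1.0]})
        with pytest.warns(UserWarning, match="missing"):
            out = cs.apply_hard_filters(rec, "FS > 60.0")
        assert len(out) == 1

    def test_unparsable_expression_positional_error(self):
        with pytest.raises(ValueError, match="clause #2"):
            HardFilterExpression.parse("QD < 2.0 || nonsense")


class TestBurden:
    def test_linear_subtraction(self):
        out = cs.estimate_burden({"t1": 1.2}, [0.2], callable_mb=1.0)
        assert out.loc["t1", "corrected"] == pytest.approx(1.0)
        out = cs.estimate_burden({"t1": 0.2}, [0.1, 0.3], callable_mb=1.0)
        assert out.loc["t1", "corrected"] == pytest.approx(0.0)

    def test_negative_correction_warns(self):
        with pytest.warns(UserWarning, match="over-correction"):
            out = cs.estimate_burden({"t1": 0.1}, [0.5])
        assert out.loc["t1", "corrected"] < 0

    def test_generative_artifact_subtraction(self, rng):
        """Tumor cells with ~3553 true + ~200 artifact calls vs 200-artifact normals."""
        tumors = {f"t{i}": 3553 + rng.poisson(200) for i in range(5)}
        normals = rng.poisson(200, size=3)
        out = cs.estimate_burden(tumors, normals)
        assert out["corrected"].mean() == pytest.approx(3553, rel=0.02)
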