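"""Instrument QC chain: p-filter, region exclusion, clumping, F-filter."""

import numpy as np
import pytest

from mrpath import (ClumpConfig, LdMatrix, MHC_REGION, exclude_region,
                    f_statistic, filter_pvalue, filter_weak, ld_clump,
                    select_instruments)
from mrpath.simulate import SimConfig, simulate_ld, simulate_triplet
from conftest import make_snp
from oracles import clump_by_rebuild, clump_is_valid


class TestFilterPvalue:
    def test_strict_inequality_at_boundary(self):
        snps = [make_snp(snp_id="a", pval=1e-6), make_snp(snp_id="b", pval=2e-5),
                make_snp(snp_id="c", pval=1e-5)]
        kept = filter_pvalue(snps, 1e-5)
        assert [s.snp_id for s in kept] == ["a"]

    def test_permissive_threshold_keeps_sub_unity(self):
        snps = [make_snp(snp_id="a", pval=0.5), make_snp(snp_id="b", pval=0.999)]
        assert len(filter_pvalue(snps, 1.0)) == 2

    def test_empty_input(self):
        assert filter_pvalue([], 1e-5) == []


class TestExcludeRegion:
    def test_mhc_snp_removed(self):
        snp = make_snp(chrom="6", pos=30_000_000)
        assert exclude_region([snp], MHC_REGION) == []

    def test_one_below_start_retained(self):
        snp = make_snp(chrom="6", pos=28_477_896)
        assert exclude_region([snp], MHC_REGION) == [snp]

    def test_boundary_positions_inclusive(self):
        inside = [make_snp(chrom="6", pos=28_477_897),
                  make_snp(chrom="6", pos=33_448_354)]
        assert exclude_region(inside, MHC_REGION) == []

    def test_chromosome_mismatch_retained(self):
        snp = make_snp(chrom="7", pos=30_000_000)
        assert exclude_region([snp], MHC_REGION) == [snp]


class TestFStatistic:
    def test_direct_formula(self):
        assert f_statistic(make_snp(beta=0.1, se=0.02)) == pytest.approx(25.0)

    def test_zero_beta(self):
        assert f_statistic(make_snp(beta=0.0)) == 0.0

    def test_threshold_is_strict(self):
        # beta=0.0632, se=0.02 -> F = 9.9856 < 10: removed
        near = make_snp(snp_id="near", beta=0.0632, se=0.02)
        strong = make_snp(snp_id="strong", beta=0.1, se=0.02)
        assert f_statistic(near) == pytest.approx(9.9856)
        kept = filter_weak([near, strong], min_f=10.0)
        assert [s.snp_id for s in kept] == ["strong"]

    def test_filter_weak_matches_rowwise_recomputation(self, rng):
        snps = [make_snp(snp_id=f"s{i}", beta=float(b), se=float(s))
                for i, (b, s) in enumerate(zip(rng.normal(0, 0.1, 30),
                                               rng.uniform(0.01, 0.05, 30)))]
        kept = {s.snp_id for s in filter_weak(snps, 10.0)}
        oracle = {s.snp_id for s in snps if s.beta ** 2 / s.se ** 2 > 10.0}
        assert kept == oracle

    def test_min_f_zero_keeps_nonzero_betas(self):
        snps = [make_snp(snp_id=f"s{i}", beta=0.01 * (i + 1)) for i in range(3)]
        assert len(filter_weak(snps, 0.0)) == 3


class TestLdClump:
    def test_independent_snps_all_retained(self):
        snps = [make_snp(snp_id=f"s{i}", pos=1000 + i, pval=10 ** -(6 + i))
                for i in range(3)]
        ld = LdMatrix.identity([s.snp_id for s in snps])
        assert len(ld_clump(snps, ld)) == 3

    def test_correlated_pair_prunes_weaker(self):
        a = make_snp(snp_id="a", pos=1000, pval=1e-8)
        b = make_snp(snp_id="b", pos=2000, pval=1e-6)
        ld = LdMatrix(["a", "b"], [[1.0, 0.9], [0.9, 1.0]])
        kept = ld_clump([b, a], ld, window_kb=10, r2_max=0.001)
        assert [s.snp_id for s in kept] == ["a"]

    def test_window_limits_pruning(self):
        # high r^2 but 20 Mb apart with a 10 Mb window: both kept
        a = make_snp(snp_id="a", pos=1_000_000, pval=1e-8)
        b = make_snp(snp_id="b", pos=21_000_000, pval=1e-6)
        ld = LdMatrix(["a", "b"], [[1.0, 0.9], [0.9, 1.0]])
        assert len(ld_clump([a, b], ld, window_kb=10_000, r2_max=0.001)) == 2

    def test_strict_mode_missing_snp_errors(self):
        a = make_snp(snp_id="a", pos=1000, pval=1e-8)
        b = make_snp(snp_id="b", pos=2000, pval=1e-6)
        ld = LdMatrix.identity(["a"])
        with pytest.raises(KeyError):
            ld_clump([a, b], ld, strict=True)
        assert len(ld_clump([a, b], ld, strict=False)) == 2

    def test_ar1_block_against_brute_force(self):
        cfg = SimConfig(seed=11, n_snp=5, ld_block_size=5, ld_rho=0.99,
                        gamma_sd=0.3)
        exposure, _, _, _ = simulate_triplet(cfg)
        panel = [s for s in exposure if s.chrom == "1"]
        ld = simulate_ld(cfg)
        kept = ld_clump(panel, ld, window_kb=10_000, r2_max=0.001)
        assert len(kept) == 1  # one survivor per tight block
        discarded = [s for s in panel if s not in kept]
        assert clump_is_valid(kept, discarded, ld, 10_000, 0.001)

    def test_deterministic_under_input_permutation(self, rng):
        snps = [make_snp(snp_id=f"s{i}", pos=1000 * i + 1,
                         pval=float(p)) for i, p in enumerate(rng.uniform(0, 1e-4, 10))]
        ld = LdMatrix.identity([s.snp_id for s in snps])
        ref = ld_clump(snps, ld)
        for _ in range(3):
            perm = list(rng.permutation(len(snps)))
            assert ld_clump([snps[i] for i in perm], ld) == ref

    def test_random_instances_match_rebuild_oracle(self, rng):
        """Greedy result equals an independent reimplementation and passes
        exhaustive pairwise verification on random instances, J <= 12."""
        for trial in range(60):
            j = int(rng.integers(2, 13))
            n_block = int(rng.integers(1, j + 1))
            rho = float(rng.uniform(0, 0.999))
            cfg = SimConfig(seed=int(rng.integers(2 ** 31)), n_snp=j,
                            ld_block_size=n_block, ld_rho=rho, gamma_sd=0.3)
            exposure, _, _, _ = simulate_triplet(cfg)
            panel = [s for s in exposure if s.chrom == "1"]
            ld = simulate_ld(cfg)
            window = float(rng.choice([1.0, 10.0, 10_000.0]))
            r2max = float(rng.choice([0.001, 0.1, 0.5]))
            kept = ld_clump(panel, ld, window_kb=window, r2_max=r2max)
            assert kept == clump_by_rebuild(panel, ld, window, r2max)
            discarded = [s for s in panel if s not in kept]
            assert clump_is_valid(kept, discarded, ld, window, r2max)


class TestChainAndConfig:
    def test_stage_counts_monotone(self, rng):
        cfg = SimConfig(seed=5, n_snp=30, gamma_sd=0.2, ld_block_size=3,
                        ld_rho=0.9)
        exposure, _, _, _ = simulate_triplet(cfg)
        ld = simulate_ld(cfg)
        _, counts = select_instruments(exposure, ld, ClumpConfig())
        vals = list(counts.values())
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_config_validation(self):
        with pytest.raises(Exception):
            ClumpConfig(p_threshold=0.0)
        with pytest.raises(Exception):
            ClumpConfig(r2_max=1.0)

    def test_config_from_yaml(self, tmp_path):
        p = tmp_path / "clump.yaml"
        p.write_text("p_threshold: 5.0e-5\nwindow_kb: 1000\nmhc_region: [6, 28477897, 33448354]\n")
        cfg = ClumpConfig.from_file(p)
        assert cfg.p_threshold == 5e-5 and cfg.window_kb == 1000
        assert cfg.mhc_region == ("6", 28477897, 33448354)

    def test_ld_pairs_tsv_roundtrip(self, tmp_path):
        ld = LdMatrix(["a", "b", "c"],
                      [[1.0, 0.5, 0.0], [0.5, 1.0, 0.2], [0.0, 0.2, 1.0]])
        path = tmp_path / "ld.tsv"
        ld.to_pairs_tsv(path)
        back = LdMatrix.from_pairs_tsv(path, snp_ids=["a", "b", "c"])
        np.testing.assert_allclose(back.r2, ld.r2)
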