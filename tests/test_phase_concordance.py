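"""Switch-error statistics: orientation, switches, MAF binning, pair parity."""

import numpy as np
import pytest

from haplobench.allele_freq import OVERALL5, FrequencyTable
from haplobench.model import Callset, GenotypeCall, VariantSite
from haplobench.phase_concordance import (
    PhasedSegmentPair,
    comparable_segments,
    pair_discordance_by_rank,
    pair_parity_error_by_distance,
    relative_orientation,
    switch_error,
    switch_error_by_maf,
    total_switch_error,
)
from haplobench.synthetic_data import CorruptionConfig, corrupt

from conftest import flipped_segment, make_het_truth


def _segment(truth_orient, test_orient, positions=None):
    n = len(truth_orient)
    positions = positions or [10 * (i + 1) for i in range(n)]
    sites = [VariantSite("chr1", p, "A", "G") for p in positions]
    return PhasedSegmentPair(
        chrom="chr1",
        phase_set=1,
        sites=sites,
        truth_orient=np.asarray(truth_orient, dtype=np.int8),
        test_orient=np.asarray(test_orient, dtype=np.int8),
    )


class TestRelativeOrientation:
    def test_identical_phasing_all_same(self):
        seg = _segment([0, 1, 0], [0, 1, 0])
        assert relative_orientation(seg).tolist() == [0, 0, 0]

    def test_global_swap_all_flipped_no_switches(self):
        seg = _segment([0, 1, 0], [1, 0, 1])
        assert relative_orientation(seg).tolist() == [1, 1, 1]
        assert switch_error(seg).n_switches == 0

    def test_xor_example(self):
        seg = _segment([0, 0, 1], [0, 1, 1])
        assert relative_orientation(seg).tolist() == [0, 1, 0]


class TestSwitchError:
    def test_flip_from_third_of_five(self):
        seg = _segment([0] * 5, [0, 0, 1, 1, 1])
        res = switch_error(seg)
        assert res.n_switches == 1
        assert res.n_comparable_boundaries == 4
        assert res.rate == pytest.approx(0.25)

    def test_alternating_flip_rate_one(self):
        seg = _segment([0] * 6, [0, 1, 0, 1, 0, 1])
        res = switch_error(seg)
        assert res.rate == 1.0

    def test_out_of_phase_run_flanking_hets(self):
        # agreement [same, flipped, flipped, same]: 2 switches, flanks 1-4
        seg = _segment([0, 0, 0, 0], [0, 1, 1, 0])
        res = switch_error(seg)
        assert res.n_switches == 2
        keys = {k[1] for k in res.switch_site_keys}
        assert keys == {10, 20, 30, 40}
        assert len(res.switch_site_keys) <= 2 * res.n_switches

    def test_run_touching_segment_edge_contributes_interior_flank_only(self):
        # agreement [flipped, flipped, same]: one switch, between sites 2-3
        seg = _segment([0, 0, 0], [1, 1, 0])
        res = switch_error(seg)
        assert res.n_switches == 1
        assert {k[1] for k in res.switch_site_keys} == {20, 30}


class TestTotalSwitchError:
    def _pair(self):
        # 6 truth SNPs: 5 comparable hets (one switch among 4 boundaries)
        # plus one hom-alt site that never enters phase comparison
        sites = [VariantSite("chr1", p, "A", "G") for p in range(10, 70, 10)]
        truth_genos = [
            GenotypeCall(0, 1, phased=True, phase_set=1) for _ in range(5)
        ] + [GenotypeCall(1, 1, phased=True, phase_set=1)]
        truth = Callset("T", sites, truth_genos)
        test_orient = [0, 0, 0, 1, 1]  # one switch at boundary 3-4
        test_genos = [
            GenotypeCall(o, 1 - o, phased=True) for o in test_orient
        ] + [GenotypeCall(1, 1, phased=True)]
        test = Callset("T", sites, test_genos)
        return truth, test

    def test_caption_and_conventional_denominators(self):
        truth, test = self._pair()
        res = total_switch_error(truth, test)
        assert res.n_switches == 1
        assert res.caption_rate == pytest.approx(1 / 6)
        assert res.conventional_rate == pytest.approx(1 / 4)

    def test_zero_switches_zero_under_both(self):
        truth, _ = self._pair()
        res = total_switch_error(truth, truth)
        assert res.n_switches == 0
        assert res.caption_rate == 0 and res.conventional_rate == 0

    def test_caption_arithmetic_on_synthetic_counts(self):
        truth = make_het_truth(400, seed=21)
        flips = np.zeros(400, dtype=bool)
        flips[200:] = True  # a single long-range switch
        test = flipped_segment(truth, flips)
        res = total_switch_error(truth, test)
        assert res.n_switches == 1
        assert res.caption_rate == pytest.approx(1 / 400)

    def test_genotype_discordant_sites_excluded_from_phasing(self):
        truth, test = self._pair()
        # make one comparable het genotype-discordant in test: drops a boundary
        test.genotypes[0] = GenotypeCall(1, 1, phased=True)
        test._calls = None
        res = total_switch_error(truth, test)
        assert res.n_comparable_hets == 4
        assert res.n_comparable_boundaries == 3


class TestSwitchErrorByMaf:
    def _freqs(self, sites, mafs):
        return FrequencyTable(sites, {"ALL": np.asarray(mafs)})

    def test_no_switches_all_bins_zero(self):
        truth = make_het_truth(50, seed=1)
        test = flipped_segment(truth, np.zeros(50, dtype=bool))
        freqs = self._freqs(truth.sites, np.full(50, 0.1))
        table = switch_error_by_maf(truth, test, freqs, OVERALL5)
        assert table.overall_errors == 0
        assert table.n_total.sum() == 50

    def test_single_switch_bins_both_flanking_hets(self):
        truth = make_het_truth(2, seed=2)
        test = flipped_segment(truth, np.array([False, True]))
        freqs = self._freqs(truth.sites, [0.003, 0.2])
        table = switch_error_by_maf(truth, test, freqs, OVERALL5)
        errs = dict(zip(table.labels, table.n_errors))
        assert errs["0.2-0.5%"] == 1
        assert errs[">=5%"] == 1

    def test_rare_only_flips_confined_to_low_bins(self):
        n = 2000
        truth = make_het_truth(n, seed=3)
        rng = np.random.default_rng(4)
        maf = np.where(rng.random(n) < 0.05, 0.001, 0.3)
        # flip isolated rare hets; each out-of-phase run also drags its two
        # (mostly common) neighbours in, so the contrast rests on the much
        # smaller rare denominator
        flips = np.zeros(n, dtype=bool)
        rare_idx = np.flatnonzero(maf == 0.001)[::2]
        flips[rare_idx] = True
        test = flipped_segment(truth, flips)
        freqs = self._freqs(truth.sites, maf)
        table = switch_error_by_maf(truth, test, freqs, OVERALL5)
        rates = dict(zip(table.labels, table.rate))
        assert rates["0.0-0.2%"] > 5 * rates[">=5%"]

    def test_invariant_maf_excluded_with_warning(self):
        truth = make_het_truth(3, seed=5)
        test = flipped_segment(truth, np.zeros(3, dtype=bool))
        freqs = self._freqs(truth.sites, [0.0, 0.1, 0.1])
        with pytest.warns(UserWarning, match="MAF = 0"):
            table = switch_error_by_maf(truth, test, freqs, OVERALL5)
        assert table.n_total.sum() == 2


class TestPairParity:
    def test_zero_intermediate_switches_concordant(self):
        truth = make_het_truth(10, seed=6)
        test = flipped_segment(truth, np.zeros(10, dtype=bool))
        res = pair_parity_error_by_distance(truth, test, [1, 10**8])
        assert res.n_discordant.sum() == 0
        assert res.n_pairs.sum() == 45

    def test_parity_equals_xor_identity(self):
        # agreement [same, flipped, same]: (1,3) concordant, others not
        truth = make_het_truth(3, seed=7)
        test = flipped_segment(truth, np.array([False, True, False]))
        res = pair_parity_error_by_distance(truth, test, [1, 10**8])
        assert res.n_pairs.sum() == 3
        assert res.n_discordant.sum() == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_prefix_parity_agrees_with_xor_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 51))
        truth = make_het_truth(n, seed=seed + 100)
        test = flipped_segment(truth, rng.random(n) < 0.3)
        df = pair_discordance_by_rank(truth, test, max_rank=n - 1)
        (seg,) = comparable_segments(truth, test)
        a = relative_orientation(seg)
        for k in range(1, n):
            oracle = int(np.sum(a[:-k] != a[k:]))
            assert df.loc[df["k"] == k, "n_discordant"].item() == oracle

    def test_boundary_toggle_distance_decay(self):
        n = 20_000
        truth = make_het_truth(n, seed=8, span=2 * 10**7)
        s = 0.05
        test = corrupt(
            truth, truth.sites, CorruptionConfig(switch_rate=s, seed=9)
        )
        df = pair_discordance_by_rank(truth, test, max_rank=60)
        # non-decreasing in expectation, converging to 1/2
        assert df["rate"].iloc[0] < df["rate"].iloc[-1]
        assert abs(df["rate"].iloc[-1] - 0.5) < 0.1
        q = (1 - (1 - 2 * s) ** df["k"]) / 2
        assert np.max(np.abs(df["rate"] - q)) < 0.05

    def test_subsampling_cap_is_seeded(self):
        truth = make_het_truth(200, seed=10)
        test = flipped_segment(
            truth, np.random.default_rng(11).random(200) < 0.2
        )
        kwargs = dict(distance_edges=[1, 10**8], max_pairs_per_segment=500)
        r1 = pair_parity_error_by_distance(truth, test, seed=1, **kwargs)
        r2 = pair_parity_error_by_distance(truth, test, seed=1, **kwargs)
        assert np.array_equal(r1.n_discordant, r2.n_discordant)
        assert r1.n_pairs.sum() == 500


class TestRecovery:
    def test_independent_flip_rate(self):
        n = 15_000
        truth = make_het_truth(n, seed=12)
        p = 0.05
        cfg = CorruptionConfig(
            switch_mode="independent_flip", flip_prob=p, seed=13
        )
        test = corrupt(truth, truth.sites, cfg)
        res = total_switch_error(truth, test)
        expected = 2 * p * (1 - p)
        se = np.sqrt(expected * (1 - expected) / res.n_comparable_boundaries)
        assert abs(res.conventional_rate - expected) < 3 * se

    def test_boundary_toggle_rate(self):
        n = 15_000
        truth = make_het_truth(n, seed=14)
        s = 0.03
        test = corrupt(
            truth, truth.sites, CorruptionConfig(switch_rate=s, seed=15)
        )
        res = total_switch_error(truth, test)
        se = np.sqrt(s * (1 - s) / res.n_comparable_boundaries)
        assert abs(res.conventional_rate - s) < 3 * se

    def test_global_label_swap_invariance(self):
        truth = make_het_truth(500, seed=16)
        rng = np.random.default_rng(17)
        test = flipped_segment(truth, rng.random(500) < 0.1)
        swapped = flipped_segment(test, np.ones(500, dtype=bool))
        for t in (test, swapped):
            res = total_switch_error(truth, t)
            assert res.n_switches == total_switch_error(truth, test).n_switches
        r1 = pair_parity_error_by_distance(truth, test, [1, 10**8])
        r2 = pair_parity_error_by_distance(truth, swapped, [1, 10**8])
        assert np.array_equal(r1.n_discordant, r2.n_discordant)
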