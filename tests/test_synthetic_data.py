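"""Generator properties: determinism, limit cases and parameter recovery."""

import json

import numpy as np
import pytest
from scipy import stats

from haplobench.allele_freq import compute_frequency_table
from haplobench.synthetic_data import (
    CorruptionConfig,
    SimulationConfig,
    corrupt,
    make_fixture_suite,
    sample_truth,
    simulate_panel,
)
from haplobench.vcf_io import read_callset, read_panel


class TestSimulatePanel:
    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(n_haplotypes=40, n_sites=200, seed=5)
        p1, p2 = simulate_panel(cfg), simulate_panel(cfg)
        assert np.array_equal(p1.alleles, p2.alleles)
        assert [s.pos for s in p1.sites] == [s.pos for s in p2.sites]

    def test_no_copying_every_haplotype_is_a_founder(self):
        cfg = SimulationConfig(
            n_haplotypes=40,
            n_sites=100,
            copy_switch_rate=0.0,
            mutation_rate=0.0,
            n_founders=4,
            n_groups=1,
            seed=6,
        )
        panel = simulate_panel(cfg)
        founders = panel.alleles[:4]
        for row in panel.alleles[4:]:
            assert any(np.array_equal(row, f) for f in founders)

    def test_full_switching_decorrelates_neighbours(self):
        # with rho=1 each site copies an independent template
        cfg = SimulationConfig(
            n_haplotypes=200,
            n_sites=500,
            copy_switch_rate=1.0,
            n_founders=10,
            n_groups=1,
            group_drift=0.0,
            seed=7,
        )
        panel = simulate_panel(cfg)
        x = panel.alleles[10:].astype(float)  # non-founder haplotypes
        keep = (x.std(axis=0) > 0).nonzero()[0]
        r = [
            abs(np.corrcoef(x[:, i], x[:, j])[0, 1])
            for i, j in zip(keep[:-1], keep[1:])
        ]
        assert np.mean(r) < 0.2

    def test_low_switching_builds_more_ld_than_high(self):
        def mean_adjacent_r(rho):
            cfg = SimulationConfig(
                n_haplotypes=200,
                n_sites=500,
                copy_switch_rate=rho,
                mutation_rate=0.0,
                n_founders=6,
                n_groups=1,
                group_drift=0.0,
                seed=8,
            )
            panel = simulate_panel(cfg)
            x = panel.alleles[6:].astype(float)
            keep = (x.std(axis=0) > 0).nonzero()[0]
            return np.mean(
                [
                    abs(np.corrcoef(x[:, i], x[:, j])[0, 1])
                    for i, j in zip(keep[:-1], keep[1:])
                ]
            )

        assert mean_adjacent_r(0.001) > 2 * mean_adjacent_r(1.0)

    def test_sfs_matches_configured_spectrum(self):
        # the drawn target counts are an exact multinomial from the 1/i
        # spectrum: chi-square over pooled count classes must not reject
        h = 20
        cfg = SimulationConfig(n_haplotypes=h, n_sites=10_000, seed=9)
        panel = simulate_panel(cfg)
        counts = np.rint(panel.target_aaf * h).astype(int)
        w = 1.0 / np.arange(1, h)
        w /= w.sum()
        observed = np.bincount(counts, minlength=h)[1:h]
        res = stats.chisquare(observed, w * len(counts))
        assert res.pvalue > 0.01

    def test_realized_frequencies_track_targets(self):
        cfg = SimulationConfig(n_haplotypes=400, n_sites=2000, seed=10)
        panel = simulate_panel(cfg)
        realized = panel.alleles.mean(axis=0)
        r = np.corrcoef(realized, panel.target_aaf)[0, 1]
        assert r > 0.95

    def test_group_structure(self, small_panel):
        assert small_panel.groups() == ["POP1", "POP2"]
        ft = compute_frequency_table(small_panel)
        assert set(ft.groups) == {"POP1", "POP2", "ALL"}

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_haplotypes=41)
        with pytest.raises(ValueError):
            SimulationConfig(copy_switch_rate=1.5)


class TestSampleTruth:
    def test_homref_sites_absent(self, small_panel, small_truth):
        for _, g in small_truth:
            assert not g.is_hom_ref

    def test_infinite_block_length_single_phase_set(self, small_panel):
        truth = sample_truth(small_panel, phase_block_mean_len=np.inf, seed=1)
        assert len({g.phase_set for g in truth.genotypes}) == 1

    def test_finite_blocks_create_multiple_phase_sets(self, small_truth):
        assert len({g.phase_set for g in small_truth.genotypes}) > 1

    def test_expected_callset_size(self, deep_panel):
        # P(non-homref) per site from realized panel frequencies under
        # random mating of two copied haplotypes
        p = deep_panel.alleles.mean(axis=0)
        expected = np.sum(1 - (1 - p) ** 2)
        var = np.sum((1 - (1 - p) ** 2) * (1 - p) ** 2)
        sizes = [
            len(sample_truth(deep_panel, 100_000, seed=s, mutation_rate=0.0))
            for s in range(3)
        ]
        assert abs(np.mean(sizes) - expected) < 3 * np.sqrt(var)

    def test_deterministic(self, small_panel):
        t1 = sample_truth(small_panel, 50_000, seed=3)
        t2 = sample_truth(small_panel, 50_000, seed=3)
        assert [s.key for s in t1.sites] == [s.key for s in t2.sites]
        assert t1.genotypes == t2.genotypes


class TestCorrupt:
    def test_zero_rates_identity_with_homref_fill(self, small_panel, small_truth):
        cfg = CorruptionConfig(info_score_model=None, seed=0)
        test = corrupt(small_truth, small_panel.sites, cfg)
        assert len(test) == len(small_panel.sites)
        truth_calls = small_truth.calls
        for s, g in test:
            t = truth_calls.get(s.key)
            if t is None:
                assert g.is_hom_ref
            else:
                assert {g.allele_a, g.allele_b} == {t.allele_a, t.allele_b}

    def test_genotype_error_recovery(self):
        from conftest import make_het_truth

        truth = make_het_truth(20_000, seed=4)
        g = 0.05
        test = corrupt(
            truth, truth.sites, CorruptionConfig(genotype_error_rate=g, seed=5)
        )
        mismatches = sum(
            1
            for (s, t), (_, c) in zip(truth, test)
            if t.gt_class != c.gt_class
        )
        se = np.sqrt(g * (1 - g) / len(truth))
        assert abs(mismatches / len(truth) - g) < 3 * se

    def test_dropout_removes_sites(self, small_panel, small_truth):
        cfg = CorruptionConfig(dropout_rate=0.3, seed=6)
        test = corrupt(small_truth, small_panel.sites, cfg)
        frac = len(test) / len(small_panel.sites)
        assert 0.6 < frac < 0.8

    def test_info_scores_lower_on_errors(self, small_panel, small_truth):
        cfg = CorruptionConfig(genotype_error_rate=0.3, seed=7)
        test = corrupt(small_truth, small_panel.sites, cfg)
        truth_calls = small_truth.calls
        err_scores, ok_scores = [], []
        for s, g in test:
            t = truth_calls.get(s.key)
            t_cls = t.gt_class if t is not None else "homref"
            (err_scores if g.gt_class != t_cls else ok_scores).append(
                g.info_score
            )
        assert np.mean(err_scores) < np.mean(ok_scores)

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            CorruptionConfig(genotype_error_rate=1.2)
        with pytest.raises(ValueError):
            CorruptionConfig(class_rates={"het": {"homref": 0.8, "homalt": 0.5}})
        with pytest.raises(ValueError):
            CorruptionConfig(switch_mode="sideways")


class TestFixtureSuite:
    def test_small_suite_roundtrips(self, tmp_path):
        manifest = make_fixture_suite(tmp_path / "fx", scale="small", seed=3)
        panel = read_panel(tmp_path / "fx" / "panel.vcf", tmp_path / "fx" / "groups.tsv")
        assert panel.n_sites == manifest["simulation"]["n_sites"]
        for ind in manifest["individuals"]:
            truth = read_callset(tmp_path / "fx" / ind["truth_vcf"], ind["sample"])
            assert len(truth) == ind["n_truth_sites"]
            test = read_callset(tmp_path / "fx" / ind["test_vcf"], ind["sample"])
            assert len(test) > 0
            assert any(g.info_score is not None for g in test.genotypes)

    def test_manifest_rates_recoverable(self, tmp_path):
        from haplobench.allele_freq import CONTINENT6, compute_frequency_table
        from haplobench.genotype_concordance import genotype_error

        make_fixture_suite(tmp_path / "fx", scale="standard", seed=4)
        with open(tmp_path / "fx" / "manifest.json") as fh:
            manifest = json.load(fh)
        panel = read_panel(tmp_path / "fx" / "panel.vcf", tmp_path / "fx" / "groups.tsv")
        freqs = compute_frequency_table(panel)
        g = manifest["corruption"]["genotype_error_rate"]
        rates = []
        n = 0
        for ind in manifest["individuals"]:
            truth = read_callset(tmp_path / "fx" / ind["truth_vcf"], ind["sample"])
            test = read_callset(tmp_path / "fx" / ind["test_vcf"], ind["sample"])
            # dropped-out sites must not count as hom-ref miscalls here
            table = genotype_error(
                truth, test, "all_sites", freqs, CONTINENT6,
                missing_site_policy="exclude",
            )
            rates.append(table.overall_rate)
            n += table.overall_total
        se = np.sqrt(g * (1 - g) / n)
        assert abs(np.mean(rates) - g) < 3 * se

    def test_same_seed_byte_identical(self, tmp_path):
        make_fixture_suite(tmp_path / "a", scale="small", seed=9)
        make_fixture_suite(tmp_path / "b", scale="small", seed=9)
        for name in ("manifest.json", "panel.vcf", "truth_IND0.vcf", "test_IND0.vcf"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_unknown_scale(self, tmp_path):
        with pytest.raises(ValueError, match="scale"):
            make_fixture_suite(tmp_path, scale="huge")
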