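"""Shared fixtures: toy VCFs and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from haplobench.model import Callset, GenotypeCall, VariantSite
from haplobench.synthetic_data import SimulationConfig, sample_truth, simulate_panel

# Six records exercising one filter rule each: the first survives everything.
TOY_VCF = "\n".join(
    [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=100000>",
        "##contig=<ID=chrX,length=100000>",
        '##FILTER=<ID=q10,Description="low quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1",
        "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:PS\t0|1:7",
        "chr1\t200\t.\tA\tG,T\t.\tPASS\t.\tGT\t1|2",
        "chr1\t300\t.\tAT\tA\t.\tPASS\t.\tGT\t0|1",
        "chr1\t400\t.\tC\tT\t.\tq10\t.\tGT\t0|1",
        "chr1\t500\t.\tC\tT\t.\tPASS\t.\tGT\t0/1",
        "chrX\t600\t.\tG\tA\t.\tPASS\t.\tGT\t1|1",
    ]
) + "\n"


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture(scope="session")
def small_panel():
    cfg = SimulationConfig(
        n_haplotypes=60, n_sites=400, chrom_length=500_000, seed=11
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_truth(small_panel):
    return sample_truth(small_panel, phase_block_mean_len=50_000, seed=12)


@pytest.fixture(scope="session")
def deep_panel():
    """2,000 haplotypes: deep enough to segregate genuinely rare variants
    (MAF down to 5e-4), as rare-variant metrics require."""
    cfg = SimulationConfig(
        n_haplotypes=2000, n_sites=4000, chrom_length=4_000_000, seed=42
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def deep_truth(deep_panel):
    return sample_truth(deep_panel, phase_block_mean_len=100_000, seed=43)


def make_het_truth(
    n: int,
    seed: int = 0,
    chrom: str = "chr1",
    phase_set: int = 1,
    span: int = 10_000_000,
) -> Callset:
    """An all-het phased truth callset with random orientations: the
    minimal substrate for phase-error statistics."""
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(span, size=n, replace=False) + 1)
    sites = [VariantSite(chrom, int(p), "A", "G") for p in positions]
    genos = [
        GenotypeCall(int(o), 1 - int(o), phased=True, phase_set=phase_set)
        for o in rng.integers(0, 2, size=n)
    ]
    return Callset("HETS", sites, genos)


def flipped_segment(truth: Callset, flip_mask) -> Callset:
    """Copy of an all-het callset with orientations flipped where masked;
    chromosome-wide phasing (no PS)."""
    genos = []
    for (site, g), flip in zip(truth, flip_mask):
        o = g.allele_a ^ int(flip)
        genos.append(GenotypeCall(o, 1 - o, phased=True, phase_set=None))
    return Callset(truth.sample_id, list(truth.sites), genos)
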