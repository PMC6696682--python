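"""Synthetic haplotype panels, truth diplotypes and corrupted callsets.

The generator emulates the shape of a population reference panel and of
experimentally phased single-sample callsets well enough that every
concordance metric can be tested by parameter recovery:

* Site alternate-allele frequencies are drawn from a neutral-like spectrum
  (mass proportional to 1/i over minor-allele counts), giving the strong
  rare-variant excess real panels show.
* Haplotypes are built by a copying mosaic: each new haplotype copies a
  randomly switching template among its group's founder haplotypes
  (switch probability ``copy_switch_rate`` per site, mismatch probability
  ``mutation_rate``), so linkage decays with distance.
* Groups ("continents") get their frequencies perturbed by a
  Balding-Nichols drift draw with parameter ``group_drift``.
* Truth callsets are diploid copies from the panel with hom-ref sites
  omitted (single-sample VCF semantics) and phase-set breaks placed by a
  memoryless process along the chromosome.
* ``corrupt`` turns a truth callset into a test/imputed stand-in with
  known genotype-class error rates, a switch-error process (independent
  flips or boundary toggles), dropout, and quality scores drawn lower for
  erroneous sites.

Every operation is fully determined by its seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .allele_freq import FrequencyTable
from .model import Callset, GenotypeCall, HaplotypePanel, VariantSite
from .vcf_io import write_callset, write_groups, write_panel

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Panel-simulation parameters.

    Defaults give a small but structured panel: 100 samples in two groups
    over 2,000 segregating sites on a 2 Mb chromosome, with enough copying
    correlation that phase statistics see realistic LD decay.
    """

    n_haplotypes: int = 200
    n_sites: int = 2000
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    sfs_shape: str = "neutral"  # "neutral" (∝ 1/i) or "uniform"
    copy_switch_rate: float = 0.02
    mutation_rate: float = 0.002
    n_groups: int = 2
    group_drift: float = 0.05
    n_founders: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (2 per sample)")
        for name in ("copy_switch_rate", "mutation_rate", "group_drift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sfs_shape not in ("neutral", "uniform"):
            raise ValueError(f"unknown sfs_shape {self.sfs_shape!r}")


@dataclass
class CorruptionConfig:
    """Error-injection parameters for building test/imputed callsets.

    ``genotype_error_rate`` applies a uniform mis-call probability (the
    wrong class drawn uniformly from the two alternatives); ``class_rates``
    instead gives per-class transition rates, e.g.
    ``{"het": {"homref": 0.02, "homalt": 0.01}}``. ``homref -> het`` drives
    false positives. Phase corruption acts on comparable het boundaries:
    ``boundary_toggle`` flips the carried phase state with probability
    ``switch_rate`` per boundary (expected consecutive switch rate s);
    ``independent_flip`` flips each het with probability ``flip_prob``
    (expected consecutive switch rate 2p(1-p)).
    """

    genotype_error_rate: float = 0.0
    class_rates: Optional[Dict[str, Dict[str, float]]] = None
    switch_mode: str = "boundary_toggle"  # or "independent_flip"
    switch_rate: float = 0.0
    flip_prob: float = 0.0
    dropout_rate: float = 0.0
    info_score_model: Optional[Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {"correct": (12.0, 1.5), "error": (2.0, 6.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "genotype_error_rate",
            "switch_rate",
            "flip_prob",
            "dropout_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.switch_mode not in ("boundary_toggle", "independent_flip"):
            raise ValueError(f"unknown switch_mode {self.switch_mode!r}")
        if self.class_rates is not None:
            for cls, row in self.class_rates.items():
                if cls not in ("homref", "het", "homalt"):
                    raise ValueError(f"unknown genotype class {cls!r}")
                if any(not 0.0 <= r <= 1.0 for r in row.values()) or sum(
                    row.values()
                ) > 1.0 + 1e-12:
                    raise ValueError(f"class {cls!r}: rates must lie in [0,1] and sum <= 1")


def _draw_spectrum(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Target AAFs: alternate-allele counts i in 1..H-1 drawn with mass
    ∝ 1/i (the unfolded neutral spectrum), so rare ALT alleles dominate."""
    h = cfg.n_haplotypes
    counts = np.arange(1, h)
    if cfg.sfs_shape == "neutral":
        w = 1.0 / counts
    else:
        w = np.ones_like(counts, dtype=float)
    w /= w.sum()
    return rng.choice(counts, size=cfg.n_sites, p=w) / h


def _mosaic_copy(
    rng: np.random.Generator,
    templates: np.ndarray,
    n_new: int,
    rho: float,
    theta: float,
) -> np.ndarray:
    """Build haplotypes as switching copies of template haplotypes."""
    k, l = templates.shape
    out = np.empty((n_new, l), dtype=np.uint8)
    for i in range(n_new):
        switches = rng.random(l) < rho
        switches[0] = True  # initial template draw
        n_seg = int(switches.sum())
        seg_templates = rng.integers(0, k, size=n_seg)
        template_per_site = seg_templates[np.cumsum(switches) - 1]
        alleles = templates[template_per_site, np.arange(l)]
        mism = rng.random(l) < theta
        out[i] = alleles ^ mism
    return out


def simulate_panel(config: SimulationConfig) -> HaplotypePanel:
    """Simulate a grouped haplotype panel under the copying-mosaic model."""
    rng = np.random.default_rng(config.seed)
    aaf = _draw_spectrum(rng, config)
    if np.all(aaf == 0):
        raise ValueError("degenerate configuration: all target frequencies are 0")
    positions = np.sort(
        rng.choice(config.chrom_length - 1, size=config.n_sites, replace=False) + 1
    )
    refs = rng.integers(0, 4, size=config.n_sites)
    alts = (refs + rng.integers(1, 4, size=config.n_sites)) % 4
    sites = [
        VariantSite(
            chrom=config.chrom,
            pos=int(p),
            ref=str(_BASES[r]),
            alt=str(_BASES[a]),
        )
        for p, r, a in zip(positions, refs, alts)
    ]

    n_samples = config.n_haplotypes // 2
    group_of_sample = [f"POP{1 + (i * config.n_groups) // n_samples}" for i in range(n_samples)]
    sample_ids = [f"SIM{i:04d}" for i in range(n_samples)]
    alleles = np.empty((config.n_haplotypes, config.n_sites), dtype=np.uint8)
    f = config.group_drift
    for g in sorted(set(group_of_sample)):
        rows = np.asarray(
            [
                j
                for i, gg in enumerate(group_of_sample)
                if gg == g
                for j in (2 * i, 2 * i + 1)
            ]
        )
        if f > 0:
            a = np.clip(aaf, 1e-6, 1 - 1e-6)
            p_g = rng.beta(a * (1 - f) / f, (1 - a) * (1 - f) / f)
        else:
            p_g = aaf
        n_f = min(config.n_founders, len(rows))
        founders = (rng.random((n_f, config.n_sites)) < p_g).astype(np.uint8)
        alleles[rows[:n_f]] = founders
        n_rest = len(rows) - n_f
        if n_rest > 0:
            alleles[rows[n_f:]] = _mosaic_copy(
                rng, founders, n_rest, config.copy_switch_rate, config.mutation_rate
            )
    return HaplotypePanel(
        sites=sites,
        alleles=alleles,
        sample_ids=sample_ids,
        sample_groups=dict(zip(sample_ids, group_of_sample)),
        target_aaf=aaf,
    )


def sample_truth(
    panel: HaplotypePanel,
    phase_block_mean_len: float = 100_000.0,
    seed: int = 0,
    sample_id: str = "TRUTH",
    copy_switch_rate: float = 0.02,
    mutation_rate: float = 0.002,
) -> Callset:
    """Draw one phased truth individual from the panel.

    The diplotype is two mosaic copies of the panel haplotypes. Sites where
    the individual is hom-ref are omitted (a single-sample VCF records a
    SNP only when the individual carries a variant). Phase-set boundaries
    fall between consecutive retained sites with probability
    ``1 - exp(-gap / phase_block_mean_len)``; each phase set is labelled by
    the position of its first variant, as linked-read pipelines do.
    """
    rng = np.random.default_rng(seed)
    hap = _mosaic_copy(rng, panel.alleles, 2, copy_switch_rate, mutation_rate)
    h1, h2 = hap[0], hap[1]
    keep = (h1 | h2).astype(bool)  # drop hom-ref sites
    kept_idx = np.flatnonzero(keep)
    sites = [panel.sites[int(i)] for i in kept_idx]
    pos = np.asarray([s.pos for s in sites], dtype=np.int64)
    if len(pos) and np.isfinite(phase_block_mean_len):
        gaps = np.diff(pos)
        brk = rng.random(len(gaps)) < (1.0 - np.exp(-gaps / phase_block_mean_len))
        block_id = np.concatenate([[0], np.cumsum(brk)])
    else:
        block_id = np.zeros(len(pos), dtype=np.int64)
    genos: List[GenotypeCall] = []
    block_start: Dict[int, int] = {}
    for j, i in enumerate(kept_idx):
        b = int(block_id[j])
        ps = block_start.setdefault(b, int(pos[j]))
        genos.append(
            GenotypeCall(
                allele_a=int(h1[i]),
                allele_b=int(h2[i]),
                phased=True,
                phase_set=ps,
            )
        )
    return Callset(sample_id, sites, genos, meta={"seed": seed})


_CLASS_TO_GT = {"homref": (0, 0), "homalt": (1, 1)}


def _effective_class_rates(cfg: CorruptionConfig) -> Dict[str, Dict[str, float]]:
    if cfg.class_rates is not None:
        return cfg.class_rates
    g = cfg.genotype_error_rate
    if g == 0:
        return {}
    # uniform mis-call: wrong class chosen uniformly between the other two
    return {
        "homref": {"het": g / 2, "homalt": g / 2},
        "het": {"homref": g / 2, "homalt": g / 2},
        "homalt": {"homref": g / 2, "het": g / 2},
    }


def corrupt(
    truth: Callset,
    panel_sites: Sequence[VariantSite],
    config: CorruptionConfig,
) -> Callset:
    """Corrupt a truth callset into a test/imputed stand-in.

    The output covers the full panel-site universe (hom-ref filled at
    truth-absent sites, as imputation output does), with genotype classes
    perturbed per the class-rate table, dropout applied, phase errors
    injected over the het boundaries, and a quality score drawn per site
    (stochastically lower at erroneous sites). With all rates at zero the
    result is the truth restricted to panel sites with hom-ref fill, phased
    chromosome-wide.
    """
    rng = np.random.default_rng(config.seed)
    rates = _effective_class_rates(config)
    truth_calls = truth.calls

    # 1. genotype corruption over the panel universe
    new_class: List[str] = []
    for site in panel_sites:
        g = truth_calls.get(site.key)
        cls = g.gt_class if g is not None else "homref"
        row = rates.get(cls)
        if row:
            u = rng.random()
            acc = 0.0
            for target, r in row.items():
                acc += r
                if u < acc:
                    cls = target
                    break
        new_class.append(cls)

    # 2. dropout
    keep = rng.random(len(panel_sites)) >= config.dropout_rate

    # 3. phase: baseline orientation copies truth at comparable hets, then
    # the switch process perturbs it; non-comparable hets get a coin flip.
    flip_state: Dict[object, int] = {}
    sites_out: List[VariantSite] = []
    genos_out: List[GenotypeCall] = []
    err_flags: List[bool] = []
    for i, site in enumerate(panel_sites):
        if not keep[i]:
            continue
        cls = new_class[i]
        g = truth_calls.get(site.key)
        truth_cls = g.gt_class if g is not None else "homref"
        is_err = cls != truth_cls
        if cls == "het":
            if g is not None and g.is_het and g.phased:
                ps_key = (site.chrom, g.phase_set)
                state = flip_state.get(ps_key)
                if state is None:
                    state = 0  # first comparable het of this truth phase set
                elif config.switch_mode == "boundary_toggle":
                    if rng.random() < config.switch_rate:
                        state ^= 1
                flip_state[ps_key] = state
                orient = g.allele_a
                if config.switch_mode == "independent_flip":
                    if rng.random() < config.flip_prob:
                        orient ^= 1
                else:
                    orient ^= state
                gt = (orient, 1 - orient)
            else:
                o = int(rng.random() < 0.5)
                gt = (o, 1 - o)
        else:
            gt = _CLASS_TO_GT[cls]
        score: Optional[float] = None
        if config.info_score_model is not None:
            a, b = config.info_score_model["error" if is_err else "correct"]
            score = float(rng.beta(a, b))
        sites_out.append(site)
        genos_out.append(
            GenotypeCall(
                allele_a=gt[0],
                allele_b=gt[1],
                phased=True,
                phase_set=None,  # chromosome-wide phasing, no PS tag
                info_score=score,
            )
        )
        err_flags.append(is_err)
    return Callset(
        truth.sample_id,
        sites_out,
        genos_out,
        meta={"seed": config.seed, "n_injected_errors": int(sum(err_flags))},
    )


def impute_as_homref(
    truth: Callset,
    panel_sites: Sequence[VariantSite],
    freqs: FrequencyTable,
    maf_threshold: float = 0.002,
    base_error_rate: float = 0.05,
    group: str = "ALL",
    seed: int = 0,
) -> Callset:
    """Imputation stand-in that collapses rare variants to hom-ref.

    Mimics reference-panel imputation of rare variants: at every site with
    MAF <= ``maf_threshold`` the prediction is the major-allele homozygote
    (hom-ref where the minor allele is ALT -- the best matching reference
    haplotypes carry the major allele), erasing whatever rare variant the
    truth individual carries; truth non-hom-ref genotypes elsewhere are
    miscalled with probability ``base_error_rate``; truth hom-ref sites at
    common-MAF positions are predicted correctly (imputation errors
    concentrate on segregating genotypes). Used to reproduce the opposite
    error-vs-MAF trends of the experimental-SNP and all-panel-SNP
    universes.
    """
    rng = np.random.default_rng(seed)
    aaf_arr = freqs.aaf[group]
    maf = freqs.maf(group)
    idx = freqs.index
    truth_calls = truth.calls
    sites_out: List[VariantSite] = []
    genos_out: List[GenotypeCall] = []
    for site in panel_sites:
        g = truth_calls.get(site.key)
        cls = g.gt_class if g is not None else "homref"
        j = idx[site.key]
        rare = maf[j] <= maf_threshold
        if rare:
            cls = "homref" if aaf_arr[j] <= 0.5 else "homalt"
        elif cls != "homref" and rng.random() < base_error_rate:
            others = [c for c in ("homref", "het", "homalt") if c != cls]
            cls = others[int(rng.random() < 0.5)]
        if cls == "het":
            o = g.allele_a if (g is not None and g.is_het) else int(rng.random() < 0.5)
            gt = (o, 1 - o)
        else:
            gt = _CLASS_TO_GT[cls]
        sites_out.append(site)
        genos_out.append(
            GenotypeCall(allele_a=gt[0], allele_b=gt[1], phased=True, phase_set=None)
        )
    return Callset(truth.sample_id, sites_out, genos_out, meta={"seed": seed})


SCALES: Dict[str, Dict[str, int]] = {
    "small": {"n_haplotypes": 60, "n_sites": 400, "n_individuals": 2},
    "standard": {"n_haplotypes": 200, "n_sites": 4000, "n_individuals": 3},
}


def make_fixture_suite(
    out_dir: Union[str, Path],
    scale: str = "small",
    seed: int = 0,
) -> Dict[str, object]:
    """Write a complete fixture set (panel, groups, truth and corrupted
    VCFs) plus a JSON manifest recording every injected rate and seed."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(SCALES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dims = SCALES[scale]
    root = np.random.SeedSequence(seed)
    sim_seed, *ind_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(1 + dims["n_individuals"])
    ]
    sim_cfg = SimulationConfig(
        n_haplotypes=dims["n_haplotypes"],
        n_sites=dims["n_sites"],
        chrom_length=500_000 if scale == "small" else 2_000_000,
        seed=sim_seed,
    )
    panel = simulate_panel(sim_cfg)
    write_panel(panel, out / "panel.vcf")
    write_groups(dict(panel.sample_groups), out / "groups.tsv")

    corruption = CorruptionConfig(
        genotype_error_rate=0.03,
        switch_mode="boundary_toggle",
        switch_rate=0.05,
        dropout_rate=0.02,
    )
    manifest: Dict[str, object] = {
        "scale": scale,
        "seed": seed,
        "simulation": asdict(sim_cfg),
        "corruption": {**asdict(corruption), "seed": None},
        "phase_block_mean_len": 50_000.0,
        "individuals": [],
    }
    for i, ind_seed in enumerate(ind_seeds):
        name = f"IND{i}"
        truth = sample_truth(
            panel,
            phase_block_mean_len=50_000.0,
            seed=ind_seed,
            sample_id=name,
            copy_switch_rate=sim_cfg.copy_switch_rate,
            mutation_rate=sim_cfg.mutation_rate,
        )
        cfg_i = CorruptionConfig(**{**asdict(corruption), "seed": ind_seed + 1})
        test = corrupt(truth, panel.sites, cfg_i)
        write_callset(truth, out / f"truth_{name}.vcf")
        write_callset(test, out / f"test_{name}.vcf")
        manifest["individuals"].append(
            {
                "sample": name,
                "seed": ind_seed,
                "corruption_seed": ind_seed + 1,
                "truth_vcf": f"truth_{name}.vcf",
                "test_vcf": f"test_{name}.vcf",
                "n_truth_sites": len(truth),
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


__all__ = [
    "SimulationConfig",
    "CorruptionConfig",
    "simulate_panel",
    "sample_truth",
    "corrupt",
    "impute_as_homref",
    "make_fixture_suite",
    "SCALES",
]
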