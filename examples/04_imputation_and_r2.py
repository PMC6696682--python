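"""Imputation error under both site universes, plus pooled dosage r².

Uses a deep panel (2,000 haplotypes) so genuinely rare variants segregate,
then applies a rare-variant-collapsing imputation stand-in. The error
DECREASES with MAF over the experimental SNPs (the individual's own
variants) but INCREASES with MAF over all panel SNPs, because rare panel
sites are overwhelmingly hom-ref and imputed correctly -- two opposite
trends from one callset.
"""

import numpy as np

from haplobench import (
    AAF9,
    CONTINENT6,
    SimulationConfig,
    compute_frequency_table,
    imputation_error,
    impute_as_homref,
    pooled_r2,
    sample_truth,
    simulate_panel,
)

panel = simulate_panel(
    SimulationConfig(n_haplotypes=2000, n_sites=4000, chrom_length=4_000_000, seed=7)
)
truth = sample_truth(panel, phase_block_mean_len=100_000, seed=8)
freqs = compute_frequency_table(panel)
imputed = impute_as_homref(
    truth, panel.sites, freqs, maf_threshold=0.002, base_error_rate=0.05, seed=9
)

for universe in ("experimental", "all_sites"):
    table = imputation_error(truth, imputed, universe, freqs, CONTINENT6)
    rates = ", ".join(
        f"{lab}: {100 * r:.2f}%" if np.isfinite(r) else f"{lab}: --"
        for lab, r in zip(table.labels, table.rate)
    )
    print(f"{universe:>12}: {rates}")

res = pooled_r2([truth], [imputed], freqs, AAF9)
print("\npooled r2 per AAF bin (NaN = zero-variance pool, reported missing):")
for lab, n, r2 in zip(res.labels, res.n_pool, res.r2):
    print(f"  {lab:>8}: n={n:5d} r2={r2:.3f}" if np.isfinite(r2) else f"  {lab:>8}: n={n:5d} r2=--")
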