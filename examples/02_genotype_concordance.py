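"""Genotype discordance by MAF bin, truth-class rates and FP/FN partition.

Simulates a panel, draws one truth individual, corrupts it with a known 3%
genotype-error rate, and measures the discordance back -- overall, per
continent-style MAF bin (including the invariant MAF=0 bin), stratified by
truth genotype class, and partitioned into false positives / negatives.
"""

from haplobench import (
    CONTINENT6,
    CorruptionConfig,
    SimulationConfig,
    compute_frequency_table,
    corrupt,
    error_by_truth_class,
    fp_fn_partition,
    genotype_error,
    sample_truth,
    simulate_panel,
)

panel = simulate_panel(SimulationConfig(n_haplotypes=200, n_sites=4000, seed=2))
truth = sample_truth(panel, phase_block_mean_len=100_000, seed=3)
test = corrupt(truth, panel.sites, CorruptionConfig(genotype_error_rate=0.03, seed=4))
freqs = compute_frequency_table(panel)

table = genotype_error(truth, test, "all_sites", freqs, CONTINENT6)
print(table.to_dataframe(sample=truth.sample_id).to_string(index=False))
print(f"\noverall discordance: {100 * table.overall_rate:.2f}% "
      "(should sit within binomial noise of the injected 3%)")

cls = error_by_truth_class(truth, test)
print(f"truth-het error {cls.het_rate:.3f} (n={cls.n_het}), "
      f"truth-homalt error {cls.homalt_rate:.3f} (n={cls.n_homalt})")

part = fp_fn_partition(truth, test, [s.key for s in panel.sites])
print(f"FP={part.fp} FN={part.fn} other={part.other} "
      f"(sum equals total mismatches: {part.total_mismatches})")
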