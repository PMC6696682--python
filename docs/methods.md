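# Methods

## Problem setting

`haplobench` quantifies how well a *test* callset — low-coverage consortium
genotypes, or the hard calls of statistical imputation — reproduces an
experimentally phased *truth* callset for one individual. Truth callsets of
this kind (linked-read pipelines, Long Ranger and similar) are single-sample
VCFs that record a site only when the individual carries a variant, and
whose phasing is broken into *phase sets* (`PS` tag): blocks of variants
phased relative to each other, with no phase defined between blocks. Both
properties shape the metric definitions below.

All analyses operate on biallelic autosomal SNPs that are phased and
`PASS`, after removing records at duplicated positions. Duplicate removal
keeps **no** survivor: since either callset may carry the duplicate, a
keep-first rule would treat the two sides asymmetrically. Each removed
record is attributed to exactly one rule in a fixed order (multiallelic →
indel → non-PASS → unphased → non-autosome, then duplicate), so the filter
report conserves counts: input = output + Σ removals. Records with missing
or half-missing genotypes (`./.`, `0/.`) are treated as absent sites at the
I/O layer and counted separately; the hom-ref assumption is applied only
inside the concordance computations.

## Allele frequencies and binning

Frequencies always come from a designated haplotype panel (two phased
haplotypes per sample), optionally per group ("continent"), never from
annotations on the evaluated callsets; MAF = min(AAF, 1 − AAF). Three bin
schemes are used:

| scheme | bins | used for |
|---|---|---|
| `continent6` | {0}, (0, 0.2%], (0.2, 0.5%], (0.5, 1%], (1, 5%], (5, 50%] on MAF | genotyping error, per-individual imputation error |
| `overall5` | same without the {0} bin | phasing error, panel comparison |
| `aaf9` | <0.2%, 0.2–0.5%, 0.5–1%, 1–2%, 2–5%, 5–10%, 10–20%, 20–50%, 50–100% on AAF | pooled r² |

Printed bin labels of this kind are ambiguous at their edges, so a
convention is required: intervals are left-open right-closed, the invariant
bin is exactly {0}, and the `aaf9` scheme's lowest bin is closed at 0. This
makes "MAF = 0.0%" and "MAF ≥ 5%" both literal. A MAF of exactly 0 under
`overall5` cannot be binned and is excluded with a warning (genotype
metrics) or a named error (direct bin assignment).

## Genotype concordance

Genotypes are compared as unordered allele pairs — equivalently, by class
(hom-ref / het / hom-alt) — never by phase; phase errors are measured
separately. Two site universes:

- **experimental**: the truth callset's own sites. Sites absent from the
  test callset are counted as test = hom-ref by default (mirroring the
  hom-ref assumption; switchable to exclusion, which is what parameter-
  recovery tests use when dropout is injected).
- **all_sites**: the full panel site list, with truth-absent sites assumed
  hom-ref — absence from a single-sample VCF is informative.

Mismatches over the panel universe are partitioned into **FP** (test
non-hom-ref, truth hom-ref), **FN** (test hom-ref, truth non-hom-ref) and
**other** (het ↔ hom-alt); the three always sum to the total mismatch
count. FP and FN rates are normalised by the truth hom-ref and truth
non-hom-ref site counts respectively — one of several defensible axes, so
raw counts are always emitted alongside.

## Phase concordance

A site is *comparable* when it is het in both callsets, phased in both,
with identical ref/alt, inside one truth phase set — and inside one test
phase set when the test carries `PS` tags (truth segments are split at test
block boundaries). Genotype-discordant sites never enter phase statistics.

Per comparable het, the *relative orientation* is the XOR of the two
callsets' haplotype assignments; a global relabelling of either side's
haplotypes shifts every orientation uniformly and changes nothing
downstream (tested as an invariant). A **switch** occurs at a boundary
between consecutive comparable hets whose relative orientation differs.

Two total-rate denominators are reported side by side: switches divided by
the total number of truth SNPs (hom and het alike), and the conventional
switches per comparable het boundary. The first follows the benchmarking
convention this package reproduces; the second is what `vcftools
--diff-switch-error` style tools report, and what the corruption parameter
*s* recovers directly.

**Switch error by MAF** counts, per bin, the hets flanking each switch
boundary (each site at most once — "both heterozygotes at the ends of each
out-of-phase segment") over the comparable hets in the bin. A flipped run
touching a phase-set edge has no switch boundary at that end and
contributes nothing there. Because every out-of-phase run drags its two
boundary-adjacent (typically common) neighbours into the numerator,
rare-site phase errors elevate low-MAF bins most clearly when rare sites
are a small fraction of the hets — which is how the rare-flip recovery test
is constructed.

**Pair parity by distance** extends switches to all het pairs: a pair is
discordant iff the number of switch boundaries strictly between its
members is odd, computed by a prefix-sum of switch indicators. This is
algebraically the XOR of the two orientations, and the test suite requires
exact agreement between the counting route and the XOR oracle. Under
independent boundary toggles with probability *s*, a pair separated by *k*
boundaries is discordant with probability (1 − (1 − 2s)^k)/2. The
Monte-Carlo standard error of the all-pairs estimator must account for
window overlap: with c = 1 − 2s, window parities at lag d < k covary as
c^(2d) − c^(2k), giving

    Var = [ n(1 − c^2k) + Σ_{d=1}^{k−1} 2(n − d)(c^{2d} − c^{2k}) ] / (4 n²)

which the acceptance tests use; the naive binomial SE understates the true
spread several-fold at small *s*. Distance bins default to log₁₀-spaced
edges from 100 bp to 1 Mb; pair enumeration is exact by default with an
optional seeded per-segment subsampling cap for very dense segments.

## Imputation accuracy

Discordance reuses the genotype machinery under both universes. Sites with
an INFO-style quality score below a threshold (0.3 by default in the
pipeline) are removed before the filtered analysis; unscored sites are
retained unless explicitly dropped. Pooled **r²** is the squared Pearson
correlation between truth and imputed alternate-allele dosages (0/1/2)
pooled across all sites and samples within each `aaf9` bin; pooling is the
standard answer to per-SNP r² being undefined at a handful of individuals.
Zero-variance pools are reported as missing, never as 0 or 1, to avoid
biasing panel comparisons. The reference-panel harness checks that all runs
share one site universe and emits aligned per-run tables with pairwise
per-bin rate ratios.

## Synthetic data generator

The generator produces data with the statistical features the metrics are
sensitive to, not a demographic simulation:

- **Site frequencies**: alternate-allele counts i ∈ {1, …, H−1} drawn with
  mass ∝ 1/i (the unfolded neutral spectrum), giving the rare-ALT excess
  real panels show. A uniform option exists. An import hook (`read_panel`)
  accepts externally simulated haplotypes, e.g. coalescent output written
  as VCF.
- **Haplotypes**: per group, `n_founders` haplotypes drawn i.i.d. from the
  group's frequencies, the rest built by a copying mosaic — the template
  switches with probability ρ (`copy_switch_rate`, default 0.02/site) and
  the copied allele mismatches with probability θ (`mutation_rate`,
  default 0.002). Small ρ yields long shared segments, hence LD decaying
  with distance; ρ = 1 decorrelates sites.
- **Groups**: founder frequencies per group are Balding–Nichols draws,
  Beta(p(1−F)/F, (1−p)(1−F)/F) with drift F = 0.05 — the standard
  population-structure perturbation — producing group-invariant sites for
  the `continent6` MAF = 0 bin.
- **Truth individuals**: two mosaic copies of the panel; hom-ref sites are
  omitted; phase-set breaks fall between consecutive sites with probability
  1 − exp(−gap/mean length), i.e. a memoryless process, each block labelled
  by its first variant's position.
- **Corruption**: genotype classes transition per a rate table (a uniform
  error rate draws the wrong class uniformly; `homref → het` drives FP);
  output covers the full panel universe with hom-ref fill, as imputed VCFs
  do, and is phased chromosome-wide (no PS). Phase corruption either
  toggles a carried flip state at each comparable het boundary
  (consecutive switch rate = s) or flips each het independently
  (consecutive switch rate = 2p(1−p)). Dropout removes sites. Quality
  scores are Beta draws — Beta(12, 1.5) for correct sites, Beta(2, 6) for
  erroneous ones — so score filtering preferentially removes errors.
  Errors are independent across sites by default.
- **Rare-variant imputation stand-in** (`impute_as_homref`): at MAF ≤
  threshold the prediction is the major-allele homozygote, erasing the
  individual's rare variants; elsewhere truth non-hom-ref genotypes are
  miscalled at a base rate and hom-ref sites are left correct, since real
  imputation errors concentrate on segregating genotypes. This reproduces
  the signature two-universe reversal: error falling with MAF over
  experimental SNPs while rising with MAF over all panel SNPs.

Everything is determined by integer seeds (numpy `SeedSequence` spawning
inside the fixture suite), and the suite writes a JSON manifest of every
rate and seed next to the VCFs.

What the generator does *not* emulate: recombination-map heterogeneity,
realistic demography, sequencing-read-level error structure, indels and
structural variants, genotype likelihoods, and clustered error processes
beyond the provided options. Passing recovery tests therefore demonstrate
the correctness of the metric implementations under known error processes,
not the error levels of any real callset.

## Problem sizes and numerical choices

Unit tests run on panels of 60–200 haplotypes over a few hundred sites;
rare-variant behaviour uses a 2,000-haplotype, 4,000-site panel (MAF
resolution 5 × 10⁻⁴); phase-statistic recoveries use 20,000-het segments
and the parity-decay check uses 10⁵ hets with pair separation up to k = 50.
Statistical recoveries are asserted within 3 standard errors of the
injected value under a fixed seed. Empty bins and zero denominators yield
NaN (flagged), never silent zeros. The pipeline's TSV outputs format floats
with `%.10g` and carry a configuration-hash header line, making repeat runs
byte-identical.

## Known limitations

- Switch errors are not decomposed into short-range flips vs long-range
  switches; the pair-parity statistic covers the distance dimension
  instead.
- Dosage-based r² from genotype probabilities is not implemented; hard
  calls are used (an imputed VCF with posterior dosages would need
  rounding upstream).
- The FP/FN rate normalisation is a documented choice; alternative
  normalisations must be derived from the emitted raw counts.
- Multiallelic sites are filtered, not decomposed.
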