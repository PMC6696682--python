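"""VCF reading, filtering, phase-set splitting and writing.

All VCF access goes through :mod:`pysam`. Reading preserves records that the
standard filters will later remove (multiallelic sites, indels, non-PASS,
unphased, duplicated positions) so that the filter report can attribute every
removal to exactly one rule. Records with a missing or half-missing genotype
are treated as absent sites and counted separately; they never enter a
callset.
"""

from __future__ import annotations

import csv
from collections import Counter, OrderedDict
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .model import (
    Callset,
    GenotypeCall,
    HaplotypePanel,
    SiteKey,
    VariantSite,
    chrom_sort_key,
    is_autosome,
)

DEFAULT_SCORE_KEY = "INFO"

# Removal attribution order: each failing record is charged to the FIRST rule
# it fails, in this fixed order; dedup is evaluated last, over the survivors.
RULE_ORDER = ("multiallelic", "indel", "non-PASS", "unphased", "non-autosome")


class MissingSampleError(KeyError):
    """Requested sample is not present in the VCF."""


class MalformedRecordError(ValueError):
    """A VCF record could not be interpreted; the position is reported."""


@dataclass(frozen=True)
class FilterRules:
    """Which of the standard site filters to apply."""

    biallelic: bool = True
    snp_only: bool = True
    pass_only: bool = True
    phased_only: bool = True
    autosomes_only: bool = True
    dedup: bool = True

    @classmethod
    def none(cls) -> "FilterRules":
        return cls(**{f.name: False for f in fields(cls)})


@dataclass
class FilterReport:
    """Per-rule removal counts from one ``filter_sites`` run."""

    removed: "OrderedDict[str, int]" = field(default_factory=OrderedDict)
    n_input: int = 0
    n_output: int = 0

    def total_removed(self) -> int:
        return sum(self.removed.values())

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("rule\tremoved_count\n")
            for rule, n in self.removed.items():
                fh.write(f"{rule}\t{n}\n")


@dataclass
class PhaseSetSegment:
    """Ordered heterozygous sites sharing one phase set on one chromosome."""

    chrom: str
    phase_set: Optional[int]
    sites: List[VariantSite]

    @property
    def informative(self) -> bool:
        """At least two hets are needed for any relative-phase statement."""
        return len(self.sites) >= 2


def _filter_string(rec: pysam.VariantRecord) -> str:
    keys = list(rec.filter.keys())
    if not keys:  # '.' or explicit PASS both read back as pass-worthy
        return "PASS"
    return ";".join(keys)


def read_callset(
    path: Union[str, Path],
    sample: str,
    score_key: str = DEFAULT_SCORE_KEY,
) -> Callset:
    """Read one sample's calls from a VCF into a :class:`Callset`.

    Phased status comes from the GT separator; the phase set from the PS tag
    when present (calls phased without PS fall into one implicit phase set
    per chromosome, represented as ``phase_set=None``). A per-site score is
    captured from ``score_key``, looked up first in FORMAT then in INFO.
    Records with missing or half-missing GT are skipped and counted under
    ``meta['missing_gt']``.
    """
    vcf = pysam.VariantFile(str(path))
    if sample not in vcf.header.samples:
        raise MissingSampleError(
            f"sample {sample!r} not in {path} (has: {list(vcf.header.samples)})"
        )
    sites: List[VariantSite] = []
    genos: List[GenotypeCall] = []
    n_missing = 0
    for rec in vcf:
        sdata = rec.samples[sample]
        gt = sdata.get("GT")
        if gt is None or len(gt) != 2 or any(a is None for a in gt):
            n_missing += 1
            continue
        a, b = gt
        if not isinstance(a, int) or not isinstance(b, int):
            raise MalformedRecordError(
                f"malformed GT at {rec.chrom}:{rec.pos}: {gt!r}"
            )
        phased = bool(sdata.phased)
        try:
            ps = sdata.get("PS") if phased else None
        except (KeyError, ValueError):  # PS not defined in header
            ps = None
        score = None
        for container in (sdata, rec.info):
            try:
                score = container.get(score_key)
            except (KeyError, ValueError):  # key not defined in header
                continue
            if score is not None:
                break
        alts = rec.alts or ()
        sites.append(
            VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=",".join(alts) if alts else ".",
                site_id=rec.id,
                filter=_filter_string(rec),
            )
        )
        genos.append(
            GenotypeCall(
                allele_a=a,
                allele_b=b,
                phased=phased,
                phase_set=int(ps) if ps is not None else None,
                info_score=float(score) if score is not None else None,
            )
        )
    vcf.close()
    return Callset(sample, sites, genos, meta={"missing_gt": n_missing})


def filter_sites(
    callset: Callset, rules: FilterRules = FilterRules()
) -> Tuple[Callset, FilterReport]:
    """Apply the standard site filters; every removal is counted once.

    Rules cover biallelic, SNP-only, PASS, phased, autosome restriction and
    duplicate-position removal. Duplicate positions are removed entirely --
    no survivor is kept -- so the operation is symmetric between the two
    callsets being compared.
    """
    report = FilterReport(n_input=len(callset))
    for rule in RULE_ORDER + ("duplicate",):
        report.removed[rule] = 0

    kept: List[Tuple[VariantSite, GenotypeCall]] = []
    for site, geno in callset:
        failed: Optional[str] = None
        if rules.biallelic and not site.is_biallelic:
            failed = "multiallelic"
        elif rules.snp_only and not site.is_snp:
            failed = "indel"
        elif rules.pass_only and site.filter != "PASS":
            failed = "non-PASS"
        elif rules.phased_only and not geno.phased:
            failed = "unphased"
        elif rules.autosomes_only and not is_autosome(site.chrom):
            failed = "non-autosome"
        if failed is None:
            kept.append((site, geno))
        else:
            report.removed[failed] += 1

    if rules.dedup:
        counts = Counter(s.key for s, _ in kept)
        deduped = [(s, g) for s, g in kept if counts[s.key] == 1]
        report.removed["duplicate"] = len(kept) - len(deduped)
        kept = deduped

    out = Callset(
        callset.sample_id,
        [s for s, _ in kept],
        [g for _, g in kept],
        meta=dict(callset.meta),
    )
    report.n_output = len(out)
    return out, report


def split_phase_sets(callset: Callset) -> List[PhaseSetSegment]:
    """Group the heterozygous sites into per-chromosome phase-set segments.

    Homozygous calls carry no phase information and are excluded. Phased
    calls without a PS tag share one implicit phase set per chromosome.
    Segments with fewer than two hets are returned but flagged uninformative.
    """
    groups: "OrderedDict[Tuple[str, Optional[int]], List[VariantSite]]" = OrderedDict()
    for site, geno in callset:
        if not geno.is_het:
            continue
        groups.setdefault((site.chrom, geno.phase_set), []).append(site)
    return [
        PhaseSetSegment(chrom=chrom, phase_set=ps, sites=sites)
        for (chrom, ps), sites in groups.items()
    ]


def subset_to_positions(
    callset: Callset, positions: Iterable[SiteKey]
) -> Callset:
    """Restrict a callset to a sorted position list (order preserved)."""
    return callset.subset(positions)


def _build_header(
    sample: Optional[str],
    chrom_lengths: Dict[str, int],
    score_key: Optional[str] = None,
    extra_samples: Sequence[str] = (),
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted(chrom_lengths, key=chrom_sort_key):
        header.add_line(
            f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>"
        )
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.add_line(
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">'
    )
    if score_key:
        header.add_line(
            f'##INFO=<ID={score_key},Number=1,Type=Float,'
            'Description="Imputation quality score">'
        )
    if sample is not None:
        header.add_sample(sample)
    for s in extra_samples:
        header.add_sample(s)
    return header


def write_callset(
    callset: Callset,
    path: Union[str, Path],
    score_key: str = DEFAULT_SCORE_KEY,
) -> None:
    """Write a single-sample VCF with GT ('|' separator iff phased) and PS.

    Round-trips with :func:`read_callset` field for field.
    """
    lengths: Dict[str, int] = {}
    for s in callset.sites:
        lengths[s.chrom] = max(lengths.get(s.chrom, 0), s.pos + 1000)
    any_scores = any(g.info_score is not None for g in callset.genotypes)
    header = _build_header(
        callset.sample_id, lengths, score_key if any_scores else None
    )
    out = pysam.VariantFile(str(path), "w", header=header)
    for site, geno in callset:
        rec = out.new_record(
            contig=site.chrom,
            start=site.pos - 1,
            alleles=(site.ref, *site.alt.split(",")),
            id=site.site_id,
        )
        if site.filter == "PASS":
            rec.filter.add("PASS")
        else:
            for f in site.filter.split(";"):
                rec.filter.add(f)
        sdata = rec.samples[callset.sample_id]
        sdata["GT"] = (geno.allele_a, geno.allele_b)
        sdata.phased = geno.phased
        if geno.phase_set is not None:
            sdata["PS"] = geno.phase_set
        if geno.info_score is not None:
            rec.info[score_key] = geno.info_score
        out.write(rec)
    out.close()


def write_panel(panel: HaplotypePanel, path: Union[str, Path]) -> None:
    """Write a haplotype panel as a multi-sample phased VCF."""
    lengths: Dict[str, int] = {}
    for s in panel.sites:
        lengths[s.chrom] = max(lengths.get(s.chrom, 0), s.pos + 1000)
    header = _build_header(None, lengths, None, extra_samples=panel.sample_ids)
    out = pysam.VariantFile(str(path), "w", header=header)
    for j, site in enumerate(panel.sites):
        rec = out.new_record(
            contig=site.chrom,
            start=site.pos - 1,
            alleles=(site.ref, site.alt),
            id=site.site_id,
        )
        rec.filter.add("PASS")
        for i, sample in enumerate(panel.sample_ids):
            sdata = rec.samples[sample]
            sdata["GT"] = (
                int(panel.alleles[2 * i, j]),
                int(panel.alleles[2 * i + 1, j]),
            )
            sdata.phased = True
        out.write(rec)
    out.close()


def read_panel(
    vcf_path: Union[str, Path], groups_path: Union[str, Path]
) -> HaplotypePanel:
    """Read a multi-sample phased VCF plus a (sample, group) TSV."""
    groups = read_groups(groups_path)
    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    sites: List[VariantSite] = []
    rows: List[List[int]] = []
    for rec in vcf:
        alts = rec.alts or ()
        sites.append(
            VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=",".join(alts) if alts else ".",
                site_id=rec.id,
                filter=_filter_string(rec),
            )
        )
        col: List[int] = []
        for sample in samples:
            gt = rec.samples[sample].get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                raise MalformedRecordError(
                    f"panel GT missing at {rec.chrom}:{rec.pos} for {sample}"
                )
            col.extend(gt)
        rows.append(col)
    vcf.close()
    alleles = np.array(rows, dtype=np.uint8).T if rows else np.zeros((2 * len(samples), 0), np.uint8)
    return HaplotypePanel(
        sites=sites,
        alleles=alleles,
        sample_ids=samples,
        sample_groups=groups,
    )


def read_groups(path: Union[str, Path]) -> Dict[str, str]:
    """Read a two-column (sample, group) TSV; a header line is optional."""
    groups: Dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "sample" and row[1] == "group":
                continue
            groups[row[0]] = row[1]
    return groups


def write_groups(groups: Dict[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_positions(path: Union[str, Path]) -> List[SiteKey]:
    """Read a (chrom, pos) position list TSV."""
    out: List[SiteKey] = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "chrom":
                continue
            out.append((row[0], int(row[1])))
    return out


__all__ = [
    "FilterRules",
    "FilterReport",
    "PhaseSetSegment",
    "MissingSampleError",
    "MalformedRecordError",
    "read_callset",
    "filter_sites",
    "split_phase_sets",
    "subset_to_positions",
    "write_callset",
    "write_panel",
    "read_panel",
    "read_groups",
    "write_groups",
    "read_positions",
    "DEFAULT_SCORE_KEY",
    "RULE_ORDER",
]
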