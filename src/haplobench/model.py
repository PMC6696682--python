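"""Core data model: variant sites, genotype calls, callsets and haplotype panels.

Coordinates follow VCF convention throughout: 1-based, inclusive. A
:class:`Callset` represents one individual's calls over an ordered site list;
sites absent from a callset carry no genotype at the I/O layer (the hom-ref
assumption is applied only inside the concordance modules, where evaluation
over a larger site universe requires it).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np

SiteKey = Tuple[str, int]

_AUTOSOME_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2])$")


def is_autosome(chrom: str) -> bool:
    """True for human autosome names, with or without a ``chr`` prefix."""
    return bool(_AUTOSOME_RE.match(chrom))


def chrom_sort_key(chrom: str) -> Tuple[int, str]:
    m = re.match(r"^(chr)?(\d+)$", chrom)
    if m:
        return (int(m.group(2)), "")
    return (10**6, chrom)


@dataclass(frozen=True)
class VariantSite:
    """One variant site.

    ``alt`` may hold a comma-joined allele list straight off a VCF record;
    after the biallelic/SNP filters it is a single base differing from
    ``ref``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    site_id: Optional[str] = None
    filter: str = "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos} at {self.chrom}")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos)

    @property
    def is_biallelic(self) -> bool:
        return "," not in self.alt

    @property
    def is_snp(self) -> bool:
        return (
            self.is_biallelic
            and len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref != self.alt
        )


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype at one site.

    ``allele_a``/``allele_b`` are allele indices (0 = ref); after biallelic
    filtering they are 0 or 1. When ``phased`` is false the ordering of the
    two alleles carries no meaning. ``phase_set`` groups co-phased variants
    (the VCF PS tag) and is meaningful only for phased calls.
    """

    allele_a: int
    allele_b: int
    phased: bool = False
    phase_set: Optional[int] = None
    info_score: Optional[float] = None

    def __post_init__(self) -> None:
        for a in (self.allele_a, self.allele_b):
            if a < 0:
                raise ValueError(f"allele index must be >= 0, got {a}")

    @property
    def is_het(self) -> bool:
        return self.allele_a != self.allele_b

    @property
    def is_hom_ref(self) -> bool:
        return self.allele_a == 0 and self.allele_b == 0

    @property
    def is_hom_alt(self) -> bool:
        return self.allele_a == 1 and self.allele_b == 1

    @property
    def dosage(self) -> int:
        """Count of alternate alleles: 0, 1 or 2 for a biallelic site."""
        return self.allele_a + self.allele_b

    @property
    def gt_class(self) -> str:
        if self.is_het:
            return "het"
        return "homref" if self.allele_a == 0 else "homalt"


@dataclass
class Callset:
    """One individual's genotype calls over an ordered site universe.

    Sites and genotypes are parallel lists ordered by (chrom, pos).
    Duplicate positions may be present before the dedup filter; the
    ``calls`` mapping view is available once they are gone.
    """

    sample_id: str
    sites: List[VariantSite]
    genotypes: List[GenotypeCall]
    meta: Dict[str, object] = field(default_factory=dict)
    _calls: Optional[Dict[SiteKey, GenotypeCall]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.genotypes):
            raise ValueError("sites and genotypes must be parallel lists")
        keys = [(chrom_sort_key(s.chrom), s.pos) for s in self.sites]
        if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("sites must be ordered by (chrom, pos)")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[Tuple[VariantSite, GenotypeCall]]:
        return iter(zip(self.sites, self.genotypes))

    @property
    def has_duplicates(self) -> bool:
        seen = set()
        for s in self.sites:
            if s.key in seen:
                return True
            seen.add(s.key)
        return False

    @property
    def calls(self) -> Mapping[SiteKey, GenotypeCall]:
        """Site-keyed view of the genotypes; requires unique positions."""
        if self._calls is None:
            calls: Dict[SiteKey, GenotypeCall] = {}
            for s, g in zip(self.sites, self.genotypes):
                if s.key in calls:
                    raise ValueError(
                        f"duplicate position {s.key}; apply the dedup filter first"
                    )
                calls[s.key] = g
            self._calls = calls
        return self._calls

    def call_at(self, key: SiteKey) -> Optional[GenotypeCall]:
        return self.calls.get(key)

    def subset(self, keys: Iterable[SiteKey]) -> "Callset":
        keep = set(keys)
        pairs = [(s, g) for s, g in self if s.key in keep]
        return Callset(
            self.sample_id,
            [s for s, _ in pairs],
            [g for _, g in pairs],
            meta=dict(self.meta),
        )

    def het_sites(self) -> List[VariantSite]:
        return [s for s, g in self if g.is_het]


@dataclass
class HaplotypePanel:
    """H phased haplotypes over L sites, with per-sample group labels.

    ``alleles`` is an H x L uint8 array of 0/1; haplotypes 2i and 2i+1
    belong to sample i. Allele frequencies for every concordance metric come
    from this panel.
    """

    sites: List[VariantSite]
    alleles: np.ndarray
    sample_ids: List[str]
    sample_groups: Mapping[str, str]
    target_aaf: Optional[np.ndarray] = None  # generator's drawn frequencies

    def __post_init__(self) -> None:
        h, l = self.alleles.shape
        if h % 2:
            raise ValueError("haplotype count must be even (2 per sample)")
        if h != 2 * len(self.sample_ids):
            raise ValueError("alleles rows must be 2 x number of samples")
        if l != len(self.sites):
            raise ValueError("alleles columns must match site count")
        for s in self.sample_ids:
            if s not in self.sample_groups:
                raise ValueError(f"sample {s!r} has no group label")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def site_keys(self) -> List[SiteKey]:
        return [s.key for s in self.sites]

    def haplotype_rows(self, group: str = "ALL") -> np.ndarray:
        """Row indices of the haplotypes belonging to ``group``."""
        if group == "ALL":
            return np.arange(self.n_haplotypes)
        rows = [
            j
            for i, s in enumerate(self.sample_ids)
            if self.sample_groups[s] == group
            for j in (2 * i, 2 * i + 1)
        ]
        if not rows:
            raise KeyError(f"no samples in group {group!r}")
        return np.asarray(rows)

    def groups(self) -> List[str]:
        seen: Dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.sample_groups[s], None)
        return list(seen)


def sorted_sites(sites: Iterable[VariantSite]) -> List[VariantSite]:
    return sorted(sites, key=lambda s: (chrom_sort_key(s.chrom), s.pos))


__all__ = [
    "VariantSite",
    "GenotypeCall",
    "Callset",
    "HaplotypePanel",
    "SiteKey",
    "is_autosome",
    "chrom_sort_key",
    "sorted_sites",
]
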