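"""Group-specific allele frequencies and frequency binning.

Frequencies always come from a designated haplotype panel (two phased
haplotypes per sample), never from annotations on the callsets being
evaluated. Minor allele frequency is ``maf = min(aaf, 1 - aaf)``.

Three binning schemes are provided:

* ``CONTINENT6`` -- MAF bins {0}, (0, 0.2%], (0.2, 0.5%], (0.5, 1%],
  (1, 5%], (5, 50%]; used for genotyping error and per-individual
  imputation error against group-specific frequencies. The invariant bin
  is exactly {0}.
* ``OVERALL5`` -- the same without the invariant bin; used for phasing
  error and reference-panel comparisons against overall frequencies.
  A MAF of exactly 0 cannot be binned and must be pre-excluded.
* ``AAF9`` -- alternate-allele-frequency bins <0.2%, 0.2-0.5%, 0.5-1%,
  1-2%, 2-5%, 5-10%, 10-20%, 20-50%, 50-100%; used for pooled r².

Intervals are left-open right-closed, (lo, hi], so the printed labels
"0.2-0.5%" and "MAF >= 5%" are both literal; the AAF scheme's lowest bin is
closed at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import HaplotypePanel, SiteKey, VariantSite


class InvariantSiteError(ValueError):
    """A frequency of exactly 0 was given to a scheme with no invariant bin."""


@dataclass(frozen=True)
class BinningScheme:
    """An ordered partition of the frequency axis into labelled bins."""

    name: str
    edges: Tuple[float, ...]  # increasing; bins are (edges[i], edges[i+1]]
    labels: Tuple[str, ...]  # one per interval, invariant bin excluded
    has_invariant_bin: bool = False  # prepend the exact-{0} bin
    closed_at_zero: bool = False  # lowest interval includes 0

    def __post_init__(self) -> None:
        if any(a >= b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")
        if len(self.labels) != len(self.edges) - 1:
            raise ValueError("need one label per interval")
        if self.has_invariant_bin and self.closed_at_zero:
            raise ValueError("invariant bin and closed-at-zero are exclusive")

    @property
    def invariant_label(self) -> str:
        return "0.0%"

    @property
    def all_labels(self) -> Tuple[str, ...]:
        if self.has_invariant_bin:
            return (self.invariant_label, *self.labels)
        return self.labels

    def assign(self, freq: float) -> str:
        """Bin label for one frequency. Every in-domain value maps to
        exactly one bin."""
        return self.all_labels[_assign_indices(np.array([freq]), self)[0]]

    def assign_many(self, freqs: np.ndarray) -> np.ndarray:
        """Vectorised assignment; returns indices into ``all_labels``."""
        return _assign_indices(np.asarray(freqs, dtype=float), self)


def _assign_indices(freqs: np.ndarray, scheme: BinningScheme) -> np.ndarray:
    lo, hi = scheme.edges[0], scheme.edges[-1]
    if np.any((freqs < lo) | (freqs > hi)):
        bad = freqs[(freqs < lo) | (freqs > hi)][0]
        raise ValueError(f"frequency {bad} outside domain of {scheme.name}")
    # (lo, hi] intervals: value equal to an edge belongs to the bin below it
    idx = np.searchsorted(scheme.edges, freqs, side="left") - 1
    at_zero = freqs == 0.0
    if scheme.has_invariant_bin:
        idx = idx + 1
        idx[at_zero] = 0
    elif scheme.closed_at_zero:
        idx[at_zero] = 0
    elif np.any(at_zero):
        raise InvariantSiteError(
            f"MAF = 0 cannot be binned under {scheme.name}; "
            "exclude invariant sites first"
        )
    return idx


_MAF_EDGES = (0.0, 0.002, 0.005, 0.01, 0.05, 0.5)
_MAF_LABELS = ("0.0-0.2%", "0.2-0.5%", "0.5-1%", "1-5%", ">=5%")

CONTINENT6 = BinningScheme(
    name="continent6",
    edges=_MAF_EDGES,
    labels=_MAF_LABELS,
    has_invariant_bin=True,
)

OVERALL5 = BinningScheme(
    name="overall5",
    edges=_MAF_EDGES,
    labels=_MAF_LABELS,
)

AAF9 = BinningScheme(
    name="aaf9",
    edges=(0.0, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0),
    labels=(
        "<0.2%",
        "0.2-0.5%",
        "0.5-1%",
        "1-2%",
        "2-5%",
        "5-10%",
        "10-20%",
        "20-50%",
        "50-100%",
    ),
    closed_at_zero=True,
)

SCHEMES: Dict[str, BinningScheme] = {
    s.name: s for s in (CONTINENT6, OVERALL5, AAF9)
}


@dataclass
class FrequencyTable:
    """Per-site alternate-allele frequencies for one or more groups."""

    sites: List[VariantSite]
    aaf: Dict[str, np.ndarray]  # group -> length-L array
    _index: Optional[Dict[SiteKey, int]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for g, arr in self.aaf.items():
            if len(arr) != len(self.sites):
                raise ValueError(f"group {g!r}: aaf length mismatch")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"group {g!r}: aaf outside [0, 1]")

    @property
    def groups(self) -> List[str]:
        return list(self.aaf)

    def maf(self, group: str) -> np.ndarray:
        a = self.aaf[group]
        return np.minimum(a, 1.0 - a)

    @property
    def index(self) -> Dict[SiteKey, int]:
        if self._index is None:
            self._index = {s.key: i for i, s in enumerate(self.sites)}
        return self._index

    def maf_at(self, key: SiteKey, group: str) -> float:
        return float(self.maf(group)[self.index[key]])

    def aaf_at(self, key: SiteKey, group: str) -> float:
        return float(self.aaf[group][self.index[key]])

    def to_dataframe(self, scheme: Optional[BinningScheme] = None) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            maf = self.maf(g)
            df = pd.DataFrame(
                {
                    "chrom": [s.chrom for s in self.sites],
                    "pos": [s.pos for s in self.sites],
                    "group": g,
                    "aaf": self.aaf[g],
                    "maf": maf,
                }
            )
            if scheme is not None:
                labels = np.asarray(scheme.all_labels)
                df["bin"] = labels[scheme.assign_many(maf)]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_tsv(
        self, path: Union[str, Path], scheme: Optional[BinningScheme] = None
    ) -> None:
        self.to_dataframe(scheme).to_csv(path, sep="\t", index=False)


def compute_group_af(
    panel: HaplotypePanel,
    group: str = "ALL",
    exclude_samples: Sequence[str] = (),
) -> FrequencyTable:
    """Alternate-allele frequency of each panel site within one group.

    ``aaf = (# alt alleles among the group's haplotypes) / (# haplotypes)``.
    ``exclude_samples`` drops listed samples (e.g. truth-sequenced
    individuals) from the count; by default the full panel is used.
    """
    rows = panel.haplotype_rows(group)
    if exclude_samples:
        drop = {
            j
            for i, s in enumerate(panel.sample_ids)
            if s in set(exclude_samples)
            for j in (2 * i, 2 * i + 1)
        }
        rows = np.asarray([r for r in rows if r not in drop])
    if rows.size == 0:
        raise KeyError(f"group {group!r} is empty after exclusions")
    aaf = panel.alleles[rows].mean(axis=0)
    return FrequencyTable(sites=list(panel.sites), aaf={group: aaf})


def compute_frequency_table(
    panel: HaplotypePanel,
    groups: Optional[Iterable[str]] = None,
    include_all: bool = True,
    exclude_samples: Sequence[str] = (),
) -> FrequencyTable:
    """Frequency table over several groups (plus the pooled "ALL" column)."""
    wanted = list(groups) if groups is not None else panel.groups()
    if include_all and "ALL" not in wanted:
        wanted.append("ALL")
    aaf: Dict[str, np.ndarray] = {}
    for g in wanted:
        aaf[g] = compute_group_af(panel, g, exclude_samples).aaf[g]
    return FrequencyTable(sites=list(panel.sites), aaf=aaf)


def assign_bin(freq: float, scheme: BinningScheme) -> str:
    """Bin label for one frequency under a scheme (module-level alias)."""
    return scheme.assign(freq)


__all__ = [
    "BinningScheme",
    "FrequencyTable",
    "InvariantSiteError",
    "CONTINENT6",
    "OVERALL5",
    "AAF9",
    "SCHEMES",
    "compute_group_af",
    "compute_frequency_table",
    "assign_bin",
]
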