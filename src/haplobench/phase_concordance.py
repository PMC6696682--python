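"""Switch-error and pair-parity statistics between two phasings.

All statistics are computed over *comparable* heterozygotes: sites that are
het in both callsets with identical ref/alt alleles, lying inside one truth
phase set (and one test phase set, when the test callset carries PS tags).
Genotype-discordant sites are excluded here -- genotype and phase errors are
deliberately kept separate.

The per-site *relative orientation* (truth haplotype assignment XOR test
haplotype assignment) is the working representation: a global swap of either
callset's haplotype labels maps same<->flipped uniformly and leaves every
downstream statistic unchanged. A *switch* occurs at a boundary between
consecutive comparable hets whose relative orientations differ.

Two denominators are reported for the total switch error: the number of
switches divided by the total number of truth SNPs (the figure-caption
convention of the study this reproduces), and the conventional rate, switches
divided by comparable het boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .allele_freq import BinningScheme, FrequencyTable, OVERALL5
from .model import Callset, SiteKey, VariantSite
from .vcf_io import split_phase_sets

DEFAULT_DISTANCE_EDGES = tuple(np.logspace(2, 6, 13))  # 100 bp .. 1 Mb


@dataclass
class PhasedSegmentPair:
    """Comparable hets of one truth phase set (x one test phase set).

    ``truth_orient``/``test_orient`` give, per site, which haplotype carries
    the alternate allele (the first allele of the phased genotype).
    """

    chrom: str
    phase_set: Optional[int]
    sites: List[VariantSite]
    truth_orient: np.ndarray
    test_orient: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sites)
        if len(self.truth_orient) != n or len(self.test_orient) != n:
            raise ValueError("orientation arrays must match site count")
        pos = [s.pos for s in self.sites]
        if any(a >= b for a, b in zip(pos, pos[1:])):
            raise ValueError("sites must be strictly increasing in position")

    @property
    def informative(self) -> bool:
        return len(self.sites) >= 2

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([s.pos for s in self.sites], dtype=np.int64)


@dataclass
class SwitchResult:
    """Switches along one segment pair."""

    n_sites: int
    n_switches: int
    n_comparable_boundaries: int
    switch_boundaries: List[Tuple[SiteKey, SiteKey]]
    switch_site_keys: List[SiteKey]  # unique flanking hets, <=2 per switch

    @property
    def rate(self) -> float:
        if self.n_comparable_boundaries == 0:
            return float("nan")
        return self.n_switches / self.n_comparable_boundaries


@dataclass
class TotalSwitchResult:
    """Genome-wide switch totals for one individual."""

    n_switches: int
    n_truth_snps: int
    n_comparable_boundaries: int
    n_comparable_hets: int
    n_segments: int

    @property
    def caption_rate(self) -> float:
        """Switches / total truth SNPs (hom and het alike)."""
        return self.n_switches / self.n_truth_snps if self.n_truth_snps else float("nan")

    @property
    def conventional_rate(self) -> float:
        """Switches / comparable het boundaries."""
        if self.n_comparable_boundaries == 0:
            return float("nan")
        return self.n_switches / self.n_comparable_boundaries

    def to_dataframe(self, **extra: object) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "n_switches": self.n_switches,
                    "n_truth_snps": self.n_truth_snps,
                    "n_comparable_boundaries": self.n_comparable_boundaries,
                    "caption_rate": self.caption_rate,
                    "conventional_rate": self.conventional_rate,
                }
            ]
        )
        for k, v in extra.items():
            df.insert(0, k, v)
        return df


@dataclass
class PairParityResult:
    """Discordant het pairs (odd intermediate switch count) by distance bin."""

    bin_edges: np.ndarray
    n_pairs: np.ndarray
    n_discordant: np.ndarray
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_pairs > 0, self.n_discordant / np.maximum(self.n_pairs, 1), np.nan
            )

    def to_dataframe(self, **extra: object) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "dist_lo": self.bin_edges[:-1],
                "dist_hi": self.bin_edges[1:],
                "n_pairs": self.n_pairs,
                "n_discordant": self.n_discordant,
                "rate": self.rate,
            }
        )
        for k, v in extra.items():
            df.insert(0, k, v)
        return df


def comparable_segments(truth: Callset, test: Callset) -> List[PhasedSegmentPair]:
    """Pair up the two phasings within truth phase sets.

    A site is comparable when het in both callsets, phased in both, with
    identical ref/alt. When the test callset carries PS tags, truth phase
    sets are further split at test phase-set boundaries so that every
    segment lies inside one phase set on both sides.
    """
    test_calls = test.calls
    test_sites = {s.key: s for s in test.sites}
    out: List[PhasedSegmentPair] = []
    for seg in split_phase_sets(truth):
        runs: List[Tuple[List[VariantSite], List[int], List[int]]] = []
        current_ps: object = object()  # sentinel: always differs initially
        for site in seg.sites:
            g_truth = truth.calls[site.key]
            g_test = test_calls.get(site.key)
            t_site = test_sites.get(site.key)
            if (
                g_test is None
                or not g_test.is_het
                or not g_test.phased
                or not g_truth.phased
                or t_site is None
                or (t_site.ref, t_site.alt) != (site.ref, site.alt)
            ):
                continue
            if not runs or g_test.phase_set != current_ps:
                runs.append(([], [], []))
                current_ps = g_test.phase_set
            sites_r, to_r, te_r = runs[-1]
            sites_r.append(site)
            to_r.append(g_truth.allele_a)
            te_r.append(g_test.allele_a)
        for sites_r, to_r, te_r in runs:
            out.append(
                PhasedSegmentPair(
                    chrom=seg.chrom,
                    phase_set=seg.phase_set,
                    sites=sites_r,
                    truth_orient=np.asarray(to_r, dtype=np.int8),
                    test_orient=np.asarray(te_r, dtype=np.int8),
                )
            )
    return out


def relative_orientation(segment: PhasedSegmentPair) -> np.ndarray:
    """Per-site agreement sequence: 0 = same, 1 = flipped (XOR)."""
    return (segment.truth_orient ^ segment.test_orient).astype(np.int8)


def switch_error(segment: PhasedSegmentPair) -> SwitchResult:
    """Count switches between consecutive comparable hets in one segment.

    ``switch_site_keys`` holds the union, over switch boundaries, of the two
    flanking hets ("both heterozygotes at the ends of each out-of-phase
    segment"); a run of flipped sites touching the segment edge has no
    switch boundary at that end and contributes nothing there.
    """
    a = relative_orientation(segment)
    n = len(a)
    if n < 2:
        return SwitchResult(n, 0, max(n - 1, 0), [], [])
    sw = a[1:] != a[:-1]
    idx = np.flatnonzero(sw)
    boundaries = [
        (segment.sites[i].key, segment.sites[i + 1].key) for i in idx
    ]
    seen: Dict[SiteKey, None] = {}
    for left, right in boundaries:
        seen.setdefault(left, None)
        seen.setdefault(right, None)
    return SwitchResult(
        n_sites=n,
        n_switches=int(sw.sum()),
        n_comparable_boundaries=n - 1,
        switch_boundaries=boundaries,
        switch_site_keys=list(seen),
    )


def total_switch_error(truth: Callset, test: Callset) -> TotalSwitchResult:
    """Aggregate switches over all truth phase sets.

    Both the caption-style rate (switches / total truth SNPs) and the
    conventional rate (switches / comparable het boundaries) are exposed.
    """
    n_switches = 0
    n_boundaries = 0
    n_hets = 0
    segs = comparable_segments(truth, test)
    for seg in segs:
        if not seg.informative:
            continue
        res = switch_error(seg)
        n_switches += res.n_switches
        n_boundaries += res.n_comparable_boundaries
        n_hets += res.n_sites
    return TotalSwitchResult(
        n_switches=n_switches,
        n_truth_snps=len(truth),
        n_comparable_boundaries=n_boundaries,
        n_comparable_hets=n_hets,
        n_segments=len(segs),
    )


def switch_error_by_maf(
    truth: Callset,
    test: Callset,
    freqs: FrequencyTable,
    scheme: BinningScheme = OVERALL5,
    group: str = "ALL",
) -> "BinnedErrorTable":
    """Switch-flanking hets per MAF bin over comparable het denominators.

    Numerator: switch positions (each flanking het counted at most once per
    individual) falling in the bin. Denominator: comparable hets in the bin.
    MAF = 0 sites cannot be binned without an invariant bin and are excluded
    with a warning.
    """
    from .genotype_concordance import BinnedErrorTable

    idx = freqs.index
    maf = freqs.maf(group)
    switch_keys: Dict[SiteKey, None] = {}
    het_keys: List[SiteKey] = []
    for seg in comparable_segments(truth, test):
        if not seg.informative:
            continue
        het_keys.extend(s.key for s in seg.sites)
        for k in switch_error(seg).switch_site_keys:
            switch_keys.setdefault(k, None)

    def _mafs(keys: Sequence[SiteKey]) -> np.ndarray:
        return np.asarray([maf[idx[k]] for k in keys], dtype=float)

    het_maf = _mafs(het_keys)
    sw_maf = _mafs(list(switch_keys))
    n_zero = int((het_maf == 0).sum()) if het_maf.size else 0
    if n_zero and not scheme.has_invariant_bin and not scheme.closed_at_zero:
        warnings.warn(
            f"{n_zero} comparable hets have MAF = 0 and were excluded "
            f"(no invariant bin in scheme {scheme.name})"
        )
        het_maf = het_maf[het_maf > 0]
        sw_maf = sw_maf[sw_maf > 0]
    n_bins = len(scheme.all_labels)
    n_total = np.bincount(
        scheme.assign_many(het_maf) if het_maf.size else np.array([], dtype=np.intp),
        minlength=n_bins,
    ).astype(np.int64)
    n_err = np.bincount(
        scheme.assign_many(sw_maf) if sw_maf.size else np.array([], dtype=np.intp),
        minlength=n_bins,
    ).astype(np.int64)
    return BinnedErrorTable(
        scheme=scheme,
        n_total=n_total,
        n_errors=n_err,
        meta={
            "metric": "switch_error_by_maf",
            "sample": truth.sample_id,
            "group": group,
            "excluded_invariant": n_zero,
        },
    )


def _segment_pair_arrays(
    segment: PhasedSegmentPair, max_rank: Optional[int]
) -> Tuple[np.ndarray, np.ndarray]:
    """(distance, discordant) over all het pairs of one segment.

    Discordance is computed by counting the switch boundaries strictly
    between the pair (via a prefix sum) and taking its parity; this agrees
    exactly with the XOR of the two relative orientations.
    """
    a = relative_orientation(segment)
    n = len(a)
    if n < 2:
        return np.empty(0, np.int64), np.empty(0, bool)
    pos = segment.positions
    prefix = np.concatenate([[0], np.cumsum((a[1:] != a[:-1]).astype(np.int64))])
    top = min(max_rank, n - 1) if max_rank else n - 1
    dists: List[np.ndarray] = []
    disc: List[np.ndarray] = []
    for k in range(1, top + 1):
        n_inter = prefix[k:] - prefix[:-k]  # switches strictly between i, i+k
        dists.append(pos[k:] - pos[:-k])
        disc.append((n_inter % 2) == 1)
    return np.concatenate(dists), np.concatenate(disc)


def pair_parity_error_by_distance(
    truth: Callset,
    test: Callset,
    distance_edges: Sequence[float] = DEFAULT_DISTANCE_EDGES,
    max_rank: Optional[int] = None,
    max_pairs_per_segment: Optional[int] = None,
    seed: int = 0,
) -> PairParityResult:
    """All-pairs phase discordance binned by inter-SNP distance.

    A pair of comparable hets is discordant when the number of switches
    strictly between them is odd. ``max_rank`` restricts pairs to at most
    that many het boundaries apart; ``max_pairs_per_segment`` subsamples
    very dense segments (seeded), exact enumeration being the default.
    """
    rng = np.random.default_rng(seed)
    edges = np.asarray(distance_edges, dtype=float)
    n_bins = len(edges) - 1
    n_pairs = np.zeros(n_bins, dtype=np.int64)
    n_disc = np.zeros(n_bins, dtype=np.int64)
    for seg in comparable_segments(truth, test):
        d, x = _segment_pair_arrays(seg, max_rank)
        if d.size == 0:
            continue
        if max_pairs_per_segment is not None and d.size > max_pairs_per_segment:
            take = rng.choice(d.size, size=max_pairs_per_segment, replace=False)
            d, x = d[take], x[take]
        which = np.searchsorted(edges, d, side="left") - 1
        which[d == edges[0]] = 0
        ok = (which >= 0) & (which < n_bins) & (d <= edges[-1])
        n_pairs += np.bincount(which[ok], minlength=n_bins)
        n_disc += np.bincount(which[ok], weights=x[ok], minlength=n_bins).astype(np.int64)
    return PairParityResult(
        bin_edges=edges,
        n_pairs=n_pairs,
        n_discordant=n_disc,
        meta={"sample": truth.sample_id, "max_rank": max_rank},
    )


def pair_discordance_by_rank(
    truth: Callset, test: Callset, max_rank: int
) -> pd.DataFrame:
    """Pair discordance as a function of het-boundary separation k.

    Under independent boundary toggles with probability s the expected
    discordance at separation k is (1 - (1 - 2s)**k) / 2.
    """
    n_pairs = np.zeros(max_rank + 1, dtype=np.int64)
    n_disc = np.zeros(max_rank + 1, dtype=np.int64)
    for seg in comparable_segments(truth, test):
        a = relative_orientation(seg)
        n = len(a)
        if n < 2:
            continue
        prefix = np.concatenate(
            [[0], np.cumsum((a[1:] != a[:-1]).astype(np.int64))]
        )
        for k in range(1, min(max_rank, n - 1) + 1):
            n_inter = prefix[k:] - prefix[:-k]
            n_pairs[k] += n - k
            n_disc[k] += int(((n_inter % 2) == 1).sum())
    ks = np.arange(1, max_rank + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(
            n_pairs[1:] > 0, n_disc[1:] / np.maximum(n_pairs[1:], 1), np.nan
        )
    return pd.DataFrame(
        {"k": ks, "n_pairs": n_pairs[1:], "n_discordant": n_disc[1:], "rate": rate}
    )


def switch_boundaries_bed(
    truth: Callset, test: Callset, path: Union[str, Path]
) -> None:
    """Write switch boundary intervals (between flanking hets) as BED."""
    with open(path, "w") as fh:
        for seg in comparable_segments(truth, test):
            for (c1, p1), (c2, p2) in switch_error(seg).switch_boundaries:
                fh.write(f"{c1}\t{p1 - 1}\t{p2}\n")


__all__ = [
    "PhasedSegmentPair",
    "SwitchResult",
    "TotalSwitchResult",
    "PairParityResult",
    "comparable_segments",
    "relative_orientation",
    "switch_error",
    "total_switch_error",
    "switch_error_by_maf",
    "pair_parity_error_by_distance",
    "pair_discordance_by_rank",
    "switch_boundaries_bed",
    "DEFAULT_DISTANCE_EDGES",
]
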