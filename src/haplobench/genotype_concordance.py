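"""Genotype concordance between a truth callset and a test callset.

Genotypes are compared as unordered allele pairs (phase is the business of
:mod:`haplobench.phase_concordance`), which for biallelic SNPs reduces to
comparing the genotype class: hom-ref, het or hom-alt.

Two site universes are supported. Under ``"experimental"`` the comparison
runs over the truth callset's own sites -- the sites where the truth
individual carries a variant. Under ``"all_sites"`` it runs over the full
panel site list, with sites absent from the truth callset assumed
homozygous-reference (single-sample VCFs only record non-hom-ref sites, so
absence is informative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .allele_freq import BinningScheme, FrequencyTable
from .model import Callset, SiteKey

HOMREF, HET, HOMALT, ABSENT = 0, 1, 2, 3
_CLASS_NAMES = {HOMREF: "homref", HET: "het", HOMALT: "homalt", ABSENT: "absent"}

Universe = str  # "experimental" | "all_sites"


class UniverseError(ValueError):
    """Evaluation universes of two runs do not match."""


@dataclass(frozen=True)
class SiteComparison:
    """Truth vs test genotype class at one site, after hom-ref substitution."""

    key: SiteKey
    truth_class: str
    test_class: str

    @property
    def concordant(self) -> bool:
        eff = lambda c: "homref" if c == "absent" else c
        return eff(self.truth_class) == eff(self.test_class)


@dataclass
class BinnedErrorTable:
    """Per-bin numerator/denominator counts for any binned error metric."""

    scheme: BinningScheme
    n_total: np.ndarray
    n_errors: np.ndarray
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = self.scheme.all_labels
        if len(self.n_total) != len(labels) or len(self.n_errors) != len(labels):
            raise ValueError("counts must have one entry per bin")
        if np.any(self.n_errors > self.n_total) or np.any(self.n_errors < 0):
            raise ValueError("need 0 <= n_errors <= n_total in every bin")

    @property
    def labels(self) -> Tuple[str, ...]:
        return self.scheme.all_labels

    @property
    def rate(self) -> np.ndarray:
        """Per-bin error rate; NaN where the bin is empty."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_total > 0, self.n_errors / np.maximum(self.n_total, 1), np.nan
            )

    @property
    def overall_total(self) -> int:
        return int(self.n_total.sum())

    @property
    def overall_errors(self) -> int:
        return int(self.n_errors.sum())

    @property
    def overall_rate(self) -> float:
        return self.overall_errors / self.overall_total if self.overall_total else float("nan")

    def to_dataframe(self, **extra: object) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin": list(self.labels),
                "n_total": self.n_total,
                "n_errors": self.n_errors,
                "rate": self.rate,
            }
        )
        for k, v in extra.items():
            df.insert(0, k, v)
        return df

    def to_tsv(self, path: Union[str, Path], **extra: object) -> None:
        self.to_dataframe(**extra).to_csv(path, sep="\t", index=False)


@dataclass
class ClassErrorRates:
    """Discordance stratified by the truth genotype class (het vs hom-alt)."""

    n_het: int
    het_errors: int
    n_homalt: int
    homalt_errors: int

    @property
    def het_rate(self) -> float:
        return self.het_errors / self.n_het if self.n_het else float("nan")

    @property
    def homalt_rate(self) -> float:
        return self.homalt_errors / self.n_homalt if self.n_homalt else float("nan")

    @property
    def ratio(self) -> float:
        """hom-alt error rate over het error rate; NaN when undefined."""
        het = self.het_rate
        if not np.isfinite(het) or het == 0 or self.n_homalt == 0:
            return float("nan")
        return self.homalt_rate / het


@dataclass
class FpFnPartition:
    """FP / FN / other-mismatch partition of discordant sites.

    FP: test non-hom-ref where truth is hom-ref. FN: test hom-ref where
    truth is non-hom-ref. Other: het vs hom-alt disagreements. Rates are
    normalised per truth site class (raw counts are kept so any other
    normalisation can be derived).
    """

    fp: int
    fn: int
    other: int
    n_truth_homref: int
    n_truth_nonhomref: int

    @property
    def total_mismatches(self) -> int:
        return self.fp + self.fn + self.other

    @property
    def fp_rate(self) -> float:
        return self.fp / self.n_truth_homref if self.n_truth_homref else float("nan")

    @property
    def fn_rate(self) -> float:
        return self.fn / self.n_truth_nonhomref if self.n_truth_nonhomref else float("nan")

    def to_dataframe(self, **extra: object) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "FP": self.fp,
                    "FN": self.fn,
                    "other": self.other,
                    "fp_rate": self.fp_rate,
                    "fn_rate": self.fn_rate,
                }
            ]
        )
        for k, v in extra.items():
            df.insert(0, k, v)
        return df


def class_codes(
    callset: Callset,
    universe: Sequence[SiteKey],
    absent_as_homref: bool = True,
) -> np.ndarray:
    """Genotype-class codes of a callset over a site universe."""
    calls = callset.calls
    out = np.empty(len(universe), dtype=np.int8)
    for i, key in enumerate(universe):
        g = calls.get(key)
        if g is None:
            out[i] = HOMREF if absent_as_homref else ABSENT
        else:
            out[i] = g.dosage  # 0/1/2 == homref/het/homalt for biallelic
    return out


def _universe_keys(
    truth: Callset, freqs: FrequencyTable, universe: Universe
) -> List[SiteKey]:
    if universe == "experimental":
        return [s.key for s in truth.sites]
    if universe == "all_sites":
        return [s.key for s in freqs.sites]
    raise ValueError(f"unknown universe {universe!r}")


def genotype_error(
    truth: Callset,
    test: Callset,
    universe: Universe,
    freqs: FrequencyTable,
    scheme: BinningScheme,
    group: str = "ALL",
    missing_site_policy: str = "homref",
) -> BinnedErrorTable:
    """Genotype discordance per frequency bin over the chosen universe.

    ``missing_site_policy`` controls universe sites absent from the test
    callset: ``"homref"`` (default, mirroring the hom-ref assumption) or
    ``"exclude"``. Sites with MAF exactly 0 are excluded when the scheme
    has no invariant bin, with the excluded count recorded in ``meta``.
    """
    if missing_site_policy not in ("homref", "exclude"):
        raise ValueError(f"unknown missing_site_policy {missing_site_policy!r}")
    keys = _universe_keys(truth, freqs, universe)
    truth_codes = class_codes(truth, keys, absent_as_homref=True)
    test_codes = class_codes(
        test, keys, absent_as_homref=(missing_site_policy == "homref")
    )

    idx = freqs.index
    maf_all = freqs.maf(group)
    try:
        maf = maf_all[np.array([idx[k] for k in keys], dtype=np.intp)] if keys else np.array([])
    except KeyError as e:
        raise KeyError(f"universe site {e.args[0]} missing from frequency table")

    keep = test_codes != ABSENT
    n_excluded_missing = int((~keep).sum())
    n_excluded_invariant = 0
    if not scheme.has_invariant_bin and not scheme.closed_at_zero:
        inv = maf == 0.0
        n_excluded_invariant = int((keep & inv).sum())
        keep &= ~inv

    maf_k = maf[keep]
    errors = (truth_codes[keep] != test_codes[keep]).astype(np.int64)
    bins = scheme.assign_many(maf_k) if maf_k.size else np.array([], dtype=np.intp)
    n_bins = len(scheme.all_labels)
    n_total = np.bincount(bins, minlength=n_bins).astype(np.int64)
    n_errors = np.bincount(bins, weights=errors, minlength=n_bins).astype(np.int64)
    return BinnedErrorTable(
        scheme=scheme,
        n_total=n_total,
        n_errors=n_errors,
        meta={
            "universe": universe,
            "group": group,
            "sample": truth.sample_id,
            "excluded_missing_test": n_excluded_missing,
            "excluded_invariant": n_excluded_invariant,
        },
    )


def error_by_truth_class(
    truth: Callset,
    test: Callset,
    missing_site_policy: str = "homref",
) -> ClassErrorRates:
    """Discordance at truth-het vs truth-hom-alt sites, plus their ratio."""
    keys = [s.key for s in truth.sites]
    truth_codes = class_codes(truth, keys, absent_as_homref=True)
    test_codes = class_codes(
        test, keys, absent_as_homref=(missing_site_policy == "homref")
    )
    keep = test_codes != ABSENT
    het = keep & (truth_codes == HET)
    homalt = keep & (truth_codes == HOMALT)
    return ClassErrorRates(
        n_het=int(het.sum()),
        het_errors=int((test_codes[het] != HET).sum()),
        n_homalt=int(homalt.sum()),
        homalt_errors=int((test_codes[homalt] != HOMALT).sum()),
    )


def fp_fn_partition(
    truth: Callset,
    test: Callset,
    panel_sites: Sequence[SiteKey],
) -> FpFnPartition:
    """Partition all discordant panel sites into FP, FN and other.

    Evaluated over the full panel universe with truth-absent (and
    test-absent) sites taken as hom-ref. FP + FN + other equals the total
    mismatch count by construction.
    """
    truth_codes = class_codes(truth, panel_sites, absent_as_homref=True)
    test_codes = class_codes(test, panel_sites, absent_as_homref=True)
    mism = truth_codes != test_codes
    fp = int((mism & (truth_codes == HOMREF)).sum())
    fn = int((mism & (test_codes == HOMREF) & (truth_codes != HOMREF)).sum())
    other = int(mism.sum()) - fp - fn
    return FpFnPartition(
        fp=fp,
        fn=fn,
        other=other,
        n_truth_homref=int((truth_codes == HOMREF).sum()),
        n_truth_nonhomref=int((truth_codes != HOMREF).sum()),
    )


def compare_site(
    key: SiteKey, truth: Callset, test: Callset
) -> SiteComparison:
    """Single-site truth/test comparison record (mainly for reporting)."""
    name = lambda cs: _CLASS_NAMES[
        cs.calls[key].dosage if key in cs.calls else ABSENT
    ]
    return SiteComparison(key=key, truth_class=name(truth), test_class=name(test))


__all__ = [
    "BinnedErrorTable",
    "ClassErrorRates",
    "FpFnPartition",
    "SiteComparison",
    "UniverseError",
    "genotype_error",
    "error_by_truth_class",
    "fp_fn_partition",
    "class_codes",
    "compare_site",
    "HOMREF",
    "HET",
    "HOMALT",
    "ABSENT",
]
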