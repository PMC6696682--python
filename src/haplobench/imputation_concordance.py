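"""Imputation accuracy: discordance, INFO-score filtering and pooled r².

Imputed callsets are ordinary :class:`~haplobench.model.Callset` objects
whose calls carry an ``info_score`` (the per-site quality score emitted by
imputation software, in [0, 1]). Discordance reuses the genotype-concordance
machinery -- the phase of imputed output is never compared. The r² metric is
the squared Pearson correlation between true and imputed alternate-allele
dosages (0/1/2) pooled across all sites and samples within each
alternate-allele-frequency bin; pooling sidesteps the tiny per-SNP sample
sizes that make per-SNP r² meaningless with a handful of individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .allele_freq import AAF9, BinningScheme, FrequencyTable
from .genotype_concordance import (
    ABSENT,
    BinnedErrorTable,
    UniverseError,
    class_codes,
    genotype_error,
)
from .model import Callset, SiteKey


@dataclass
class R2Result:
    """Pooled dosage r² per AAF bin; NaN marks an undefined (zero-variance)
    pool, reported as missing rather than 0 or 1."""

    scheme: BinningScheme
    n_pool: np.ndarray
    r2: np.ndarray
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def labels(self) -> Tuple[str, ...]:
        return self.scheme.all_labels

    def to_dataframe(self, **extra: object) -> pd.DataFrame:
        df = pd.DataFrame(
            {"bin": list(self.labels), "n_pool": self.n_pool, "r2": self.r2}
        )
        for k, v in extra.items():
            df.insert(0, k, v)
        return df

    def to_tsv(self, path: Union[str, Path], **extra: object) -> None:
        self.to_dataframe(**extra).to_csv(path, sep="\t", index=False)


def imputation_error(
    truth: Callset,
    imputed: Callset,
    universe: str,
    freqs: FrequencyTable,
    scheme: BinningScheme,
    group: str = "ALL",
    missing_site_policy: str = "homref",
) -> BinnedErrorTable:
    """Per-bin imputed-genotype discordance (unordered allele comparison).

    Identical semantics to genotype concordance: under ``"experimental"``
    the universe is the truth callset's sites; under ``"all_sites"`` it is
    the panel, with truth-absent sites assumed hom-ref.
    """
    table = genotype_error(
        truth, imputed, universe, freqs, scheme, group, missing_site_policy
    )
    table.meta["metric"] = "imputation_error"
    return table


def filter_by_info(
    imputed: Callset, min_info: float, drop_unscored: bool = False
) -> Callset:
    """Remove sites whose score is strictly below ``min_info``.

    Sites without a score are retained unless ``drop_unscored``.
    """
    if not 0.0 <= min_info <= 1.0:
        raise ValueError(f"min_info must be in [0, 1], got {min_info}")
    pairs = [
        (s, g)
        for s, g in imputed
        if (g.info_score is None and not drop_unscored)
        or (g.info_score is not None and g.info_score >= min_info)
    ]
    return Callset(
        imputed.sample_id,
        [s for s, _ in pairs],
        [g for _, g in pairs],
        meta=dict(imputed.meta),
    )


def _dosages(
    callset: Callset, keys: Sequence[SiteKey], absent_as_homref: bool
) -> np.ndarray:
    codes = class_codes(callset, keys, absent_as_homref=absent_as_homref)
    return codes  # 0/1/2 codes double as alt dosages; ABSENT handled upstream


def pooled_r2(
    truth_callsets: Sequence[Callset],
    imputed_callsets: Sequence[Callset],
    aaf: FrequencyTable,
    scheme: BinningScheme = AAF9,
    group: str = "ALL",
) -> R2Result:
    """Squared Pearson correlation of pooled dosages per AAF bin.

    Truth/imputed callsets are paired positionally. The pool runs over every
    panel site and every individual, with sites absent from a callset taken
    as hom-ref (dosage 0); binning uses the alternate-allele frequency, not
    the MAF.
    """
    if len(truth_callsets) != len(imputed_callsets):
        raise ValueError("need one imputed callset per truth callset")
    keys = [s.key for s in aaf.sites]
    bins = scheme.assign_many(aaf.aaf[group])
    n_bins = len(scheme.all_labels)
    truth_pool: List[np.ndarray] = []
    imp_pool: List[np.ndarray] = []
    bin_pool: List[np.ndarray] = []
    for t_cs, i_cs in zip(truth_callsets, imputed_callsets):
        td = _dosages(t_cs, keys, absent_as_homref=True)
        im = _dosages(i_cs, keys, absent_as_homref=True)
        keep = (td != ABSENT) & (im != ABSENT)
        truth_pool.append(td[keep])
        imp_pool.append(im[keep])
        bin_pool.append(bins[keep])
    t = np.concatenate(truth_pool) if truth_pool else np.empty(0, np.int8)
    m = np.concatenate(imp_pool) if imp_pool else np.empty(0, np.int8)
    b = np.concatenate(bin_pool) if bin_pool else np.empty(0, np.intp)
    n_pool = np.bincount(b, minlength=n_bins).astype(np.int64)
    r2 = np.full(n_bins, np.nan)
    for j in range(n_bins):
        sel = b == j
        if sel.sum() < 2:
            continue
        x = t[sel].astype(float)
        y = m[sel].astype(float)
        if x.var() == 0.0 or y.var() == 0.0:
            continue  # undefined, stays NaN
        r = np.corrcoef(x, y)[0, 1]
        r2[j] = r * r
    return R2Result(
        scheme=scheme,
        n_pool=n_pool,
        r2=r2,
        meta={"group": group, "n_individuals": len(truth_callsets)},
    )


@dataclass
class PanelComparison:
    """Aligned per-run error tables plus pairwise per-bin rate ratios."""

    tables: Dict[str, BinnedErrorTable]

    def ratios(self) -> pd.DataFrame:
        labels = None
        cols: Dict[str, np.ndarray] = {}
        for run, table in self.tables.items():
            labels = list(table.labels)
            cols[run] = table.rate
        df = pd.DataFrame({"bin": labels, **{f"rate_{r}": v for r, v in cols.items()}})
        runs = list(self.tables)
        with np.errstate(invalid="ignore", divide="ignore"):
            for i, a in enumerate(runs):
                for b_run in runs[i + 1 :]:
                    df[f"ratio_{a}_vs_{b_run}"] = cols[a] / cols[b_run]
        return df


def compare_reference_panels(
    truth: Callset,
    imputed_runs: Mapping[str, Callset],
    freqs: FrequencyTable,
    scheme: BinningScheme,
    universe: str = "all_sites",
    group: str = "ALL",
) -> PanelComparison:
    """Error tables for several imputation runs of one individual.

    Every run must cover the same site universe (imputation against a
    different reference panel still outputs the same target sites); a
    mismatch raises :class:`UniverseError`.
    """
    site_sets = {run: frozenset(s.key for s in cs.sites) for run, cs in imputed_runs.items()}
    ref: Optional[frozenset] = None
    for run, ss in site_sets.items():
        if ref is None:
            ref = ss
        elif ss != ref:
            raise UniverseError(
                f"run {run!r} covers a different site universe than the others"
            )
    tables = {
        run: imputation_error(truth, cs, universe, freqs, scheme, group)
        for run, cs in imputed_runs.items()
    }
    return PanelComparison(tables=tables)


__all__ = [
    "R2Result",
    "PanelComparison",
    "imputation_error",
    "filter_by_info",
    "pooled_r2",
    "compare_reference_panels",
]
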