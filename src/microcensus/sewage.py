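"""Sewage preprocessing: family-level taxonomic filter and OTU screening.

Raw sewage mixes a gut-microbiome signal with organisms native to the water
matrix.  Before census estimation, taxa are restricted to the family-level
clades that dominate a reference gut cohort (the smallest family prefix
covering a target share of reads, minus families with a plausible tap-water
niche), samples are renormalized over the retained taxa, and individual
OTUs whose mean abundance differs significantly between sewage and the
reference cohort are screened out with Welch's two-sample t-test.

The Welch screen deliberately applies no multiple-testing correction: it
retains OTUs at raw p > alpha, i.e. it is a feature screen that errs toward
dropping OTUs, not an inference procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import OtuTable, TaxonomyMap, UNKNOWN_FAMILY, to_relative

__all__ = [
    "DEFAULT_EXCLUDED_FAMILIES",
    "FamilyFilter",
    "build_family_filter",
    "apply_family_filter",
    "welch_retain",
]

#: Families with a plausible ecological niche in tap water, excluded from
#: the gut filter by default.
DEFAULT_EXCLUDED_FAMILIES = frozenset({"Enterobacteriaceae", "Burkholderiaceae"})


@dataclass
class FamilyFilter:
    """Set of gut-associated families retained for census estimation."""

    retained: frozenset
    coverage: float
    excluded: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.retained = frozenset(self.retained)
        self.excluded = frozenset(self.excluded)
        if self.retained & self.excluded:
            raise ValueError("retained and excluded families overlap")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage target must lie in (0, 1]")

    def to_tsv(self, path: str | Path, shares: pd.Series | None = None) -> None:
        families = sorted(self.retained | self.excluded)
        df = pd.DataFrame(
            {
                "family": families,
                "share": [None if shares is None else shares.get(f) for f in families],
                "retained": [f in self.retained for f in families],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def _family_shares(table: OtuTable, taxonomy: TaxonomyMap) -> pd.Series:
    """Share of total reads per family, descending."""
    totals = table.data.sum(axis=0)
    families = pd.Series(
        [taxonomy.family_of(t) for t in table.taxon_ids], index=table.data.columns
    )
    shares = totals.groupby(families).sum()
    return (shares / shares.sum()).sort_values(ascending=False)


def build_family_filter(
    reference: OtuTable,
    taxonomy: TaxonomyMap,
    coverage: float = 0.99,
    exclude: frozenset = DEFAULT_EXCLUDED_FAMILIES,
) -> FamilyFilter:
    """Select the smallest family prefix covering ``coverage`` of reference reads.

    Families are ranked by total read share in the reference cohort; the
    shortest descending prefix reaching the coverage target is retained, and
    the excluded families are removed from the retained set afterwards (so
    exclusion cannot be compensated by extending the prefix).
    """
    if len(taxonomy) == 0:
        raise ValueError("empty taxonomy map")
    shares = _family_shares(reference, taxonomy)
    cumulative = shares.cumsum()
    cutoff = int(np.searchsorted(cumulative.to_numpy(), coverage) + 1)
    retained = set(shares.index[:cutoff]) - set(exclude)
    return FamilyFilter(
        retained=frozenset(retained), coverage=coverage, excluded=frozenset(exclude)
    )


def apply_family_filter(
    table: OtuTable,
    taxonomy: TaxonomyMap,
    family_filter: FamilyFilter,
    keep_unknown: bool = False,
) -> tuple[OtuTable, pd.Series]:
    """Drop taxa outside the retained families and renormalize each sample.

    Returns the filtered relative-abundance table and the per-sample
    retained read fraction.  Samples losing all reads are dropped (they
    carry no gut signal to estimate from).  Unknown-family taxa are dropped
    unless ``keep_unknown`` and the sentinel family was retained.
    """
    retained_set = set(family_filter.retained)
    if not keep_unknown:
        retained_set.discard(UNKNOWN_FAMILY)
    keep = [t for t in table.taxon_ids if taxonomy.family_of(t) in retained_set]
    if not keep:
        raise ValueError("no taxa fall inside the retained families")
    totals = table.data.sum(axis=1)
    kept_reads = table.data.loc[:, keep].sum(axis=1)
    fraction = (kept_reads / totals).rename("retained_fraction")
    nonzero = kept_reads > 0
    filtered = OtuTable(table.data.loc[nonzero, keep].copy(), is_relative=False)
    return to_relative(filtered), fraction


def welch_retain(
    sewage: OtuTable,
    reference: OtuTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen OTUs by Welch's unequal-variance two-sample t-test.

    For each OTU present in both tables with at least two observations per
    side, tests the null of equal means between sewage and reference
    samples; OTUs with two-sided p > ``alpha`` (mean not significantly
    different from the gut cohort) are flagged retained.  Returns a frame
    with columns otu, t, df, p, retained; OTUs absent from either table are
    listed with NaN statistics and retained = False.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    shared = [t for t in sewage.taxon_ids if t in reference.data.columns]
    missing = [t for t in sewage.taxon_ids if t not in reference.data.columns]
    for otu in shared:
        a = sewage.data[otu].to_numpy(dtype=float)
        b = reference.data[otu].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            rows.append((otu, np.nan, np.nan, np.nan, False))
            continue
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb == 0:
            # both sides constant: equal constants carry no evidence of a
            # difference, unequal constants are an exact difference
            equal = a.mean() == b.mean()
            t, p, df = (0.0, 1.0, np.nan) if equal else (np.inf, 0.0, np.nan)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            df = (va + vb) ** 2 / (
                va**2 / (a.size - 1) + vb**2 / (b.size - 1)
            )
        rows.append((otu, float(t), float(df), float(p), bool(p > alpha)))
    for otu in missing:
        rows.append((otu, np.nan, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["otu", "t", "df", "p", "retained"])
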