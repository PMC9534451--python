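"""Sub-species diversity from pooled allele counts.

A sewage sample pools the strains of many hosts, so the nucleotide
diversity and the number of polymorphic sites of a prevalent gut species
grow as more hosts contribute.  This module computes those metrics from
per-sample allele-count profiles over marker genes and simulates their
growth with the number of aggregated hosts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ALLELES",
    "SnvProfile",
    "DiversitySummary",
    "nucleotide_diversity",
    "polymorphic_sites",
    "aggregate_profiles",
    "diversity_vs_population",
]

ALLELES = ("A", "C", "G", "T")
_ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}


@dataclass
class SnvProfile:
    """Per-sample allele counts over the sites of one species' marker genes.

    ``counts`` is a genes x sites x 4 tensor of non-negative integers in the
    A, C, G, T allele order; site indices are 1-based in the TSV
    serialization and 0-based in the array.
    """

    species: str
    gene_ids: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != 4:
            raise ValueError("counts must be genes x sites x 4")
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length must match the counts tensor")
        if np.any(self.counts < 0):
            raise ValueError("allele counts must be non-negative")

    @property
    def depths(self) -> np.ndarray:
        """Per-site depth: the sum of the four allele counts."""
        return self.counts.sum(axis=2)

    def to_tsv(self, path: str | Path) -> None:
        """Write in long format (species, gene, site, allele, count),
        omitting zero counts."""
        rows = []
        for g, gid in enumerate(self.gene_ids):
            for s in range(self.counts.shape[1]):
                for a, allele in enumerate(ALLELES):
                    c = int(self.counts[g, s, a])
                    if c:
                        rows.append((self.species, gid, s + 1, allele, c))
        pd.DataFrame(
            rows, columns=["species", "gene", "site", "allele", "count"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SnvProfile":
        df = pd.read_csv(path, sep="\t", dtype={"species": str, "gene": str})
        species = df["species"].unique()
        if len(species) != 1:
            raise ValueError(f"expected one species per file, got {list(species)}")
        if df.duplicated(["gene", "site", "allele"]).any():
            raise ValueError("duplicate (gene, site, allele) record")
        gene_ids = sorted(df["gene"].unique())
        n_sites = int(df["site"].max())
        counts = np.zeros((len(gene_ids), n_sites, 4), dtype=np.int64)
        gidx = {g: i for i, g in enumerate(gene_ids)}
        for rec in df.itertuples(index=False):
            counts[gidx[rec.gene], rec.site - 1, _ALLELE_INDEX[rec.allele]] = rec.count
        return cls(species=str(species[0]), gene_ids=gene_ids, counts=counts)


@dataclass
class DiversitySummary:
    """Per-gene and species-level diversity of one profile."""

    species: str
    per_gene: pd.DataFrame  # columns: gene, pi, polymorphic, covered
    pi: float  # species-level: mean of gene-level pi over covered genes
    polymorphic: int  # species-level: total polymorphic sites
    covered: int


def _site_heterozygosity(counts: np.ndarray, min_depth: int) -> tuple:
    """Per-site heterozygosity with the small-depth D/(D-1) correction.

    Returns (h, covered_mask) for one gene's sites x 4 count block.
    """
    depths = counts.sum(axis=1).astype(float)
    covered = depths >= min_depth
    h = np.zeros(counts.shape[0])
    d = depths[covered]
    freqs = counts[covered] / d[:, None]
    h[covered] = (d / (d - 1.0)) * (1.0 - np.sum(freqs**2, axis=1))
    return h, covered


def nucleotide_diversity(profile: SnvProfile, min_depth: int = 2) -> DiversitySummary:
    """Mean per-site heterozygosity over covered sites, averaged over genes.

    A site is covered when its depth is at least ``min_depth`` (default 2,
    the minimum at which heterozygosity is defined).  Gene-level pi is the
    mean site heterozygosity over the gene's covered sites; species-level pi
    averages over genes that have covered sites.
    """
    rows = []
    for g, gid in enumerate(profile.gene_ids):
        h, covered = _site_heterozygosity(profile.counts[g], min_depth)
        n_cov = int(covered.sum())
        pi = float(h[covered].mean()) if n_cov else np.nan
        poly = int(np.sum(h[covered] > 0))
        rows.append((gid, pi, poly, n_cov))
    per_gene = pd.DataFrame(rows, columns=["gene", "pi", "polymorphic", "covered"])
    if per_gene["covered"].sum() == 0:
        raise ValueError(f"no site reaches depth {min_depth} in {profile.species!r}")
    valid = per_gene["covered"] > 0
    return DiversitySummary(
        species=profile.species,
        per_gene=per_gene,
        pi=float(per_gene.loc[valid, "pi"].mean()),
        polymorphic=int(per_gene["polymorphic"].sum()),
        covered=int(per_gene["covered"].sum()),
    )


def polymorphic_sites(
    profile: SnvProfile, min_minor_count: int = 1, min_depth: int = 2
) -> int:
    """Number of covered sites with minor-allele evidence.

    A site counts when its depth reaches ``min_depth`` and the reads not
    carrying the major allele number at least ``min_minor_count``.
    """
    depths = profile.depths
    covered = depths >= min_depth
    minor = depths - profile.counts.max(axis=2)
    return int(np.sum(covered & (minor >= min_minor_count)))


def aggregate_profiles(profiles: Sequence[SnvProfile]) -> SnvProfile:
    """Pool profiles of the same species by summing allele counts."""
    if not profiles:
        raise ValueError("at least one profile is required")
    first = profiles[0]
    for other in profiles[1:]:
        if other.species != first.species:
            raise ValueError(
                f"species mismatch: {first.species!r} vs {other.species!r}"
            )
        if other.gene_ids != first.gene_ids or other.counts.shape != first.counts.shape:
            raise ValueError("profiles use different gene/site coordinate systems")
    total = np.sum([p.counts for p in profiles], axis=0)
    return SnvProfile(species=first.species, gene_ids=list(first.gene_ids), counts=total)


def diversity_vs_population(
    profiles: Sequence[SnvProfile],
    sizes: Sequence[int],
    reps: int = 50,
    seed: int = 0,
    min_minor_count: int = 1,
    min_depth: int = 2,
) -> tuple[pd.DataFrame, float]:
    """Simulate diversity growth with the number of aggregated hosts.

    For each size, ``reps`` without-replacement host subsets are aggregated
    and summarized.  Returns the per-size curve (mean and sd of pi and of
    the polymorphic-site count) and the Pearson correlation between the mean
    polymorphic-site count and the size.
    """
    n_hosts = len(profiles)
    if max(sizes) > n_hosts:
        raise ValueError(
            f"size {max(sizes)} exceeds the number of hosts ({n_hosts})"
        )
    rng = np.random.default_rng(seed)
    records = []
    for size in sizes:
        pis, polys = [], []
        n_draws = 1 if size == n_hosts else reps
        for _ in range(n_draws):
            idx = rng.choice(n_hosts, size=size, replace=False)
            agg = aggregate_profiles([profiles[i] for i in idx])
            pis.append(nucleotide_diversity(agg, min_depth=min_depth).pi)
            polys.append(polymorphic_sites(agg, min_minor_count, min_depth))
        records.append(
            {
                "size": size,
                "pi_mean": float(np.mean(pis)),
                "pi_sd": float(np.std(pis)),
                "polymorphic_mean": float(np.mean(polys)),
                "polymorphic_sd": float(np.std(polys)),
                "reps": n_draws,
            }
        )
    curve = pd.DataFrame(records)
    if len(sizes) >= 2:
        r = float(stats.pearsonr(curve["size"], curve["polymorphic_mean"])[0])
    else:
        r = np.nan
    return curve, r
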