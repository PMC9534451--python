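"""Synthetic cohorts, counts, sewage samples, and SNV populations.

Every downstream module is testable without any external download: the
generators here emulate the statistical structure the census method relies
on — heavy-tailed (log-normal) inter-host variation in taxon relative
abundances, multinomial sequencing noise, sewage as a gut mixture diluted by
water-associated background taxa, and sub-species variation driven by a
small pool of population haplotypes per gene.

All generators are seed-deterministic and return their ground-truth
parameters alongside the data so tests can do parameter recovery against
analytic truth rather than against the implementation under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import OtuTable, TaxonomyMap
from .subspecies import SnvProfile

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "SewageSample",
    "SnvPopulation",
    "cohort_spec",
    "synth_cohort",
    "synth_counts",
    "synth_taxonomy",
    "synth_sewage",
    "synth_snv_population",
    "PRESETS",
]

#: Fixture presets: desk-scale and full cohort-scale.
PRESETS = {
    "small": {"n0": 200, "p": 50},
    "cohort_scale": {"n0": 1100, "p": 300},
}

WATER_FAMILIES = ("Enterobacteriaceae", "Burkholderiaceae")

# Gut-associated bacterial families used to label synthetic taxa; a realistic
# roster so family-level filtering behaves as it would on survey data.
GUT_FAMILIES = (
    "Lachnospiraceae",
    "Ruminococcaceae",
    "Bacteroidaceae",
    "Bifidobacteriaceae",
    "Erysipelotrichaceae",
    "Prevotellaceae",
    "Veillonellaceae",
    "Akkermansiaceae",
    "Christensenellaceae",
    "Rikenellaceae",
    "Tannerellaceae",
    "Oscillospiraceae",
    "Eubacteriaceae",
    "Clostridiaceae",
    "Streptococcaceae",
    "Lactobacillaceae",
    "Desulfovibrionaceae",
    "Sutterellaceae",
    "Acidaminococcaceae",
    "Methanobacteriaceae",
)


@dataclass
class CohortSpec:
    """Ground-truth parameters of a synthetic cohort.

    Per taxon j, a host's pre-normalization abundance is a zero-inflated
    log-normal: 0 with probability ``zero_inflation[j]``, otherwise
    LogNormal(log_mean[j], log_sd[j]).  Rows are then closed to the simplex.
    """

    n0: int
    p: int
    log_mean: np.ndarray
    log_sd: np.ndarray
    zero_inflation: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.log_mean = np.asarray(self.log_mean, dtype=float)
        self.log_sd = np.asarray(self.log_sd, dtype=float)
        self.zero_inflation = np.asarray(self.zero_inflation, dtype=float)
        if self.p < 2:
            raise ValueError("need at least 2 taxa")
        for name, v in (
            ("log_mean", self.log_mean),
            ("log_sd", self.log_sd),
            ("zero_inflation", self.zero_inflation),
        ):
            if v.shape != (self.p,):
                raise ValueError(f"{name} must have length p = {self.p}")
        if np.any(self.log_sd <= 0):
            raise ValueError("log_sd must be strictly positive")
        if np.any((self.zero_inflation < 0) | (self.zero_inflation >= 1)):
            raise ValueError("zero_inflation must lie in [0, 1)")

    def analytic_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Pre-normalization mean and variance of each taxon's abundance."""
        m, s, q = self.log_mean, self.log_sd, self.zero_inflation
        e1 = np.exp(m + s**2 / 2)
        e2 = np.exp(2 * m + 2 * s**2)
        mean = (1 - q) * e1
        var = (1 - q) * e2 - mean**2
        return mean, var


@dataclass
class SyntheticCohort:
    """A generated cohort table together with its generating truth."""

    table: OtuTable
    spec: CohortSpec
    redraws: int = 0


def cohort_spec(
    n0: int = 1100,
    p: int = 300,
    seed: int = 0,
    zero_inflation: float = 0.05,
    log_mean_sd: float = 2.0,
    log_sd_range: tuple = (0.5, 2.0),
) -> CohortSpec:
    """Draw a realistic cohort specification.

    Defaults emulate a population-scale 16S gut survey: a few hundred taxa
    whose mean abundances span orders of magnitude (log-means spread with
    standard deviation ``log_mean_sd`` on the natural-log scale, giving a
    heavy-tailed rank-abundance curve), inter-host log-standard-deviations
    between 0.5 and 2 (so different taxa's mixture variances shrink at
    different rates), and mild zero inflation.
    """
    rng = np.random.default_rng(seed)
    return CohortSpec(
        n0=n0,
        p=p,
        log_mean=rng.normal(0.0, log_mean_sd, size=p),
        log_sd=rng.uniform(*log_sd_range, size=p),
        zero_inflation=np.full(p, float(zero_inflation)),
        seed=seed,
    )


def synth_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a relative-abundance cohort table from a spec.

    Any all-zero row (possible only under zero inflation) is redrawn; the
    number of redraws is recorded on the result.
    """
    rng = np.random.default_rng(spec.seed)
    rows = np.empty((spec.n0, spec.p))
    redraws = 0
    for i in range(spec.n0):
        while True:
            raw = rng.lognormal(spec.log_mean, spec.log_sd)
            keep = rng.random(spec.p) >= spec.zero_inflation
            raw = raw * keep
            total = raw.sum()
            if total > 0:
                rows[i] = raw / total
                break
            redraws += 1
    data = pd.DataFrame(
        rows,
        index=[f"host_{i:04d}" for i in range(spec.n0)],
        columns=[f"otu_{j:04d}" for j in range(spec.p)],
    )
    return SyntheticCohort(OtuTable(data, is_relative=True), spec, redraws)


def synth_counts(cohort: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Multinomial read counts at a fixed sequencing depth per sample."""
    if not cohort.is_relative:
        raise ValueError("synth_counts expects a relative-abundance table")
    if depth < 1:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    counts = np.vstack(
        [rng.multinomial(depth, row) for row in cohort.values]
    ).astype(float)
    return OtuTable(
        pd.DataFrame(counts, index=cohort.data.index, columns=cohort.data.columns),
        is_relative=False,
    )


def synth_taxonomy(
    taxon_ids: Sequence,
    seed: int = 0,
    families: Sequence[str] = GUT_FAMILIES,
    unknown_fraction: float = 0.0,
) -> TaxonomyMap:
    """Assign taxa to families with heavy-tailed family sizes.

    Families are sampled with geometric-decay weights so a handful dominate,
    as in real gut surveys.  A fraction of taxa can be left unassigned.
    """
    rng = np.random.default_rng(seed)
    weights = 0.7 ** np.arange(len(families))
    weights = weights / weights.sum()
    mapping = {}
    for tid in taxon_ids:
        if unknown_fraction and rng.random() < unknown_fraction:
            continue
        mapping[tid] = families[int(rng.choice(len(families), p=weights))]
    return TaxonomyMap(mapping)


@dataclass
class SewageSample:
    """Synthetic sewage: an n-person gut mixture diluted by background taxa."""

    table: OtuTable
    taxonomy: TaxonomyMap
    true_n: int
    background_fraction: float
    pure_mixture: np.ndarray = field(repr=False, default=None)


def synth_sewage(
    cohort: OtuTable,
    n: int,
    background_fraction: float = 0.25,
    background_taxa: int = 10,
    seed: int = 0,
    taxonomy: TaxonomyMap | None = None,
) -> SewageSample:
    """Build one synthetic sewage sample.

    ``n`` random hosts (without replacement) are mixed evenly; background
    taxa assigned to water-associated families are then added so that they
    occupy ``background_fraction`` of the sample.  The returned taxonomy
    covers both gut and background taxa.
    """
    if not cohort.is_relative:
        raise ValueError("synth_sewage expects a relative-abundance cohort")
    if not 0 <= background_fraction < 1:
        raise ValueError("background_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.choice(cohort.n_samples, size=n, replace=False)
    gut = cohort.values[idx].mean(axis=0)
    if taxonomy is None:
        taxonomy = synth_taxonomy(cohort.taxon_ids, seed=seed)
    mapping = dict(taxonomy.mapping)
    if background_fraction > 0 and background_taxa > 0:
        bg_ids = [f"water_{j:03d}" for j in range(background_taxa)]
        bg_props = rng.dirichlet(np.ones(background_taxa)) * background_fraction
        values = np.concatenate([gut * (1 - background_fraction), bg_props])
        columns = list(cohort.taxon_ids) + bg_ids
        for j, bid in enumerate(bg_ids):
            mapping[bid] = WATER_FAMILIES[j % len(WATER_FAMILIES)]
    else:
        values = gut
        columns = list(cohort.taxon_ids)
    data = pd.DataFrame([values], index=["sewage_0"], columns=columns)
    return SewageSample(
        table=OtuTable(data, is_relative=True),
        taxonomy=TaxonomyMap(mapping),
        true_n=n,
        background_fraction=background_fraction,
        pure_mixture=gut,
    )


@dataclass
class SnvPopulation:
    """Synthetic host SNV profiles plus the generating haplotype pool."""

    profiles: list
    pool: np.ndarray  # genes x pool_size x sites, allele indices 0..3
    assignments: np.ndarray  # hosts x genes, index into the pool

    def pool_polymorphic_sites(self, hosts: Sequence[int] | None = None) -> int:
        """Exact polymorphic-site count implied by the haplotypes of a host
        subset (all hosts by default), ignoring sequencing noise."""
        hosts = range(self.assignments.shape[0]) if hosts is None else hosts
        total = 0
        for g in range(self.pool.shape[0]):
            haps = self.pool[g, self.assignments[list(hosts), g]]
            total += int(np.sum(np.any(haps != haps[0], axis=0)))
        return total


def synth_snv_population(
    hosts: int,
    genes: int = 10,
    sites_per_gene: int = 100,
    haplotype_pool_size: int = 5,
    depth: int = 50,
    seed: int = 0,
    noise_rate: float = 0.0,
    divergence: float = 0.02,
    species: str = "synthetic_species",
) -> SnvPopulation:
    """Generate per-host allele-count profiles driven by shared haplotypes.

    Each gene has a pool of ``haplotype_pool_size`` population haplotypes
    derived from one random reference sequence by substituting a
    ``divergence`` fraction of sites per haplotype (marker genes of
    conspecific strains differ at a few percent of positions, so distinct
    haplotypes carry mostly private variants).  Each host carries one pool
    haplotype per gene (drawn uniformly), read at ``depth`` coverage.
    ``noise_rate`` is the per-read probability of a random substitute allele
    (within-host minor-allele noise); the default 0 makes single hosts
    exactly clonal, so all observed polymorphism in an aggregate comes from
    between-host haplotype variation.
    """
    if haplotype_pool_size < 1:
        raise ValueError("haplotype_pool_size must be >= 1")
    if not 0 < divergence <= 1:
        raise ValueError("divergence must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_sub = max(1, int(round(divergence * sites_per_gene)))
    pool = np.empty((genes, haplotype_pool_size, sites_per_gene), dtype=np.int64)
    for g in range(genes):
        reference = rng.integers(0, 4, size=sites_per_gene)
        pool[g, 0] = reference
        for h in range(1, haplotype_pool_size):
            hap = reference.copy()
            where = rng.choice(sites_per_gene, size=n_sub, replace=False)
            hap[where] = (hap[where] + rng.integers(1, 4, size=n_sub)) % 4
            pool[g, h] = hap
    assignments = rng.integers(0, haplotype_pool_size, size=(hosts, genes))
    gene_ids = [f"gene_{g:02d}" for g in range(genes)]
    profiles = []
    for h in range(hosts):
        counts = np.zeros((genes, sites_per_gene, 4), dtype=np.int64)
        for g in range(genes):
            hap = pool[g, assignments[h, g]]
            if noise_rate > 0:
                errors = rng.binomial(depth, noise_rate, size=sites_per_gene)
                for s in range(sites_per_gene):
                    counts[g, s, hap[s]] = depth - errors[s]
                    if errors[s]:
                        others = [a for a in range(4) if a != hap[s]]
                        counts[g, s, others] += rng.multinomial(
                            errors[s], np.full(3, 1 / 3)
                        )
            else:
                counts[g, np.arange(sites_per_gene), hap] = depth
        profiles.append(
            SnvProfile(species=species, gene_ids=list(gene_ids), counts=counts)
        )
    return SnvPopulation(profiles=profiles, pool=pool, assignments=assignments)
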