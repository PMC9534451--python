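"""Reference-cohort model: feature selection and moment estimation.

The census statistic compares a mixture profile against the per-taxon mean
and standard deviation of relative abundances in a reference cohort of
single-host gut microbiomes.  Only the diagonal of the cohort covariance is
estimated: with hundreds of taxa and O(1000) hosts the full covariance is
ill-conditioned or singular, while its diagonal is estimable coordinate by
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import OtuTable

__all__ = ["ReferenceModel", "select_top_features", "fit_reference"]

_SCHEMA_VERSION = 1


@dataclass
class ReferenceModel:
    """Selected taxa with estimated population mean and standard deviation.

    Attributes
    ----------
    feature_ids
        Ordered taxon identifiers (length p).
    mu_hat
        Per-taxon mean relative abundance over the reference cohort.
    sigma_hat
        Per-taxon standard deviation, the square root of the population
        variance estimator with divisor n0 (not n0 - 1).
    n0
        Reference cohort size.
    """

    feature_ids: list
    mu_hat: np.ndarray
    sigma_hat: np.ndarray
    n0: int

    def __post_init__(self) -> None:
        self.mu_hat = np.asarray(self.mu_hat, dtype=float)
        self.sigma_hat = np.asarray(self.sigma_hat, dtype=float)
        p = len(self.feature_ids)
        if self.mu_hat.shape != (p,) or self.sigma_hat.shape != (p,):
            raise ValueError("feature_ids, mu_hat and sigma_hat lengths differ")
        if np.any(self.sigma_hat <= 0):
            bad = self.feature_ids[int(np.argmin(self.sigma_hat))]
            raise ValueError(f"non-positive standard deviation for feature {bad!r}")
        if np.any((self.mu_hat < 0) | (self.mu_hat > 1)):
            raise ValueError("mean relative abundances must lie in [0, 1]")

    @property
    def p(self) -> int:
        return len(self.feature_ids)

    def save(self, path: str | Path) -> None:
        """Serialize to a plain-text key-value header plus feature table."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# microcensus-reference-model v{_SCHEMA_VERSION}\n")
            fh.write(f"# n0\t{self.n0}\n")
            fh.write("feature_id\tmu_hat\tsigma_hat\n")
            for fid, mu, sd in zip(self.feature_ids, self.mu_hat, self.sigma_hat):
                fh.write(f"{fid}\t{float(mu)!r}\t{float(sd)!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceModel":
        path = Path(path)
        lines = path.read_text().splitlines()
        if not lines or not lines[0].startswith("# microcensus-reference-model"):
            raise ValueError(f"{path} is not a reference model file")
        version = int(lines[0].rsplit("v", 1)[1])
        if version != _SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {version}")
        n0 = int(lines[1].split("\t")[1])
        body = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype={"feature_id": str},
            float_precision="round_trip",
        )
        return cls(
            feature_ids=body["feature_id"].tolist(),
            mu_hat=body["mu_hat"].to_numpy(),
            sigma_hat=body["sigma_hat"].to_numpy(),
            n0=n0,
        )


def select_top_features(
    table: OtuTable, k: int, rank_by: str = "mean"
) -> list:
    """Rank taxa by abundance over the cohort and return the top ``k``.

    Taxa with zero cross-sample variance are skipped regardless of abundance
    (they would make the standard-deviation matrix singular).  Ties in the
    ranking statistic are broken lexicographically by taxon id.

    Parameters
    ----------
    table
        Relative-abundance cohort table.
    k
        Number of features to keep.
    rank_by
        ``"mean"`` (default) or ``"median"`` relative abundance.
    """
    if not table.is_relative:
        raise ValueError("feature selection expects a relative-abundance table")
    if rank_by not in ("mean", "median"):
        raise ValueError(f"rank_by must be 'mean' or 'median', got {rank_by!r}")
    values = table.values
    variances = values.var(axis=0)
    eligible = variances > 0
    n_eligible = int(eligible.sum())
    if k > n_eligible:
        raise ValueError(
            f"requested {k} features but only {n_eligible} taxa have nonzero "
            "cross-sample variance"
        )
    stat = values.mean(axis=0) if rank_by == "mean" else np.median(values, axis=0)
    taxa = np.asarray(table.taxon_ids, dtype=object)
    order = sorted(
        np.where(eligible)[0], key=lambda j: (-stat[j], str(taxa[j]))
    )
    return [taxa[j] for j in order[:k]]


def fit_reference(
    table: OtuTable, features: list, robust: bool = False
) -> ReferenceModel:
    """Estimate per-taxon mean and standard deviation over the cohort.

    The default estimators are the cohort mean and the population standard
    deviation (divisor n0).  With ``robust=True`` the median and the scaled
    median absolute deviation (consistent for the normal) are used instead,
    a simple guard for heavy-tailed taxa.
    """
    if not table.is_relative:
        raise ValueError("fit_reference expects a relative-abundance table")
    if table.n_samples < 2:
        raise ValueError("at least 2 reference samples are required")
    missing = [f for f in features if f not in table.data.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")
    x = table.data.loc[:, features].to_numpy(dtype=float)
    n0 = table.n_samples
    if robust:
        mu = np.median(x, axis=0)
        sigma = 1.4826 * np.median(np.abs(x - mu), axis=0)
    else:
        mu = x.mean(axis=0)
        sigma = np.sqrt(np.sum((x - mu) ** 2, axis=0) / n0)
    zero = np.where(sigma <= 0)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance feature {features[int(zero[0])]!r} cannot be fitted"
        )
    return ReferenceModel(list(features), mu, sigma, n0)
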