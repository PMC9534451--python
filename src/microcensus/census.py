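"""The census statistic, bootstrap nulls, and maximum-likelihood size estimation.

The statistic for a mixture profile w against a reference model is

    T = sum_j ((w_j - mu_hat_j) / sigma_hat_j)^2,

the squared Euclidean norm of the per-taxon standardized deviation from the
cohort mean.  It is the diagonal-covariance analogue of Hotelling's T^2
(T_tilde = n * T when the cohort covariance is diagonal), chosen because
with p comparable to or exceeding the cohort size the full sample covariance
is singular while its diagonal remains well estimated.

Because an n-person mixture is a mean of n host profiles, T shrinks roughly
as 1/n; the sampling distribution of T at each candidate n, simulated by
resampling the reference cohort, serves as a likelihood for n.  A point
estimate maximizes the kernel-density-estimated likelihood over a discrete
grid n = 1..N, and a one-sided confidence interval [1, q_hat / T0] follows
from the asymptotically n-free distribution of n*T.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .datamodel import OtuTable
from .reference import ReferenceModel

__all__ = [
    "TStatNull",
    "CensusModel",
    "CensusEstimate",
    "t_statistic",
    "build_null",
    "density_at",
    "estimate_population",
    "estimate_many",
]

logger = logging.getLogger(__name__)

NullMode = Literal["plain_bootstrap", "subsample_corrected"]

_MIN_BANDWIDTH = 1e-12
_ARCHIVE_VERSION = 1


def _silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, floored at a tiny positive value.

    Uses the robust min(sd, IQR/1.34) spread estimate.  A degenerate
    all-equal sample falls back to the floor (point mass), which is logged.
    """
    b = samples.size
    sd = samples.std()
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * b ** (-0.2)
    if h < _MIN_BANDWIDTH:
        logger.warning(
            "degenerate statistic sample (spread %.3g); bandwidth floored", spread
        )
        return _MIN_BANDWIDTH
    return float(h)


@dataclass
class TStatNull:
    """Bootstrap sample of the statistic at one candidate population size."""

    n: int
    t_samples: np.ndarray
    bandwidth: float
    mode: NullMode

    def __post_init__(self) -> None:
        self.t_samples = np.asarray(self.t_samples, dtype=float)
        if self.t_samples.size < 100:
            raise ValueError("at least 100 bootstrap replicates are required")
        if np.any(self.t_samples < 0):
            raise ValueError("statistic samples must be non-negative")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass
class CensusModel:
    """Reference model plus per-size bootstrap null distributions for n = 1..N."""

    reference: ReferenceModel
    nulls: list
    N: int
    B: int
    mode: NullMode
    seed: int
    train_sample_ids: list | None = None

    def __post_init__(self) -> None:
        if len(self.nulls) != self.N or any(
            null.n != i + 1 for i, null in enumerate(self.nulls)
        ):
            raise ValueError("nulls must be indexed contiguously 1..N")
        if self.N > self.reference.n0 / 3:
            logger.warning(
                "N = %d exceeds n0/3 = %.0f; the subsampling theory wants "
                "n much smaller than the cohort size",
                self.N,
                self.reference.n0 / 3,
            )

    def null_for(self, n: int) -> TStatNull:
        if not 1 <= n <= self.N:
            raise ValueError(f"candidate size {n} outside 1..{self.N}")
        return self.nulls[n - 1]

    def pooled_nt(self) -> np.ndarray:
        """All n * T samples pooled across candidate sizes."""
        return np.concatenate(
            [null.n * null.t_samples for null in self.nulls]
        )

    def save(self, directory: str | Path) -> None:
        """Serialize to a directory of plain-text files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.reference.save(directory / "reference.tsv")
        meta = {
            "version": _ARCHIVE_VERSION,
            "N": self.N,
            "B": self.B,
            "mode": self.mode,
            "seed": self.seed,
            "bandwidths": [null.bandwidth for null in self.nulls],
            "train_sample_ids": self.train_sample_ids,
        }
        (directory / "meta.json").write_text(json.dumps(meta))
        matrix = np.column_stack([null.t_samples for null in self.nulls])
        pd.DataFrame(matrix, columns=[str(n) for n in range(1, self.N + 1)]).to_csv(
            directory / "nulls.tsv", sep="\t", index=False
        )

    @classmethod
    def load(cls, directory: str | Path) -> "CensusModel":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        if meta["version"] != _ARCHIVE_VERSION:
            raise ValueError(f"unsupported archive version {meta['version']}")
        reference = ReferenceModel.load(directory / "reference.tsv")
        matrix = pd.read_csv(directory / "nulls.tsv", sep="\t").to_numpy()
        nulls = [
            TStatNull(
                n=n,
                t_samples=matrix[:, n - 1],
                bandwidth=meta["bandwidths"][n - 1],
                mode=meta["mode"],
            )
            for n in range(1, meta["N"] + 1)
        ]
        return cls(
            reference=reference,
            nulls=nulls,
            N=meta["N"],
            B=meta["B"],
            mode=meta["mode"],
            seed=meta["seed"],
            train_sample_ids=meta.get("train_sample_ids"),
        )


@dataclass
class CensusEstimate:
    """Point estimate of the contributor count with likelihood curve and CI."""

    t0: float
    n_hat: int
    loglik: np.ndarray
    alpha: float
    ci: tuple = field(default=(1, 1.0))

    def __post_init__(self) -> None:
        if self.ci[0] != 1:
            raise ValueError("confidence interval lower bound is 1 by construction")
        if self.ci[1] < 1:
            raise ValueError("confidence interval upper bound must be >= 1")


def _align_profile(w, model: ReferenceModel) -> np.ndarray:
    """Restrict/reorder a query profile to the model's feature ids."""
    if isinstance(w, OtuTable):
        if w.n_samples != 1:
            raise ValueError("expected a single-sample table")
        w = w.data.iloc[0]
    if isinstance(w, dict):
        w = pd.Series(w)
    if isinstance(w, pd.Series):
        missing = [f for f in model.feature_ids if f not in w.index]
        if missing:
            raise ValueError(f"query profile is missing features: {missing}")
        return w.loc[model.feature_ids].to_numpy(dtype=float)
    arr = np.asarray(w, dtype=float)
    if arr.shape != (model.p,):
        raise ValueError(
            f"unlabeled query profile must have length p = {model.p}, "
            f"got shape {arr.shape}"
        )
    return arr


def t_statistic(w, model: ReferenceModel) -> float:
    """Sum of squared standardized deviations of ``w`` from the cohort mean."""
    x = _align_profile(w, model)
    z = (x - model.mu_hat) / model.sigma_hat
    return float(np.dot(z, z))


def build_null(
    model: ReferenceModel,
    table: OtuTable,
    N: int = 300,
    B: int = 10_000,
    mode: NullMode = "plain_bootstrap",
    seed: int = 0,
) -> CensusModel:
    """Simulate the statistic's sampling distribution for each n = 1..N.

    ``plain_bootstrap`` resamples n hosts with replacement and computes the
    statistic against the model's mu_hat / sigma_hat.  ``subsample_corrected``
    draws a without-replacement size-n subset A, centers at the cohort mean,
    and stores ||sigma_hat^-1 (X_bar_A - X_bar_n0)||^2 / (1 - n/n0), the
    finite-population-corrected construction whose empirical law is a
    consistent estimate of the distribution of T_n.

    Replicates are built incrementally: each of the B bootstrap chains keeps
    a running sum that is extended by one freshly drawn host per candidate
    size, so each stored sample has exactly the distribution above while the
    full grid costs O(N B p) rather than O(N^2 B p).
    """
    if not table.is_relative:
        raise ValueError("build_null expects a relative-abundance cohort")
    if N < 1 or B < 100:
        raise ValueError("require N >= 1 and B >= 100")
    n0 = table.n_samples
    if mode == "subsample_corrected" and N >= n0:
        raise ValueError(
            f"subsample_corrected requires N < n0 (correction factor 1 - n/n0 "
            f"must stay positive); got N = {N}, n0 = {n0}"
        )
    if mode not in ("plain_bootstrap", "subsample_corrected"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    x = table.data.loc[:, model.feature_ids].to_numpy(dtype=float)
    inv_sigma = 1.0 / model.sigma_hat
    if mode == "plain_bootstrap":
        center = model.mu_hat
    else:
        center = x.mean(axis=0)
        # one permutation per replicate; the size-n prefix is a uniform
        # without-replacement subset for every n
        perms = np.argsort(rng.random((B, n0)), axis=1)[:, :N]
    sums = np.zeros((B, model.p))
    nulls = []
    for n in range(1, N + 1):
        if mode == "plain_bootstrap":
            idx = rng.integers(0, n0, size=B)
        else:
            idx = perms[:, n - 1]
        sums += x[idx]
        z = (sums / n - center) * inv_sigma
        t = np.einsum("ij,ij->i", z, z)
        if mode == "subsample_corrected":
            t = t / (1.0 - n / n0)
        nulls.append(
            TStatNull(n=n, t_samples=t, bandwidth=_silverman_bandwidth(t), mode=mode)
        )
    return CensusModel(
        reference=model,
        nulls=nulls,
        N=N,
        B=B,
        mode=mode,
        seed=seed,
        train_sample_ids=list(table.sample_ids),
    )


def _density_many(null: TStatNull, ts: np.ndarray) -> np.ndarray:
    """Gaussian KDE of the null, evaluated at an array of points."""
    h = null.bandwidth
    u = (ts[:, None] - null.t_samples[None, :]) / h
    return np.exp(-0.5 * u * u).mean(axis=1) / (h * np.sqrt(2 * np.pi))


def density_at(null: TStatNull, t: float) -> float:
    """Gaussian kernel density estimate of the null at ``t``."""
    return float(_density_many(null, np.asarray([t], dtype=float))[0])


def _quantile_nt(census: CensusModel, alpha: float, pool: bool, n_hat: int) -> float:
    if pool:
        return float(np.quantile(census.pooled_nt(), 1 - alpha))
    null = census.null_for(n_hat)
    return float(np.quantile(null.n * null.t_samples, 1 - alpha))


def estimate_population(
    w,
    census: CensusModel,
    alpha: float = 0.05,
    pooled_quantile: bool = True,
) -> CensusEstimate:
    """Maximum-likelihood contributor count for one mixture profile.

    The observed statistic T0 is referred to each candidate size's estimated
    density; n_hat is the size with the highest density (smallest n on exact
    ties).  The one-sided 1-alpha confidence interval is [1, q_hat / T0]
    where q_hat is the empirical (1-alpha) quantile of the n * T samples —
    pooled across all candidate sizes by default, since the limiting law of
    n * T does not depend on n; ``pooled_quantile=False`` uses the null at
    n_hat instead.
    """
    return estimate_many(
        np.asarray([_align_profile(w, census.reference)]),
        census,
        alpha=alpha,
        pooled_quantile=pooled_quantile,
    )[0]


def estimate_many(
    profiles: np.ndarray,
    census: CensusModel,
    alpha: float = 0.05,
    pooled_quantile: bool = True,
) -> list:
    """Vectorized :func:`estimate_population` for a reps x p profile matrix."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if census.N < 1 or not census.nulls:
        raise ValueError("census model holds no null distributions")
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] != census.reference.p:
        raise ValueError(
            f"profiles must be reps x p with p = {census.reference.p}"
        )
    z = (profiles - census.reference.mu_hat) / census.reference.sigma_hat
    t0s = np.einsum("ij,ij->i", z, z)
    dens = np.column_stack(
        [_density_many(null, t0s) for null in census.nulls]
    )  # reps x N
    n_hats = np.argmax(dens, axis=1) + 1  # argmax takes the first (smallest) tie
    with np.errstate(divide="ignore"):
        logliks = np.log(dens)
    estimates = []
    for i, t0 in enumerate(t0s):
        n_hat = int(n_hats[i])
        if t0 == 0.0:
            # a profile exactly at the cohort mean is "maximally mixed":
            # the KDE argmax at 0 reflects bandwidths, not likelihood, so
            # report the most-mixed candidate and a vacuous interval
            logger.warning(
                "query statistic is exactly 0 (profile at the cohort mean); "
                "reporting n_hat = N = %d with a vacuous interval",
                census.N,
            )
            n_hat = census.N
            upper = float(census.N)
        else:
            q = _quantile_nt(census, alpha, pooled_quantile, n_hat)
            upper = max(1.0, q / t0)
        estimates.append(
            CensusEstimate(
                t0=float(t0),
                n_hat=n_hat,
                loglik=logliks[i],
                alpha=alpha,
                ci=(1, upper),
            )
        )
    return estimates
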