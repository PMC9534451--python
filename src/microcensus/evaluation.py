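"""Error metrics, cohort splitting, feature tuning, and the benchmark harness.

Performance is measured by the absolute percentage error of the estimated
contributor count, delta = |n_pred - n_true| / n_true * 100%, and its mean
over predictions (MAPE).  The protocol is subject-level: the cohort is split
into disjoint train and test halves, the feature count k is tuned by
repeated holdout validation inside the training half, and the benchmark
estimates simulated mixtures built from hosts the model never saw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .census import CensusModel, build_null, estimate_many
from .datamodel import OtuTable
from .mixture import sample_mixtures
from .reference import fit_reference, select_top_features

__all__ = [
    "BenchmarkResult",
    "percentage_error",
    "mape",
    "split_cohort",
    "tune_features",
    "benchmark",
]


def percentage_error(predicted: int, actual: int) -> float:
    """delta = |n_pred - n_true| / n_true, in percent."""
    if actual < 1:
        raise ValueError("actual population size must be >= 1")
    return abs(predicted - actual) / actual * 100.0


def mape(predictions: Sequence[int], actuals: Sequence[int]) -> float:
    """Mean absolute percentage error over paired predictions, in percent."""
    predictions = np.asarray(predictions, dtype=float)
    actuals = np.asarray(actuals, dtype=float)
    if predictions.shape != actuals.shape or predictions.size == 0:
        raise ValueError("predictions and actuals must be equal-length, nonempty")
    if np.any(actuals < 1):
        raise ValueError("actual population sizes must be >= 1")
    return float(np.mean(np.abs(predictions - actuals) / actuals) * 100.0)


def split_cohort(
    table: OtuTable, fraction: float = 0.5, seed: int = 0
) -> tuple[OtuTable, OtuTable]:
    """Disjoint subject-level partition into (train, test).

    ``fraction`` is the share of subjects assigned to the training half
    (rounded to the nearest subject); the split is a uniform random
    partition, deterministic given ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = table.n_samples
    n_train = int(round(n * fraction))
    n_train = min(max(n_train, 1), n - 1)
    perm = rng.permutation(n)
    ids = np.asarray(table.sample_ids, dtype=object)
    train_ids = sorted(ids[perm[:n_train]])
    test_ids = sorted(ids[perm[n_train:]])
    return table.subset_samples(train_ids), table.subset_samples(test_ids)


@dataclass
class BenchmarkResult:
    """Per-size prediction records and the overall MAPE of one benchmark run."""

    records: pd.DataFrame  # columns: size, rep, predicted, delta_pct
    per_size: pd.DataFrame  # columns: size, mean, sd, mape_pct, reps
    mape_pct: float
    settings: dict

    def to_tsv(self, path: str | Path) -> None:
        """Per-size rows plus a trailing summary block."""
        path = Path(path)
        with path.open("w") as fh:
            self.per_size.to_csv(fh, sep="\t", index=False)
            fh.write(f"# overall_mape_pct\t{self.mape_pct!r}\n")
            for key, value in sorted(self.settings.items()):
                fh.write(f"# {key}\t{value}\n")


def _estimate_mixture_batch(
    census: CensusModel,
    table: OtuTable,
    sizes: Sequence[int],
    reps: int,
    seed: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Simulate mixtures per size from ``table`` and estimate each one."""
    features = census.reference.feature_ids
    rows = []
    for i, size in enumerate(sizes):
        batch = sample_mixtures(
            table, n=size, reps=reps, scheme="with_replacement", seed=seed + i
        )
        cols = [batch.taxon_ids.index(f) for f in features]
        profiles = batch.values[:, cols]
        for rep, est in enumerate(estimate_many(profiles, census, alpha=alpha)):
            rows.append(
                {
                    "size": size,
                    "rep": rep,
                    "predicted": est.n_hat,
                    "delta_pct": percentage_error(est.n_hat, size),
                    "t0": est.t0,
                    "ci_upper": est.ci[1],
                }
            )
    return pd.DataFrame(rows)


def tune_features(
    train: OtuTable,
    k_grid: Sequence[int],
    sizes: Sequence[int] = (1, 5, 10, 25, 50, 100),
    reps: int = 20,
    holdouts: int = 5,
    seed: int = 0,
    N: int = 150,
    B: int = 500,
) -> tuple[int, pd.DataFrame]:
    """Tune the feature count k by repeated 50-50 holdout validation.

    For each holdout split and each k, the reference model and null are
    built on one half and mixtures simulated from the other half are
    estimated; the k minimizing the mean validation MAPE across holdouts is
    returned (smallest k on ties).
    """
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    records = []
    for h in range(holdouts):
        half_a, half_b = split_cohort(train, 0.5, seed=seed * 1009 + h)
        for k in k_grid:
            features = select_top_features(half_a, k)
            model = fit_reference(half_a, features)
            census = build_null(model, half_a, N=N, B=B, seed=seed * 131 + h)
            result = _estimate_mixture_batch(
                census, half_b, sizes, reps, seed=seed * 977 + h
            )
            records.append(
                {
                    "holdout": h,
                    "k": k,
                    "mape_pct": mape(result["predicted"], result["size"]),
                }
            )
    errors = pd.DataFrame(records)
    return select_best_k(errors), errors


def select_best_k(errors: pd.DataFrame) -> int:
    """Smallest k attaining the minimal mean validation MAPE across holdouts."""
    mean_by_k = errors.groupby("k")["mape_pct"].mean().sort_index()
    return int(mean_by_k.index[np.argmin(mean_by_k.to_numpy())])


def benchmark(
    census: CensusModel,
    test: OtuTable,
    sizes: Sequence[int],
    reps: int = 1000,
    seed: int = 0,
) -> BenchmarkResult:
    """Estimate simulated mixtures of known size from held-out subjects.

    Raises if any test subject was used to build the census nulls (the
    benchmark is only meaningful on unseen hosts); pass a census built from
    the same table deliberately to measure training error by clearing
    ``census.train_sample_ids`` or using :func:`training_error`.
    """
    if census.train_sample_ids is not None:
        overlap = set(census.train_sample_ids) & set(test.sample_ids)
        if overlap:
            raise ValueError(
                f"{len(overlap)} test subjects were used to build the census "
                f"model (e.g. {sorted(overlap)[:3]})"
            )
    records = _estimate_mixture_batch(census, test, sizes, reps, seed)
    per_size = (
        records.groupby("size")
        .agg(
            mean=("predicted", "mean"),
            sd=("predicted", "std"),
            mape_pct=("delta_pct", "mean"),
            reps=("predicted", "size"),
        )
        .reset_index()
    )
    return BenchmarkResult(
        records=records,
        per_size=per_size,
        mape_pct=float(records["delta_pct"].mean()),
        settings={
            "k": census.reference.p,
            "N": census.N,
            "B": census.B,
            "mode": census.mode,
            "null_seed": census.seed,
            "benchmark_seed": seed,
            "reps_per_size": reps,
        },
    )


def training_error(
    census: CensusModel,
    train: OtuTable,
    sizes: Sequence[int],
    reps: int = 1000,
    seed: int = 0,
) -> BenchmarkResult:
    """Benchmark against mixtures drawn from the training subjects themselves."""
    records = _estimate_mixture_batch(census, train, sizes, reps, seed)
    per_size = (
        records.groupby("size")
        .agg(
            mean=("predicted", "mean"),
            sd=("predicted", "std"),
            mape_pct=("delta_pct", "mean"),
            reps=("predicted", "size"),
        )
        .reset_index()
    )
    return BenchmarkResult(
        records=records,
        per_size=per_size,
        mape_pct=float(records["delta_pct"].mean()),
        settings={"mode": "training_error", "reps_per_size": reps, "seed": seed},
    )
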