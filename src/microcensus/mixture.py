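"""Ideal sewage mixtures: equal-weight averages of individual profiles.

A sewage sample fed exclusively by the feces of n hosts, mixed evenly, has
the profile X_bar_n = sum_i X_i / n — the arithmetic mean of the hosts'
relative-abundance vectors.  Simulated mixtures of known n built from a
cohort are the training and benchmarking substrate for the census model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .datamodel import OtuTable

__all__ = ["MixtureBatch", "ideal_mixture", "sample_mixtures"]

Scheme = Literal["with_replacement", "without_replacement"]


@dataclass
class MixtureBatch:
    """A batch of simulated multi-person mixture profiles.

    ``values`` is reps x p; each row is an equal-weight mean of ``n`` cohort
    rows drawn under ``scheme``.
    """

    values: np.ndarray
    n: int
    scheme: Scheme
    seed: int
    taxon_ids: list | None = None


def ideal_mixture(profiles: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of one or more equal-length profiles."""
    if len(profiles) == 0:
        raise ValueError("at least one profile is required")
    arrays = [np.asarray(p, dtype=float) for p in profiles]
    lengths = {a.shape for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"profile length mismatch: {sorted(lengths)}")
    return np.mean(arrays, axis=0)


def sample_mixtures(
    table: OtuTable,
    n: int,
    reps: int,
    scheme: Scheme = "with_replacement",
    seed: int = 0,
) -> MixtureBatch:
    """Draw ``reps`` independent n-person mixtures from a cohort.

    ``with_replacement`` draws n hosts i.i.d. uniformly (a host may recur in
    one mixture); ``without_replacement`` draws a uniform size-n subset of
    the cohort.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n0 = table.n_samples
    if scheme == "without_replacement" and n > n0:
        raise ValueError(
            f"cannot draw {n} distinct hosts from a cohort of {n0} without replacement"
        )
    if scheme not in ("with_replacement", "without_replacement"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    x = table.values
    out = np.empty((reps, table.n_taxa))
    for r in range(reps):
        if scheme == "with_replacement":
            idx = rng.integers(0, n0, size=n)
        else:
            idx = rng.choice(n0, size=n, replace=False)
        out[r] = x[idx].mean(axis=0)
    return MixtureBatch(out, n=n, scheme=scheme, seed=seed, taxon_ids=table.taxon_ids)
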