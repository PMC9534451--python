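"""End-to-end validation protocols run on synthetic study conditions.

Each function here sets up one self-contained experiment — asymptotic
behavior of the census statistic, agreement of the two null constructions,
parameter recovery, interval coverage, screen calibration, SAD and
sub-species properties — generates its own synthetic inputs from a single
integer seed, executes the package's estimators, and returns the measured
quantities.  The pytest suite asserts on these results and the acceptance
script reports them, so the numbers always come from a fresh computation.

Problem sizes are desk-scale: a single CPU runs the full battery in a few
minutes (the heaviest run, parameter recovery on a 1,000-host cohort with
2,000 bootstrap replicates per candidate size, dominates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .census import build_null, estimate_many, t_statistic
from .datamodel import OtuTable
from .evaluation import mape
from .sewage import welch_retain
from .mixture import sample_mixtures
from .reference import ReferenceModel, fit_reference, select_top_features
from .sad import compare_sads, fit_sad
from .subspecies import (
    aggregate_profiles,
    diversity_vs_population,
    nucleotide_diversity,
)
from .synthetic import PRESETS, cohort_spec, synth_cohort, synth_counts, synth_snv_population

__all__ = [
    "chi_square_limit",
    "null_construction_agreement",
    "median_monotonicity",
    "parameter_recovery",
    "ci_coverage",
    "welch_calibration",
    "sad_recovery",
    "snv_diversity_growth",
]


def _sub(seed: int, offset: int) -> int:
    return int((seed * 1_000_003 + offset) % (2**31 - 1))


def _true_model(p: int) -> ReferenceModel:
    # standardized exponential coordinates: mean 1, sd 1, all moments finite
    return ReferenceModel(
        [f"f{j}" for j in range(p)], np.full(p, 1.0), np.full(p, 1.0), n0=10**6
    )


def chi_square_limit(
    seed: int, p: int = 20, n: int = 200, reps: int = 5000
) -> dict:
    """Distribution of n*T under known truth vs its chi-square(p) limit.

    Coordinates are i.i.d. standardized exponentials (independent, skewed,
    finite moments), with the TRUE mean and standard deviation supplied to
    the statistic, so n*T should be asymptotically chi-square with p degrees
    of freedom and E[n*T] = p exactly.
    """
    rng = np.random.default_rng(_sub(seed, 1))
    model = _true_model(p)
    nT = np.empty(reps)
    for r in range(reps):
        w = rng.exponential(1.0, size=(n, p)).mean(axis=0)
        nT[r] = n * t_statistic(w, model)
    ks = float(stats.kstest(nT, "chi2", args=(p,)).statistic)
    return {
        "ks_distance": ks,
        "mean_nT": float(nT.mean()),
        "se_mean": float(nT.std(ddof=1) / np.sqrt(reps)),
        "p": p,
        "n": n,
        "reps": reps,
    }


def null_construction_agreement(
    seed: int, n: int = 20, n0: int = 2000, p: int = 100, k: int = 50, B: int = 4000
) -> dict:
    """KS distance between the two null constructions of n*T at one size.

    The plain with-replacement bootstrap (centered at mu_hat) and the
    finite-population-corrected without-replacement subsample (centered at
    the cohort mean) both target the sampling law of T_n; with n much
    smaller than n0 they must agree.
    """
    cohort = synth_cohort(cohort_spec(n0=n0, p=p, seed=_sub(seed, 2))).table
    features = select_top_features(cohort, k)
    model = fit_reference(cohort, features)
    boot = build_null(model, cohort, N=n, B=B, mode="plain_bootstrap",
                      seed=_sub(seed, 3))
    sub = build_null(model, cohort, N=n, B=B, mode="subsample_corrected",
                     seed=_sub(seed, 4))
    ks = float(
        stats.ks_2samp(
            n * boot.null_for(n).t_samples, n * sub.null_for(n).t_samples
        ).statistic
    )
    return {"ks_distance": ks, "n": n, "n0": n0, "B": B}


def median_monotonicity(
    seed: int, sizes: tuple = (1, 5, 25, 100, 300), B: int = 1000
) -> dict:
    """Median of the bootstrap statistic across candidate sizes, per preset.

    The statistic measures squared deviation of a mixture from the cohort
    mean, which shrinks as contributors are added; its median must fall
    strictly with n on every fixture cohort.
    """
    out = {}
    for i, (preset, dims) in enumerate(sorted(PRESETS.items())):
        cohort = synth_cohort(cohort_spec(seed=_sub(seed, 5 + i), **dims)).table
        k = min(dims["p"] // 2, 120)
        model = fit_reference(cohort, select_top_features(cohort, k))
        census = build_null(model, cohort, N=max(sizes), B=B, seed=_sub(seed, 8 + i))
        medians = [float(np.median(census.null_for(n).t_samples)) for n in sizes]
        out[preset] = {
            "sizes": list(sizes),
            "medians": medians,
            "strictly_decreasing": all(
                a > b for a, b in zip(medians, medians[1:])
            ),
        }
    return out


def parameter_recovery(
    seed: int,
    n0: int = 1000,
    p: int = 120,
    k: int = 120,
    B: int = 2000,
    N: int = 300,
    sizes: tuple = (5, 25, 100),
    reps: int = 200,
) -> dict:
    """Recover known contributor counts from simulated mixtures.

    Builds the census model on a population-scale synthetic cohort and
    estimates mixtures of known size drawn from it; reports the median
    estimate and error per size and the overall MAPE.
    """
    cohort = synth_cohort(cohort_spec(n0=n0, p=p, seed=_sub(seed, 10))).table
    features = select_top_features(cohort, k)
    model = fit_reference(cohort, features)
    census = build_null(model, cohort, N=N, B=B, seed=_sub(seed, 11))
    col_idx = [cohort.taxon_ids.index(f) for f in features]
    per_size = {}
    predictions, actuals = [], []
    for s_i, true_n in enumerate(sizes):
        batch = sample_mixtures(cohort, n=true_n, reps=reps,
                                seed=_sub(seed, 20 + s_i))
        estimates = estimate_many(batch.values[:, col_idx], census)
        preds = [e.n_hat for e in estimates]
        per_size[true_n] = {
            "median_n_hat": float(np.median(preds)),
            "median_error_pct": float(
                abs(np.median(preds) - true_n) / true_n * 100
            ),
            "mape_pct": mape(preds, [true_n] * reps),
        }
        predictions += preds
        actuals += [true_n] * reps
    return {
        "per_size": per_size,
        "overall_mape_pct": mape(predictions, actuals),
        "settings": {"n0": n0, "p": p, "B": B, "N": N, "reps": reps},
    }


def ci_coverage(
    seed: int,
    sizes: tuple = (10, 50, 150),
    trials: int = 1000,
    alpha: float = 0.05,
    n0: int = 1000,
    p: int = 120,
    B: int = 2000,
    N: int = 300,
) -> dict:
    """Empirical coverage of the one-sided interval [1, q_hat / T0].

    ``trials`` query mixtures are spread evenly over the true sizes; a trial
    is covered when the true n falls inside its interval.  The pooled
    (1 - alpha) quantile of n*T across all candidate sizes provides q_hat.
    """
    cohort = synth_cohort(cohort_spec(n0=n0, p=p, seed=_sub(seed, 30))).table
    features = select_top_features(cohort, min(p, 120))
    model = fit_reference(cohort, features)
    census = build_null(model, cohort, N=N, B=B, seed=_sub(seed, 31))
    q = float(np.quantile(census.pooled_nt(), 1 - alpha))
    col_idx = [cohort.taxon_ids.index(f) for f in features]
    per_size = {}
    covered_total = 0
    base = trials // len(sizes)
    counts = [base + (1 if i < trials % len(sizes) else 0)
              for i in range(len(sizes))]
    for s_i, (true_n, n_trials) in enumerate(zip(sizes, counts)):
        batch = sample_mixtures(cohort, n=true_n, reps=n_trials,
                                seed=_sub(seed, 40 + s_i))
        z = (batch.values[:, col_idx] - model.mu_hat) / model.sigma_hat
        t0 = np.einsum("ij,ij->i", z, z)
        upper = np.where(t0 > 0, np.maximum(1.0, q / np.where(t0 > 0, t0, 1)),
                         float(N))
        covered = int(np.sum(true_n <= upper))
        per_size[true_n] = {"coverage": covered / n_trials, "trials": n_trials}
        covered_total += covered
    return {
        "coverage": covered_total / trials,
        "per_size": per_size,
        "nominal": 1 - alpha,
        "q_hat": q,
    }


def welch_calibration(
    seed: int, n_otus: int = 5000, n_per_side: int = 25, alpha: float = 0.05
) -> dict:
    """Null rejection rate of the Welch screen at its nominal level.

    Both sides are drawn from one population of OTU abundances whose
    within-group errors are normal (the sampling model under which the
    t reference distribution is exact), with per-OTU means and spreads
    varying log-normally across OTUs.  The screen should reject a fraction
    alpha of OTUs.
    """
    rng = np.random.default_rng(_sub(seed, 50))
    mu = rng.lognormal(-4.0, 1.0, size=(n_otus, 1))
    cv = 0.2
    a = np.abs(rng.normal(mu, cv * mu, size=(n_otus, n_per_side)))
    b = np.abs(rng.normal(mu, cv * mu, size=(n_otus, n_per_side)))
    ids = [f"otu_{i}" for i in range(n_otus)]
    sewage = OtuTable(
        pd.DataFrame(a.T, index=[f"s{i}" for i in range(n_per_side)], columns=ids)
    )
    reference = OtuTable(
        pd.DataFrame(b.T, index=[f"r{i}" for i in range(n_per_side)], columns=ids)
    )
    screen = welch_retain(sewage, reference, alpha=alpha)
    return {
        "rejection_rate": float(np.mean(screen["p"] <= alpha)),
        "alpha": alpha,
        "n_otus": n_otus,
    }


def sad_recovery(seed: int, S: int = 500, reps: int = 50) -> dict:
    """SAD maximum-likelihood sanity: recovery, identity, and the size trend.

    Fits the lognormal to a known lognormal sample, checks Fisher's
    constraint on the log-series parameter, and measures the lognormal mean
    rank R^2 on synthetic single- and 100-person communities.
    """
    rng = np.random.default_rng(_sub(seed, 60))
    meanlog, sdlog = 2.0, 1.0
    fit = fit_sad(rng.lognormal(meanlog, sdlog, size=S), "lognormal")
    counts = rng.integers(1, 60, size=200)
    ls = fit_sad(counts, "logseries")
    alpha, N_tot = ls.params["alpha"], float(counts.sum())
    identity_error = abs(alpha * np.log1p(N_tot / alpha) - 200)
    cohort = synth_cohort(cohort_spec(n0=300, p=150, seed=_sub(seed, 61))).table
    counts_table = synth_counts(cohort, depth=4000, seed=_sub(seed, 62))
    comparison = compare_sads(
        counts_table, sizes=(1, 100), reps=reps, seed=_sub(seed, 63),
        models=("lognormal",),
    )
    by_size = comparison.set_index("size")["mean_r2"]
    return {
        "meanlog_error_se": float(abs(fit.params["meanlog"] - meanlog)
                                  / (sdlog / np.sqrt(S))),
        "sdlog_error_se": float(abs(fit.params["sdlog"] - sdlog)
                                / (sdlog / np.sqrt(2 * S))),
        "logseries_identity_error": float(identity_error),
        "lognormal_r2_size1": float(by_size.loc[1]),
        "lognormal_r2_size100": float(by_size.loc[100]),
    }


def snv_diversity_growth(
    seed: int,
    hosts: int = 60,
    haplotype_pool_size: int = 30,
    sizes: tuple = (1, 2, 5, 10, 20, 40, 60),
    reps: int = 25,
) -> dict:
    """Growth of sub-species diversity with the number of aggregated hosts.

    A strain-rich synthetic population (marker-gene haplotypes at percent
    divergence, near host-specific strains) is aggregated at increasing
    sizes; reports the Pearson correlation of the mean polymorphic-site
    count with size, and the single-host vs fully pooled diversity.
    """
    pop = synth_snv_population(
        hosts=hosts,
        genes=10,
        sites_per_gene=100,
        haplotype_pool_size=haplotype_pool_size,
        depth=50,
        seed=_sub(seed, 70),
    )
    curve, r = diversity_vs_population(
        pop.profiles, sizes=sizes, reps=reps, seed=_sub(seed, 71)
    )
    single_pi = float(np.mean([nucleotide_diversity(p).pi for p in pop.profiles]))
    pooled_pi = float(nucleotide_diversity(aggregate_profiles(pop.profiles)).pi)
    poly = curve.set_index("size")["polymorphic_mean"]
    pi_means = curve.set_index("size")["pi_mean"]
    return {
        "pearson_r": float(r),
        "single_host_pi": single_pi,
        "pooled_pi": pooled_pi,
        "polymorphic_non_decreasing": bool(np.all(np.diff(poly.to_numpy()) >= 0)),
        "pi_normalized": (pi_means / pi_means.max()).tolist(),
        "polymorphic_normalized": (poly / poly.max()).tolist(),
        "sizes": list(sizes),
    }
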