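"""Paired-plate nonparametric bootstrap for effect sizes.

Resampling mirrors the experimental sampling scheme: the replicate plates
of the inoculated group and, separately, those of the control group are
resampled with replacement (each group keeping its size), and the effect
is recomputed.  Because both species share a plate, a plate's two records
always travel together — host-specificity effects resample whole plates,
never species independently.  Intervals are equal-tailed percentile CIs:
the alpha/2 and 1-alpha/2 empirical quantiles of the replicate
distribution, computed with linear interpolation between order statistics
(numpy's default quantile rule).  Bias is the mean of the replicates minus
the observed effect.

``exhaustive_bootstrap`` enumerates *all* joint with-replacement resamples
of small designs (each of the ``n^n`` per-group resamples equally likely),
giving the exact bootstrap distribution used to validate the Monte-Carlo
routines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .effects import (
    EffectKind,
    cell_fractions,
    control_mean,
    effect_vs_control,
    host_specificity,
)
from .plates import (
    CONTROL,
    Dataset,
    ResponseKind,
    SeedFateError,
    Species,
    Temperature,
)

__all__ = [
    "BootstrapResult",
    "ExactBootstrapDistribution",
    "bootstrap_effect",
    "bootstrap_host_specificity",
    "bootstrap_control_mean",
    "exhaustive_bootstrap",
]

DEFAULT_N_REPS = 10_000


@dataclass(frozen=True)
class BootstrapResult:
    """Observed effect with its percentile CI and bootstrap bias."""

    estimate: float
    ci_low: float
    ci_high: float
    bias: float
    n_reps: int
    alpha: float
    rng_seed: int


def _check_params(n_reps: int, alpha: float) -> None:
    if n_reps < 1:
        raise SeedFateError(f"n_reps must be >= 1, got {n_reps}")
    if not 0.0 < alpha < 1.0:
        raise SeedFateError(f"alpha must be in (0, 1), got {alpha}")


def _summarize(
    estimate: float,
    reps: np.ndarray,
    n_reps: int,
    alpha: float,
    rng_seed: int,
) -> BootstrapResult:
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapResult(
        estimate=float(estimate),
        ci_low=float(lo),
        ci_high=float(hi),
        bias=float(reps.mean() - estimate),
        n_reps=n_reps,
        alpha=alpha,
        rng_seed=int(rng_seed),
    )


def bootstrap_effect(
    dataset: Dataset,
    group: str,
    species: Species,
    temperature: Temperature,
    response: ResponseKind,
    n_reps: int = DEFAULT_N_REPS,
    alpha: float = 0.05,
    rng_seed: int = 0,
    return_replicates: bool = False,
):
    """CI and bias for an inoculated-vs-control effect.

    Each replicate draws a with-replacement resample of the inoculated
    plates and an independent one of the control plates (inoculated group
    drawn first; both sizes preserved) and recomputes the difference of
    mean fractions.
    """
    _check_params(n_reps, alpha)
    est = effect_vs_control(dataset, group, species, temperature, response).effect
    t = cell_fractions(dataset, group, species, temperature, response)
    c = cell_fractions(dataset, CONTROL, species, temperature, response)
    rng = np.random.default_rng(rng_seed)
    it = rng.integers(0, t.size, size=(n_reps, t.size))
    ic = rng.integers(0, c.size, size=(n_reps, c.size))
    reps = t[it].mean(axis=1) - c[ic].mean(axis=1)
    result = _summarize(est, reps, n_reps, alpha, rng_seed)
    return (result, reps) if return_replicates else result


def bootstrap_host_specificity(
    dataset: Dataset,
    group: str,
    species_a: Species,
    species_b: Species,
    temperature: Temperature,
    response: ResponseKind,
    n_reps: int = DEFAULT_N_REPS,
    alpha: float = 0.05,
    rng_seed: int = 0,
    return_replicates: bool = False,
):
    """CI and bias for a between-species difference of effects.

    Whole plates are the resampling units: one index resample of the
    inoculated plates and one of the control plates are shared by both
    species within a replicate, so the within-plate correlation between
    species is preserved exactly.
    """
    _check_params(n_reps, alpha)
    est = host_specificity(
        dataset, group, species_a, species_b, temperature, response
    ).effect
    ta = cell_fractions(dataset, group, species_a, temperature, response)
    tb = cell_fractions(dataset, group, species_b, temperature, response)
    ca = cell_fractions(dataset, CONTROL, species_a, temperature, response)
    cb = cell_fractions(dataset, CONTROL, species_b, temperature, response)
    rng = np.random.default_rng(rng_seed)
    it = rng.integers(0, ta.size, size=(n_reps, ta.size))
    ic = rng.integers(0, ca.size, size=(n_reps, ca.size))
    reps = (ta[it].mean(axis=1) - ca[ic].mean(axis=1)) - (
        tb[it].mean(axis=1) - cb[ic].mean(axis=1)
    )
    result = _summarize(est, reps, n_reps, alpha, rng_seed)
    return (result, reps) if return_replicates else result


def bootstrap_control_mean(
    dataset: Dataset,
    species: Species,
    temperature: Temperature,
    response: ResponseKind,
    n_reps: int = DEFAULT_N_REPS,
    alpha: float = 0.05,
    rng_seed: int = 0,
    return_replicates: bool = False,
):
    """CI for the uninoculated baseline fraction (control plates only)."""
    _check_params(n_reps, alpha)
    est = control_mean(dataset, species, temperature, response).effect
    c = cell_fractions(dataset, CONTROL, species, temperature, response)
    rng = np.random.default_rng(rng_seed)
    ic = rng.integers(0, c.size, size=(n_reps, c.size))
    reps = c[ic].mean(axis=1)
    result = _summarize(est, reps, n_reps, alpha, rng_seed)
    return (result, reps) if return_replicates else result


# -- exact enumeration oracle ---------------------------------------------

MAX_ENUMERATION = 1_000_000


@dataclass(frozen=True)
class ExactBootstrapDistribution:
    """All equally likely joint resample values of a small design."""

    values: np.ndarray  # one entry per joint resample, each probability 1/len

    def mean(self) -> float:
        return float(self.values.mean())

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.values, q)

    def bias(self, observed: float) -> float:
        return self.mean() - observed

    def cdf(self, x: float) -> float:
        return float(np.mean(self.values <= x))

    def cdf_strict(self, x: float) -> float:
        return float(np.mean(self.values < x))


def exhaustive_bootstrap(
    stat: Callable[[Sequence[np.ndarray]], float],
    groups: Sequence[np.ndarray],
) -> ExactBootstrapDistribution:
    """Exact bootstrap distribution of ``stat`` by full enumeration.

    ``groups`` are the per-group plate value arrays (1-D, or 2-D with one
    row per plate for paired statistics); rows are the resampling units.
    Every combination of per-group with-replacement resamples (``n^n`` per
    group, enumerated jointly across groups) is visited once.
    """
    groups = [np.asarray(g) for g in groups]
    sizes = [g.shape[0] for g in groups]
    if any(s < 1 for s in sizes):
        raise SeedFateError("every group needs at least one plate")
    total = 1
    for s in sizes:
        total *= s ** s
    if total > MAX_ENUMERATION:
        raise SeedFateError(
            f"enumeration of {total} joint resamples exceeds the "
            f"{MAX_ENUMERATION} limit"
        )
    per_group_indices = [
        list(itertools.product(range(s), repeat=s)) for s in sizes
    ]
    values = np.empty(total, dtype=float)
    for k, combo in enumerate(itertools.product(*per_group_indices)):
        resampled = [g[list(idx)] for g, idx in zip(groups, combo)]
        values[k] = stat(resampled)
    return ExactBootstrapDistribution(values=values)
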