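"""Empirical p-values by permuting genotype rows only.

Only the rows of the genetic blocks [Z | V] are shuffled across individuals;
the response, the covariate block and the kinship matrix stay fixed, so the
phenotype-covariate relationship is preserved while the genotype-phenotype
link is destroyed.  The genetic covariance is re-estimated for every
permutation (group membership of genotype rows changes); the covariate term
is constant across permutations.

One :class:`PermutationPlan` (L orderings drawn from a seeded generator) is
shared across the windows of a run so that genome-wide null statistics are
comparable and runs reproduce bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .engine import (
    CaseControlDesign,
    LongitudinalCovariates,
    TestSpec,
    TestResult,
    _block_quad,
    t2_statistic,
)
from .pedigree import KinshipMatrix
from .windows import CollapsedBlocks

__all__ = [
    "PermutationPlan",
    "PermutationResult",
    "make_plan",
    "permutation_pvalue",
    "detection_rates",
    "type1_power_scan",
]

log = logging.getLogger(__name__)


@dataclass
class PermutationPlan:
    """L seeded row orderings of 0..n-1 applied jointly to Z and V."""

    permutations: np.ndarray
    seed: int
    scope: str = "all"

    def __post_init__(self) -> None:
        self.permutations = np.asarray(self.permutations, dtype=np.intp)
        if self.permutations.ndim != 2:
            raise ValueError("permutations must be an L x n array")
        n = self.n
        ref = np.arange(n)
        for row in self.permutations:
            if not np.array_equal(np.sort(row), ref):
                raise ValueError("each permutation must be a bijection on individuals")

    @property
    def L(self) -> int:
        return self.permutations.shape[0]

    @property
    def n(self) -> int:
        return self.permutations.shape[1]


def make_plan(
    n: int,
    L: int,
    seed: int,
    scope: str = "all",
    families: list | np.ndarray | None = None,
) -> PermutationPlan:
    """Draw L permutations of n individuals.

    ``scope='all'`` permutes across everyone (default: this is what breaks
    the genotype-phenotype link while the kinship denominator stays fixed);
    ``scope='within-family'`` restricts shuffles to family blocks for users
    worried about exchangeability.
    """
    if L < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    if scope == "all":
        perms = np.array([rng.permutation(n) for _ in range(L)])
    elif scope == "within-family":
        if families is None:
            raise ValueError("within-family scope requires family labels")
        families = np.asarray(families)
        if families.size != n:
            raise ValueError("family labels must cover all individuals")
        perms = np.tile(np.arange(n), (L, 1))
        for fam in dict.fromkeys(families.tolist()):
            idx = np.nonzero(families == fam)[0]
            for l in range(L):
                perms[l, idx] = idx[rng.permutation(idx.size)]
    else:
        raise ValueError("scope must be 'all' or 'within-family'")
    return PermutationPlan(permutations=perms, seed=seed, scope=scope)


@dataclass
class PermutationResult:
    p: float
    observed: TestResult
    perm_stats: np.ndarray
    n_retried: int = 0

    @property
    def L(self) -> int:
        return self.perm_stats.size


def _genetic_term(blocks: CollapsedBlocks, nc: int, nd: int, q_phi: float,
                  separate: bool, perm: np.ndarray | None, cache: dict) -> float:
    """Genetic quadratic-form term, optionally under a row permutation.

    Exploits that X'X and the column sums are permutation-invariant: only the
    case-row sum changes, so per permutation the cost is one slice-sum plus a
    rank-two covariance update.
    """
    if separate:
        parts = [("Z", blocks.Z), ("V", blocks.V)]
    else:
        parts = [("ZV", cache.setdefault("ZV", blocks.matrix()))]
    total = 0.0
    for name, X in parts:
        if X.shape[1] == 0:
            continue
        key = ("XtX", name)
        if key not in cache:
            cache[key] = X.T @ X
            cache[("sum", name)] = X.sum(axis=0)
        rows = X if perm is None else X[perm]
        case_sum = rows[:nc].sum(axis=0)
        quad, _, _ = _block_quad(
            X, nc, nd, XtX=cache[key], col_sum=cache[("sum", name)],
            case_sum=case_sum,
        )
        total += quad
    return total / q_phi


def permutation_pvalue(
    blocks: CollapsedBlocks,
    covs: LongitudinalCovariates | None,
    design: CaseControlDesign,
    phi: KinshipMatrix | np.ndarray | None,
    spec: TestSpec,
    plan: PermutationPlan,
    pseudo_count: int = 0,
) -> PermutationResult:
    """Empirical p for one window: #{T2_perm >= T2_obs} / L (ties count).

    ``pseudo_count=1`` switches to the small-sample (r+1)/(L+1) estimate.
    A permuted replicate that fails numerically is recomputed with a fresh
    seeded permutation and logged.
    """
    if plan.n != design.n:
        raise ValueError("permutation plan size does not match design")
    observed = t2_statistic(blocks, covs, design, phi, spec)
    nc, nd = design.n_c, design.n_d
    cache: dict = {}
    # covariate term is invariant under genotype-only permutation
    const_term = observed.covariate_term
    obs_genetic = _genetic_term(
        blocks, nc, nd, observed.q_phi, spec.separate_covariance, None, cache
    )
    t_obs = obs_genetic + const_term
    stats = np.empty(plan.L)
    retry_rng = np.random.default_rng(plan.seed + 0x9E3779B9)
    n_retried = 0
    for l in range(plan.L):
        perm = plan.permutations[l]
        for _attempt in range(5):
            try:
                g = _genetic_term(
                    blocks, nc, nd, observed.q_phi,
                    spec.separate_covariance, perm, cache,
                )
                if np.isfinite(g):
                    break
                raise np.linalg.LinAlgError("non-finite permuted statistic")
            except np.linalg.LinAlgError:
                n_retried += 1
                log.warning("degenerate permuted replicate %d; redrawing", l)
                perm = retry_rng.permutation(design.n)
        stats[l] = g + const_term
    exceed = int(np.sum(stats >= t_obs - 1e-12))
    if pseudo_count:
        p = (exceed + 1) / (plan.L + 1)
    else:
        p = exceed / plan.L
    return PermutationResult(
        p=p, observed=observed, perm_stats=stats, n_retried=n_retried
    )


def detection_rates(
    pvalues: np.ndarray, truth: np.ndarray, cutoffs
) -> dict[float, float]:
    """Fraction of truth-labelled windows with p <= cutoff, per cutoff.

    On genuinely associated windows this is power; on a genotype-permuted
    (null) dataset the same quantity is the empirical type-I error rate.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if pvalues.shape != truth.shape:
        raise ValueError("p-value and truth vectors must align")
    n_true = int(truth.sum())
    if n_true == 0:
        raise ValueError("no truth-labelled windows: rate undefined")
    p_true = pvalues[truth]
    return {float(c): float(np.mean(p_true <= c)) for c in np.atleast_1d(cutoffs)}


# Alias matching the scan terminology: power on true windows, type-I on a
# genotype-permuted dataset, both via the same rate computation.
type1_power_scan = detection_rates
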