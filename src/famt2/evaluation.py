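"""Genome-scan driver, calibration summaries and method comparison."""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .engine import (
    LongitudinalCovariates,
    TestSpec,
    build_response,
    t2_statistic,
)
from .pedigree import KinshipMatrix, Pedigree, compute_kinship
from .permutation import PermutationPlan, make_plan, permutation_pvalue
from .windows import (
    VariantTable,
    classify_by_maf,
    collapse,
    make_windows,
    prune_degenerate,
)

__all__ = [
    "ScanConfig",
    "ScanReport",
    "MethodComparison",
    "genomic_inflation",
    "binomial_tail",
    "compare_methods",
    "run_scan",
]

CHI2_1_MEDIAN = chi2.ppf(0.5, 1)  # 0.4549364...


def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor: median 1-df chi-square quantile of the
    observed p-values over the null median 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = chi2.isf(p, 1)
    return float(np.median(q) / CHI2_1_MEDIAN)


def binomial_tail(k: int, n: int) -> float:
    """Exact one-sided P(X >= k), X ~ Binomial(n, 1/2), by pmf summation."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    total = sum(comb(n, i) for i in range(k, n + 1))
    return float(total / 2**n)


@dataclass
class MethodComparison:
    n_better: int
    n_similar: int
    n_worse: int
    n_no_power: int
    tail_prob: float | None


def compare_methods(
    power_a,
    power_b,
    margin: float | None = None,
    n_replicates: int | None = None,
    cutoff: float = 0.05,
) -> MethodComparison:
    """Per-window comparison of two per-window power vectors.

    Windows where both powers fall below ``2 * cutoff`` count as having no
    power for any test and are excluded.  Of the rest, a window is *similar*
    when |power_a - power_b| <= margin (default: two Monte-Carlo standard
    errors from ``n_replicates``), otherwise *better*/*worse* for method A.
    ``tail_prob`` is the exact one-sided binomial tail
    P(X >= max(n_better, n_worse)) with X ~ Binomial(n_better + n_worse, 1/2);
    it is None when no window is decisive.
    """
    a = np.asarray(power_a, dtype=float)
    b = np.asarray(power_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("power vectors must cover the same windows")
    if margin is None:
        if n_replicates is None:
            raise ValueError("give either margin or n_replicates")
        pbar = np.clip((a + b) / 2, 1e-12, 1)
        margin_vec = 2 * np.sqrt(pbar * (1 - pbar) * 2 / n_replicates)
    else:
        margin_vec = np.full(a.shape, margin)
    no_power = (a < 2 * cutoff) & (b < 2 * cutoff)
    similar = ~no_power & (np.abs(a - b) <= margin_vec)
    better = ~no_power & ~similar & (a > b)
    worse = ~no_power & ~similar & (b > a)
    nb, nw = int(better.sum()), int(worse.sum())
    tail = binomial_tail(max(nb, nw), nb + nw) if nb + nw else None
    return MethodComparison(
        n_better=nb,
        n_similar=int(similar.sum()),
        n_worse=nw,
        n_no_power=int(no_power.sum()),
        tail_prob=tail,
    )


@dataclass
class ScanConfig:
    """Configuration of a windowed scan."""

    methods: tuple[str, ...] = ("T2", "T2.longi")
    maf_threshold: float = 0.05
    width: int = 10_000
    phi_star: str = "identity"
    df_mode: str = "rank"
    permutations: int = 1000
    seed: int = 0
    perm_scope: str = "all"
    pseudo_count: int = 0
    # response rule: longitudinal methods use any-time, single-time-point
    # comparators use the first measurement; override to force one rule.
    response_mode: str | None = None
    use_kinship: bool = True
    run_permutations: bool = True

    def response_for(self, method: str) -> str:
        if self.response_mode is not None:
            return self.response_mode
        return "any-time" if method.endswith(".longi") else "time-1"


@dataclass
class ScanReport:
    """Per-window, per-method results plus the inputs needed for summaries."""

    table: pd.DataFrame
    config: ScanConfig
    lambdas: dict[str, float] = field(default_factory=dict)

    def genomic_inflation(self, method: str, kind: str = "p_asym",
                          truth: np.ndarray | None = None) -> float:
        sub = self.table[self.table["method"] == method]
        p = sub[kind].to_numpy()
        win = sub["window"].to_numpy()
        if truth is not None:
            p = p[~np.asarray(truth)[win]]
        p = p[np.isfinite(p)]
        return genomic_inflation(np.clip(p, 1e-300, 1.0))

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _check_alignment(variants: VariantTable, ped: Pedigree, ids: list[str]) -> None:
    sets = {
        "genotypes": set(variants.samples),
        "pedigree": set(ped.ids),
        "phenotypes": set(ids),
    }
    union = set.union(*sets.values())
    problems = []
    for name, s in sets.items():
        missing = union - s
        if missing:
            problems.append(f"{name} lacks: {sorted(missing)[:10]}")
    if problems:
        raise ValueError("individual sets do not match; " + "; ".join(problems))
    if list(variants.samples) != list(ids):
        raise ValueError("genotype sample order must match phenotype order")


def run_scan(
    variants: VariantTable,
    ped: Pedigree,
    outcomes: np.ndarray,
    covariates: LongitudinalCovariates | None,
    config: ScanConfig,
    plan: PermutationPlan | None = None,
) -> ScanReport:
    """Window, collapse and test every method over the genome.

    Rows of ``outcomes``/``covariates`` and ``variants.dosages`` follow
    ``variants.samples``, which must equal the phenotype individual order.
    Untestable windows (empty, or fully monomorphic) yield NaN rows so the
    report always holds one row per window per method.
    """
    _check_alignment(variants, ped, list(variants.samples))
    phi_full = (
        compute_kinship(ped).reorder(list(variants.samples))
        if config.use_kinship
        else KinshipMatrix(np.eye(len(variants.samples)), list(variants.samples))
    )
    windows = make_windows(variants, config.width)
    rare = classify_by_maf(variants, config.maf_threshold)
    if plan is None and config.run_permutations:
        fam_of = {iid: ped.family[ped.index_of(iid)] for iid in ped.ids}
        plan = make_plan(
            n=len(variants.samples),
            L=config.permutations,
            seed=config.seed,
            scope=config.perm_scope,
            families=[fam_of[i] for i in variants.samples],
        )

    # designs and reordered inputs are shared by methods with one response rule
    per_mode: dict[str, tuple] = {}
    for method in config.methods:
        mode = config.response_for(method)
        if mode in per_mode:
            continue
        design = build_response(outcomes, mode)
        phi = KinshipMatrix(
            phi_full.values[np.ix_(design.order, design.order)],
            [variants.samples[k] for k in design.order],
        )
        covs = covariates.permute_rows(design.order) if covariates is not None else None
        per_mode[mode] = (design, phi, covs)

    rows = []
    for w_id, window in enumerate(windows):
        collapsed: dict[str, object] = {}
        for method in config.methods:
            spec = TestSpec(
                method=method, phi_star=config.phi_star, df_mode=config.df_mode
            )
            design, phi, covs = per_mode[config.response_for(method)]
            row = {
                "window": w_id,
                "chrom": window.chrom,
                "start": window.start,
                "end": window.end,
                "method": method,
                "t2": np.nan,
                "df": 0,
                "p_asym": np.nan,
                "p_perm": np.nan,
                "n_common": 0,
                "n_rare_groups": 0,
            }
            if window.n_variants > 0:
                strat = spec.collapse_strategy
                if strat not in collapsed:
                    collapsed[strat] = prune_degenerate(
                        collapse(window, variants, rare, strat)
                    )
                blocks = collapsed[strat]
                row["n_common"] = blocks.n_common
                row["n_rare_groups"] = blocks.n_rare_groups
                if blocks.n_common + blocks.n_rare_groups > 0:
                    ordered = type(blocks)(
                        Z=blocks.Z[design.order],
                        V=blocks.V[design.order],
                        z_indices=blocks.z_indices,
                        groups=blocks.groups,
                        strategy=blocks.strategy,
                    )
                    use_covs = covs if spec.longitudinal else None
                    if config.run_permutations:
                        pr = permutation_pvalue(
                            ordered, use_covs, design, phi, spec, plan,
                            pseudo_count=config.pseudo_count,
                        )
                        res = pr.observed
                        row["p_perm"] = pr.p
                    else:
                        res = t2_statistic(ordered, use_covs, design, phi, spec)
                    row.update(
                        t2=res.t2, df=res.df, p_asym=res.p_asym
                    )
            rows.append(row)
    table = pd.DataFrame(rows)
    report = ScanReport(table=table, config=config)
    for method in config.methods:
        p = table.loc[table["method"] == method, "p_asym"].to_numpy()
        p = p[np.isfinite(p)]
        if p.size:
            report.lambdas[method] = genomic_inflation(np.clip(p, 1e-300, 1.0))
    return report
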