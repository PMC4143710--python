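"""Seeded gene-dropping simulator for pedigrees, genotypes and phenotypes.

All test inputs are generated here: multi-generation pedigrees, founder
haplotypes drawn from a finite pool with tunable LD, Mendelian transmission
with per-interval recombination, AR(1) longitudinal covariates and a per-time
logistic event model with a shared individual liability intercept.

The LD model is deliberately simple: pool haplotypes come from a latent
Gaussian AR(1) process thresholded at each variant's target allele frequency,
so adjacent variants are correlated with decay controlled by ``ld_decay`` and
marginal frequencies approximate the requested MAF spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .pedigree import Pedigree
from .windows import VariantTable, Window

__all__ = [
    "SimScenario",
    "make_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "causal_windows",
    "write_vcf",
    "write_ped",
    "write_long_csv",
    "write_truth_bed",
]


@dataclass
class SimScenario:
    """Generative parameters for one simulated dataset."""

    # pedigree
    n_families: int = 10
    generations: int = 3
    sibship: int = 3
    # variants
    n_variants: int = 100
    chrom: str = "1"
    spacing: int = 1000
    positions: np.ndarray | None = None
    pool_size: int = 200
    ld_decay: float = 0.5
    recomb: float = 0.01
    common_frac: float = 0.5
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    rare_maf_range: tuple[float, float] = (0.001, 0.05)
    # genetic effects (log-odds per unit causal burden, possibly per time)
    causal_variants: tuple[int, ...] = ()
    causal_beta: float = 0.0
    beta_time_scale: tuple[float, ...] | None = None
    # covariates
    n_covariates: int = 2
    n_times: int = 3
    cov_rho: float = 0.8
    cov_mean: float = 0.0
    cov_sd: float = 1.0
    cov_beta: tuple[float, ...] | None = None
    # event model
    event_rate: float = 0.1
    any_prevalence: float | None = None
    liability_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must lie in [0, 1)")
        if not -1 < self.cov_rho < 1:
            raise ValueError("|cov_rho| must be < 1")
        if not 0 < self.event_rate < 1:
            raise ValueError("event_rate must lie in (0, 1)")
        if not 0 <= self.recomb <= 1:
            raise ValueError("recomb must be a probability")


def make_pedigree(
    n_families: int, generations: int = 3, sibship: int = 2
) -> Pedigree:
    """Regular multi-generation pedigree: one founder couple per family;
    every child marries an unrelated founder spouse except in the last
    generation."""
    ids: list[str] = []
    father: list[str | None] = []
    mother: list[str | None] = []
    family: list[str] = []
    sex: list[int] = []

    def add(iid, fid, mid, fam, sx):
        ids.append(iid)
        father.append(fid)
        mother.append(mid)
        family.append(fam)
        sex.append(sx)

    for f in range(n_families):
        fam = f"F{f + 1}"
        dad, mom = f"{fam}_G1_M", f"{fam}_G1_F"
        add(dad, None, None, fam, 1)
        add(mom, None, None, fam, 2)
        couples = [(dad, mom)]
        for g in range(2, generations + 1):
            nxt: list[tuple[str, str]] = []
            child_no = 0
            for (d, m) in couples:
                for s in range(sibship):
                    child_no += 1
                    kid = f"{fam}_G{g}_C{child_no}"
                    kid_sex = 1 if s % 2 == 0 else 2
                    add(kid, d, m, fam, kid_sex)
                    if g < generations:
                        spouse = f"{fam}_G{g}_S{child_no}"
                        add(spouse, None, None, fam, 2 if kid_sex == 1 else 1)
                        nxt.append((kid, spouse) if kid_sex == 1 else (spouse, kid))
            couples = nxt
    return Pedigree(ids=ids, father=father, mother=mother, family=family, sex=sex)


def _variant_positions(sc: SimScenario) -> np.ndarray:
    if sc.positions is not None:
        return np.asarray(sc.positions, dtype=np.int64)
    return (np.arange(sc.n_variants, dtype=np.int64) * sc.spacing
            + max(sc.spacing // 2, 1))


def _haplotype_pool(sc: SimScenario, rng: np.random.Generator):
    """(pool K x M of 0/1 minor alleles, target frequencies)."""
    M = sc.n_variants
    n_common = int(round(sc.common_frac * M))
    is_common = np.zeros(M, dtype=bool)
    is_common[rng.choice(M, size=n_common, replace=False)] = True
    freq = np.where(
        is_common,
        rng.uniform(*sc.common_maf_range, size=M),
        rng.uniform(*sc.rare_maf_range, size=M),
    )
    z = np.empty((sc.pool_size, M))
    z[:, 0] = rng.standard_normal(sc.pool_size)
    a = sc.ld_decay
    innov = rng.standard_normal((sc.pool_size, M))
    for m in range(1, M):
        z[:, m] = a * z[:, m - 1] + np.sqrt(1 - a * a) * innov[:, m]
    pool = (z < norm.ppf(freq)).astype(np.int8)
    return pool, freq


def _meiosis(h1: np.ndarray, h2: np.ndarray, recomb: float,
             rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete: per-adjacent-interval crossover, no interference."""
    M = h1.size
    start = rng.integers(2)
    if recomb > 0 and M > 1:
        cross = rng.random(M - 1) < recomb
        state = (start + np.concatenate([[0], np.cumsum(cross)])) % 2
    else:
        state = np.full(M, start)
    return np.where(state == 0, h1, h2)


def simulate_genotypes(
    sc: SimScenario, ped: Pedigree | None = None
) -> tuple[VariantTable, Pedigree]:
    """Gene-drop a variant panel through a pedigree (the scenario's regular
    pedigree by default, or any explicit one).

    Founders draw two haplotypes uniformly from the pool; non-founders
    inherit one recombinant haplotype per parent; dosage = minor-allele count.
    """
    rng = np.random.default_rng(sc.seed)
    if ped is None:
        ped = make_pedigree(sc.n_families, sc.generations, sc.sibship)
    pool, freq = _haplotype_pool(sc, rng)
    n, M = ped.n, sc.n_variants
    hapA = np.empty((n, M), dtype=np.int8)
    hapB = np.empty((n, M), dtype=np.int8)
    for k in ped.topological_order():
        f, m = ped.father[k], ped.mother[k]
        if f is None and m is None:
            hapA[k] = pool[rng.integers(sc.pool_size)]
            hapB[k] = pool[rng.integers(sc.pool_size)]
        else:
            fi, mi = ped.index_of(f), ped.index_of(m)
            hapA[k] = _meiosis(hapA[fi], hapB[fi], sc.recomb, rng)
            hapB[k] = _meiosis(hapA[mi], hapB[mi], sc.recomb, rng)
    pos = _variant_positions(sc)
    vt = VariantTable(
        chrom=np.array([sc.chrom] * M, dtype=object),
        pos=pos,
        ids=np.array([f"v{m + 1}" for m in range(M)], dtype=object),
        dosages=(hapA + hapB).astype(float),
        samples=list(ped.ids),
    )
    return vt, ped


def simulate_phenotypes(
    sc: SimScenario,
    variants: VariantTable,
    seed: int | None = None,
    max_resample: int = 20,
):
    """Longitudinal covariates plus per-time binary events.

    Covariates follow per-individual AR(1) series; the event at time j is
    Bernoulli with logit = intercept_j + time-scaled genetic burden +
    covariate effects + shared individual liability.  The per-time intercept
    is calibrated so the mean event probability matches ``event_rate``.

    Returns ``(outcomes n x J, covariate matrix n x (C*J))`` with the
    covariate-major-then-time column layout.  Degenerate draws (all cases or
    all controls under the any-time rule) are resampled with a warning.
    """
    import warnings

    rng = np.random.default_rng(sc.seed + 1 if seed is None else seed)
    n = variants.n_individuals
    C, J = sc.n_covariates, sc.n_times

    A = np.empty((n, C * J))
    for c in range(C):
        e = rng.standard_normal((n, J))
        series = np.empty((n, J))
        series[:, 0] = e[:, 0]
        for j in range(1, J):
            series[:, j] = (sc.cov_rho * series[:, j - 1]
                            + np.sqrt(1 - sc.cov_rho**2) * e[:, j])
        A[:, c * J:(c + 1) * J] = sc.cov_mean + sc.cov_sd * series

    if sc.causal_variants:
        idx = np.asarray(sc.causal_variants, dtype=int)
        burden = variants.dosages[:, idx].sum(axis=1) * sc.causal_beta
    else:
        burden = np.zeros(n)
    scale = (np.ones(J) if sc.beta_time_scale is None
             else np.asarray(sc.beta_time_scale, dtype=float))
    if scale.size != J:
        raise ValueError("beta_time_scale must have one entry per time")
    gamma = (np.zeros(C) if sc.cov_beta is None
             else np.asarray(sc.cov_beta, dtype=float))
    if gamma.size != C:
        raise ValueError("cov_beta must have one entry per covariate")

    base = np.log(sc.event_rate / (1 - sc.event_rate))
    for attempt in range(max_resample):
        b = sc.liability_sd * rng.standard_normal(n)
        lps = np.empty((n, J))
        for j in range(J):
            lp = scale[j] * burden + b
            for c in range(C):
                lp = lp + gamma[c] * A[:, c * J + j]
            lps[:, j] = base + lp - lp.mean()  # mean prob tracks event_rate
        if sc.any_prevalence is not None:
            lps += _calibrate_any(lps, sc.any_prevalence)
        prob = 1.0 / (1.0 + np.exp(-lps))
        outcomes = (rng.random((n, J)) < prob).astype(int)
        any_case = outcomes.max(axis=1)
        if 0 < any_case.sum() < n:
            return outcomes, A
        warnings.warn("degenerate phenotype draw (all cases or all controls); "
                      "resampling")
    raise RuntimeError("could not draw a non-degenerate phenotype")


def _calibrate_any(lps: np.ndarray, target: float) -> float:
    """Intercept shift making the expected any-time case fraction hit target."""

    def any_rate(delta: float) -> float:
        p = 1.0 / (1.0 + np.exp(-(lps + delta)))
        return float(np.mean(1.0 - np.prod(1.0 - p, axis=1)))

    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if any_rate(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def causal_windows(sc: SimScenario, variants: VariantTable,
                   windows: list[Window]) -> np.ndarray:
    """Boolean truth mask over windows: True where a causal variant falls."""
    causal = set(int(i) for i in sc.causal_variants)
    return np.array(
        [bool(causal.intersection(map(int, w.variant_indices))) for w in windows]
    )


def write_vcf(variants: VariantTable, path: str) -> None:
    """Minimal uncompressed VCF with a DS (dosage) FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = variants.chromosomes
        for c in chroms:
            mx = int(variants.pos[variants.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={mx + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(variants.samples) + "\n")
        for m in range(variants.n_variants):
            col = variants.dosages[:, m]
            cells = []
            for v in col:
                gt = "1/1" if v > 1.5 else ("0/1" if v > 0.5 else "0/0")
                cells.append(f"{gt}:{v:g}")
            fh.write(
                f"{variants.chrom[m]}\t{variants.pos[m]}\t{variants.ids[m]}"
                f"\tA\tT\t.\tPASS\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def write_ped(ped: Pedigree, path: str,
              phenotype: np.ndarray | None = None) -> None:
    with open(path, "w") as fh:
        for k, iid in enumerate(ped.ids):
            ph = "-9" if phenotype is None else str(int(phenotype[k]) + 1)
            fh.write(
                f"{ped.family[k]}\t{iid}\t{ped.father[k] or '0'}\t"
                f"{ped.mother[k] or '0'}\t{ped.sex[k]}\t{ph}\n"
            )


def write_long_csv(ids: list[str], outcomes: np.ndarray, A: np.ndarray,
                   n_covariates: int, n_times: int, path: str) -> None:
    """Long-format phenotype table: individual,time,outcome,cov1..covC."""
    with open(path, "w") as fh:
        header = ["individual", "time", "outcome"] + [
            f"cov{c + 1}" for c in range(n_covariates)
        ]
        fh.write(",".join(header) + "\n")
        for i, iid in enumerate(ids):
            for j in range(n_times):
                row = [iid, str(j + 1), str(int(outcomes[i, j]))]
                row += [f"{A[i, c * n_times + j]:.6g}" for c in range(n_covariates)]
                fh.write(",".join(row) + "\n")


def write_truth_bed(windows: list[Window], truth: np.ndarray, path: str) -> None:
    with open(path, "w") as fh:
        for k, w in enumerate(windows):
            if truth[k]:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\twin{k}\n")
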