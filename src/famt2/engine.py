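"""Multivariate case/control test statistics for family data.

The statistic compares the case and control mean vectors of up to three
column blocks — common variants Z, collapsed rare variants V, and
longitudinal covariates A — while modelling three correlation sources:

* between columns of a block, via a pooled within-group covariance Sigma;
* between individuals, via the kinship-derived matrix Phi (and Phi* for the
  covariate block, either the identity or Phi itself);
* between repeated covariate measures, implicitly through Sigma_A over the
  covariate-major-by-time layout of A.

Writing the stacked column vector eta = (Z', V', A')' and the contrast
matrix H with one row per column variable, each row being
``(u - n_c/n * 1)'`` (u the case indicator ordered cases-first), the
statistic is the quadratic form ``(H eta)' Gamma^{-1} (H eta)`` with
``Gamma = H Var(eta) H'`` and ``Var(eta) = diag(Sigma_Z (x) Phi,
Sigma_V (x) Phi, Sigma_A (x) Phi*)``.  Because every H row uses the same
contrast ``c = u - n_c/n * 1``, the form factorises into

    T2 = d_ZV' Sigma_ZV^+ d_ZV / q_Phi  +  d_A' Sigma_A^+ d_A / q_Phi*

with ``d = (n_c n_d / n) * (case mean - control mean)`` per block and
``q_M = c' M c``.  For unrelated individuals (Phi = I) and a single block
this reduces exactly to the classical two-sample Hotelling T^2 since
``q_I = n_c n_d / n``.

Method variants:

========================  ==========  ====================  ==========
method                    collapsing  genetic covariance    A block
========================  ==========  ====================  ==========
``T2``                    sum         joint over [Z | V]    no
``CMC.ZXpaper``           sum         separate Z and V      no
``CMC.ZXcode``            max         joint over [Z | V]    no
``T2.longi``              sum         joint over [Z | V]    yes
``CMC.ZXpaper.longi``     sum         separate Z and V      yes
``CMC.ZXcode.longi``      max         joint over [Z | V]    yes
========================  ==========  ====================  ==========

Singular covariances are handled by a rank-revealing Moore-Penrose
pseudo-inverse (relative eigenvalue cutoff ``1e-10`` times the largest
eigenvalue); the chi-square degrees of freedom count either all tested
variables or the retained ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .pedigree import KinshipMatrix
from .windows import CollapsedBlocks

__all__ = [
    "METHODS",
    "LongitudinalCovariates",
    "CaseControlDesign",
    "TestSpec",
    "TestResult",
    "build_response",
    "pooled_covariance",
    "t2_statistic",
    "asymptotic_pvalue",
    "read_longitudinal",
]

METHODS = (
    "T2",
    "CMC.ZXpaper",
    "CMC.ZXcode",
    "T2.longi",
    "CMC.ZXpaper.longi",
    "CMC.ZXcode.longi",
)

PINV_RTOL = 1e-10


@dataclass
class LongitudinalCovariates:
    """n x (C*J) covariate matrix, covariate-major then time.

    Column ``c * J + j`` holds covariate ``c`` at measurement ``j``.
    """

    values: np.ndarray
    n_covariates: int
    n_times: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_covariates * self.n_times
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValueError(
                f"covariate matrix must have C*J = {expected} columns, "
                f"got shape {self.values.shape}"
            )
        if np.isnan(self.values).any():
            raise ValueError("missing covariate values are not supported")

    def permute_rows(self, idx: np.ndarray) -> "LongitudinalCovariates":
        return LongitudinalCovariates(
            self.values[np.asarray(idx)], self.n_covariates, self.n_times
        )


@dataclass
class CaseControlDesign:
    """Binary response with individuals ordered cases-first.

    ``order`` maps positions in the cases-first layout back to the original
    row indices, i.e. reordered_X = X[order].  ``labels`` is the cases-first
    indicator vector u (1 for the first ``n_c`` entries).
    """

    labels: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.order = np.asarray(self.order, dtype=int)
        if not np.all(np.diff(self.labels) <= 0):
            raise ValueError("labels must be ordered cases-first")
        if self.n_c < 2 or self.n_d < 2:
            raise ValueError(
                "need at least two cases and two controls for the pooled covariance"
            )

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def n_c(self) -> int:
        return int(self.labels.sum())

    @property
    def n_d(self) -> int:
        return self.n - self.n_c

    def contrast(self) -> np.ndarray:
        """The shared H-row c = u - (n_c/n) * 1 in cases-first order."""
        return self.labels - self.n_c / self.n


def build_response(
    outcomes: np.ndarray, mode: str | int = "any-time"
) -> CaseControlDesign:
    """Derive case status from per-time binary outcomes (n x J).

    ``mode='any-time'`` marks a case on an event at any measurement;
    ``mode='time-k'`` (1-based, or an int) uses only measurement k.  The
    returned design records the stable cases-first permutation that genotype
    and covariate rows must follow.
    """
    outcomes = np.asarray(outcomes)
    if outcomes.ndim == 1:
        outcomes = outcomes[:, None]
    if np.isnan(outcomes.astype(float)).any():
        raise ValueError("every individual needs outcomes at all times")
    if mode == "any-time":
        case = outcomes.max(axis=1) > 0
    else:
        if isinstance(mode, str):
            if not mode.startswith("time-"):
                raise ValueError(f"unknown response mode {mode!r}")
            k = int(mode[5:])
        else:
            k = int(mode)
        if not 1 <= k <= outcomes.shape[1]:
            raise ValueError(f"time index {k} outside 1..{outcomes.shape[1]}")
        case = outcomes[:, k - 1] > 0
    if case.all() or not case.any():
        raise ValueError("all-case or all-control response: statistic undefined")
    order = np.argsort(~case, kind="stable")
    return CaseControlDesign(labels=case[order].astype(int), order=order)


@dataclass
class TestSpec:
    """Configuration of one statistic."""

    __test__ = False  # not a pytest collection target

    method: str = "T2"
    phi_star: str = "identity"
    df_mode: str = "rank"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.phi_star not in ("identity", "kinship"):
            raise ValueError("phi_star must be 'identity' or 'kinship'")
        if self.df_mode not in ("n_variables", "rank"):
            raise ValueError("df_mode must be 'n_variables' or 'rank'")

    @property
    def longitudinal(self) -> bool:
        return self.method.endswith(".longi")

    @property
    def collapse_strategy(self) -> str:
        return "max-adjacent" if self.method.startswith("CMC.ZXcode") else "sum-adjacent"

    @property
    def separate_covariance(self) -> bool:
        # CMC.ZXpaper treats common and rare blocks as uncorrelated.
        return self.method.startswith("CMC.ZXpaper")


@dataclass
class TestResult:
    t2: float
    df: int
    p_asym: float
    method: str
    q_phi: float
    q_phi_star: float | None
    genetic_term: float
    covariate_term: float
    n_variables: int
    rank: int
    n_variables_genetic: int = 0
    rank_genetic: int = 0
    extra: dict = field(default_factory=dict)


def pooled_covariance(X: np.ndarray, design: CaseControlDesign) -> np.ndarray:
    """Two-sample pooled covariance with divisor n - 2.

    Rows of ``X`` must be in the design's cases-first order.
    """
    X = np.asarray(X, dtype=float)
    nc, n = design.n_c, design.n
    xc = X[:nc].mean(axis=0)
    xd = X[nc:].mean(axis=0)
    dc = X[:nc] - xc
    dd = X[nc:] - xd
    return (dc.T @ dc + dd.T @ dd) / (n - 2)


def _pinv_quad(S: np.ndarray, d: np.ndarray, rtol: float = PINV_RTOL):
    """Quadratic form d' S^+ d via eigendecomposition; returns (value, rank)."""
    S = np.atleast_2d(S)
    if S.shape[0] == 0:
        return 0.0, 0
    w, U = np.linalg.eigh(S)
    cutoff = rtol * max(w[-1], 0.0)
    keep = w > cutoff
    rank = int(keep.sum())
    if rank == 0:
        return 0.0, 0
    proj = U[:, keep].T @ d
    return float(np.sum(proj**2 / w[keep])), rank


def _block_quad(
    X: np.ndarray,
    nc: int,
    nd: int,
    XtX: np.ndarray | None = None,
    col_sum: np.ndarray | None = None,
    case_sum: np.ndarray | None = None,
):
    """Numerator quadratic form d' Sigma^+ d for one block (rows cases-first).

    Uses the identity  pooled SS = X'X - nc xbar_c xbar_c' - nd xbar_d xbar_d'
    so that a row permutation only changes the case-row sum; ``XtX`` and
    ``col_sum`` may be precomputed and shared across permutations.
    """
    n = nc + nd
    if X.shape[1] == 0:
        return 0.0, 0, 0
    if XtX is None:
        XtX = X.T @ X
    if col_sum is None:
        col_sum = X.sum(axis=0)
    if case_sum is None:
        case_sum = X[:nc].sum(axis=0)
    xc = case_sum / nc
    xd = (col_sum - case_sum) / nd
    SS = XtX - nc * np.outer(xc, xc) - nd * np.outer(xd, xd)
    S = SS / (n - 2)
    d = (nc * nd / n) * (xc - xd)
    quad, rank = _pinv_quad(S, d)
    return quad, rank, X.shape[1]


def t2_statistic(
    blocks: CollapsedBlocks,
    covs: LongitudinalCovariates | None,
    design: CaseControlDesign,
    phi: KinshipMatrix | np.ndarray | None,
    spec: TestSpec,
) -> TestResult:
    """Compute the test statistic for one window.

    All row orders (blocks, covariates, phi) must already match the design's
    cases-first order.
    """
    nc, nd, n = design.n_c, design.n_d, design.n
    c = design.contrast()
    phi_m = phi.values if isinstance(phi, KinshipMatrix) else phi
    if phi_m is None:
        q_phi = nc * nd / n
    else:
        phi_m = np.asarray(phi_m, dtype=float)
        if phi_m.shape != (n, n):
            raise ValueError("kinship matrix order does not match design")
        q_phi = float(c @ phi_m @ c)
    if q_phi <= 0:
        raise np.linalg.LinAlgError("contrast quadratic form on Phi is not positive")

    if blocks.Z.shape[1] == 0 and blocks.V.shape[1] == 0:
        raise ValueError("window has no testable genetic columns")

    if spec.separate_covariance:
        quad_z, rank_z, p_z = _block_quad(blocks.Z, nc, nd)
        quad_v, rank_v, p_v = _block_quad(blocks.V, nc, nd)
        quad_g = quad_z + quad_v
        rank_g = rank_z + rank_v
        p_g = p_z + p_v
    else:
        quad_g, rank_g, p_g = _block_quad(blocks.matrix(), nc, nd)
    genetic_term = quad_g / q_phi

    covariate_term = 0.0
    q_phi_star: float | None = None
    rank_a = p_a = 0
    if spec.longitudinal:
        if covs is None:
            raise ValueError(f"method {spec.method} requires longitudinal covariates")
        if spec.phi_star == "kinship":
            if phi_m is None:
                raise ValueError("phi_star='kinship' requires a kinship matrix")
            q_phi_star = float(c @ phi_m @ c)
        else:
            q_phi_star = nc * nd / n  # q_I, closed form
        quad_a, rank_a, p_a = _block_quad(covs.values, nc, nd)
        covariate_term = quad_a / q_phi_star

    t2 = genetic_term + covariate_term
    n_variables = p_g + p_a
    rank = rank_g + rank_a
    df = n_variables if spec.df_mode == "n_variables" else rank
    p_asym = _chi2_sf(t2, df)
    return TestResult(
        t2=t2,
        df=df,
        p_asym=p_asym,
        method=spec.method,
        q_phi=q_phi,
        q_phi_star=q_phi_star,
        genetic_term=genetic_term,
        covariate_term=covariate_term,
        n_variables=n_variables,
        rank=rank,
        n_variables_genetic=p_g,
        rank_genetic=rank_g,
    )


def _chi2_sf(t2: float, df: int) -> float:
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(chi2.sf(t2, df))


def asymptotic_pvalue(result: TestResult, df_mode: str | None = None) -> float:
    """Upper-tail chi-square p at the requested degrees-of-freedom convention.

    ``df_mode=None`` reuses the df recorded in the result.
    """
    if result.t2 < 0:
        raise ValueError("statistic must be non-negative")
    if df_mode is None:
        df = result.df
    elif df_mode == "n_variables":
        df = result.n_variables
    elif df_mode == "rank":
        df = result.rank
    else:
        raise ValueError("df_mode must be 'n_variables' or 'rank'")
    return _chi2_sf(result.t2, df)


def read_longitudinal(path: str):
    """Read a long-format phenotype table.

    Columns: ``individual``, ``time``, ``outcome``, then one column per
    covariate.  Returns ``(ids, outcomes, LongitudinalCovariates)`` with rows
    in first-appearance order of individuals and times sorted ascending.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"individual", "time", "outcome"}
    if not required.issubset(df.columns):
        raise ValueError(f"longitudinal table needs columns {sorted(required)}")
    cov_names = [c for c in df.columns if c not in required]
    ids = list(dict.fromkeys(df["individual"].astype(str)))
    times = sorted(df["time"].unique())
    J, C, n = len(times), len(cov_names), len(ids)
    outcomes = np.full((n, J), np.nan)
    A = np.full((n, C * J), np.nan)
    row_of = {iid: k for k, iid in enumerate(ids)}
    col_of_time = {t: j for j, t in enumerate(times)}
    for _, row in df.iterrows():
        i = row_of[str(row["individual"])]
        j = col_of_time[row["time"]]
        outcomes[i, j] = row["outcome"]
        for ci, name in enumerate(cov_names):
            A[i, ci * J + j] = row[name]
    if np.isnan(outcomes).any() or np.isnan(A).any():
        raise ValueError("incomplete longitudinal table: every individual needs "
                         "all times (missing data unsupported)")
    covs = LongitudinalCovariates(A, n_covariates=C, n_times=J)
    return ids, outcomes.astype(int), covs
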