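"""Compositional correlation inference (SparCC) with permutation pseudo-p values.

Read counts from amplicon libraries are compositional: only relative abundances
are observed, so naive Pearson correlations between OTU columns are spurious.
SparCC instead works with log-ratio variances

    t_ij = Var_samples[ log(f_i / f_j) ]

which are invariant to the per-sample normalization, and approximates the
correlation of the latent log *basis* abundances. Under the sparsity assumption
(most pairs uncorrelated) the basis log-variances w_i = omega_i^2 satisfy the
linear system

    sum_{j in N(i)} t_ij  =  |N(i)| * w_i + sum_{j in N(i)} w_j

(with N(i) all partners of i, the system matrix is (D-2)I + J), from which

    rho_ij = (w_i + w_j - t_ij) / (2 * omega_i * omega_j).

Strongly correlated pairs violate the sparsity assumption and are iteratively
excluded from the row sums before re-solving. Fractions are estimated from
counts by Dirichlet posterior draws (prior 1), the whole procedure is repeated
``n_inner`` times, and estimates are aggregated by the element-wise median.

Significance follows the survey's bootstrap convention: each OTU column is
independently permuted across samples B=100 times, correlations are recomputed,
and a pair is significant at pseudo-p < 0.01 exactly when its observed
coefficient exceeds the coefficient in every one of the 100 null datasets
(add-one permutation p-value (1+k)/(B+1)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParameterError
from .otu import OtuTable

logger = logging.getLogger(__name__)

_OMEGA_EPS = 1e-12


def enumerate_pairs(n: int, include_self: bool = False) -> int:
    """Number of OTU pairs among n OTUs; with self-pairs this is n(n+1)/2."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    return n * (n + 1) // 2 if include_self else n * (n - 1) // 2


def estimate_fractions(
    counts: np.ndarray,
    prior: float = 1.0,
    method: str = "dirichlet",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Component fractions from counts, per sample (rows).

    ``method="dirichlet"`` draws once from the posterior Dirichlet(counts+prior);
    ``method="point"`` returns the posterior mean (count+prior)/(total+D*prior).
    Accepts a single count vector or a sample x OTU matrix.
    """
    arr = np.asarray(counts, dtype=float)
    single_row = arr.ndim == 1
    counts = np.atleast_2d(arr)
    if np.any(counts < 0):
        raise ParameterError("counts must be nonnegative")
    if np.any(counts.sum(axis=1) == 0):
        raise DegenerateDataError("all-zero count row: fractions undefined")
    alpha = counts + prior
    if method == "dirichlet":
        rng = rng or np.random.default_rng()
        draws = rng.standard_gamma(alpha)
        # guard against underflow to exactly zero at tiny shape parameters
        draws = np.maximum(draws, np.finfo(float).tiny)
        frac = draws / draws.sum(axis=1, keepdims=True)
    elif method == "point":
        frac = alpha / alpha.sum(axis=1, keepdims=True)
    else:
        raise ParameterError(f"unknown method {method!r}")
    return frac[0] if single_row else frac


@dataclass(frozen=True)
class LogRatioVariances:
    """Symmetric matrix t_ij of sample variances of log(f_i/f_j)."""

    t: np.ndarray
    n_samples: int

    @property
    def n_otus(self) -> int:
        return self.t.shape[0]


def logratio_variance_matrix(fractions: np.ndarray) -> LogRatioVariances:
    """t_ij = unbiased sample variance over samples of log(f_i/f_j).

    Computed via the log-fraction covariance: t_ij = v_ii + v_jj - 2 v_ij.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 2 or fractions.shape[0] < 2:
        raise ParameterError("fractions must be (n_samples >= 2) x n_otus")
    if np.any(fractions <= 0):
        raise DegenerateDataError("zero fraction: log-ratio undefined")
    logf = np.log(fractions)
    cov = np.cov(logf, rowvar=False, ddof=1)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    t = np.maximum(0.5 * (t + t.T), 0.0)
    np.fill_diagonal(t, 0.0)
    return LogRatioVariances(t=t, n_samples=fractions.shape[0])


@dataclass(frozen=True)
class BasisSystem:
    """Basis log-variances omega_i^2 solved under the sparsity approximation."""

    omega_sq: np.ndarray
    excluded_pairs: frozenset[tuple[int, int]] = frozenset()
    clamped: np.ndarray | None = None  # True where a negative solution was clamped


def solve_basis_variances(
    T: LogRatioVariances | np.ndarray,
    excluded_pairs: frozenset[tuple[int, int]] | set | None = None,
) -> BasisSystem:
    """Solve the basis-variance linear system, skipping excluded pairs.

    With no exclusions the system matrix is (D-2)I + J. Excluding pair (i, j)
    removes t_ij from both row sums and drops the corresponding coupling.
    Negative solutions are clamped to a small epsilon and flagged.
    """
    t = T.t if isinstance(T, LogRatioVariances) else np.asarray(T, dtype=float)
    D = t.shape[0]
    if D <= 2:
        raise DegenerateDataError("basis variances need at least 3 OTUs")
    if D == 3:
        logger.warning("solve_basis_variances: D=3 is below the reliable regime (D>=4)")
    excluded = {tuple(sorted(p)) for p in (excluded_pairs or set())}
    active = np.ones((D, D), dtype=bool)
    np.fill_diagonal(active, False)
    for i, j in excluded:
        active[i, j] = active[j, i] = False
    M = active.astype(float)
    np.fill_diagonal(M, active.sum(axis=1))
    b = (t * active).sum(axis=1)
    try:
        w = np.linalg.solve(M, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(f"singular basis system: {exc}") from exc
    clamped = w < _OMEGA_EPS
    if clamped.any():
        logger.debug("clamped %d negative basis variances", int(clamped.sum()))
    w = np.where(clamped, _OMEGA_EPS, w)
    return BasisSystem(omega_sq=w, excluded_pairs=frozenset(excluded), clamped=clamped)


def correlations_from_basis(
    T: LogRatioVariances | np.ndarray, basis: BasisSystem
) -> np.ndarray:
    """rho_ij = (w_i + w_j - t_ij) / (2 omega_i omega_j), clamped to [-1, 1].

    Pairs involving an omega clamped at the degeneracy floor are undefined and
    reported as NaN.
    """
    t = T.t if isinstance(T, LogRatioVariances) else np.asarray(T, dtype=float)
    w = basis.omega_sq
    omega = np.sqrt(w)
    denom = 2.0 * np.outer(omega, omega)
    rho = (w[:, None] + w[None, :] - t) / denom
    n_clamped = int(np.sum(np.abs(rho) > 1))  # diagonal is exactly 1, never counted
    if n_clamped > 0:
        logger.debug("clamped %d correlations outside [-1, 1]", n_clamped)
    rho = np.clip(rho, -1.0, 1.0)
    undefined = basis.clamped if basis.clamped is not None else (w <= _OMEGA_EPS)
    rho[undefined, :] = np.nan
    rho[:, undefined] = np.nan
    np.fill_diagonal(rho, 1.0)
    return rho


def _counts_of(table: OtuTable | np.ndarray) -> np.ndarray:
    return table.counts if isinstance(table, OtuTable) else np.asarray(table)


def sparcc_correlations(
    table: OtuTable | np.ndarray,
    n_inner: int = 20,
    excl_threshold: float = 0.1,
    max_excl_iter: int = 10,
    prior: float = 1.0,
    method: str = "dirichlet",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Full SparCC estimate: median over n_inner Dirichlet-resampled solutions.

    Each inner iteration: draw fractions, build the log-ratio variance matrix,
    then iteratively exclude the single most extreme pair with |rho| above
    ``excl_threshold`` (at most ``max_excl_iter`` exclusions) and re-solve.
    """
    counts = _counts_of(table)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    estimates = []
    for _ in range(n_inner):
        frac = estimate_fractions(counts, prior=prior, method=method, rng=rng)
        T = logratio_variance_matrix(frac)
        rho = _rho_with_exclusions(T, excl_threshold, max_excl_iter)
        estimates.append(rho)
        if method == "point":
            break  # deterministic fractions: further iterations are identical
    rho = np.nanmedian(np.stack(estimates), axis=0)
    rho = np.clip(0.5 * (rho + rho.T), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _rho_with_exclusions(
    T: LogRatioVariances, excl_threshold: float, max_excl_iter: int
) -> np.ndarray:
    excluded: set[tuple[int, int]] = set()
    basis = solve_basis_variances(T, excluded)
    rho = correlations_from_basis(T, basis)
    for _ in range(max_excl_iter):
        absr = np.abs(np.where(np.isnan(rho), 0.0, rho))
        np.fill_diagonal(absr, 0.0)
        for i, j in excluded:
            absr[i, j] = absr[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= excl_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        basis = solve_basis_variances(T, excluded)
        rho = correlations_from_basis(T, basis)
    return rho


@dataclass(frozen=True)
class CorrelationTable:
    """Pairwise basis correlations with permutation pseudo-p values."""

    rho: np.ndarray
    pseudo_p: np.ndarray
    B: int
    alpha: float = 0.01
    otu_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.rho.shape != self.pseudo_p.shape:
            raise ParameterError("rho and pseudo_p shapes differ")
        if np.any(self.pseudo_p <= 0):
            raise ParameterError("pseudo_p must be > 0 (add-one convention)")

    def to_frame(self) -> pd.DataFrame:
        D = self.rho.shape[0]
        ids = self.otu_ids or tuple(f"OTU_{k}" for k in range(D))
        iu, ju = np.triu_indices(D, k=1)
        return pd.DataFrame(
            {
                "otu_i": [ids[i] for i in iu],
                "otu_j": [ids[j] for j in ju],
                "rho": self.rho[iu, ju],
                "pseudo_p": self.pseudo_p[iu, ju],
            }
        )


def bootstrap_pseudo_p(
    table: OtuTable | np.ndarray,
    rho_obs: np.ndarray,
    B: int = 100,
    seed: int = 0,
    tail: str = "one_sided_positive",
    alpha: float = 0.01,
    **sparcc_kwargs,
) -> CorrelationTable:
    """Permutation-null pseudo-p values for every pair.

    Null tables permute each OTU's counts independently across samples (all
    pairwise dependence broken, marginals preserved); pseudo_p =
    (1 + #{b : rho_b >= rho_obs}) / (B + 1). ``tail="two_sided"`` compares |rho|.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    if tail not in ("one_sided_positive", "two_sided"):
        raise ParameterError(f"unknown tail {tail!r}")
    counts = _counts_of(table)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(rho_obs, dtype=np.int64)
    obs = np.abs(rho_obs) if tail == "two_sided" else rho_obs
    for _ in range(B):
        null_counts = rng.permuted(counts, axis=0)
        rho_b = sparcc_correlations(null_counts, seed=rng, **sparcc_kwargs)
        stat_b = np.abs(rho_b) if tail == "two_sided" else rho_b
        exceed += stat_b >= obs
    pseudo_p = (1.0 + exceed) / (B + 1.0)
    np.fill_diagonal(pseudo_p, 1.0)
    otu_ids = table.otu_ids if isinstance(table, OtuTable) else None
    return CorrelationTable(rho=rho_obs, pseudo_p=pseudo_p, B=B, alpha=alpha, otu_ids=otu_ids)


def significant_pairs(corr: CorrelationTable, alpha: float = 0.01) -> pd.DataFrame:
    """Edges (otu_i, otu_j, rho) with pseudo_p < alpha; self-pairs excluded."""
    df = corr.to_frame()
    return df[df["pseudo_p"] < alpha].drop(columns="pseudo_p").reset_index(drop=True)


def write_correlations(corr: CorrelationTable, path) -> None:
    corr.to_frame().to_csv(path, index=False)
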