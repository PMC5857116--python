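"""Dimensionality and local-independence checks for the Rasch fit.

Two nonparametric procedures:

* **Modified parallel analysis** (Drasgow–Lissak): the observed second
  eigenvalue of the inter-item tetrachoric correlation matrix is compared with
  its Monte-Carlo distribution under the fitted unidimensional Rasch model,
  using the estimated person abilities as the trait distribution.  A
  non-significant p-value is consistent with unidimensionality.

* **Ponocny's T1 quasi-exact test** for positive local dependence: for each
  item pair the number of persons answering both items identically is compared
  against its distribution over binary matrices with exactly the observed row
  and column margins, sampled by an MCMC of 2x2 checkerboard swaps (which
  connect the whole fixed-margin reference set).

Tetrachoric correlations are maximum-likelihood on each 2x2 table, with a 0.5
continuity correction when a cell is empty; the bivariate normal rectangle
probabilities are evaluated through Owen's T function.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri, owens_t

from .exceptions import DataValidationError, DegenerateInputError
from .rasch import RaschResults

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Bivariate normal CDF and tetrachoric correlation
# ---------------------------------------------------------------------------

def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho
    (Owen's 1956 T-function decomposition)."""
    if rho >= 1.0:
        return float(ndtr(min(h, k)))
    if rho <= -1.0:
        return float(max(0.0, ndtr(h) + ndtr(k) - 1.0))
    if h == 0.0 and k == 0.0:
        return 0.25 + np.arcsin(rho) / (2.0 * np.pi)
    s = np.sqrt(1.0 - rho * rho)

    def owen_term(x, num):
        if x == 0.0:
            if num == 0.0:
                return 0.0
            return 0.25 if num > 0 else -0.25
        return float(owens_t(x, num / (x * s)))

    beta = 0.0
    if h * k < 0 or (h * k == 0.0 and h + k < 0):
        beta = 0.5
    val = (0.5 * (ndtr(h) + ndtr(k))
           - owen_term(h, k - rho * h)
           - owen_term(k, h - rho * k)
           - beta)
    return float(min(1.0, max(0.0, val)))


def tetrachoric_from_counts(n11: float, n10: float, n01: float, n00: float) -> float:
    """ML tetrachoric correlation of a 2x2 table (x=1/0 rows, y=1/0 columns).

    With an empty cell the table gets a 0.5 continuity correction on every
    cell before estimation.
    """
    cells = np.array([n11, n10, n01, n00], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    n11, n10, n01, n00 = cells
    n = cells.sum()
    px = (n11 + n10) / n  # P(x = 1)
    py = (n11 + n01) / n
    tau_x = ndtri(1.0 - px)   # x = 1  <=>  Z1 > tau_x
    tau_y = ndtri(1.0 - py)
    p11 = n11 / n
    # P(Z1 > tau_x, Z2 > tau_y) = 1 - F(tau_x) - F(tau_y) + F2(tau_x, tau_y, rho)
    target = p11 - 1.0 + ndtr(tau_x) + ndtr(tau_y)

    def g(rho):
        return bvn_cdf(tau_x, tau_y, rho) - target

    lo, hi = -0.9999, 0.9999
    glo, ghi = g(lo), g(hi)
    if glo >= 0:
        return -1.0
    if ghi <= 0:
        return 1.0
    return float(optimize.brentq(g, lo, hi, xtol=1e-10))


def tetrachoric_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise tetrachoric correlation matrix of a complete 0/1 matrix."""
    X = np.asarray(X, dtype=int)
    m = X.shape[1]
    R = np.eye(m)
    for i, j in itertools.combinations(range(m), 2):
        xi, xj = X[:, i], X[:, j]
        n11 = int(np.sum((xi == 1) & (xj == 1)))
        n10 = int(np.sum((xi == 1) & (xj == 0)))
        n01 = int(np.sum((xi == 0) & (xj == 1)))
        n00 = int(np.sum((xi == 0) & (xj == 0)))
        R[i, j] = R[j, i] = tetrachoric_from_counts(n11, n10, n01, n00)
    return R


def _second_eigenvalue(R: np.ndarray) -> float:
    ev = np.linalg.eigvalsh(R)
    if ev[0] < -1e-8:
        warnings.warn(
            "tetrachoric matrix not positive semi-definite; "
            "negative eigenvalues clipped", RuntimeWarning)
        ev = np.clip(ev, 0.0, None)
    return float(np.sort(ev)[-2])


# ---------------------------------------------------------------------------
# Modified parallel analysis
# ---------------------------------------------------------------------------

@dataclass
class ParallelAnalysisResult:
    p_value: float
    observed_second_eigenvalue: float
    null_second_eigenvalues: np.ndarray
    n_mc: int
    seed: int


def modified_parallel_analysis(
    matrix: pd.DataFrame | np.ndarray,
    fit: RaschResults,
    n_mc: int = 2000,
    seed: int = 0,
) -> ParallelAnalysisResult:
    """Unidimensionality check against the fitted Rasch model.

    The null distribution is built from ``n_mc`` datasets simulated under the
    fitted difficulties with each person's estimated ability (extreme raw
    scores get anchor abilities solved at 0.3 / m-0.3 expected score, since
    their ML abilities are infinite).  p includes the observed matrix:
    ``p = (1 + #{null >= observed}) / (n_mc + 1)``.
    """
    if n_mc < 100:
        raise DataValidationError("n_mc must be at least 100")
    if not fit.converged:
        raise DataValidationError("Rasch fit did not converge")
    X = _complete_int_matrix(matrix)
    obs = _second_eigenvalue(tetrachoric_matrix(X))

    beta = fit.params.to_numpy()
    m = len(beta)
    from .rasch import _solve_theta
    theta_tbl = fit.theta_by_score["theta"].to_numpy()
    theta_lo = _solve_theta(beta, 0.3)
    theta_hi = _solve_theta(beta, m - 0.3)
    raw = X.sum(axis=1)
    theta = np.where(raw == 0, theta_lo,
                     np.where(raw == m, theta_hi, theta_tbl[np.clip(raw, 1, m - 1) - 1]))
    P = 1.0 / (1.0 + np.exp(-(theta[:, None] - beta[None, :])))

    rng = np.random.default_rng(seed)
    null = np.empty(n_mc)
    for b in range(n_mc):
        sim = (rng.random(P.shape) < P).astype(int)
        null[b] = _second_eigenvalue(tetrachoric_matrix(sim))
    p = (1.0 + float(np.sum(null >= obs))) / (n_mc + 1.0)
    return ParallelAnalysisResult(p, obs, null, n_mc, seed)


def _complete_int_matrix(matrix) -> np.ndarray:
    arr = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    keep = ~np.isnan(arr).any(axis=1)
    arr = arr[keep]
    if arr.shape[0] == 0:
        raise DegenerateInputError("no complete cases")
    return arr.astype(int)


# ---------------------------------------------------------------------------
# Fixed-margin sampling and Ponocny's T1
# ---------------------------------------------------------------------------

@dataclass
class MarginFixedSampler:
    """MCMC settings for sampling 0/1 matrices with the observed margins.

    One sweep = ``n_persons`` proposed 2x2 checkerboard swaps.
    """
    seed: int = 0
    burn_in: int = 1000
    thin: int = 16
    n_samples: int = 500


def sample_fixed_margins(matrix, sampler: MarginFixedSampler):
    """Yield ``n_samples`` matrices with exactly the observed row/column sums.

    A proposal picks two rows and two columns; if the 2x2 submatrix is a
    checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]) it is flipped, preserving
    all margins.  These swaps connect the whole reference set, so after
    burn-in the chain samples it uniformly.  If no swap is ever accepted
    during burn-in the matrix is degenerate and the observed matrix itself is
    emitted (with a warning).
    """
    X = _complete_int_matrix(matrix)
    n, m = X.shape
    if n < 2 or m < 2:
        raise DegenerateInputError("need at least a 2x2 matrix")
    x = X.ravel().tolist()  # flat python list: fast scalar access in the chain
    rng = np.random.default_rng(sampler.seed)
    accepted = 0

    def sweeps(k):
        nonlocal accepted
        total = k * n
        rows = rng.integers(0, n, size=(total, 2))
        cols = rng.integers(0, m, size=(total, 2))
        for (r1, r2), (c1, c2) in zip(rows.tolist(), cols.tolist()):
            if r1 == r2 or c1 == c2:
                continue
            i11 = r1 * m + c1
            i12 = r1 * m + c2
            i21 = r2 * m + c1
            i22 = r2 * m + c2
            a, b, c, d = x[i11], x[i12], x[i21], x[i22]
            if a == d and b == c and a != b:
                x[i11] = b
                x[i12] = a
                x[i21] = d
                x[i22] = c
                accepted += 1

    sweeps(sampler.burn_in)
    if accepted == 0:
        warnings.warn("no admissible checkerboard swap found during burn-in; "
                      "matrix margins admit (almost) a single matrix", RuntimeWarning)
    for _ in range(sampler.n_samples):
        sweeps(sampler.thin)
        yield np.array(x, dtype=int).reshape(n, m)


def _t1_statistics(X: np.ndarray) -> np.ndarray:
    """Per ordered pair (i<j): # persons with identical answers on i and j."""
    n, m = X.shape
    out = []
    for i, j in itertools.combinations(range(m), 2):
        out.append(int(np.sum(X[:, i] == X[:, j])))
    return np.array(out)


def ponocny_t1(matrix, sampler: MarginFixedSampler) -> pd.DataFrame:
    """Quasi-exact test for positive local dependence on every item pair.

    One-sided toward excess agreement: p = (1 + #{sampled >= observed}) /
    (n_samples + 1).  Pairs with p < .05 indicate local dependence.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
    else:
        names = [f"item_{j + 1}" for j in range(np.asarray(matrix).shape[1])]
    X = _complete_int_matrix(matrix)
    # canonical row order: the pair statistics ignore person order, and a
    # canonical chain start makes the p-values exactly reorder-invariant
    X = X[np.lexsort(X.T[::-1])]
    obs = _t1_statistics(X)
    ge = np.zeros(len(obs))
    count = 0
    for sim in sample_fixed_margins(X, sampler):
        ge += _t1_statistics(sim) >= obs
        count += 1
    p = (1.0 + ge) / (count + 1.0)
    pairs = list(itertools.combinations(range(len(names)), 2))
    return pd.DataFrame({
        "item_i": [names[i] for i, _ in pairs],
        "item_j": [names[j] for _, j in pairs],
        "statistic": obs,
        "p_value": p,
        "locally_dependent": p < 0.05,
    })
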