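"""Dichotomous Rasch model fitted by conditional maximum likelihood.

The Rasch measurement model puts persons and items on one latent scale: the
probability that person v endorses item i is

    P(X_vi = 1 | theta_v, beta_i) = exp(theta_v - beta_i) / (1 + exp(theta_v - beta_i))

with person ability theta_v and item difficulty beta_i in logits.  Conditioning
on each person's raw score eliminates the person parameters, so the item
difficulties are estimated from the conditional likelihood

    L(beta) = prod_v  exp(-sum_i x_vi beta_i) / gamma_{r_v}(eps),

where eps_i = exp(-beta_i) and gamma_r is the elementary symmetric function
(ESF) of order r.  The ESFs and their partial versions are computed with the
log-domain summation recursion; the likelihood is maximised by Newton
iterations with analytic gradient and Hessian.  Difficulties are reported
under the sum-zero convention; standard errors come from the observed
information matrix (delta method for the centred parameterisation).

Persons with zero or perfect raw scores carry no conditional information and
are excluded from estimation, fit statistics and reliability; their maximum
likelihood ability is undefined and reported as NaN.

The public surface follows the Model/Results convention: build a
:class:`RaschModel` from a response matrix, call :meth:`~RaschModel.fit`, and
read estimates, fit statistics and reliability off the returned
:class:`RaschResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DataValidationError, DegenerateInputError, InestimableItemError

logger = logging.getLogger(__name__)

_NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# Elementary symmetric functions (log domain)
# ---------------------------------------------------------------------------

def log_esf(log_eps: np.ndarray) -> np.ndarray:
    """log gamma_r, r = 0..m, of eps_i = exp(log_eps_i), by the summation
    recursion  gamma_r <- gamma_r + eps_i * gamma_{r-1}."""
    m = len(log_eps)
    lg = np.full(m + 1, _NEG_INF)
    lg[0] = 0.0
    for le in log_eps:
        lg[1:] = np.logaddexp(lg[1:], lg[:-1] + le)
    return lg


def log_esf_without(log_eps: np.ndarray, skip) -> np.ndarray:
    """ESFs of the item set excluding the indices in ``skip``."""
    mask = np.ones(len(log_eps), dtype=bool)
    mask[list(np.atleast_1d(skip))] = False
    return log_esf(log_eps[mask])


def conditional_pattern_logprob(pattern: np.ndarray, beta: np.ndarray) -> float:
    """log P(pattern | raw score) under difficulties ``beta`` — brute-force
    reference quantity used for oracle checks (valid for any m)."""
    r = int(pattern.sum())
    lg = log_esf(-beta)
    return float(-(pattern * beta).sum() - lg[r])


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class RaschModel:
    """Dichotomous Rasch model for a persons × items 0/1 matrix.

    Parameters
    ----------
    endog
        Response matrix (``DataFrame`` or array); cells 0/1/NaN.  Persons
        with any missing cell are excluded from estimation (complete-case
        CML) and reported in ``n_dropped_incomplete``.
    """

    def __init__(self, endog, item_names=None):
        if isinstance(endog, pd.DataFrame):
            self.item_names = list(endog.columns)
            self.person_index = endog.index
            data = endog.to_numpy(dtype=float)
        else:
            data = np.asarray(endog, dtype=float)
            self.item_names = list(item_names) if item_names is not None else [
                f"item_{j + 1}" for j in range(data.shape[1])
            ]
            self.person_index = pd.RangeIndex(data.shape[0])
        if data.ndim != 2 or data.shape[1] < 2:
            raise DataValidationError("need a 2-D matrix with at least 2 items")
        ok = np.isnan(data) | (data == 0) | (data == 1)
        if not ok.all():
            raise DataValidationError("response cells must be 0, 1 or missing")
        self._complete = ~np.isnan(data).any(axis=1)
        self.n_dropped_incomplete = int((~self._complete).sum())
        self.data = data
        self.X = data[self._complete].astype(int)
        self.m = data.shape[1]

        raw = self.X.sum(axis=1)
        self._nonextreme = (raw > 0) & (raw < self.m)
        self.raw_scores = raw
        Xne = self.X[self._nonextreme]
        if Xne.shape[0] < 2:
            raise DegenerateInputError("fewer than 2 persons with non-extreme raw scores")
        self.item_margins = Xne.sum(axis=0)
        counts = np.bincount(Xne.sum(axis=1), minlength=self.m + 1)
        self.score_counts = counts  # n_r, r = 0..m (extremes are zero here)
        self.n_nonextreme = Xne.shape[0]
        for j, s in enumerate(self.item_margins):
            if s == 0:
                raise InestimableItemError(self.item_names[j], "0")
            if s == self.n_nonextreme:
                raise InestimableItemError(self.item_names[j], "1")

    # -- conditional likelihood ------------------------------------------
    def loglike(self, beta: np.ndarray) -> float:
        """Conditional log-likelihood at difficulties ``beta``."""
        beta = np.asarray(beta, dtype=float)
        lg = log_esf(-beta)
        ll = -float(self.item_margins @ beta)
        for r in range(1, self.m):
            if self.score_counts[r]:
                ll -= self.score_counts[r] * lg[r]
        return ll

    def _pi_matrix(self, beta: np.ndarray) -> np.ndarray:
        """pi[r, i] = P(X_i = 1 | raw score r), r = 1..m-1 (row r-1)."""
        m = self.m
        lg = log_esf(-beta)
        pi = np.empty((m - 1, m))
        for i in range(m):
            lgi = log_esf_without(-beta, i)
            for r in range(1, m):
                pi[r - 1, i] = np.exp(-beta[i] + lgi[r - 1] - lg[r])
        return pi

    def score_vector(self, beta: np.ndarray) -> np.ndarray:
        """Gradient of the conditional log-likelihood."""
        pi = self._pi_matrix(beta)
        nr = self.score_counts[1:self.m]
        return -(self.item_margins - nr @ pi)  # d/d beta

    def _hessian_nll(self, beta: np.ndarray) -> np.ndarray:
        """Hessian of the *negative* conditional log-likelihood (PSD)."""
        m = self.m
        lg = log_esf(-beta)
        pi = self._pi_matrix(beta)
        nr = self.score_counts[1:m].astype(float)
        H = np.zeros((m, m))
        for i in range(m):
            H[i, i] = float(nr @ (pi[:, i] * (1.0 - pi[:, i])))
        for i in range(m):
            for j in range(i + 1, m):
                lgij = log_esf_without(-beta, (i, j))
                pij = np.zeros(m - 1)
                for r in range(2, m):
                    pij[r - 1] = np.exp(-beta[i] - beta[j] + lgij[r - 2] - lg[r])
                val = float(nr @ (pij - pi[:, i] * pi[:, j]))
                H[i, j] = H[j, i] = val
        return H

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "RaschResults":
        """Newton maximisation of the conditional likelihood.

        Convergence: gradient infinity-norm below ``tol`` (default 1e-8).
        """
        m = self.m
        p = self.item_margins / self.n_nonextreme
        beta = np.log((1.0 - p) / p)
        beta -= beta[0]  # identification: fix first item during iteration
        free = np.arange(1, m)
        converged = False
        for it in range(1, maxiter + 1):
            g = -self.score_vector(beta)  # gradient of nll
            if np.max(np.abs(g[free])) < tol:
                converged = True
                break
            H = self._hessian_nll(beta)
            step = np.linalg.solve(H[np.ix_(free, free)], g[free])
            # dampen long steps for stability far from the optimum
            norm = np.max(np.abs(step))
            if norm > 3.0:
                step *= 3.0 / norm
            beta[free] -= step
        if not converged:
            logger.warning("CML Newton did not converge in %d iterations", maxiter)

        H = self._hessian_nll(beta)
        V_free = np.linalg.inv(H[np.ix_(free, free)])
        # delta method to the sum-zero (centred) parameterisation
        B = np.zeros((m, m - 1))
        B[1:, :] = np.eye(m - 1)
        B -= B.mean(axis=0, keepdims=True)  # subtracting the mean of beta
        cov = B @ V_free @ B.T
        beta_centered = beta - beta.mean()
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return RaschResults(self, beta_centered, se, cov, converged, it)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def _solve_theta(beta: np.ndarray, r: float) -> float:
    """Ability solving sum_i sigma(theta - beta_i) = r."""
    f = lambda t: np.sum(1.0 / (1.0 + np.exp(-(t - beta)))) - r
    return float(optimize.brentq(f, -50.0, 50.0, xtol=1e-10))


@dataclass
class ReliabilityReport:
    psi: float
    mean_interitem_r: float
    n_persons_used: int


class RaschResults:
    """Estimates and diagnostics of a conditional-ML Rasch fit.

    Attributes
    ----------
    params : pd.Series
        Sum-zero item difficulties (logits).
    bse : pd.Series
        Standard errors from the observed information matrix.
    """

    def __init__(self, model: RaschModel, beta, se, cov, converged, niter):
        self.model = model
        self.params = pd.Series(beta, index=model.item_names, name="difficulty")
        self.bse = pd.Series(se, index=model.item_names, name="se")
        self.cov_params = cov
        self.converged = converged
        self.niter = niter
        self.loglike = model.loglike(beta)
        self._theta_by_score = None

    # -- abilities --------------------------------------------------------
    @property
    def theta_by_score(self) -> pd.DataFrame:
        """ML ability and SE per raw score 1..m-1 (extremes undefined)."""
        if self._theta_by_score is None:
            beta = self.params.to_numpy()
            m = self.model.m
            rows = []
            for r in range(1, m):
                th = _solve_theta(beta, r)
                p = 1.0 / (1.0 + np.exp(-(th - beta)))
                info = float(np.sum(p * (1 - p)))
                rows.append({"raw_score": r, "theta": th, "se": 1.0 / np.sqrt(info)})
            self._theta_by_score = pd.DataFrame(rows).set_index("raw_score")
        return self._theta_by_score

    def extreme_thetas(self) -> tuple[float, float]:
        """Finite abilities assigned to zero and perfect raw scores by
        natural-cubic-spline extrapolation of theta over raw scores 1..m-1
        (the ML estimates there are infinite)."""
        from scipy.interpolate import CubicSpline
        tbl = self.theta_by_score
        cs = CubicSpline(tbl.index.to_numpy(dtype=float),
                         tbl["theta"].to_numpy(), bc_type="natural")
        return float(cs(0.0)), float(cs(float(self.model.m)))

    def abilities(self) -> pd.DataFrame:
        """Per complete-case person: raw score, ability, SE, extreme flag."""
        tbl = self.theta_by_score
        raw = self.model.raw_scores
        theta = np.full(len(raw), np.nan)
        se = np.full(len(raw), np.nan)
        ne = self.model._nonextreme
        theta[ne] = tbl["theta"].to_numpy()[raw[ne] - 1]
        se[ne] = tbl["se"].to_numpy()[raw[ne] - 1]
        idx = self.model.person_index[self.model._complete]
        return pd.DataFrame(
            {"raw_score": raw, "theta": theta, "theta_se": se, "extreme": ~ne},
            index=idx,
        )

    def expected(self) -> np.ndarray:
        """Model probabilities for non-extreme complete persons (n_ne × m)."""
        beta = self.params.to_numpy()
        tbl = self.theta_by_score["theta"].to_numpy()
        raw = self.model.raw_scores[self.model._nonextreme]
        th = tbl[raw - 1][:, None]
        return 1.0 / (1.0 + np.exp(-(th - beta[None, :])))

    def residuals(self) -> np.ndarray:
        """Standardized residuals z = (x - E) / sqrt(E(1-E)) for non-extreme
        persons."""
        E = self.expected()
        X = self.model.X[self.model._nonextreme]
        return (X - E) / np.sqrt(E * (1 - E))

    # -- fit statistics ---------------------------------------------------
    def item_fit(self) -> pd.DataFrame:
        """Outfit/infit mean squares, standardized fit t, chi-square per item.

        Outfit is the unweighted mean of squared standardized residuals,
        infit the information-weighted version.  t statistics use the
        Wilson–Hilferty cube-root transformation with the kurtosis-based
        variance.  chi2 = sum of squared residuals, df = n_nonextreme - 1,
        with the p-value Bonferroni-multiplied by the number of items.
        Flags mark mean squares outside (0.60, 1.40) or |t| > 2.50.
        """
        E = self.expected()
        X = self.model.X[self.model._nonextreme].astype(float)
        W = E * (1 - E)
        C = W * (1.0 - 3.0 * W)  # fourth central moment of a Bernoulli
        Z2 = (X - E) ** 2 / W
        N = X.shape[0]

        outfit = Z2.mean(axis=0)
        var_out = np.clip((C / W**2).sum(axis=0) / N**2 - 1.0 / N, 1e-12, None)
        infit = ((X - E) ** 2).sum(axis=0) / W.sum(axis=0)
        var_in = np.clip((C - W**2).sum(axis=0) / W.sum(axis=0) ** 2, 1e-12, None)

        def wh_t(msq, var):
            q = np.sqrt(var)
            return (np.cbrt(msq) - 1.0) * (3.0 / q) + q / 3.0

        chi2 = Z2.sum(axis=0)
        df = N - 1
        p = stats.chi2.sf(chi2, df)
        p_bonf = np.clip(p * self.model.m, 0.0, 1.0)
        out = pd.DataFrame({
            "outfit_msq": outfit,
            "infit_msq": infit,
            "outfit_t": wh_t(outfit, var_out),
            "infit_t": wh_t(infit, var_in),
            "chi2": chi2,
            "df": df,
            "p": p,
            "p_bonferroni": p_bonf,
        }, index=self.model.item_names)
        out["misfit"] = (
            (out["outfit_msq"] < 0.60) | (out["outfit_msq"] > 1.40)
            | (out["infit_msq"] < 0.60) | (out["infit_msq"] > 1.40)
            | (out["outfit_t"].abs() > 2.50) | (out["infit_t"].abs() > 2.50)
        )
        out.index.name = "item"
        return out

    def reliability(self, matrix: pd.DataFrame | None = None) -> ReliabilityReport:
        """Person separation index and mean inter-item correlation.

        PSI = (var(theta_hat) - mean(SE^2)) / var(theta_hat), clipped to
        [0, 1].  Following the separation-reliability convention of the
        standard Rasch software, the ability variance is taken over *all*
        complete-case persons, with zero/perfect raw scores assigned
        spline-extrapolated abilities (their ML estimates are infinite),
        while the mean squared SE uses non-extreme persons only.  Dropping
        extreme persons from the variance is not an option: on score
        distributions typical of a ~30%-endorsement screening scale it
        roughly halves the index.  The mean inter-item correlation is the
        average pairwise Pearson correlation of the item columns
        (pairwise-complete), taken from ``matrix`` if given, else from the
        fitted data.
        """
        ab = self.abilities()
        ne = ab.loc[~ab["extreme"]]
        if len(ne) < 2:
            raise DegenerateInputError("fewer than 2 non-extreme persons")
        th_lo, th_hi = self.extreme_thetas()
        theta_all = ab["theta"].to_numpy().copy()
        raw = ab["raw_score"].to_numpy()
        theta_all[raw == 0] = th_lo
        theta_all[raw == self.model.m] = th_hi
        v = float(np.var(theta_all, ddof=1))
        if v <= 0:
            psi = float("nan")
        else:
            psi = float(np.clip((v - float((ne["theta_se"] ** 2).mean())) / v, 0.0, 1.0))
        if matrix is None:
            matrix = pd.DataFrame(self.model.data, columns=self.model.item_names)
        corr = matrix.corr(method="pearson")
        iu = np.triu_indices(len(corr), k=1)
        mean_r = float(np.nanmean(corr.to_numpy()[iu]))
        return ReliabilityReport(psi=psi, mean_interitem_r=mean_r,
                                 n_persons_used=len(ne))

    def summary(self) -> str:
        fit = self.item_fit()
        lines = [
            "Dichotomous Rasch model (conditional maximum likelihood)",
            f"  persons (complete): {self.model.X.shape[0]}   "
            f"non-extreme: {self.model.n_nonextreme}   items: {self.model.m}",
            f"  converged: {self.converged} in {self.niter} Newton iterations; "
            f"conditional log-likelihood {self.loglike:.4f}",
            "",
            f"{'item':<12}{'difficulty':>11}{'SE':>8}{'outfit':>8}{'infit':>8}"
            f"{'outfit_t':>10}{'infit_t':>9}{'p_bonf':>9}",
        ]
        for name in self.model.item_names:
            r = fit.loc[name]
            lines.append(
                f"{name:<12}{self.params[name]:>11.3f}{self.bse[name]:>8.3f}"
                f"{r['outfit_msq']:>8.3f}{r['infit_msq']:>8.3f}"
                f"{r['outfit_t']:>10.2f}{r['infit_t']:>9.2f}{r['p_bonferroni']:>9.3f}"
            )
        return "\n".join(lines)
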