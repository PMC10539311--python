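"""Beta-binomial regression of far-contact rates.

The null model for delocalization scoring: for RNA i with N_i total contacts,
the far-contact count K_i (trans contacts, or cis contacts beyond a travel
distance threshold) is beta-binomial,

    E[K_i | N_i]   = pi_i N_i
    var[K_i | N_i] = pi_i (1 - pi_i) N_i (1 + (N_i - 1) gamma)

with a logit-linear mean

    logit(pi_i) = eta_chr(i) + eta_expr * ln(N_i)

using chromosome-specific intercepts (no global intercept) and a shared
intraclass-correlation overdispersion gamma in [0, 1).  The implied Beta
mixing distribution has concentration alpha + beta = 1/gamma - 1, which is
the conjugate prior used downstream for empirical-Bayes shrinkage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

logger = logging.getLogger(__name__)

__all__ = ["BetaBinomialGLM", "BetaBinomialGLMResults", "betabin_logpmf"]

_GAMMA_EPS = 1e-8


def betabin_logpmf(k, n, pi, gamma):
    """Beta-binomial log pmf with mean rate ``pi`` and ICC ``gamma``.

    ``gamma`` -> 0 reduces to the binomial pmf (handled explicitly).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    pi = np.clip(np.asarray(pi, dtype=float), 1e-12, 1 - 1e-12)
    binom = (special.gammaln(n + 1) - special.gammaln(k + 1)
             - special.gammaln(n - k + 1))
    if np.all(np.asarray(gamma) < _GAMMA_EPS):
        return binom + k * np.log(pi) + (n - k) * np.log1p(-pi)
    s = 1.0 / gamma - 1.0
    a, b = pi * s, (1.0 - pi) * s
    return (binom + special.betaln(k + a, n - k + b) - special.betaln(a, b))


class BetaBinomialGLM:
    """Beta-binomial GLM of far-contact counts with logit mean link.

    Parameters
    ----------
    far : array-like
        Far-contact counts K_i.
    total : array-like
        Total contact counts N_i (the conditioning variable).
    chrom : array-like
        Source chromosome of each RNA (one intercept per level).
    expr_covariate : array-like, optional
        Expression covariate; defaults to ln(N_i).
    """

    def __init__(self, far, total, chrom, expr_covariate=None,
                 include_expr: bool = True):
        self.far = np.asarray(far, dtype=float)
        self.total = np.asarray(total, dtype=float)
        chrom = pd.Categorical(chrom)
        self.chrom_levels = list(chrom.categories)
        self.chrom_codes = np.asarray(chrom.codes)
        self.include_expr = bool(include_expr)
        if expr_covariate is None:
            expr_covariate = np.log(self.total)
        self.expr = np.asarray(expr_covariate, dtype=float)
        if not (len(self.far) == len(self.total) == len(self.chrom_codes) == len(self.expr)):
            raise ValueError("far, total, chrom and expr_covariate must be equal length")
        if np.any(self.far < 0) or np.any(self.far > self.total):
            raise ValueError("need 0 <= far <= total")
        counts = np.bincount(self.chrom_codes, minlength=len(self.chrom_levels))
        if np.any(counts < 2):
            short = [c for c, n in zip(self.chrom_levels, counts) if n < 2]
            raise ValueError(f"need >= 2 training RNAs per chromosome; short: {short}")
        # design: chromosome dummies (no global intercept) + expression column
        cols = [(self.chrom_codes == j).astype(float)
                for j in range(len(self.chrom_levels))]
        self.param_names = [f"eta_chr[{c}]" for c in self.chrom_levels]
        if self.include_expr:
            cols.append(self.expr)
            self.param_names = self.param_names + ["eta_expr"]
        self._X = np.column_stack(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, far="N_far", total="N", chrom="chrom",
                       expr=None) -> "BetaBinomialGLM":
        return cls(df[far], df[total], df[chrom],
                   None if expr is None else df[expr])

    # ------------------------------------------------------------------ fitting
    def _loglike(self, theta: np.ndarray) -> float:
        eta = self._X @ theta[:-1]
        pi = special.expit(eta)
        gamma = special.expit(theta[-1])
        return float(np.sum(betabin_logpmf(self.far, self.total, pi, gamma)))

    def _initial_params(self) -> np.ndarray:
        glm = sm.GLM(
            np.column_stack([self.far, self.total - self.far]),
            self._X,
            family=sm.families.Binomial(),
        )
        res = glm.fit()
        pi = np.clip(res.fittedvalues, 1e-9, 1 - 1e-9)
        # method-of-moments gamma from the binomial-fit residuals
        num = (self.far - self.total * pi) ** 2 - self.total * pi * (1 - pi)
        den = pi * (1 - pi) * self.total * np.maximum(self.total - 1, 1)
        gamma0 = float(np.clip(np.mean(num) / max(np.mean(den), 1e-300), 1e-5, 0.5))
        return np.append(res.params, special.logit(gamma0))

    def fit(self, maxiter: int = 500, gtol: float = 1e-8,
            n_restarts: int = 3, seed: int = 0) -> "BetaBinomialGLMResults":
        """Maximize the beta-binomial log-likelihood jointly over all parameters."""
        theta0 = self._initial_params()
        neg = lambda t: -self._loglike(t)
        best = None
        rng = np.random.default_rng(seed)
        # logit-gamma bounded: the binomial limit pushes it to -inf
        bounds = [(None, None)] * (theta0.size - 1) + [(-20.0, 8.0)]
        theta0[-1] = np.clip(theta0[-1], -19.0, 7.0)
        start = theta0
        for attempt in range(n_restarts + 1):
            res = optimize.minimize(neg, start, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": maxiter, "gtol": gtol,
                                             "ftol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                break
            start = theta0 + rng.normal(scale=0.5, size=theta0.size)
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("beta-binomial GLM fit failed: no finite optimum")
        converged = bool(best.success)
        if not converged:
            # L-BFGS-B line searches fail where the likelihood is flat in
            # logit-gamma (binomial limit); polish with a simplex search
            polish = optimize.minimize(neg, best.x, method="Nelder-Mead",
                                       options={"xatol": 1e-8, "fatol": 1e-10,
                                                "maxiter": 5000})
            if polish.fun <= best.fun + 1e-6:
                best = polish if polish.fun < best.fun else best
                converged = bool(polish.success)
        if not converged:
            raise RuntimeError(
                f"beta-binomial GLM did not converge after {n_restarts} restarts: "
                f"{best.message}; llf={-best.fun:.6g}"
            )
        from statsmodels.tools.numdiff import approx_hess

        hess = approx_hess(best.x, self._loglike)
        try:
            cov = np.linalg.inv(-hess)
            bse = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            cov = np.full((best.x.size,) * 2, np.nan)
            bse = np.full(best.x.size, np.nan)
        return BetaBinomialGLMResults(self, best.x, cov, bse, -best.fun, converged)


class BetaBinomialGLMResults:
    """Fitted beta-binomial GLM: coefficients, overdispersion and SEs."""

    def __init__(self, model: BetaBinomialGLM, theta, cov, bse, llf, converged):
        self.model = model
        self._theta = np.asarray(theta, dtype=float)
        self.cov_params = cov
        self.llf = float(llf)
        self.converged = bool(converged)
        names = model.param_names + ["logit_gamma"]
        self.params = pd.Series(self._theta, index=names)
        self.bse = pd.Series(np.asarray(bse, dtype=float), index=names)

    # -------------------------------------------------------------- accessors
    @property
    def gamma(self) -> float:
        """Overdispersion (beta-binomial intraclass correlation), in [0, 1)."""
        return float(special.expit(self._theta[-1]))

    @property
    def gamma_bse(self) -> float:
        """Delta-method SE of gamma."""
        g = self.gamma
        return float(self.bse.iloc[-1] * g * (1 - g))

    @property
    def eta_chr(self) -> pd.Series:
        return pd.Series(self._theta[: len(self.model.chrom_levels)],
                         index=self.model.chrom_levels)

    @property
    def eta_expr(self) -> float:
        if not self.model.include_expr:
            return 0.0
        return float(self._theta[len(self.model.chrom_levels)])

    @property
    def prior_concentration(self) -> float:
        """alpha + beta = 1/gamma - 1 of the implied Beta mixing distribution."""
        return 1.0 / self.gamma - 1.0

    def predict(self, chrom, expr_covariate) -> np.ndarray:
        """Model mean rate pi_model for new RNAs.

        A chromosome unseen in training gets the mean of the fitted
        intercepts (with a warning).
        """
        chrom = np.asarray(chrom, dtype=object)
        expr = np.asarray(expr_covariate, dtype=float)
        lookup = self.eta_chr
        mean_eta = float(lookup.mean())
        unseen = sorted(set(chrom) - set(lookup.index))
        if unseen:
            logger.warning("chromosomes %s unseen in training; using mean intercept", unseen)
        eta0 = np.array([lookup.get(c, mean_eta) for c in chrom])
        return special.expit(eta0 + self.eta_expr * expr)

    def summary(self) -> str:
        lines = ["Beta-binomial GLM (logit mean link, shared overdispersion)",
                 f"  n obs: {len(self.model.far)}   llf: {self.llf:.3f}   "
                 f"converged: {self.converged}",
                 f"  gamma: {self.gamma:.5f} (SE {self.gamma_bse:.5f})",
                 "  coefficients:"]
        for name in self.params.index[:-1]:
            lines.append(f"    {name:<18s} {self.params[name]: .5f}  "
                         f"(SE {self.bse[name]:.5f})")
        return "\n".join(lines)
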