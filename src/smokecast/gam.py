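"""Gamma log-link penalized-spline regression (the GAM stage).

The daily PM2.5 responses are strictly positive and right-skewed with a
variance that grows with the mean, so they are modelled as Gamma with a log
link: E[y_i] = exp(eta_i), eta = X beta, where X collects an intercept and
centred spline blocks (see :mod:`smokecast.basis`). Fitting maximizes the
penalized likelihood by iteratively reweighted least squares; for the Gamma
log-link pairing the Fisher weights are identically one, so each step is a
penalized linear solve against the working response z = eta + (y - mu)/mu.
Smoothing parameters are chosen by maximizing a Laplace-approximate
restricted marginal likelihood (REML), with the Gamma shape set to its
profile maximum-likelihood estimate at each evaluation.

Model complexity is measured by the effective degrees of freedom
edf = tr[(X'X + S_lambda)^-1 X'X], and models are compared with
AIC = -2 loglik(beta_hat, shape_hat) + 2 (edf + 1), the +1 counting the
estimated dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import brentq, minimize
from scipy.special import digamma, gammaln

from .basis import SmoothTerm, TermBasis, build_basis

__all__ = [
    "ModelFormula",
    "GammaGAM",
    "GammaGAMResults",
    "fit_gamma_gam",
    "gamma_deviance",
    "gamma_loglik",
    "gamma_shape_mle",
    "r2_correlation",
]

#: U/V wind components may only appear jointly, as one 2-D smooth.
WIND_PAIRS = (("u_coast_aft", "v_coast_aft"), ("u_inland", "v_inland"))

_ETA_CLIP = 30.0


@dataclass(frozen=True)
class ModelFormula:
    """Response plus a set of smooth terms; the intercept is always present.

    Terms are stored sorted by name so that formulas compare and print
    deterministically.
    """

    response: str
    terms: tuple[SmoothTerm, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(sorted(self.terms, key=lambda t: t.name)))
        seen: set[str] = set()
        for t in self.terms:
            for v in t.variables:
                if v in seen:
                    raise ValueError(f"predictor {v!r} appears in two terms")
                seen.add(v)
        for pair in WIND_PAIRS:
            for t in self.terms:
                got = set(t.variables) & set(pair)
                if got and set(t.variables) != set(pair):
                    raise ValueError(f"wind components {pair} must enter jointly, got {t.variables}")

    def __str__(self) -> str:
        rhs = " + ".join(t.name for t in self.terms) or "1"
        return f"{self.response} ~ {rhs}"


class _Design:
    """Assembled design matrix: intercept column plus centred term blocks."""

    def __init__(self, formula: ModelFormula, data: pd.DataFrame):
        self.formula = formula
        self.bases: list[TermBasis] = [build_basis(t, data) for t in formula.terms]
        blocks = [np.ones((len(data), 1))] + [b.columns for b in self.bases]
        self.X = np.ascontiguousarray(np.column_stack(blocks))
        self.slices: list[slice] = []
        self.col_names = ["intercept"]
        start = 1
        for b in self.bases:
            q = b.columns.shape[1]
            self.slices.append(slice(start, start + q))
            self.col_names += [f"{b.term.name}.{j + 1}" for j in range(q)]
            start += q
        self.p = start

    def embed_penalties(self) -> list[np.ndarray]:
        """Per-term penalty matrices embedded into the full p x p frame."""
        out = []
        for b, sl in zip(self.bases, self.slices):
            S = np.zeros((self.p, self.p))
            S[sl, sl] = b.penalty
            out.append(S)
        return out

    def design(self, data: pd.DataFrame) -> np.ndarray:
        missing = [v for t in self.formula.terms for v in t.variables if v not in data.columns]
        if missing:
            raise ValueError(f"newdata is missing predictor column(s): {missing}")
        blocks = [np.ones((len(data), 1))] + [b.design(data) for b in self.bases]
        return np.column_stack(blocks)

    def extrapolates(self, data: pd.DataFrame) -> np.ndarray:
        if not self.bases:
            return np.zeros(len(data), dtype=bool)
        return np.any([b.extrapolates(data) for b in self.bases], axis=0)


def gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Gamma deviance 2 sum(-log(y/mu) + (y - mu)/mu)."""
    r = y / mu
    return float(2.0 * np.sum(-np.log(r) + r - 1.0))


def gamma_loglik(y: np.ndarray, mu: np.ndarray, shape: float) -> float:
    """Gamma log-likelihood with mean ``mu`` and shape ``shape``."""
    a = shape
    return float(
        np.sum(a * np.log(a) - gammaln(a) + (a - 1.0) * np.log(y) - a * np.log(mu) - a * y / mu)
    )


def gamma_shape_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile maximum-likelihood Gamma shape given fitted means."""
    c = float(np.mean(y / mu - np.log(y / mu))) - 1.0
    if c < 1e-12:
        return 1e10
    f = lambda a: np.log(a) - digamma(a) - c
    return float(brentq(f, 1e-8, 1e12, xtol=1e-12, rtol=1e-10))


def r2_correlation(observed, predicted) -> float:
    """Squared Pearson correlation of observed vs predicted values; NaN when
    either vector has zero variance."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.std() == 0.0 or p.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(o, p)[0, 1] ** 2)


def _chol(A: np.ndarray):
    try:
        return cho_factor(A, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(A) / A.shape[0]
        return cho_factor(A + jitter * np.eye(A.shape[0]), lower=True, check_finite=False)


def _pirls(X, y, G, Slam, eta0=None, tol=1e-8, maxiter=200):
    """Penalized IRLS for the Gamma/log model at fixed smoothing.

    Returns (beta, eta, deviance, converged, n_iter, chol_factor).
    """
    eta = np.log(y) if eta0 is None else eta0.copy()
    dev_prev = np.inf
    beta_prev = None
    beta = None
    ch = None
    converged = False
    for it in range(1, maxiter + 1):
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        z = np.clip(eta, -_ETA_CLIP, _ETA_CLIP) + (y - mu) / mu
        ch = _chol(G + Slam)
        beta = cho_solve(ch, X.T @ z, check_finite=False)
        eta_new = X @ beta
        mu_new = np.exp(np.clip(eta_new, -_ETA_CLIP, _ETA_CLIP))
        dev = gamma_deviance(y, mu_new)
        halvings = 0
        while beta_prev is not None and (not np.isfinite(dev) or dev > dev_prev + 1e-10) and halvings < 30:
            beta = 0.5 * (beta + beta_prev)
            eta_new = X @ beta
            dev = gamma_deviance(y, np.exp(np.clip(eta_new, -_ETA_CLIP, _ETA_CLIP)))
            halvings += 1
        eta = eta_new
        if np.isfinite(dev) and abs(dev_prev - dev) < tol * (abs(dev) + 0.1):
            converged = True
            dev_prev = dev
            break
        dev_prev = dev
        beta_prev = beta
    return beta, eta, dev_prev, converged, it, ch


class GammaGAM:
    """Gamma log-link additive model built from a daily model table.

    Parameters
    ----------
    data : DataFrame containing the response column and every predictor
        named by the formula's terms. The response must be strictly
        positive.
    formula : the response and smooth-term specification.

    Examples
    --------
    >>> formula = ModelFormula("mean_pm", (SmoothTerm(("temperature",)),))
    >>> res = GammaGAM(table, formula).fit()
    >>> res.aic  # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, formula: ModelFormula):
        y = data[formula.response].to_numpy(dtype=float)
        if np.any(~np.isfinite(y)) or np.any(y <= 0.0):
            raise ValueError("response must be strictly positive and finite")
        self.endog = y
        self.formula = formula
        self.data = data
        self.design = _Design(formula, data)
        self.exog = self.design.X
        self._G = self.exog.T @ self.exog
        self._penalties = self.design.embed_penalties()

    @classmethod
    def from_daily_table(cls, table: pd.DataFrame, response: str, terms) -> "GammaGAM":
        return cls(table, ModelFormula(response, tuple(terms)))

    @property
    def nobs(self) -> int:
        return len(self.endog)

    # -- fitting -------------------------------------------------------

    def _slam(self, lambdas: np.ndarray) -> np.ndarray:
        Slam = np.zeros_like(self._G)
        for lam, S in zip(lambdas, self._penalties):
            Slam += lam * S
        return Slam

    def _reml_score(self, rho: np.ndarray, eta_cache: list, tol: float) -> float:
        """Negative Laplace-approximate REML at log smoothing ``rho``."""
        rho = np.clip(rho, -15.0, 18.0)
        lam = np.exp(rho)
        Slam = self._slam(lam)
        beta, eta, _, _, _, ch = _pirls(
            self.exog, self.endog, self._G, Slam, eta0=eta_cache[0], tol=tol, maxiter=100
        )
        eta_cache[0] = eta
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        a = min(gamma_shape_mle(self.endog, mu), 1e8)
        ll = gamma_loglik(self.endog, mu, a)
        pen = float(beta @ Slam @ beta)
        ranks = [b.rank for b in self.design.bases]
        log_det_s = sum(
            r * (lr + np.log(a)) + b.log_det_plus
            for r, lr, b in zip(ranks, rho, self.design.bases)
        )
        log_det_h = self.design.p * np.log(a) + 2.0 * np.sum(np.log(np.diag(ch[0])))
        mp = self.design.p - sum(ranks)
        reml = ll - 0.5 * a * pen + 0.5 * log_det_s - 0.5 * log_det_h + 0.5 * mp * np.log(2 * np.pi)
        return -reml

    def fit(
        self,
        method: str = "reml",
        lambdas=None,
        tol: float = 1e-8,
        maxiter: int = 200,
        search_tol: float = 1e-6,
    ) -> "GammaGAMResults":
        """Fit the model.

        method="reml" optimizes one smoothing parameter per term by
        Nelder-Mead on the REML score; passing ``lambdas`` (sequence or
        mapping by term name) skips the search and fits at fixed smoothing.
        """
        nterms = len(self.design.bases)
        if lambdas is not None:
            if isinstance(lambdas, dict):
                lam = np.array([lambdas[b.term.name] for b in self.design.bases], dtype=float)
            else:
                lam = np.asarray(lambdas, dtype=float)
        elif method == "reml" and nterms > 0:
            x0 = np.array(
                [
                    np.log(
                        max(np.trace(self._G[sl, sl]) / max(np.trace(b.penalty), 1e-12), 1e-3)
                    )
                    for b, sl in zip(self.design.bases, self.design.slices)
                ]
            )
            cache = [None]
            res = minimize(
                self._reml_score,
                x0,
                args=(cache, search_tol),
                method="Nelder-Mead",
                options={"xatol": 0.05, "fatol": 1e-3, "maxfev": 120 * max(nterms, 1)},
            )
            lam = np.exp(np.clip(res.x, -15.0, 18.0))
        else:
            lam = np.empty(0)
        Slam = self._slam(lam)
        beta, eta, dev, converged, n_iter, ch = _pirls(
            self.exog, self.endog, self._G, Slam, tol=tol, maxiter=maxiter
        )
        if not converged:
            warnings.warn(f"PIRLS did not converge for {self.formula}", RuntimeWarning)
        F = cho_solve(ch, self._G, check_finite=False)
        edf = float(np.trace(F))
        edf_by_term = {
            b.term.name: float(np.trace(F[sl, sl]))
            for b, sl in zip(self.design.bases, self.design.slices)
        }
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        shape = gamma_shape_mle(self.endog, mu)
        ll = gamma_loglik(self.endog, mu, shape)
        null_dev = gamma_deviance(self.endog, np.full_like(self.endog, self.endog.mean()))
        return GammaGAMResults(
            model=self,
            params=beta,
            lambdas={b.term.name: float(l) for b, l in zip(self.design.bases, lam)},
            edf=edf,
            edf_by_term=edf_by_term,
            deviance=float(dev),
            null_deviance=float(null_dev),
            shape=float(shape),
            loglik=float(ll),
            converged=bool(converged),
            n_iter=int(n_iter),
        )


@dataclass
class GammaGAMResults:
    """Fitted Gamma GAM: coefficients, smoothing, and fit statistics."""

    model: GammaGAM
    params: np.ndarray
    lambdas: dict
    edf: float
    edf_by_term: dict
    deviance: float
    null_deviance: float
    shape: float
    loglik: float
    converged: bool
    n_iter: int

    @property
    def scale(self) -> float:
        """Gamma dispersion estimate (1 / shape)."""
        return 1.0 / self.shape

    @property
    def aic(self) -> float:
        """AIC with the effective degrees of freedom plus one for the
        dispersion."""
        return -2.0 * self.loglik + 2.0 * (self.edf + 1.0)

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.deviance / self.null_deviance

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.exp(np.clip(self.model.exog @ self.params, -_ETA_CLIP, _ETA_CLIP))

    def linear_predictor(self, newdata: pd.DataFrame) -> np.ndarray:
        return self.model.design.design(newdata) @ self.params

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        """Predicted mean response exp(eta) for new rows."""
        return np.exp(np.clip(self.linear_predictor(newdata), -_ETA_CLIP, _ETA_CLIP))

    def term_contribution(self, newdata: pd.DataFrame, term_name: str) -> np.ndarray:
        """One smooth term's (centred) contribution to the linear predictor
        for new rows."""
        des = self.model.design
        for b, sl in zip(des.bases, des.slices):
            if b.term.name == term_name or b.term.variables == (term_name,):
                return b.design(newdata) @ self.params[sl]
        raise ValueError(f"term {term_name!r} not in formula {self.model.formula}")

    def predict_info(self, newdata: pd.DataFrame):
        """(mean predictions, extrapolation mask) for new rows; the mask
        flags rows outside the training range of any term."""
        return self.predict(newdata), self.model.design.extrapolates(newdata)

    def summary(self) -> str:
        lines = [
            "Gamma GAM (log link)",
            f"  formula:            {self.model.formula}",
            f"  n obs:              {self.model.nobs}",
            f"  edf (total):        {self.edf:.2f}",
            f"  deviance explained: {100 * self.deviance_explained:.1f}%",
            f"  AIC:                {self.aic:.1f}",
            f"  shape (1/scale):    {self.shape:.3f}",
            f"  converged:          {self.converged}",
        ]
        if self.edf_by_term:
            lines.append("  terms:")
            for name, e in self.edf_by_term.items():
                lines.append(f"    {name:<30} edf={e:6.2f}  lambda={self.lambdas[name]:.3g}")
        return "\n".join(lines)


def fit_gamma_gam(formula: ModelFormula, data: pd.DataFrame, **kwargs) -> GammaGAMResults:
    """Convenience wrapper: build and fit a :class:`GammaGAM`."""
    return GammaGAM(data, formula).fit(**kwargs)
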