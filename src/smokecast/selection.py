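"""Exhaustive AIC model selection over the candidate predictor units.

The candidate set contains 11 units: nine single predictors and the two
U/V wind-component pairs, which always enter together as one isotropic 2-D
smooth (both components are needed to represent wind speed and direction).
All 2^11 = 2048 subset models are fitted on the training split and ranked
by AIC; the winner is compared with the full model on held-out test-set
predictions via the correlation-based R^2.

To keep the search fast, submodels reuse the smoothing parameters estimated
once by REML on the full model and a relaxed IRLS tolerance; the winning
formula is refitted from scratch (its own REML optimization, full
tolerance) before being reported or passed to the Bayesian stage.
``strategy="reml"`` instead runs the REML optimization for every candidate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve

from .basis import SmoothTerm
from .gam import (
    GammaGAM,
    GammaGAMResults,
    ModelFormula,
    _pirls,
    gamma_loglik,
    gamma_shape_mle,
    r2_correlation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CANDIDATE_UNITS",
    "make_term",
    "enumerate_models",
    "split_data",
    "select_best",
    "SelectionResult",
]

#: The 11 selectable units: unit name -> predictor variables.
CANDIDATE_UNITS: dict[str, tuple[str, ...]] = {
    "lag_pm": ("lag_pm",),
    "ventilation_index": ("ventilation_index",),
    "temperature": ("temperature",),
    "cloud": ("cloud",),
    "mslp_west": ("mslp_west",),
    "mslp_tasman": ("mslp_tasman",),
    "coastal_wind": ("u_coast_aft", "v_coast_aft"),
    "inland_wind": ("u_inland", "v_inland"),
    "fire_west": ("fire_west",),
    "fire_south": ("fire_south",),
    "fire_north": ("fire_north",),
}


def make_term(unit: str, basis_dims: tuple[int, int] = (10, 30)) -> SmoothTerm:
    """SmoothTerm for a candidate unit (1-D spline or 2-D wind smooth)."""
    variables = CANDIDATE_UNITS[unit]
    if len(variables) == 2:
        return SmoothTerm(variables, "isotropic_2d", basis_dims[1])
    return SmoothTerm(variables, "spline_1d", basis_dims[0])


def enumerate_models(
    response: str,
    units: list[str] | None = None,
    basis_dims: tuple[int, int] = (10, 30),
) -> list[ModelFormula]:
    """All subset formulas (including intercept-only) over the units, in
    deterministic bitmask order; U/V pairs are never split."""
    units = list(units) if units is not None else list(CANDIDATE_UNITS)
    terms = {u: make_term(u, basis_dims) for u in units}
    formulas = []
    for mask in itertools.product((False, True), repeat=len(units)):
        chosen = tuple(terms[u] for u, m in zip(units, mask) if m)
        formulas.append(ModelFormula(response, chosen))
    return formulas


def split_data(
    rows: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    method: str = "random",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition model rows into train and test sets.

    Random (default) draws a uniform partition without replacement with
    ``floor(train_fraction * n)`` training rows; "chronological" instead
    keeps the earliest rows for training.
    """
    if not (0.0 < train_fraction <= 1.0):
        raise ValueError("train_fraction must be in (0, 1]")
    n = len(rows)
    n_train = int(np.floor(train_fraction * n))
    if method == "random":
        perm = np.random.default_rng(seed).permutation(n)
    elif method == "chronological":
        key = "fire_day" if "fire_day" in rows.columns else rows.columns[0]
        perm = np.argsort(rows[key].to_numpy(), kind="stable")
    else:
        raise ValueError(f"unknown split method {method!r}")
    train = rows.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = rows.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return train, test


def _fast_subset_fit(full: GammaGAM, mask, lambdas_by_name: dict, tol: float):
    """Fit one subset model reusing the full model's design and smoothing."""
    des = full.design
    idx = [0]
    pens = []
    for inc, b, sl in zip(mask, des.bases, des.slices):
        if inc:
            pens.append((len(idx), b.penalty, lambdas_by_name[b.term.name]))
            idx.extend(range(sl.start, sl.stop))
    idx = np.asarray(idx)
    X = np.ascontiguousarray(full.exog[:, idx])
    G = full._G[np.ix_(idx, idx)]
    p = len(idx)
    Slam = np.zeros((p, p))
    for start, S, lam in pens:
        q = S.shape[0]
        Slam[start : start + q, start : start + q] = lam * S
    y = full.endog
    beta, eta, dev, converged, _, ch = _pirls(X, y, G, Slam, tol=tol, maxiter=100)
    edf = float(np.trace(cho_solve(ch, G, check_finite=False)))
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    shape = gamma_shape_mle(y, mu)
    aic = -2.0 * gamma_loglik(y, mu, shape) + 2.0 * (edf + 1.0)
    return aic, edf, converged


@dataclass
class SelectionResult:
    """Outcome of the all-subsets search.

    table : one row per candidate (terms, n_terms, aic, edf, converged).
    best / full : refitted results for the AIC winner and the all-predictor
        model.
    metrics : train/test correlation R^2 and deviance explained for both.
    """

    table: pd.DataFrame
    best: GammaGAMResults
    full: GammaGAMResults
    metrics: dict

    @property
    def best_formula(self) -> ModelFormula:
        return self.best.model.formula

    def summary(self) -> str:
        m = self.metrics
        return "\n".join(
            [
                f"All-subsets AIC selection over {len(self.table)} models",
                f"  best:  {self.best_formula}",
                f"         AIC={m['best']['aic']:.1f}  dev.expl={100 * m['best']['deviance_explained']:.1f}%  "
                f"R2={m['best']['r2_train']:.3f}  R2 test={m['best']['r2_test']:.3f}",
                f"  full:  AIC={m['full']['aic']:.1f}  dev.expl={100 * m['full']['deviance_explained']:.1f}%  "
                f"R2={m['full']['r2_train']:.3f}  R2 test={m['full']['r2_test']:.3f}",
            ]
        )


def select_best(
    train: pd.DataFrame,
    test: pd.DataFrame,
    response: str,
    units: list[str] | None = None,
    basis_dims: tuple[int, int] = (10, 30),
    strategy: str = "transfer",
    search_tol: float = 1e-6,
) -> SelectionResult:
    """Fit every candidate subset on ``train`` and pick the lowest AIC.

    Ties break deterministically toward fewer terms, then lexicographic
    formula text. Non-converged fits are excluded from the argmin and
    logged. The winner and the full model are refitted at full tolerance
    and scored on ``test``.
    """
    units = list(units) if units is not None else list(CANDIDATE_UNITS)
    full_formula = ModelFormula(response, tuple(make_term(u, basis_dims) for u in units))
    full_gam = GammaGAM(train, full_formula)
    full_res = full_gam.fit(method="reml", search_tol=search_tol)

    rows = []
    records = []
    masks = list(itertools.product((False, True), repeat=len(units)))
    for mask in masks:
        terms = tuple(make_term(u, basis_dims) for u, m in zip(units, mask) if m)
        formula = ModelFormula(response, terms)
        if strategy == "transfer":
            # formulas keep terms name-sorted; align the mask with the full
            # design's term order before slicing its columns
            chosen = {t.name for t in terms}
            design_mask = [b.term.name in chosen for b in full_gam.design.bases]
            aic, edf, converged = _fast_subset_fit(full_gam, design_mask, full_res.lambdas, search_tol)
        elif strategy == "reml":
            res = GammaGAM(train, formula).fit(method="reml", search_tol=search_tol, tol=search_tol)
            aic, edf, converged = res.aic, res.edf, res.converged
        else:
            raise ValueError(f"unknown selection strategy {strategy!r}")
        rows.append(
            {
                "terms": str(formula),
                "n_terms": len(terms),
                "aic": aic,
                "edf": edf,
                "converged": converged,
            }
        )
        records.append((formula, mask, aic, converged, len(terms)))

    usable = [r for r in records if r[3] and np.isfinite(r[2])]
    skipped = len(records) - len(usable)
    if skipped:
        logger.warning("%d candidate fits did not converge and were excluded", skipped)
    best_formula = min(usable, key=lambda r: (r[2], r[4], str(r[0])))[0]

    best_res = GammaGAM(train, best_formula).fit(method="reml")

    metrics = {}
    for label, res in (("best", best_res), ("full", full_res)):
        obs_test = test[response].to_numpy(dtype=float)
        metrics[label] = {
            "aic": res.aic,
            "deviance_explained": res.deviance_explained,
            "r2_train": r2_correlation(train[response].to_numpy(dtype=float), res.fittedvalues),
            "r2_test": r2_correlation(obs_test, res.predict(test)) if len(test) >= 3 else float("nan"),
        }

    table = pd.DataFrame(rows).sort_values(["aic", "n_terms", "terms"]).reset_index(drop=True)
    return SelectionResult(table=table, best=best_res, full=full_res, metrics=metrics)
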