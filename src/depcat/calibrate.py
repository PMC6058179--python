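"""Marginal maximum likelihood calibration and latent-trait estimation.

The model object / results object pair follows the statsmodels idiom:

>>> model = PolytomousIRT(responses, model="grm")     # doctest: +SKIP
>>> res = model.fit()                                 # doctest: +SKIP
>>> print(res.summary())                              # doctest: +SKIP

Estimation is Bock–Aitkin EM: the E-step accumulates expected category
counts on a fixed quadrature grid under a standard-normal latent prior;
the M-step maximizes each item's expected complete-data log-likelihood
(quasi-Newton on an unconstrained reparameterization, which enforces
``a > 0`` and ordered GRM thresholds by construction).  Models with
parameters shared across items (the common PCM/RSM slope, the RSM
category offsets) use block-coordinate M-steps, so every step still
increases the EM objective and the marginal likelihood is monotone.

Trait scores are EAP (posterior mean under the grid prior); ``eap_estimate``
also returns the posterior SD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import norm

from .bank import ItemBank, ItemMetadata, ItemParameters
from .models import (P_FLOOR, QuadratureGrid, ResponseMatrix, category_probs,
                     prob_table)

__all__ = [
    "FitResult",
    "PolytomousIRT",
    "fit_mml_em",
    "count_free_parameters",
    "information_criteria",
    "select_model",
    "eap_estimate",
    "eap_batch",
]


def count_free_parameters(model: str, n_items: int, n_categories: int) -> int:
    """Number of free item parameters estimated for a J-item, K-category test.

    GRM and GPCM estimate a slope and K-1 category parameters per item;
    PCM shares one estimated slope across items; RSM estimates a shared
    slope, per-item locations, and shared category offsets; NRM estimates
    K-1 free slopes and K-1 free intercepts per item.
    """
    J, K = n_items, n_categories
    if J < 1 or K < 2:
        raise ValueError("need n_items >= 1 and n_categories >= 2")
    model = model.upper()
    if model in ("GRM", "GPCM"):
        return J * K
    if model == "PCM":
        return J * (K - 1) + 1
    if model == "RSM":
        return J + (K - 1)
    if model == "NRM":
        return 2 * J * (K - 1)
    raise ValueError(f"unknown IRT model {model!r}")


def information_criteria(minus2ll: float, n_params: int, n_obs: int
                         ) -> tuple[float, float]:
    """(AIC, BIC) from a -2 log-likelihood."""
    aic = minus2ll + 2 * n_params
    bic = minus2ll + n_params * math.log(n_obs)
    return aic, bic


@dataclass
class FitResult:
    """Calibration results: fitted bank, fit indices, convergence trace."""

    bank: ItemBank
    model: str
    minus2ll: float
    n_params: int
    n_respondents: int
    converged: bool
    n_iter: int
    max_param_change: float
    loglik_trace: list[float] = field(default_factory=list)
    grid: QuadratureGrid | None = None

    @property
    def aic(self) -> float:
        return information_criteria(self.minus2ll, self.n_params,
                                    self.n_respondents)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self.minus2ll, self.n_params,
                                    self.n_respondents)[1]

    def params_frame(self) -> pd.DataFrame:
        from .bank import _bank_to_frame
        return _bank_to_frame(self.bank)

    def summary(self) -> str:
        head = [
            f"{self.model.upper()} marginal ML calibration"
            f" ({len(self.bank)} items, N={self.n_respondents})",
            f"  -2LL {self.minus2ll:.2f}   AIC {self.aic:.2f}"
            f"   BIC {self.bic:.2f}   (p={self.n_params})",
            f"  EM iterations {self.n_iter}"
            f" ({'converged' if self.converged else 'NOT converged'},"
            f" max |Δparam| {self.max_param_change:.2e})",
            "",
        ]
        return "\n".join(head) + self.params_frame().to_string(index=False)


# ---------------------------------------------------------------------------
# EAP scoring
# ---------------------------------------------------------------------------

def eap_estimate(pattern, items: Sequence[ItemParameters],
                 grid: QuadratureGrid) -> tuple[float, float]:
    """Posterior mean and SD of θ given one response pattern.

    ``θ̂ = Σ_q θ_q L(θ_q) A(θ_q) / Σ_q L(θ_q) A(θ_q)`` with the prior
    weights ``A`` summing to one.  An all-missing pattern returns the
    prior mean and SD.  Accumulation is in the log domain, so patterns far
    in the tails cannot underflow to zero posterior mass.
    """
    from .models import response_loglikelihood
    ll = response_loglikelihood(np.asarray(pattern, dtype=float),
                                list(items), grid.nodes)
    return _eap_from_loglik(np.asarray(ll), grid)


def _eap_from_loglik(ll: np.ndarray, grid: QuadratureGrid
                     ) -> tuple[float, float]:
    logpost = ll + np.log(grid.weights)
    logpost = logpost - logsumexp(logpost)
    post = np.exp(logpost)
    total = post.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("zero posterior mass on the grid")
    post = post / total
    mean = float(post @ grid.nodes)
    var = float(post @ (grid.nodes - mean) ** 2)
    return mean, math.sqrt(max(var, 0.0))


def eap_batch(responses: ResponseMatrix, items: Sequence[ItemParameters],
              grid: QuadratureGrid) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized EAP over all respondents; returns (theta_hat, post_sd)."""
    logtab = np.log(np.maximum(prob_table(items, grid.nodes), P_FLOOR))
    ll = _pattern_logliks(responses.data, logtab)
    logpost = ll + np.log(grid.weights)
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    means = post @ grid.nodes
    var = (post * (grid.nodes[None, :] - means[:, None]) ** 2).sum(axis=1)
    return means, np.sqrt(np.maximum(var, 0.0))


def _pattern_logliks(data: np.ndarray, logtab: np.ndarray) -> np.ndarray:
    """(N, Q) log-likelihood of each respondent at each node."""
    n, J = data.shape
    Q = logtab.shape[1]
    ll = np.zeros((n, Q))
    for j in range(J):
        col = data[:, j]
        obs = col >= 0
        if not obs.any():
            continue
        ll[obs] += logtab[j][:, col[obs]].T
    return ll


# ---------------------------------------------------------------------------
# M-step machinery: unconstrained reparameterizations per model
# ---------------------------------------------------------------------------

def _grm_pack(item: ItemParameters) -> np.ndarray:
    b = np.asarray(item.b)
    gaps = np.diff(b)
    return np.concatenate([[np.log(item.a), b[0]], np.log(gaps)])


def _grm_unpack(x: np.ndarray, item: ItemParameters) -> ItemParameters:
    a = float(np.exp(x[0]))
    b = x[1] + np.concatenate([[0.0], np.cumsum(np.exp(x[2:]))])
    return ItemParameters(item.item_id, "GRM", item.n_categories,
                          a=a, b=tuple(b))


def _gpcm_pack(item: ItemParameters) -> np.ndarray:
    return np.concatenate([[np.log(item.a)], np.asarray(item.steps)])


def _gpcm_unpack(x: np.ndarray, item: ItemParameters) -> ItemParameters:
    return ItemParameters(item.item_id, "GPCM", item.n_categories,
                          a=float(np.exp(x[0])), steps=tuple(x[1:]))


def _nrm_pack(item: ItemParameters) -> np.ndarray:
    return np.concatenate([np.asarray(item.slopes[1:]),
                           np.asarray(item.intercepts[1:])])


def _nrm_unpack(x: np.ndarray, item: ItemParameters) -> ItemParameters:
    K = item.n_categories
    return ItemParameters(item.item_id, "NRM", K,
                          slopes=(0.0, *x[:K - 1]),
                          intercepts=(0.0, *x[K - 1:]))


def _expected_loglik(item: ItemParameters, nodes: np.ndarray,
                     r: np.ndarray) -> float:
    P = np.maximum(category_probs(item, nodes), P_FLOOR)
    return float((r * np.log(P)).sum())


def _optimize_item(item: ItemParameters, nodes: np.ndarray, r: np.ndarray,
                   pack, unpack) -> ItemParameters:
    x0 = pack(item)

    def negf(x):
        return -_expected_loglik(unpack(x, item), nodes, r)

    res = minimize(negf, x0, method="L-BFGS-B",
                   options={"maxiter": 50, "ftol": 1e-10})
    return unpack(res.x, item)


# ---------------------------------------------------------------------------
# Starting values
# ---------------------------------------------------------------------------

def _start_items(responses: ResponseMatrix, model: str, K: int
                 ) -> list[ItemParameters]:
    items = []
    model = model.upper()
    for j, item_id in enumerate(responses.item_ids):
        col = responses.data[:, j]
        obs = col[col >= 0]
        cum = np.array([(obs >= k).mean() for k in range(1, K)])
        cum = np.clip(cum, 0.02, 0.98)
        b = np.sort(-norm.ppf(1.0 - cum))
        b += np.arange(K - 1) * 1e-3          # break exact ties
        if model == "GRM":
            items.append(ItemParameters(item_id, "GRM", K, a=1.0, b=tuple(b)))
        elif model == "GPCM":
            items.append(ItemParameters(item_id, "GPCM", K, a=1.0,
                                        steps=tuple(b)))
        elif model == "PCM":
            items.append(ItemParameters(item_id, "PCM", K, a=1.0,
                                        steps=tuple(b)))
        elif model == "RSM":
            items.append(ItemParameters(item_id, "RSM", K, a=1.0,
                                        location=float(b.mean()),
                                        taus=tuple(b - b.mean())))
        elif model == "NRM":
            items.append(ItemParameters(
                item_id, "NRM", K,
                slopes=tuple(0.5 * np.arange(K)),
                intercepts=tuple(np.zeros(K))))
        else:
            raise ValueError(f"unknown IRT model {model!r}")
    return items


def _canonical_vector(items: Sequence[ItemParameters]) -> np.ndarray:
    parts = []
    for it in items:
        for nm in ("a", "location"):
            v = getattr(it, nm)
            if v is not None:
                parts.append([v])
        for nm in ("b", "steps", "taus", "slopes", "intercepts"):
            v = getattr(it, nm)
            if v is not None:
                parts.append(v)
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

def fit_mml_em(responses: ResponseMatrix, model: str = "grm",
               grid: QuadratureGrid | None = None, tol: float = 1e-4,
               max_iter: int = 500,
               start: Sequence[ItemParameters] | None = None,
               min_n_warn: int = 100) -> FitResult:
    """Calibrate item parameters by Bock–Aitkin marginal ML EM.

    Convergence is declared when the largest absolute change in any item
    parameter falls below ``tol``.  Non-convergence within ``max_iter``
    flags the result rather than raising.
    """
    model = model.upper()
    N, J = responses.data.shape
    if N < min_n_warn:
        warnings.warn(f"only {N} respondents; calibration below"
                      f" N={min_n_warn} is unstable", UserWarning,
                      stacklevel=2)
    Ks = []
    for j in range(J):
        col = responses.data[:, j]
        obs = col[col >= 0]
        cats = np.unique(obs)
        if cats.size < 2:
            raise ValueError(f"item {responses.item_ids[j]} has fewer than"
                             " 2 observed categories")
        Ks.append(int(obs.max()) + 1)
    K = max(Ks)
    grid = grid or QuadratureGrid.standard_normal()
    items = list(start) if start is not None else _start_items(
        responses, model, K)

    data = responses.data
    logw = np.log(grid.weights)
    loglik_trace: list[float] = []
    max_change = np.inf
    it_count = 0

    for it_count in range(1, max_iter + 1):
        # E-step: posterior over nodes, expected category counts per item.
        tab = np.maximum(prob_table(items, grid.nodes), P_FLOOR)
        logtab = np.log(tab)
        ll = _pattern_logliks(data, logtab)              # (N, Q)
        joint = ll + logw
        marg = logsumexp(joint, axis=1)
        loglik_trace.append(float(marg.sum()))
        post = np.exp(joint - marg[:, None])             # (N, Q)

        # expected counts r_j: (Q, K)
        r_all = []
        for j in range(J):
            col = data[:, j]
            obs = col >= 0
            onehot = np.zeros((obs.sum(), K))
            onehot[np.arange(obs.sum()), col[obs]] = 1.0
            r_all.append(post[obs].T @ onehot)

        # M-step
        new_items = _m_step(model, items, grid.nodes, r_all)

        max_change = float(np.max(np.abs(
            _canonical_vector(new_items) - _canonical_vector(items))))
        items = new_items
        if max_change < tol:
            break

    # final marginal likelihood under the updated parameters
    tab = np.maximum(prob_table(items, grid.nodes), P_FLOOR)
    ll = _pattern_logliks(data, np.log(tab))
    marg = logsumexp(ll + logw, axis=1)
    loglik_trace.append(float(marg.sum()))
    minus2ll = -2.0 * loglik_trace[-1]

    bank = ItemBank(items, [ItemMetadata(item_id=i)
                            for i in responses.item_ids],
                    name=f"{model.lower()}_fit")
    converged = max_change < tol
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations"
                      f" (max |Δparam| {max_change:.2e})", UserWarning,
                      stacklevel=2)
    return FitResult(bank=bank, model=model, minus2ll=minus2ll,
                     n_params=count_free_parameters(model, J, K),
                     n_respondents=N, converged=converged, n_iter=it_count,
                     max_param_change=max_change, loglik_trace=loglik_trace,
                     grid=grid)


def _m_step(model: str, items: list[ItemParameters], nodes: np.ndarray,
            r_all: list[np.ndarray]) -> list[ItemParameters]:
    if model == "GRM":
        return [_optimize_item(it, nodes, r, _grm_pack, _grm_unpack)
                for it, r in zip(items, r_all)]
    if model == "GPCM":
        return [_optimize_item(it, nodes, r, _gpcm_pack, _gpcm_unpack)
                for it, r in zip(items, r_all)]
    if model == "NRM":
        return [_optimize_item(it, nodes, r, _nrm_pack, _nrm_unpack)
                for it, r in zip(items, r_all)]
    if model == "PCM":
        return _m_step_pcm(items, nodes, r_all)
    if model == "RSM":
        return _m_step_rsm(items, nodes, r_all)
    raise ValueError(f"unknown IRT model {model!r}")


def _m_step_pcm(items: list[ItemParameters], nodes: np.ndarray,
                r_all: list[np.ndarray]) -> list[ItemParameters]:
    # block 1: per-item steps at the current common slope
    a = items[0].a
    new_items = []
    for it, r in zip(items, r_all):
        def pack(i):
            return np.asarray(i.steps)

        def unpack(x, i, a=a):
            return ItemParameters(i.item_id, "PCM", i.n_categories, a=a,
                                  steps=tuple(x))
        new_items.append(_optimize_item(it, nodes, r, pack, unpack))

    # block 2: shared slope given the steps
    def neg_total(loga):
        a_try = float(np.exp(loga))
        total = 0.0
        for it, r in zip(new_items, r_all):
            trial = ItemParameters(it.item_id, "PCM", it.n_categories,
                                   a=a_try, steps=it.steps)
            total += _expected_loglik(trial, nodes, r)
        return -total

    res = minimize_scalar(neg_total, bounds=(np.log(0.05), np.log(20.0)),
                          method="bounded",
                          options={"xatol": 1e-6})
    a_new = float(np.exp(res.x))
    return [ItemParameters(it.item_id, "PCM", it.n_categories, a=a_new,
                           steps=it.steps) for it in new_items]


def _m_step_rsm(items: list[ItemParameters], nodes: np.ndarray,
                r_all: list[np.ndarray]) -> list[ItemParameters]:
    a = items[0].a
    taus = np.asarray(items[0].taus)

    # block 1: per-item locations
    locations = []
    for it, r in zip(items, r_all):
        def neg(loc, it=it, r=r):
            trial = ItemParameters(it.item_id, "RSM", it.n_categories, a=a,
                                   location=float(loc), taus=tuple(taus))
            return -_expected_loglik(trial, nodes, r)
        res = minimize_scalar(neg, bounds=(-8.0, 8.0), method="bounded",
                              options={"xatol": 1e-6})
        locations.append(float(res.x))

    # block 2: shared slope + category offsets (first tau fixed at its
    # centered role via mean-zero constraint on free offsets)
    def neg_shared(x):
        a_try = float(np.exp(x[0]))
        taus_try = np.concatenate([[taus[0]], x[1:]]) if len(x) > 1 else taus
        total = 0.0
        for it, loc, r in zip(items, locations, r_all):
            trial = ItemParameters(it.item_id, "RSM", it.n_categories,
                                   a=a_try, location=loc,
                                   taus=tuple(taus_try))
            total += _expected_loglik(trial, nodes, r)
        return -total

    x0 = np.concatenate([[np.log(a)], taus[1:]])
    res = minimize(neg_shared, x0, method="L-BFGS-B",
                   options={"maxiter": 50, "ftol": 1e-10})
    a_new = float(np.exp(res.x[0]))
    taus_new = np.concatenate([[taus[0]], res.x[1:]])
    return [ItemParameters(it.item_id, "RSM", it.n_categories, a=a_new,
                           location=loc, taus=tuple(taus_new))
            for it, loc in zip(items, locations)]


# ---------------------------------------------------------------------------
# Model object (statsmodels-style thin wrapper)
# ---------------------------------------------------------------------------

class PolytomousIRT:
    """Polytomous IRT model bound to a response matrix.

    Parameters
    ----------
    responses : ResponseMatrix or DataFrame
        Respondents x items integer categories (0..K-1, missing allowed).
    model : str
        One of ``grm``, ``gpcm``, ``pcm``, ``rsm``, ``nrm``.
    grid : QuadratureGrid, optional
        Latent prior grid (default: 61 nodes on [-4.5, 4.5], N(0,1)).
    """

    def __init__(self, responses, model: str = "grm",
                 grid: QuadratureGrid | None = None):
        if isinstance(responses, pd.DataFrame):
            responses = ResponseMatrix.from_dataframe(responses)
        self.responses = responses
        self.model = model.upper()
        self.grid = grid or QuadratureGrid.standard_normal()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: str = "grm",
                       **kwargs) -> "PolytomousIRT":
        return cls(ResponseMatrix.from_dataframe(df), model=model, **kwargs)

    def fit(self, tol: float = 1e-4, max_iter: int = 500,
            start: Sequence[ItemParameters] | None = None) -> FitResult:
        return fit_mml_em(self.responses, model=self.model, grid=self.grid,
                          tol=tol, max_iter=max_iter, start=start)


def select_model(fits: Sequence[FitResult]
                 ) -> tuple[list[FitResult], FitResult]:
    """Rank calibrations of the *same data* by AIC (BIC as tiebreak).

    Returns ``(ranked, chosen)`` where ``chosen`` is the best-fitting
    (smallest AIC) model.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    shapes = {(f.n_respondents, len(f.bank)) for f in fits}
    if len(shapes) > 1:
        raise ValueError(f"fits are not on identical data: shapes {shapes}")
    ranked = sorted(fits, key=lambda f: (f.aic, f.bic))
    return ranked, ranked[0]
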