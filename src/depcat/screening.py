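"""Item-bank quality screening: item fit, local dependence, DIF, dimensionality.

The screening cascade mirrors the development pipeline of a clinical item
bank: a one-factor screen of unidimensionality, Yen's Q3 check of local
independence, S-χ² item fit, a discrimination floor, and ordinal-logistic
DIF, applied in that order and iterated to a fixed point.  Each stage's
statistics and flags are kept in a :class:`ScreeningReport`, and removals
are logged to an exclusion ledger with the atomic reason labels
``CFA`` (low/nonsignificant loading), ``Q3``, ``S-X2``,
``Discrimination``, and ``DIF``.

Notes on the individual statistics
----------------------------------
- **S-χ²** is the Orlando–Thissen construction: observed versus
  model-expected category frequencies conditioned on rest-score groups
  (the rest-score distribution comes from the Lord–Wingersky recursion on
  the quadrature grid), with adjacent cells collapsed until every expected
  count reaches a minimum (default 1).
- **Q3** is the correlation, over respondents, of the residuals
  ``x_ij − E[x_ij | θ̂_i]`` for an item pair; under local independence its
  off-diagonal mean is slightly negative (≈ −1/(J−1)).
- **DIF** compares nested proportional-odds models ``item ~ θ`` and
  ``item ~ θ + group + θ×group`` (statsmodels ``OrderedModel``), flagging
  items whose McFadden pseudo-R² gain meets the configured threshold.
- The **unidimensionality screen** is a documented proxy for an external
  weighted-least-squares CFA: polychoric correlations (two-stage ML) and
  one-factor minimum-residual loadings, retaining items with loading
  > 0.3 that are significant at the 5% level (normal approximation on the
  Fisher-z scale — approximate by design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar
from scipy.stats import chi2, multivariate_normal, norm

from .bank import ItemBank
from .calibrate import eap_batch, fit_mml_em
from .models import (P_FLOOR, QuadratureGrid, ResponseMatrix, category_probs,
                     prob_table)

__all__ = [
    "item_fit_s_chi2",
    "q3_matrix",
    "dif_ordinal_logistic",
    "polychoric_corr_matrix",
    "unidimensionality_screen",
    "ScreeningConfig",
    "ScreeningReport",
    "run_screening_cascade",
]


# ---------------------------------------------------------------------------
# S-X2 item fit (Orlando–Thissen)
# ---------------------------------------------------------------------------

def _rest_score_distribution(tab: np.ndarray) -> np.ndarray:
    """Lord–Wingersky recursion: P(summed score = r | θ_q).

    ``tab`` is (J, Q, K); returns (R+1, Q) with R = J*(K-1).
    """
    J, Q, K = tab.shape
    dist = tab[0].T.copy()                       # (K, Q): scores 0..K-1
    for j in range(1, J):
        R_old = dist.shape[0]
        new = np.zeros((R_old + K - 1, Q))
        for k in range(K):
            new[k:k + R_old] += dist * tab[j, :, k][None, :]
        dist = new
    return dist


def item_fit_s_chi2(responses: ResponseMatrix, bank: ItemBank,
                    grid: QuadratureGrid | None = None,
                    alpha: float = 0.01,
                    min_expected: float = 1.0) -> pd.DataFrame:
    """S-χ² item fit for every item of a fitted bank.

    Returns a frame with columns ``item_id, statistic, df, p_value,
    misfit, testable``; ``misfit`` is True when ``p < alpha``.  Respondents
    with any missing response are excluded (rest scores undefined).
    """
    grid = grid or QuadratureGrid.standard_normal()
    complete = responses.mask.all(axis=1)
    data = responses.data[complete]
    if data.shape[0] == 0:
        raise ValueError("no complete response patterns for S-X2")
    J = data.shape[1]
    tab = prob_table(bank.items, grid.nodes)     # (J, Q, K)
    w = grid.weights
    rows = []
    n_params = {"GRM": bank.n_categories, "GPCM": bank.n_categories,
                "PCM": bank.n_categories - 1, "RSM": 1,
                "NRM": 2 * (bank.n_categories - 1)}
    for j in range(J):
        K = bank.items[j].n_categories
        rest_tab = np.delete(tab, j, axis=0)
        S = _rest_score_distribution(rest_tab)   # (R+1, Q)
        rest_scores = data.sum(axis=1) - data[:, j]
        R = S.shape[0] - 1
        # expected conditional category probabilities per rest score
        denom = S @ w                            # (R+1,)
        numer = np.einsum("rq,q,qk->rk", S, w, tab[j])
        with np.errstate(invalid="ignore", divide="ignore"):
            Econd = numer / np.maximum(denom[:, None], P_FLOOR)
        # observed counts
        O = np.zeros((R + 1, K))
        np.add.at(O, (rest_scores, data[:, j]), 1.0)
        N_r = O.sum(axis=1)

        # group adjacent rest scores so each group holds enough respondents
        groups: list[list[int]] = []
        current: list[int] = []
        current_n = 0.0
        for r in range(R + 1):
            current.append(r)
            current_n += N_r[r]
            if current_n >= K * min_expected:
                groups.append(current)
                current, current_n = [], 0.0
        if current:
            if groups:
                groups[-1].extend(current)
            else:
                groups.append(current)

        stat, total_cells, n_groups = 0.0, 0, 0
        for g in groups:
            n_g = N_r[g].sum()
            if n_g == 0:
                continue
            obs_g = O[g].sum(axis=0)
            exp_g = (N_r[g][:, None] * Econd[g]).sum(axis=0)
            # guard tiny model-side leakage
            exp_g = np.maximum(exp_g, P_FLOOR)
            exp_g *= n_g / exp_g.sum()
            # collapse adjacent category cells until expected >= min
            ob, ex = list(obs_g), list(exp_g)
            i = 0
            while i < len(ex) and len(ex) > 1:
                if ex[i] >= min_expected:
                    i += 1
                    continue
                tgt = i + 1 if i + 1 < len(ex) else i - 1
                ex[tgt] += ex[i]
                ob[tgt] += ob[i]
                del ex[i], ob[i]
                i = 0
            ob, ex = np.array(ob), np.array(ex)
            stat += float(((ob - ex) ** 2 / ex).sum())
            total_cells += len(ex)
            n_groups += 1

        df = total_cells - n_groups - n_params.get(bank.items[j].model, K)
        testable = df > 0 and n_groups > 0
        p = float(chi2.sf(stat, df)) if testable else np.nan
        rows.append({"item_id": bank.item_ids[j], "statistic": stat,
                     "df": df, "p_value": p,
                     "misfit": bool(testable and p < alpha),
                     "testable": testable})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Yen's Q3
# ---------------------------------------------------------------------------

def q3_matrix(responses: ResponseMatrix, bank: ItemBank,
              thetas: np.ndarray,
              threshold: float = 0.36) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residual correlations between item pairs (local dependence check).

    Returns ``(q3, flagged)``: the symmetric Q3 matrix (NaN diagonal, NaN
    for untestable zero-variance pairs) and a frame of pairs with
    ``Q3 > threshold``.
    """
    thetas = np.asarray(thetas, dtype=float)
    data = responses.data
    N, J = data.shape
    resid = np.full((N, J), np.nan)
    for j, item in enumerate(bank.items):
        P = category_probs(item, thetas)                       # (N, K)
        expected = P @ np.arange(item.n_categories)
        obs = data[:, j] >= 0
        resid[obs, j] = data[obs, j] - expected[obs]
    rframe = pd.DataFrame(resid, columns=bank.item_ids)
    q3 = rframe.corr(min_periods=3)
    np.fill_diagonal(q3.values, np.nan)
    pairs = []
    ids = bank.item_ids
    for i in range(J):
        for j in range(i + 1, J):
            val = q3.iloc[i, j]
            if np.isfinite(val) and val > threshold:
                pairs.append({"item_a": ids[i], "item_b": ids[j],
                              "q3": float(val)})
    return q3, pd.DataFrame(pairs, columns=["item_a", "item_b", "q3"])


# ---------------------------------------------------------------------------
# DIF by ordinal logistic regression
# ---------------------------------------------------------------------------

@dataclass
class DifResult:
    r2_change: float
    flagged: bool
    testable: bool
    loglik_null: float
    loglik_m1: float
    loglik_m3: float
    note: str = ""


def _mcfadden(llf: float, llnull: float) -> float:
    return 1.0 - llf / llnull


def dif_ordinal_logistic(item_responses, theta, group,
                         threshold: float = 0.02) -> DifResult:
    """Uniform+nonuniform DIF via nested proportional-odds models.

    Fits ``item ~ θ`` (M1) and ``item ~ θ + group + θ×group`` (M3) by ML
    and reports the change in McFadden pseudo-R² (against the
    intercept-only null).  ``group`` must be binary; both groups must be
    nonempty.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    y = np.asarray(item_responses)
    theta = np.asarray(theta, dtype=float)
    g = np.asarray(group)
    keep = (y >= 0) & np.isfinite(theta)
    y, theta, g = y[keep], theta[keep], g[keep]
    glevels = np.unique(g)
    if glevels.size != 2:
        raise ValueError("group must be binary with both groups nonempty")
    gnum = (g == glevels[1]).astype(float)
    cats, y_ranked = np.unique(y, return_inverse=True)
    if cats.size < 2:
        raise ValueError("item needs >= 2 observed categories")
    counts = np.bincount(y_ranked)
    llnull = float((counts * np.log(counts / counts.sum())).sum())
    y_cat = pd.Series(pd.Categorical(y_ranked, ordered=True))

    def _fit(X):
        model = OrderedModel(y_cat, X, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", maxiter=200, disp=False)
        if not np.isfinite(res.llf):
            raise RuntimeError("non-finite likelihood")
        return float(res.llf)

    try:
        ll1 = _fit(pd.DataFrame({"theta": theta}))
        ll3 = _fit(pd.DataFrame({"theta": theta, "group": gnum,
                                 "theta_x_group": theta * gnum}))
    except Exception as exc:  # separation / non-convergence
        return DifResult(np.nan, False, False, llnull, np.nan, np.nan,
                         note=f"not testable: {exc}")
    r2_change = _mcfadden(ll3, llnull) - _mcfadden(ll1, llnull)
    r2_change = max(r2_change, 0.0) if abs(r2_change) < 1e-12 else r2_change
    return DifResult(float(r2_change), bool(r2_change >= threshold), True,
                     llnull, ll1, ll3)


# ---------------------------------------------------------------------------
# Polychoric correlations + one-factor minres screen
# ---------------------------------------------------------------------------

def _polychoric_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Two-stage ML polychoric correlation of two ordinal variables."""
    cx, xr = np.unique(x, return_inverse=True)
    cy, yr = np.unique(y, return_inverse=True)
    if cx.size < 2 or cy.size < 2:
        return np.nan
    counts = np.zeros((cx.size, cy.size))
    np.add.at(counts, (xr, yr), 1.0)
    tx = norm.ppf(np.cumsum(counts.sum(axis=1))[:-1] / counts.sum())
    ty = norm.ppf(np.cumsum(counts.sum(axis=0))[:-1] / counts.sum())
    gx = np.concatenate([[-np.inf], tx, [np.inf]])
    gy = np.concatenate([[-np.inf], ty, [np.inf]])
    XX, YY = np.meshgrid(gx, gy, indexing="ij")
    corners = np.column_stack([XX.ravel(), YY.ravel()])
    finite = np.clip(corners, -8.5, 8.5)

    def negll(rho):
        mvn = multivariate_normal(mean=[0.0, 0.0],
                                  cov=[[1.0, rho], [rho, 1.0]])
        C = mvn.cdf(finite).reshape(gx.size, gy.size)
        C[0, :] = 0.0
        C[:, 0] = 0.0
        cell = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
        cell = np.maximum(cell, 1e-12)
        return -float((counts * np.log(cell)).sum())

    res = minimize_scalar(negll, bounds=(-0.995, 0.995), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


def polychoric_corr_matrix(responses: ResponseMatrix) -> np.ndarray:
    """Pairwise polychoric correlation matrix (unit diagonal).

    Repairs a non-positive-definite result by eigenvalue clipping, with a
    warning.
    """
    data = responses.data
    J = data.shape[1]
    R = np.eye(J)
    for i in range(J):
        for j in range(i + 1, J):
            keep = (data[:, i] >= 0) & (data[:, j] >= 0)
            R[i, j] = R[j, i] = _polychoric_pair(data[keep, i],
                                                 data[keep, j])
    if np.isnan(R).any():
        raise ValueError("polychoric matrix has untestable pairs")
    vals = np.linalg.eigvalsh(R)
    if vals.min() < 1e-8:
        warnings.warn("polychoric matrix not positive definite;"
                      " applying eigenvalue-clipping repair", UserWarning,
                      stacklevel=2)
        w, V = np.linalg.eigh(R)
        w = np.maximum(w, 1e-6)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def _minres_loadings(R: np.ndarray) -> np.ndarray:
    """One-factor minimum-residual loadings of a correlation matrix."""
    J = R.shape[0]
    w, V = np.linalg.eigh(R)
    lam0 = V[:, -1] * np.sqrt(max(w[-1], 1e-6))
    if lam0.sum() < 0:
        lam0 = -lam0
    iu = np.triu_indices(J, k=1)

    def resid(lam):
        M = np.outer(lam, lam)
        return (R - M)[iu]

    sol = least_squares(resid, lam0, method="lm")
    lam = sol.x
    return -lam if lam.sum() < 0 else lam


def unidimensionality_screen(responses: ResponseMatrix,
                             loading_threshold: float = 0.3,
                             alpha: float = 0.05) -> pd.DataFrame:
    """One-factor loading screen on the polychoric correlation matrix.

    Items are retained when the loading exceeds the threshold *and* is
    significant at ``alpha`` (normal approximation on the Fisher-z scale,
    an explicitly approximate stand-in for a full CFA test).
    """
    if responses.n_items < 2:
        raise ValueError("need at least 2 items")
    N = int(responses.mask.all(axis=1).sum())
    R = polychoric_corr_matrix(responses)
    lam = np.clip(_minres_loadings(R), -0.9999, 0.9999)
    zcrit = norm.ppf(1.0 - alpha / 2.0)
    se_scale = 1.0 / np.sqrt(max(N - 3, 1))
    significant = np.abs(np.arctanh(lam)) / se_scale > zcrit
    retained = (lam > loading_threshold) & significant
    return pd.DataFrame({
        "item_id": responses.item_ids,
        "loading": lam,
        "significant": significant,
        "retained": retained,
    })


# ---------------------------------------------------------------------------
# The screening cascade
# ---------------------------------------------------------------------------

@dataclass
class ScreeningConfig:
    """Thresholds of the sequential screen (field defaults are the
    published operating rules)."""

    loading_threshold: float = 0.3
    loading_alpha: float = 0.05
    q3_threshold: float = 0.36
    sx2_alpha: float = 0.01
    min_discrimination: float = 0.8
    dif_r2_threshold: float = 0.02
    model: str = "GRM"
    max_passes: int = 10
    em_tol: float = 1e-4
    em_max_iter: int = 500


@dataclass
class ScreeningReport:
    """Everything the cascade measured, plus the exclusion ledger."""

    ledger: pd.DataFrame
    surviving_bank: ItemBank
    thetas: np.ndarray
    unidimensionality: pd.DataFrame | None = None
    q3: pd.DataFrame | None = None
    item_fit: pd.DataFrame | None = None
    dif: pd.DataFrame | None = None
    n_passes: int = 0
    stages_run: list[str] = field(default_factory=list)


def run_screening_cascade(responses: ResponseMatrix,
                          config: ScreeningConfig | None = None,
                          groups: dict[str, np.ndarray] | None = None,
                          grid: QuadratureGrid | None = None
                          ) -> ScreeningReport:
    """Apply the sequential item screen until a fixed point.

    Stages per pass: unidimensionality -> Q3 local dependence -> S-χ² item
    fit -> discrimination floor -> DIF (for each grouping variable in
    ``groups``).  When a Q3 pair is flagged, the member with the lower
    discrimination is dropped.  Raises when every item is removed.
    """
    config = config or ScreeningConfig()
    grid = grid or QuadratureGrid.standard_normal()
    current = responses
    ledger_rows: list[dict] = []
    report = ScreeningReport(ledger=pd.DataFrame(), surviving_bank=None,
                             thetas=np.array([]))

    def drop(ids: list[str], reason: str):
        nonlocal current
        for item_id in ids:
            ledger_rows.append({"item_id": item_id, "reason": reason})
        keep = [i for i, iid in enumerate(current.item_ids)
                if iid not in set(ids)]
        if not keep:
            raise ValueError("empty bank: screening removed every item")
        current = ResponseMatrix(current.data[:, keep],
                                 respondent_ids=current.respondent_ids,
                                 item_ids=[current.item_ids[i] for i in keep])

    fit = None
    for n_pass in range(1, config.max_passes + 1):
        removed_any = False

        # 1. unidimensionality
        uni = unidimensionality_screen(current, config.loading_threshold,
                                       config.loading_alpha)
        report.unidimensionality = uni
        bad = uni.loc[~uni["retained"], "item_id"].tolist()
        if bad:
            drop(bad, "CFA")
            removed_any = True
        report.stages_run.append(f"pass{n_pass}:CFA")

        # calibration for the residual-based stages
        fit = fit_mml_em(current, config.model, grid=grid,
                         tol=config.em_tol, max_iter=config.em_max_iter)
        thetas, _ = eap_batch(current, fit.bank.items, grid)

        # 2. Q3 local dependence: drop the weaker member of each flagged
        # pair, re-checking after each removal.
        while True:
            q3, flagged = q3_matrix(current, fit.bank, thetas,
                                    config.q3_threshold)
            report.q3 = q3
            if flagged.empty:
                break
            worst = flagged.sort_values("q3", ascending=False).iloc[0]
            a_a = fit.bank.items[fit.bank.index_of(worst["item_a"])].a or 0
            a_b = fit.bank.items[fit.bank.index_of(worst["item_b"])].a or 0
            victim = worst["item_a"] if a_a <= a_b else worst["item_b"]
            drop([victim], "Q3")
            removed_any = True
            fit.bank = fit.bank.subset(current.item_ids)
            thetas, _ = eap_batch(current, fit.bank.items, grid)
        report.stages_run.append(f"pass{n_pass}:Q3")

        # 3. S-X2 item fit (refit after any removal above)
        if removed_any:
            fit = fit_mml_em(current, config.model, grid=grid,
                             tol=config.em_tol,
                             max_iter=config.em_max_iter)
        sx2 = item_fit_s_chi2(current, fit.bank, grid,
                              alpha=config.sx2_alpha)
        report.item_fit = sx2
        bad = sx2.loc[sx2["misfit"], "item_id"].tolist()
        if bad:
            drop(bad, "S-X2")
            removed_any = True
            fit = fit_mml_em(current, config.model, grid=grid,
                             tol=config.em_tol,
                             max_iter=config.em_max_iter)
        report.stages_run.append(f"pass{n_pass}:S-X2")

        # 4. discrimination floor
        low = [it.item_id for it in fit.bank.items
               if it.a is not None and it.a <= config.min_discrimination]
        if low:
            drop(low, "Discrimination")
            removed_any = True
            fit = fit_mml_em(current, config.model, grid=grid,
                             tol=config.em_tol,
                             max_iter=config.em_max_iter)
        report.stages_run.append(f"pass{n_pass}:Discrimination")

        # 5. DIF per grouping variable
        if groups:
            thetas, _ = eap_batch(current, fit.bank.items, grid)
            dif_rows = []
            flagged_ids = []
            for gname, glabels in groups.items():
                glabels = np.asarray(glabels)
                for j, item_id in enumerate(current.item_ids):
                    res = dif_ordinal_logistic(current.data[:, j], thetas,
                                               glabels,
                                               config.dif_r2_threshold)
                    dif_rows.append({"item_id": item_id, "group": gname,
                                     "r2_change": res.r2_change,
                                     "flagged": res.flagged,
                                     "testable": res.testable,
                                     "note": res.note})
                    if res.flagged:
                        flagged_ids.append(item_id)
            report.dif = pd.DataFrame(dif_rows)
            if flagged_ids:
                drop(sorted(set(flagged_ids)), "DIF")
                removed_any = True
                fit = fit_mml_em(current, config.model, grid=grid,
                                 tol=config.em_tol,
                                 max_iter=config.em_max_iter)
            report.stages_run.append(f"pass{n_pass}:DIF")

        report.n_passes = n_pass
        if not removed_any:
            break

    thetas, _ = eap_batch(current, fit.bank.items, grid)
    # ordered atomic reasons per removed item
    ledger = pd.DataFrame(ledger_rows, columns=["item_id", "reason"])
    ledger = (ledger.groupby("item_id", sort=False)["reason"]
              .apply(lambda s: "+".join(s)).reset_index()
              .rename(columns={"reason": "exclusion_reasons"}))
    report.ledger = ledger
    report.surviving_bank = fit.bank
    report.thetas = thetas
    return report
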