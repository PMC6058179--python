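"""Category probabilities, information, SE, and reliability for polytomous IRT.

Five models are supported, all on the pure-logistic metric (no 1.7
scaling constant):

- **GRM** (graded response): ordered categories as differences of cumulative
  two-parameter logistic curves, ``P*_k(θ) = logistic(a(θ - b_k))``.
- **GPCM / PCM / RSM** (divide-by-total family): adjacent-category logits
  ``P_k ∝ exp(Σ_{v≤k} a(θ - d_v))``, with per-item slopes (GPCM), a common
  slope (PCM), or a common slope plus item location + shared category
  offsets (RSM, ``d_v = location + τ_v``).
- **NRM** (nominal response): multinomial logits ``P_k ∝ exp(a_k θ + c_k)``
  with the first category's slope and intercept fixed at zero.

Fisher information of an item is ``I_j(θ) = Σ_k P'_k(θ)² / P_k(θ)`` with
analytic derivatives; the test-level standard error is ``1/sqrt(Σ_j I_j)``
and reliability is ``1 - 1/I`` on a latent scale fixed to mean 0, SD 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .bank import ItemBank, ItemParameters

#: floor applied inside log/derivative ratios against vanishing categories
P_FLOOR = 1e-10

__all__ = [
    "QuadratureGrid",
    "ResponseMatrix",
    "category_probs",
    "category_prob_derivs",
    "item_information",
    "test_information",
    "se_from_information",
    "reliability_from_information",
    "response_loglikelihood",
    "prob_table",
]


@dataclass(frozen=True)
class QuadratureGrid:
    """Latent-trait quadrature nodes with normalized prior weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.shape != weights.shape:
            raise ValueError("nodes and weights must be equal-length vectors")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        total = weights.sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            weights = weights / total
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return self.nodes.size

    @classmethod
    def standard_normal(cls, n_nodes: int = 61, bound: float = 4.5
                        ) -> "QuadratureGrid":
        """Equally spaced nodes on [-bound, bound], N(0,1) prior weights."""
        nodes = np.linspace(-bound, bound, n_nodes)
        w = norm.pdf(nodes)
        return cls(nodes, w / w.sum())


class ResponseMatrix:
    """Respondents x items integer category matrix with a missing mask.

    Categories are coded 0..K-1; missing entries are -1 internally.  The
    CSV convention (shared with calibration and the CAT engine) is one row
    per respondent, one column per item, blank cells for missing.
    """

    def __init__(self, data: np.ndarray,
                 respondent_ids: Sequence[str] | None = None,
                 item_ids: Sequence[str] | None = None):
        data = np.asarray(data)
        if data.ndim != 2:
            raise ValueError("response data must be 2-D")
        arr = np.where(np.isnan(data.astype(float)), -1, data).astype(int) \
            if data.dtype.kind == "f" else data.astype(int)
        self.data = arr
        n, j = arr.shape
        self.respondent_ids = (list(map(str, respondent_ids))
                               if respondent_ids is not None
                               else [f"r{i + 1}" for i in range(n)])
        self.item_ids = (list(map(str, item_ids)) if item_ids is not None
                         else [f"item{i + 1}" for i in range(j)])
        if len(self.respondent_ids) != n or len(self.item_ids) != j:
            raise ValueError("id lengths inconsistent with data shape")

    @property
    def n_respondents(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a response was observed."""
        return self.data >= 0

    def validate_against(self, bank: ItemBank) -> None:
        for j, item in enumerate(bank.items):
            col = self.data[:, j]
            obs = col[col >= 0]
            if obs.size and obs.max() >= item.n_categories:
                raise ValueError(
                    f"item {bank.item_ids[j]}: category {obs.max()} out of"
                    f" range for K={item.n_categories}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       category_offset: int = 0) -> "ResponseMatrix":
        arr = df.to_numpy(dtype=float)
        arr = np.where(np.isnan(arr), -1 + category_offset, arr)
        data = arr.astype(int) - category_offset
        return cls(data, respondent_ids=[str(i) for i in df.index],
                   item_ids=[str(c) for c in df.columns])

    @classmethod
    def from_csv(cls, path: str | Path,
                 category_offset: int = 0) -> "ResponseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls.from_dataframe(df, category_offset=category_offset)

    def to_dataframe(self) -> pd.DataFrame:
        vals = self.data.astype(float)
        vals[self.data < 0] = np.nan
        return pd.DataFrame(vals, index=self.respondent_ids,
                            columns=self.item_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, float_format="%g")


# ---------------------------------------------------------------------------
# Category probabilities and derivatives
# ---------------------------------------------------------------------------

def _grm_cumulative(item: ItemParameters, theta: np.ndarray) -> np.ndarray:
    """P(score >= k) for k = 1..K-1, shape theta.shape + (K-1,)."""
    b = np.asarray(item.b, dtype=float)
    return expit(item.a * (theta[..., None] - b))


def _adjacent_steps(item: ItemParameters) -> np.ndarray:
    if item.model == "RSM":
        return item.location + np.asarray(item.taus, dtype=float)
    return np.asarray(item.steps, dtype=float)


def category_probs(item: ItemParameters, theta) -> np.ndarray:
    """Probability of each of the K categories at trait value(s) theta.

    Returns an array of shape ``theta.shape + (K,)`` whose last axis sums
    to one.
    """
    theta = np.asarray(theta, dtype=float)
    K = item.n_categories
    if item.model == "GRM":
        cum = _grm_cumulative(item, theta)
        full = np.concatenate(
            [np.ones(theta.shape + (1,)), cum, np.zeros(theta.shape + (1,))],
            axis=-1)
        return full[..., :-1] - full[..., 1:]
    if item.model in ("GPCM", "PCM", "RSM"):
        d = _adjacent_steps(item)
        terms = item.a * (theta[..., None] - d)           # (.., K-1)
        logits = np.concatenate(
            [np.zeros(theta.shape + (1,)), np.cumsum(terms, axis=-1)],
            axis=-1)
    elif item.model == "NRM":
        slopes = np.asarray(item.slopes, dtype=float)
        intercepts = np.asarray(item.intercepts, dtype=float)
        logits = slopes * theta[..., None] + intercepts
    else:
        raise ValueError(f"unknown IRT model {item.model!r}")
    logits = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=-1, keepdims=True)


def category_prob_derivs(item: ItemParameters, theta
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(P, dP/dθ)``, each of shape ``theta.shape + (K,)``."""
    theta = np.asarray(theta, dtype=float)
    P = category_probs(item, theta)
    if item.model == "GRM":
        cum = _grm_cumulative(item, theta)
        dcum = item.a * cum * (1.0 - cum)
        full = np.concatenate(
            [np.zeros(theta.shape + (1,)), dcum, np.zeros(theta.shape + (1,))],
            axis=-1)
        dP = full[..., :-1] - full[..., 1:]
    elif item.model in ("GPCM", "PCM", "RSM"):
        scores = np.arange(item.n_categories, dtype=float)
        mean_score = (P * scores).sum(axis=-1, keepdims=True)
        dP = item.a * P * (scores - mean_score)
    elif item.model == "NRM":
        slopes = np.asarray(item.slopes, dtype=float)
        mean_slope = (P * slopes).sum(axis=-1, keepdims=True)
        dP = P * (slopes - mean_slope)
    else:
        raise ValueError(f"unknown IRT model {item.model!r}")
    return P, dP


def item_information(item: ItemParameters, theta) -> np.ndarray | float:
    """Fisher information ``Σ_k P'_k(θ)² / P_k(θ)`` of one item."""
    P, dP = category_prob_derivs(item, theta)
    info = (dP ** 2 / np.maximum(P, P_FLOOR)).sum(axis=-1)
    return float(info) if info.ndim == 0 else info


def test_information(bank: ItemBank, administered: Sequence[str] | None,
                     theta) -> np.ndarray | float:
    """Sum of item information over a subset of the bank (0 for empty)."""
    theta = np.asarray(theta, dtype=float)
    if administered is None:
        items = bank.items
    else:
        ids = set(administered)
        unknown = ids - set(bank.item_ids)
        if unknown:
            raise KeyError(f"items not in bank: {sorted(unknown)}")
        items = [it for it in bank.items if it.item_id in ids]
    total = np.zeros(theta.shape)
    for it in items:
        total = total + item_information(it, theta)
    return float(total) if total.ndim == 0 else total


def se_from_information(information) -> np.ndarray | float:
    """SE(θ) = 1/sqrt(I); undefined (raises) for nonpositive information."""
    info = np.asarray(information, dtype=float)
    if np.any(info <= 0):
        raise ValueError("SE undefined for nonpositive test information")
    se = 1.0 / np.sqrt(info)
    return float(se) if se.ndim == 0 else se


def reliability_from_information(information) -> np.ndarray | float:
    """IRT reliability ``r = 1 - 1/I`` (trait scale mean 0, SD 1).

    Values of ``I`` below 1 yield a *negative* reliability; the value is
    reported as-is with a RuntimeWarning, never clipped silently.
    """
    info = np.asarray(information, dtype=float)
    if np.any(info <= 0):
        raise ValueError("reliability undefined for nonpositive information")
    if np.any(info < 1):
        warnings.warn("test information below 1: reliability is negative",
                      RuntimeWarning, stacklevel=2)
    r = 1.0 - 1.0 / info
    return float(r) if r.ndim == 0 else r


def response_loglikelihood(pattern, items: Sequence[ItemParameters],
                           theta) -> np.ndarray | float:
    """Log-likelihood of one response pattern at trait value(s) theta.

    ``pattern`` holds integer categories aligned with ``items``; entries
    coded -1 (or NaN) are missing and contribute nothing.
    """
    pattern = np.asarray(pattern, dtype=float)
    if pattern.ndim != 1 or len(pattern) != len(items):
        raise ValueError("pattern must align with the item list")
    theta = np.asarray(theta, dtype=float)
    ll = np.zeros(theta.shape)
    for x, item in zip(pattern, items):
        if np.isnan(x) or x < 0:
            continue
        x = int(x)
        if x >= item.n_categories:
            raise ValueError(f"category {x} out of range for item"
                             f" {item.item_id} (K={item.n_categories})")
        P = category_probs(item, theta)
        ll = ll + np.log(np.maximum(P[..., x], P_FLOOR))
    return float(ll) if ll.ndim == 0 else ll


def prob_table(items: Sequence[ItemParameters], nodes: np.ndarray
               ) -> np.ndarray:
    """Stack category probabilities at the grid nodes: shape (J, Q, K).

    Assumes a common K across items (the in-bank invariant).
    """
    return np.stack([category_probs(it, nodes) for it in items])
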