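"""Aggregate CAT characteristics, criterion validity, and screening utility.

Three families of summaries, mirroring how adaptive screening instruments
are reported:

- **CAT characteristics** per stopping rule: mean/SD of items used, mean
  final SE, marginal reliability (mean over respondents of ``1 - 1/I`` at
  the final θ̂), and the Pearson correlation of the adaptive θ̂ with the
  full-bank estimate.
- **Criterion validity**: Pearson correlation of θ̂ with a continuous
  criterion score, with a 95% CI from the variance-stabilizing arctanh
  transform.
- **Predictive utility**: ROC AUC (rank / Mann-Whitney formulation with
  tie correction, Hanley–McNeil CI), and the cutoff maximizing the Youden
  index ``YI = Se + Sp - 1``.  Higher θ̂ means more severe and is the
  positive direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .cat import CatTrace

__all__ = [
    "CatCharacteristics",
    "RocResult",
    "summarize_cat_batch",
    "criterion_validity",
    "roc_auc",
    "youden_optimal_cutoff",
]


@dataclass(frozen=True)
class CatCharacteristics:
    """One row of a stopping-rule comparison table."""

    stopping_rule: str
    n_respondents: int
    mean_items_used: float
    sd_items_used: float
    mean_se: float
    marginal_reliability: float
    r_with_full_bank: float | None

    def as_dict(self) -> dict:
        return {
            "stopping_rule": self.stopping_rule,
            "n": self.n_respondents,
            "items_mean": self.mean_items_used,
            "items_sd": self.sd_items_used,
            "mean_se": self.mean_se,
            "marginal_reliability": self.marginal_reliability,
            "r": self.r_with_full_bank,
        }


def summarize_cat_batch(traces: Sequence[CatTrace],
                        full_bank_thetas: np.ndarray | None = None,
                        label: str = "") -> CatCharacteristics:
    """Aggregate a batch of traces into one characteristics row.

    Marginal reliability averages the per-respondent ``1 - 1/I`` with
    ``I`` the administered-item information at the final θ̂ (equivalently
    ``1 - SE²`` from the information-based SE).  The correlation with the
    full-bank θ̂ needs at least two aligned respondents, else it is
    reported as None.
    """
    ok = [t for t in traces if t.n_administered > 0]
    if not ok:
        raise ValueError("no scorable traces")
    n_items = np.array([t.n_administered for t in ok], dtype=float)
    ses = np.array([t.final_se for t in ok], dtype=float)
    thetas = np.array([t.final_theta for t in ok], dtype=float)
    reliability = 1.0 - ses ** 2                 # 1 - 1/I
    r = None
    if full_bank_thetas is not None:
        full = np.asarray(full_bank_thetas, dtype=float)
        if len(full) != len(traces):
            raise ValueError("full-bank estimates not aligned with traces")
        full = np.array([f for f, t in zip(full, traces)
                         if t.n_administered > 0])
        if len(full) >= 2 and np.std(full) > 0 and np.std(thetas) > 0:
            r = float(np.corrcoef(thetas, full)[0, 1])
    return CatCharacteristics(
        stopping_rule=label,
        n_respondents=len(ok),
        mean_items_used=float(n_items.mean()),
        sd_items_used=float(n_items.std(ddof=0)),
        mean_se=float(ses.mean()),
        marginal_reliability=float(reliability.mean()),
        r_with_full_bank=r,
    )


def criterion_validity(theta_hats, criterion_scores,
                       conf_level: float = 0.95
                       ) -> tuple[float, tuple[float, float]]:
    """Pearson correlation with an arctanh (Fisher-z) confidence interval."""
    x = np.asarray(theta_hats, dtype=float)
    y = np.asarray(criterion_scores, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r = float(np.corrcoef(x, y)[0, 1])
    if 1.0 - abs(r) < 1e-12:                       # degenerate: exact line
        r = 1.0 if r > 0 else -1.0
        return r, (r, r)
    z = math.atanh(r)
    half = norm.ppf(0.5 + conf_level / 2.0) / math.sqrt(x.size - 3)
    return r, (math.tanh(z - half), math.tanh(z + half))


@dataclass(frozen=True)
class RocResult:
    """ROC summary for θ̂ as a screener of a binary diagnosis."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    utility_band: str

    def as_dict(self) -> dict:
        return {"auc": self.auc, "auc_ci": list(self.auc_ci),
                "cutoff": self.cutoff, "se": self.sensitivity,
                "sp": self.specificity, "yi": self.youden,
                "band": self.utility_band}


def _utility_band(auc: float) -> str:
    if auc >= 0.9:
        return "high"
    if auc >= 0.7:
        return "moderate"
    return "small"


def roc_auc(scores, labels, conf_level: float = 0.95) -> RocResult:
    """AUC by the rank (Mann–Whitney) formulation with tie correction.

    The CI uses the Hanley–McNeil standard error.  Higher scores indicate
    the positive class.  The attached cutoff/Se/Sp/YI come from
    :func:`youden_optimal_cutoff`.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)                     # midranks handle ties
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
           + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    half = norm.ppf(0.5 + conf_level / 2.0) * math.sqrt(max(var, 0.0))
    cutoff, se, sp, yi = youden_optimal_cutoff(scores, labels)
    return RocResult(auc=float(auc),
                     auc_ci=(max(0.0, auc - half), min(1.0, auc + half)),
                     cutoff=cutoff, sensitivity=se, specificity=sp,
                     youden=yi, utility_band=_utility_band(float(auc)))


def youden_optimal_cutoff(scores, labels
                          ) -> tuple[float, float, float, float]:
    """Cutoff maximizing ``YI = Se + Sp - 1``; returns (cutoff, Se, Sp, YI).

    Candidates are midpoints between adjacent distinct scores (plus open
    ends); the rule classifies ``score >= cutoff`` as positive.  Exact YI
    ties break toward the higher sensitivity (lower cutoff).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = None
    for c in cands:
        pos = scores >= c
        se = float((pos & (labels == 1)).sum() / n1)
        sp = float((~pos & (labels == 0)).sum() / n0)
        yi = se + sp - 1.0
        # strict > keeps the earlier (lower-cutoff, higher-Se) candidate
        # only when YI ties; scan order is ascending cutoff
        if best is None or yi > best[3] + 1e-15:
            best = (float(c), se, sp, yi)
    return best
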