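"""Computerized adaptive testing engine: MFI selection, EAP updates, SE stop.

The engine replays a CAT against a calibrated bank in two modes:

- **post-hoc**: each simulated administration reads the respondent's
  *actual* recorded response to the selected item, so the CAT is a
  counterfactual shortening of a full paper-and-pencil administration;
- **generative**: responses are drawn from the item response model at a
  supplied true θ.

One session loop: select an item (random first item by default, maximum
Fisher information thereafter), observe the response, re-estimate θ by EAP
over the administered items, compute the information-based standard error
``SE = 1/sqrt(Σ_j I_j(θ̂))``, and stop once SE falls to the configured
threshold, the bank is exhausted, or the item cap is reached.  θ̂ is
re-estimated after every single administered item and stopping is checked
immediately after each update (no minimum test length).

Determinism: a single master seed; each respondent's stream is derived
from the master seed and a stable hash of the respondent id, so a batch
equals a loop of single sessions and is invariant to respondent order.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .bank import ItemBank
from .calibrate import _eap_from_loglik
from .models import (P_FLOOR, QuadratureGrid, ResponseMatrix,
                     category_probs, item_information, prob_table)

__all__ = [
    "CatConfig",
    "CatTrace",
    "CatSimulator",
    "select_first_item",
    "select_next_item_mfi",
    "should_stop",
    "run_cat_session",
    "run_cat_batch",
]


@dataclass(frozen=True)
class CatConfig:
    """Tunable knobs of one CAT run.

    ``stopping_se=None`` means no precision stop (administer until the
    bank, or ``max_items``, is exhausted).  ``first_item_rule`` is
    ``"random"``, ``"max_info_at_0"``, or a fixed item id.
    """

    stopping_se: float | None = 0.2
    max_items: int | None = None
    selection_rule: str = "MFI"
    first_item_rule: str = "random"
    n_nodes: int = 61
    grid_bound: float = 4.5
    seed: int = 0
    #: stop on the EAP posterior SD instead of the information-based SE
    use_posterior_sd: bool = False

    def __post_init__(self):
        if self.stopping_se is not None and self.stopping_se <= 0:
            raise ValueError("stopping_se must be positive or None")
        if self.max_items is not None and self.max_items < 1:
            raise ValueError("max_items must be >= 1")
        if self.selection_rule != "MFI":
            raise ValueError("only MFI selection is implemented")

    def make_grid(self) -> QuadratureGrid:
        return QuadratureGrid.standard_normal(self.n_nodes, self.grid_bound)


@dataclass
class CatTrace:
    """Per-respondent record of one adaptive session."""

    respondent_id: str
    item_ids: list[str] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    thetas: list[float] = field(default_factory=list)
    ses: list[float] = field(default_factory=list)
    stop_reason: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def n_administered(self) -> int:
        return len(self.item_ids)

    @property
    def final_theta(self) -> float:
        return self.thetas[-1]

    @property
    def final_se(self) -> float:
        return self.ses[-1]


def _respondent_rng(seed: int, respondent_id: str) -> np.random.Generator:
    key = zlib.crc32(str(respondent_id).encode("utf8"))
    return np.random.default_rng([seed, key])


def select_first_item(bank: ItemBank, rng: np.random.Generator,
                      rule: str = "random") -> str:
    """Choose the opening item (uniformly at random by default)."""
    if len(bank) == 0:
        raise ValueError("empty bank")
    if rule == "random":
        return bank.item_ids[int(rng.integers(len(bank)))]
    if rule == "max_info_at_0":
        infos = np.array([item_information(it, 0.0) for it in bank.items])
        return bank.item_ids[int(np.argmax(infos))]
    if rule in bank.item_ids:
        return rule
    raise ValueError(f"unknown first-item rule {rule!r}")


def select_next_item_mfi(bank: ItemBank, administered, theta_hat: float
                         ) -> str:
    """Unadministered item with maximum Fisher information at θ̂.

    Exact information ties break toward the lower bank index
    (deterministic).
    """
    admin = set(administered)
    best_idx, best_info = -1, -np.inf
    for idx, item in enumerate(bank.items):
        if item.item_id in admin:
            continue
        info = item_information(item, theta_hat)
        if info > best_info:
            best_idx, best_info = idx, info
    if best_idx < 0:
        raise ValueError("all items administered")
    return bank.item_ids[best_idx]


def should_stop(trace: CatTrace, config: CatConfig, bank: ItemBank,
                ineligible: set[str] | None = None) -> tuple[bool, str]:
    """Evaluate the stopping rule after the latest θ̂/SE update."""
    if trace.n_administered < 1:
        raise ValueError("stopping undefined before the first item")
    if (config.stopping_se is not None
            and trace.final_se <= config.stopping_se):
        return True, "se_met"
    unavailable = set(trace.item_ids) | (ineligible or set())
    if len(unavailable) >= len(bank):
        return True, "bank_exhausted"
    if config.max_items is not None and \
            trace.n_administered >= config.max_items:
        return True, "max_items"
    return False, ""


class CatSimulator:
    """CAT engine bound to one bank and config (precomputes grid tables)."""

    def __init__(self, bank: ItemBank, config: CatConfig | None = None):
        self.bank = bank
        self.config = config or CatConfig()
        self.grid = self.config.make_grid()
        self._logtab = np.log(np.maximum(
            prob_table(bank.items, self.grid.nodes), P_FLOOR))
        self._index = {iid: j for j, iid in enumerate(bank.item_ids)}

    # -- internal scoring -------------------------------------------------
    def _rescore(self, admin_idx: list[int], responses: list[int]
                 ) -> tuple[float, float, float]:
        """EAP θ̂, posterior SD, and information-based SE.

        The log-likelihood is re-summed in canonical bank order so a
        full-bank session reproduces the one-shot full-bank EAP exactly.
        """
        order = np.argsort(admin_idx)
        ll = np.zeros(len(self.grid))
        for pos in order:
            j = admin_idx[pos]
            ll = ll + self._logtab[j][:, responses[pos]]
        theta, post_sd = _eap_from_loglik(ll, self.grid)
        info = 0.0
        for j in admin_idx:
            info += item_information(self.bank.items[j], theta)
        se = 1.0 / np.sqrt(info) if info > 0 else np.inf
        return theta, post_sd, se

    # -- session ----------------------------------------------------------
    def run_session(self, responses=None, respondent_id: str = "r1",
                    rng: np.random.Generator | None = None,
                    true_theta: float | None = None) -> CatTrace:
        """Run one adaptive session.

        ``responses`` is the respondent's complete category vector aligned
        with the bank (post-hoc mode; -1/NaN marks missing, which makes
        the item ineligible with a trace flag).  In generative mode pass
        ``responses=None`` with a ``true_theta``; responses are drawn from
        the model.
        """
        cfg = self.config
        rng = rng or _respondent_rng(cfg.seed, respondent_id)
        posthoc = responses is not None
        if posthoc:
            responses = np.asarray(responses, dtype=float)
            if responses.shape != (len(self.bank),):
                raise ValueError("responses must align with the bank")
        elif true_theta is None:
            raise ValueError("generative mode needs true_theta")

        trace = CatTrace(respondent_id=str(respondent_id))
        ineligible: set[str] = set()
        admin_idx: list[int] = []

        def draw_response(j: int) -> int | None:
            if posthoc:
                val = responses[j]
                if np.isnan(val) or val < 0:
                    return None
                return int(val)
            P = category_probs(self.bank.items[j], float(true_theta))
            return int((P.cumsum() < rng.random()).sum())

        first = select_first_item(self.bank, rng, cfg.first_item_rule)
        next_id = first
        while True:
            j = self._index[next_id]
            x = draw_response(j)
            if x is None:
                ineligible.add(next_id)
                trace.flags.append(f"missing_response:{next_id}")
                if len(ineligible) + len(admin_idx) >= len(self.bank):
                    trace.stop_reason = "bank_exhausted"
                    break
                theta_ref = trace.thetas[-1] if trace.thetas else 0.0
                next_id = select_next_item_mfi(
                    self.bank, set(trace.item_ids) | ineligible, theta_ref)
                continue
            admin_idx.append(j)
            trace.item_ids.append(next_id)
            trace.responses.append(x)
            theta, post_sd, se = self._rescore(admin_idx, trace.responses)
            trace.thetas.append(theta)
            trace.ses.append(post_sd if cfg.use_posterior_sd else se)
            stop, reason = should_stop(trace, cfg, self.bank, ineligible)
            if stop:
                trace.stop_reason = reason
                break
            next_id = select_next_item_mfi(
                self.bank, set(trace.item_ids) | ineligible, theta)
        if not trace.thetas:
            warnings.warn(f"respondent {respondent_id}: no scorable"
                          " responses", UserWarning, stacklevel=2)
        return trace

    def run_batch(self, responses: ResponseMatrix) -> list[CatTrace]:
        """One independent session per respondent of a response matrix.

        Per-respondent RNG streams are derived from the master seed and
        the respondent id, so the batch equals looped single sessions and
        is invariant to row order.
        """
        responses.validate_against(self.bank)
        traces = []
        for i, rid in enumerate(responses.respondent_ids):
            rng = _respondent_rng(self.config.seed, rid)
            try:
                tr = self.run_session(responses.data[i], respondent_id=rid,
                                      rng=rng)
            except Exception as exc:       # keep the batch alive
                tr = CatTrace(respondent_id=rid, stop_reason="error",
                              flags=[f"error:{exc}"])
            traces.append(tr)
        return traces


def run_cat_session(responses, bank: ItemBank,
                    config: CatConfig | None = None, **kwargs) -> CatTrace:
    """Functional wrapper: one session of :class:`CatSimulator`."""
    return CatSimulator(bank, config).run_session(responses, **kwargs)


def run_cat_batch(responses: ResponseMatrix, bank: ItemBank,
                  config: CatConfig | None = None) -> list[CatTrace]:
    """Functional wrapper: one batch of :class:`CatSimulator`."""
    return CatSimulator(bank, config).run_batch(responses)
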