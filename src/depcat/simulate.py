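"""Synthetic respondents, responses, and criterion measures.

The generator reproduces the statistical structure the downstream
analyses assume, so the whole toolchain is testable without participant
data:

- latent depression severities θ from a normal mixture (default: one
  standard-normal component, matching the scale on which IRT reliability
  is defined; a "study-like" preset mixes 81% healthy / 19% patient
  components and re-standardizes to overall mean 0, SD 1);
- item responses drawn from the bank's response model at each θ;
- criterion questionnaire scores built to a target correlation ρ with θ
  (``score = ρ·z(θ) + sqrt(1-ρ²)·noise``, affinely mapped to a 0–60
  integer scale by default — CES-D-like, the range is cosmetic), with
  binary diagnosis labels either by mixture component or by thresholding
  a noisy latent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bank import ItemBank
from .models import ResponseMatrix, category_probs

__all__ = [
    "PopulationSpec",
    "CriterionSpec",
    "simulate_thetas",
    "simulate_responses",
    "simulate_criterion",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Latent-trait population: a seeded normal mixture."""

    n_respondents: int = 1000
    #: (label, proportion, mean, sd) per component
    components: tuple[tuple[str, float, float, float], ...] = (
        ("population", 1.0, 0.0, 1.0),)
    standardize: bool = False
    seed: int = 0

    def __post_init__(self):
        props = [c[1] for c in self.components]
        if not np.isclose(sum(props), 1.0):
            raise ValueError(f"component proportions sum to {sum(props)}")
        if any(c[3] <= 0 for c in self.components):
            raise ValueError("component SDs must be positive")

    @classmethod
    def study_like(cls, n_respondents: int = 1135, separation: float = 2.0,
                   seed: int = 0) -> "PopulationSpec":
        """Mixed healthy/patient population (81%/19%), patient mean above
        the healthy mean by ``separation`` SD, re-standardized overall."""
        return cls(n_respondents=n_respondents,
                   components=(("healthy", 0.81, 0.0, 1.0),
                               ("patient", 0.19, separation, 1.0)),
                   standardize=True, seed=seed)


def simulate_thetas(spec: PopulationSpec
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (thetas, component_labels) from the mixture."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_respondents
    if n == 0:
        return np.array([]), np.array([], dtype=object)
    labels_pool = [c[0] for c in spec.components]
    props = np.array([c[1] for c in spec.components])
    idx = rng.choice(len(labels_pool), size=n, p=props)
    means = np.array([c[2] for c in spec.components])[idx]
    sds = np.array([c[3] for c in spec.components])[idx]
    thetas = rng.normal(means, sds)
    if spec.standardize and n > 1:
        thetas = (thetas - thetas.mean()) / thetas.std(ddof=0)
    return thetas, np.array([labels_pool[i] for i in idx], dtype=object)


def simulate_responses(bank: ItemBank, thetas, seed: int = 0
                       ) -> ResponseMatrix:
    """Draw one response per item per respondent from the bank's model."""
    thetas = np.asarray(thetas, dtype=float)
    rng = np.random.default_rng(seed)
    n, J = thetas.size, len(bank)
    data = np.zeros((n, J), dtype=int)
    for j, item in enumerate(bank.items):
        P = category_probs(item, thetas)                  # (n, K)
        u = rng.random(n)
        data[:, j] = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return ResponseMatrix(data, item_ids=bank.item_ids)


@dataclass(frozen=True)
class CriterionSpec:
    """Criterion questionnaire emulator: correlation with θ + diagnosis rule.

    ``diagnosis`` is either ``("component", positive_label)`` — labels come
    from the population mixture — or ``("threshold", z)`` — positive when
    a noisy latent (the same one behind the score) exceeds ``z``.
    """

    rho: float = 0.9
    score_range: tuple[float, float] = (0.0, 60.0)
    discretize: bool = True
    diagnosis: tuple[str, object] = ("threshold", 1.0)

    def __post_init__(self):
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")


def simulate_criterion(thetas, spec: CriterionSpec | None = None,
                       seed: int = 0,
                       component_labels=None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Generate (continuous scores, binary labels) correlated with θ."""
    spec = spec or CriterionSpec()
    thetas = np.asarray(thetas, dtype=float)
    rng = np.random.default_rng(seed)
    n = thetas.size
    z = (thetas - thetas.mean()) / thetas.std(ddof=0) if n > 1 else thetas
    noise = rng.normal(size=n)
    latent = spec.rho * z + np.sqrt(1.0 - spec.rho ** 2) * noise
    lo, hi = spec.score_range
    # map latent (≈ N(0,1)) onto the score range, clipping 3-sigma tails
    scores = lo + (hi - lo) * np.clip((latent + 3.0) / 6.0, 0.0, 1.0)
    if spec.discretize:
        scores = np.rint(scores)
    rule, arg = spec.diagnosis
    if rule == "component":
        if component_labels is None:
            raise ValueError("component diagnosis rule needs labels")
        labels = (np.asarray(component_labels) == arg).astype(int)
    elif rule == "threshold":
        labels = (latent >= float(arg)).astype(int)
    else:
        raise ValueError(f"unknown diagnosis rule {rule!r}")
    return scores, labels
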