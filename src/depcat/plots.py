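"""Basic diagnostic plots: test information and reliability curves."""

from __future__ import annotations

import numpy as np

from .bank import ItemBank
from .models import test_information


def plot_test_information(bank: ItemBank, theta_range=(-4.0, 4.0),
                          n_points: int = 201, ax=None):
    """Test information of the full bank across the trait range."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    theta = np.linspace(*theta_range, n_points)
    info = test_information(bank, None, theta)
    ax.plot(theta, info)
    ax.set_xlabel(r"$\theta$")
    ax.set_ylabel("test information")
    ax.set_title(f"{bank.name}: {len(bank)} items")
    return ax


def plot_reliability(bank: ItemBank, theta_range=(-4.0, 4.0),
                     n_points: int = 201, ax=None):
    """IRT reliability 1 - 1/I(θ) of the full bank (clipped below at 0
    for display only)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    theta = np.linspace(*theta_range, n_points)
    info = np.asarray(test_information(bank, None, theta))
    rel = 1.0 - 1.0 / np.maximum(info, 1e-9)
    ax.plot(theta, np.clip(rel, 0.0, 1.0))
    ax.set_xlabel(r"$\theta$")
    ax.set_ylabel("reliability $1 - 1/I(\\theta)$")
    ax.set_ylim(0, 1)
    return ax
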