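"""Optional diagnostic figures: prediction overlays, attention, agreement."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import bland_altman
from .morphology import CLASS_NAMES

_CLASS_COLORS = {0: "tab:red", 1: "tab:green", 2: "tab:blue", 3: "0.6"}


def plot_prediction(true_values, pred_values, pred_classes, fs: float = 125.0, ax=None):
    """Overlay a predicted pulse (colored by cardiac-cycle class) on the truth."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 3))
    t_true = np.arange(len(true_values)) / fs
    ax.plot(t_true, true_values, "k-", lw=1.5, label="average pulse")
    t_pred = np.arange(len(pred_values)) / fs
    pred_classes = np.asarray(pred_classes)
    for c, color in _CLASS_COLORS.items():
        m = pred_classes == c
        if m.any():
            ax.plot(t_pred[m], np.asarray(pred_values)[m], ".", ms=4, color=color,
                    label=CLASS_NAMES[c])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pressure (mmHg)")
    ax.legend(fontsize=7)
    return ax


def plot_attention_map(attention, ax=None):
    """Decoder-step x input-step attention heat map for one prediction."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 3))
    ax.imshow(np.asarray(attention), aspect="auto", origin="lower",
              interpolation="nearest", cmap="viridis")
    ax.set_xlabel("input step")
    ax.set_ylabel("output step")
    return ax


def plot_bland_altman(truth, pred, ax=None):
    """Difference-vs-mean agreement plot with the 1.96-sigma limits."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(4, 4))
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    mu, (lo, hi) = bland_altman(truth, pred)
    ax.scatter((truth + pred) / 2, pred - truth, s=12, alpha=0.6)
    for y, style in ((mu, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="tab:red", ls=style, lw=1)
    ax.set_xlabel("mean (mmHg)")
    ax.set_ylabel("difference (mmHg)")
    return ax
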