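"""Thin plotting layer over the numeric analysis outputs (matplotlib)."""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_singular_spectrum(result, top=None, ax=None, log10=True):
    """Bar plot of the largest singular values (normalised to the first)."""
    ax = _axes(ax)
    sig = result.singular_values[:top]
    vals = sig / sig[0] if sig[0] > 0 else sig
    if log10:
        vals = np.log10(np.maximum(vals, 1e-300))
        ax.set_ylabel(r"$\log_{10}(\sigma_i/\sigma_1)$")
    else:
        ax.set_ylabel(r"$\sigma_i/\sigma_1$")
    ax.bar(np.arange(1, len(sig) + 1), vals)
    ax.set_xlabel("singular value index")
    return ax


def plot_irc(curves, ax=None):
    """Line plot of infinitesimal response curves over one cycle."""
    ax = _axes(ax)
    for c in curves:
        ax.plot(c.phi, c.values, label=c.parameter)
    ax.set_xlabel("phase (time units)")
    ax.set_ylabel("IRC value")
    ax.legend(fontsize="small")
    return ax


def plot_heatmap(fields, ax=None):
    """Render heat-map fields (a DataFrame from heatmap_fields) as an image."""
    ax = _axes(ax)
    arr = fields.to_numpy().T
    im = ax.imshow(arr, aspect="auto", origin="lower",
                   extent=(fields.index[0], fields.index[-1], -0.5,
                           arr.shape[0] - 0.5))
    ax.set_yticks(range(arr.shape[0]), labels=list(fields.columns))
    ax.set_xlabel("time")
    ax.figure.colorbar(im, ax=ax)
    return ax
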