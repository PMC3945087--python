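"""Figure export: filter mosaics, amplitude-spectrum panels, trade-off curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .evaluation import TradeoffCurve, amplitude_spectrum

__all__ = ["filter_mosaic", "spectrum_mosaic", "tradeoff_figure"]


def _frame(filt: np.ndarray, side: int) -> np.ndarray:
    return np.asarray(filt).reshape(side, side, order="F")


def filter_mosaic(
    pixel_filters: np.ndarray,
    side: int,
    path: str | Path | None = None,
    n_cols: int = 12,
    title: str | None = None,
):
    """Grid of pixel-space filters, subspace pairs adjacent, slowest first."""
    n = pixel_filters.shape[0]
    n_rows = int(np.ceil(n / n_cols))
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(n_cols * 0.8, n_rows * 0.8))
    axes = np.atleast_2d(axes)
    vmax = np.abs(pixel_filters).max()
    for j, ax in enumerate(axes.ravel()):
        ax.axis("off")
        if j < n:
            ax.imshow(_frame(pixel_filters[j], side), cmap="gray", vmin=-vmax, vmax=vmax)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def spectrum_mosaic(
    pixel_filters: np.ndarray,
    side: int,
    path: str | Path | None = None,
    n_cols: int = 12,
):
    """Grid of DC-centered amplitude spectra of the filters."""
    n = pixel_filters.shape[0]
    n_rows = int(np.ceil(n / n_cols))
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(n_cols * 0.8, n_rows * 0.8))
    axes = np.atleast_2d(axes)
    for j, ax in enumerate(axes.ravel()):
        ax.axis("off")
        if j < n:
            ax.imshow(amplitude_spectrum(pixel_filters[j], side), cmap="viridis")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def tradeoff_figure(curve: TradeoffCurve, path: str | Path | None = None):
    """Slowness and sparsity performance (percent of maximal gain) vs gamma."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.gammas, curve.perf_slow, "o-", color="tab:blue", label="slowness")
    ax.plot(curve.gammas, curve.perf_sparse, "s-", color="tab:red", label="sparseness")
    if curve.break_even_gamma is not None:
        ax.axvline(curve.break_even_gamma, ls="--", color="gray", lw=1)
    ax.set_xlabel(r"trade-off weight $\gamma$")
    ax.set_ylabel("performance [% of maximal gain]")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
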