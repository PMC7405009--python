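"""Mean-centred principal component analysis for qualitative exploration.

PCA here is the plain SVD of the centred data matrix: scores = U*S,
loadings = columns of V, explained-variance ratios from the squared
singular values.  The sign of each component is fixed so that its
largest-magnitude loading element is positive, making results exactly
reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # variables x components
    explained_variance_ratio: np.ndarray
    component_count: int


def mean_center(X) -> np.ndarray:
    """Subtract each column's mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("need at least one row")
    return X - X.mean(axis=0)


def pca(X_centered, n_components: int) -> PCAResult:
    """SVD-based PCA of an already-centred matrix."""
    X = np.atleast_2d(np.asarray(X_centered, dtype=float))
    n, p = X.shape
    limit = min(n - 1, p)
    if not 1 <= n_components <= limit:
        raise ValueError(
            f"n_components must be in [1, {limit}] for a {n}x{p} matrix"
        )
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|.| element of each loading vector positive
    signs = np.array([np.sign(v[np.argmax(np.abs(v))]) or 1.0 for v in vt])
    u, vt = u * signs, vt * signs[:, None]
    total_var = float((s**2).sum())
    k = n_components
    return PCAResult(
        scores=u[:, :k] * s[:k],
        loadings=vt[:k].T,
        explained_variance_ratio=(s[:k] ** 2) / total_var if total_var else np.zeros(k),
        component_count=k,
    )


def score_plane(result: PCAResult, cx: int, cy: int, labels,
                plot_path=None, csv_path=None):
    """Scatter two score components (1-based indices), coloured by label.

    Writes an image to ``plot_path`` and/or the coordinates to ``csv_path``;
    returns the coordinate table.
    """
    k = result.component_count
    for c in (cx, cy):
        if not 1 <= c <= k:
            raise ValueError(f"component {c} out of range 1..{k}")
    labels = np.asarray(labels)
    if labels.size != result.scores.shape[0]:
        raise ValueError("one label per sample is required")
    table = pd.DataFrame(
        {
            f"PC{cx}": result.scores[:, cx - 1],
            f"PC{cy}": result.scores[:, cy - 1],
            "label": labels,
        }
    )
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if plot_path is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for lab in pd.unique(labels):
            sub = table[table["label"] == lab]
            ax.scatter(sub[f"PC{cx}"], sub[f"PC{cy}"], label=str(lab), s=18)
        evr = result.explained_variance_ratio
        ax.set_xlabel(f"PC{cx} ({100 * evr[cx - 1]:.1f}%)")
        ax.set_ylabel(f"PC{cy} ({100 * evr[cy - 1]:.1f}%)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return table
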