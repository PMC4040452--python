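"""Standardized pairwise correlation analysis with Ward-ordered heat maps.

Biotic (TCC, %LNA) and abiotic (T, DO, EC, pH) channels are z-scored over
the analysis subset, then all parameter pairs are correlated with Pearson's
r (linear association) and Spearman's rho (monotone association) on
pairwise-complete observations. Two-sided p-values come from the
t-statistic t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom; no
multiple-testing correction is applied by default (raw pairwise
significance at the 95% level), but a Holm adjustment is available.

For display, parameters are reordered by agglomerative Ward clustering on
the dissimilarity d = 1 - r — the common heat-map practice, an
approximation since d is not Euclidean — with a deterministic dendrogram
traversal (smaller-height subtree first, alphabetical tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

MIN_PAIRS = 3


class DegenerateParameterError(ValueError):
    """Raised when a parameter has zero variance over the analysis subset."""


@dataclass
class CorrelationResult:
    """Symmetric PCC/SCC matrices with p-values, linkage and leaf order."""

    parameters: list[str]
    pcc: pd.DataFrame
    scc: pd.DataFrame
    p_pcc: pd.DataFrame
    p_scc: pd.DataFrame
    n_used: pd.DataFrame
    linkage: np.ndarray  # scipy linkage matrix on d = 1 - pcc
    leaf_order: list[str]


def standardize(table: pd.DataFrame, parameters: Sequence[str] | None = None) -> pd.DataFrame:
    """z-score each parameter over its non-missing values (missing kept)."""
    if parameters is None:
        parameters = list(table.columns)
    out = {}
    for p in parameters:
        col = table[p]
        if col.count() < 2:
            raise DegenerateParameterError(f"parameter {p!r} has < 2 values")
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateParameterError(f"parameter {p!r} has zero variance")
        out[p] = (col - col.mean()) / sd
    return pd.DataFrame(out, index=table.index)


def _pairwise(
    table: pd.DataFrame, method: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    params = list(table.columns)
    k = len(params)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)  # by convention
    for i in range(k):
        n[i, i] = table[params[i]].count()
        for j in range(i + 1, k):
            pair = table[[params[i], params[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < MIN_PAIRS:
                continue  # entry stays missing, count records why
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if method == "pearson":
                res = stats.pearsonr(x, y)
            else:
                res = stats.spearmanr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(params)
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(n, index=idx, columns=idx),
    )


def pearson_pairwise(table: pd.DataFrame):
    """Pairwise-complete Pearson r with two-sided t-based p-values."""
    return _pairwise(table, "pearson")


def spearman_pairwise(table: pd.DataFrame):
    """Pairwise-complete Spearman rho (mid-ranks for ties) with p-values."""
    return _pairwise(table, "spearman")


def holm_adjust(p: pd.DataFrame) -> pd.DataFrame:
    """Holm step-down adjustment over the upper triangle (optional)."""
    k = len(p)
    iu = np.triu_indices(k, 1)
    raw = p.to_numpy()[iu]
    order = np.argsort(raw)
    adj = np.empty_like(raw)
    running = 0.0
    m = len(raw)
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * raw[idx])
        adj[idx] = min(1.0, running)
    out = np.zeros((k, k))
    out[iu] = adj
    out += out.T
    return pd.DataFrame(out, index=p.index, columns=p.columns)


def _leaf_order(linkage: np.ndarray, labels: Sequence[str]) -> list[str]:
    """Dendrogram traversal: smaller-height subtree first, then alphabetical."""
    n = len(labels)

    def height(node: int) -> float:
        return 0.0 if node < n else float(linkage[node - n, 2])

    def first_label(node: int) -> str:
        return leaves(node)[0]

    def leaves(node: int) -> list[str]:
        if node < n:
            return [labels[node]]
        a, b = int(linkage[node - n, 0]), int(linkage[node - n, 1])
        ka, kb = (height(a), first_label(a)), (height(b), first_label(b))
        return leaves(a) + leaves(b) if ka <= kb else leaves(b) + leaves(a)

    return leaves(2 * n - 2) if n > 1 else list(labels)


def ward_cluster(pcc: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Ward linkage on d = 1 - r, plus the deterministic leaf order."""
    mat = pcc.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    if np.isnan(mat).any():
        raise ValueError("correlation matrix has missing entries")
    d = 1.0 - mat
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    labels = list(pcc.columns)
    if len(labels) < 2:
        return np.empty((0, 4)), labels
    linkage = hierarchy.linkage(squareform(d, checks=False), method="ward")
    return linkage, _leaf_order(linkage, labels)


def correlation_analysis(table: pd.DataFrame) -> CorrelationResult:
    """Full chain: standardize, both coefficient matrices, Ward ordering."""
    z = standardize(table)
    pcc, p_pcc, n_used = pearson_pairwise(z)
    scc, p_scc, _ = spearman_pairwise(z)
    linkage, leaf_order = ward_cluster(pcc)
    return CorrelationResult(
        parameters=list(table.columns),
        pcc=pcc,
        scc=scc,
        p_pcc=p_pcc,
        p_scc=p_scc,
        n_used=n_used,
        linkage=linkage,
        leaf_order=leaf_order,
    )


def export_heatmap(result: CorrelationResult, path: str | Path) -> dict[str, Path]:
    """Write the Ward-reordered PCC matrix as CSV and a diverging heat map.

    Positive correlations render green, inverse correlations red, on a
    [-1, 1] color key. Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    path = Path(path)
    order = result.leaf_order
    mat = result.pcc.loc[order, order]
    csv_path = path.with_suffix(".csv")
    mat.to_csv(csv_path)

    cmap = LinearSegmentedColormap.from_list(
        "red_green", ["#a50026", "#ffffff", "#006837"]
    )
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(order), 0.8 + 0.6 * len(order)))
    im = ax.imshow(mat.to_numpy(), cmap=cmap, vmin=-1, vmax=1)
    ax.set_xticks(range(len(order)), order, rotation=45, ha="right")
    ax.set_yticks(range(len(order)), order)
    for i in range(len(order)):
        for j in range(len(order)):
            ax.text(j, i, f"{mat.iloc[i, j]:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig_path = path.with_suffix(".png")
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    return {"csv": csv_path, "figure": fig_path}
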