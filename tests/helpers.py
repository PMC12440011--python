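"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: component
labeling by explicit BFS flood fill, ANOVA by direct sum-of-squares
arithmetic, QC filtering by a per-cell python loop.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS flood-fill labeling; labels 1..K in raster order of first pixels."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    labels = np.zeros((h, w), dtype=np.int32)
    current = 0
    for y in range(h):
        for x in range(w):
            if mask[y, x] and labels[y, x] == 0:
                current += 1
                queue = deque([(y, x)])
                labels[y, x] = current
                while queue:
                    cy, cx = queue.popleft()
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and labels[ny, nx] == 0:
                            labels[ny, nx] = current
                            queue.append((ny, nx))
    return labels


def anova_by_hand(groups: dict[str, np.ndarray]) -> tuple[float, int, int]:
    """F statistic and dfs by direct sum-of-squares arithmetic."""
    xs = [np.asarray(v, dtype=float) for v in groups.values()]
    all_x = np.concatenate(xs)
    grand = all_x.mean()
    ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in xs)
    ssw = sum(((x - x.mean()) ** 2).sum() for x in xs)
    k, n = len(xs), len(all_x)
    return (ssb / (k - 1)) / (ssw / (n - k)), k - 1, n - k


def qc_by_hand(X, gene_names, max_umi, max_genes, max_mito, max_ribo) -> np.ndarray:
    """Per-cell loop applying the four strict QC rules."""
    import scipy.sparse as sp

    dense = X.toarray() if sp.issparse(X) else np.asarray(X)
    kept = []
    for row in dense:
        total = row.sum()
        detected = (row > 0).sum()
        mito = sum(c for c, g in zip(row, gene_names) if g.startswith("MT-"))
        ribo = sum(c for c, g in zip(row, gene_names) if g.startswith(("RPS", "RPL")))
        mito_frac = mito / total if total else 0.0
        ribo_frac = ribo / total if total else 0.0
        kept.append(
            total < max_umi
            and detected < max_genes
            and mito_frac < max_mito
            and ribo_frac < max_ribo
        )
    return np.array(kept)
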