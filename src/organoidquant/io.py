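"""Reading and writing the pipeline's on-disk formats.

Multi-channel images travel as TIFF with one page per channel per
z-slice and the channel name (plus z index) in each page description;
a sidecar channel map can override the descriptions for foreign TIFF
dialects.  Tables are CSV/TSV, count matrices are MatrixMarket with
gene/barcode label files, and ground truth / reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio, sparse

from .types import GroundTruth, MultiChannelImage

__all__ = [
    "write_multichannel_tiff",
    "read_multichannel_tiff",
    "write_truth",
    "write_de_table",
    "read_de_table",
    "write_count_matrix",
    "read_count_matrix",
]


def write_multichannel_tiff(path: str | Path, image: MultiChannelImage) -> None:
    """One page per channel per z-slice; page description ``channel;z=i``."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tw:
        for ch in image.channel_names:
            arr = image.channels[ch]
            planes = arr[None] if arr.ndim == 2 else arr
            for z, plane in enumerate(planes):
                tw.write(
                    plane.astype(np.float32),
                    description=f"{ch};z={z}",
                    contiguous=False,
                )


def read_multichannel_tiff(
    path: str | Path, channel_map: Sequence[str] | None = None
) -> MultiChannelImage:
    """Read a page-per-channel TIFF back into a :class:`MultiChannelImage`.

    Channel names come from each page's description (``name;z=i``); for
    TIFFs without descriptions, ``channel_map`` supplies one name per
    page in order (repeated names are stacked along z).
    """
    by_channel: dict[str, list[np.ndarray]] = {}
    with tifffile.TiffFile(str(path)) as tf:
        for i, page in enumerate(tf.pages):
            desc = page.description or ""
            if channel_map is not None:
                name = channel_map[i]
            elif ";z=" in desc:
                name = desc.split(";z=")[0]
            elif desc:
                name = desc
            else:
                raise ValueError(
                    f"page {i} of {path} has no channel description; pass channel_map"
                )
            by_channel.setdefault(name, []).append(page.asarray())
    channels = {
        name: planes[0] if len(planes) == 1 else np.stack(planes)
        for name, planes in by_channel.items()
    }
    return MultiChannelImage(channels=channels)


def write_truth(path: str | Path, truth: GroundTruth, masks_path: str | Path | None = None) -> None:
    """Ground truth as JSON; boolean masks optionally as a separate TIFF."""
    payload: dict = {}
    if truth.intact_fraction is not None:
        payload["intact_fraction"] = truth.intact_fraction
    if truth.n_organoids is not None:
        payload["n_organoids"] = truth.n_organoids
    if truth.detached_counts is not None:
        payload["detached_counts"] = truth.detached_counts
    if truth.counts_by_day is not None:
        payload["counts_by_day"] = {str(k): v for k, v in truth.counts_by_day.items()}
    if truth.organoid_centroids is not None:
        payload["organoid_centroids"] = [list(c) for c in truth.organoid_centroids]
    if truth.concordant_fraction is not None:
        payload["n_overlap"] = truth.n_overlap
        payload["n_concordant"] = truth.n_concordant
        payload["concordant_fraction"] = truth.concordant_fraction
    if truth.kept_cells is not None:
        payload["kept_cells"] = np.asarray(truth.kept_cells).astype(int).tolist()
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
    if masks_path is not None and truth.intact_masks is not None:
        with tifffile.TiffWriter(Path(masks_path)) as tw:
            for ch in sorted(truth.intact_masks):
                tw.write(truth.intact_masks[ch].astype(np.uint8), description=f"{ch};intact")
                tw.write(truth.detached_masks[ch].astype(np.uint8), description=f"{ch};detached")


def write_de_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_de_table(
    path: str | Path,
    gene_col: str = "gene",
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {gene_col, lfc_col, padj_col} - set(df.columns)
    if missing:
        raise ValueError(f"DE table {path} lacks columns {sorted(missing)}")
    return df.rename(columns={gene_col: "gene", lfc_col: "log2fc", padj_col: "padj"})


def write_count_matrix(
    out_dir: str | Path,
    matrix: sparse.spmatrix,
    gene_names: Sequence[str],
    barcodes: Sequence[str],
) -> None:
    """MatrixMarket (genes x cells, 10x-style orientation) + label TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "matrix.mtx"), sparse.csc_matrix(matrix.T))
    (out / "genes.tsv").write_text("\n".join(gene_names) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(barcodes) + "\n")


def read_count_matrix(in_dir: str | Path) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Read the MatrixMarket trio back as cells-by-genes."""
    in_dir = Path(in_dir)
    mat = spio.mmread(str(in_dir / "matrix.mtx")).T.tocsr()
    genes = (in_dir / "genes.tsv").read_text().strip().split("\n")
    barcodes = (in_dir / "barcodes.tsv").read_text().strip().split("\n")
    return mat, genes, barcodes
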