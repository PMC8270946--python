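"""Delimited-text readers and writers for every pipeline artefact.

Interchange formats are deliberately plain TSV: a region x time matrix
(optional header row of TR indices, optional first column of region
labels) and a two-column (tr_index, stage) label track. Embeddings,
graphs and group tables are written as tidy TSV tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    STAGE_VOCABULARY,
    UNSCORED,
    ManifoldEmbedding,
    ParcellatedTimeseries,
    StageLabels,
)
from .manifold import StateGraph


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def read_timeseries(path: str | Path, tr_seconds: float) -> ParcellatedTimeseries:
    """Read a region x time TSV matrix.

    Accepts an optional header row (TR indices) and an optional first
    column of region labels; both are auto-detected from the first cell
    of each. Ragged rows and non-numeric cells raise with row/column
    coordinates.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip():
                rows.append(line.split("\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    header = None
    if len(widths) == 2 and not _is_float(rows[0][0]):
        # header row may be one shorter than data rows with region labels
        header, rows = rows[0], rows[1:]
        widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    has_row_labels = not _is_float(rows[0][0])
    region_ids = None
    if has_row_labels:
        region_ids = [r[0] for r in rows]
        rows = [r[1:] for r in rows]
    data = np.empty((len(rows), len(rows[0])))
    for i, r in enumerate(rows):
        for j, cell in enumerate(r):
            if not _is_float(cell):
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {i}, column {j}"
                )
            data[i, j] = float(cell)
    if tr_seconds is None or tr_seconds <= 0:
        raise ValueError(f"{path}: a positive tr_seconds must be supplied")
    return ParcellatedTimeseries(
        data=data, tr_seconds=tr_seconds, region_ids=region_ids
    )


def write_timeseries(
    path: str | Path, ts: ParcellatedTimeseries, labels_in_first_column: bool = True
) -> None:
    with open(path, "w") as fh:
        for i in range(ts.n_regions):
            cells = [f"{v:.12g}" for v in ts.data[i]]
            if labels_in_first_column:
                cells = [ts.region_ids[i]] + cells
            fh.write("\t".join(cells) + "\n")


def read_labels(
    path: str | Path,
    n_trs: int | None = None,
    vocabulary: tuple[str, ...] = STAGE_VOCABULARY,
    subject_id: str = "subject_0",
) -> StageLabels:
    """Read a (tr_index, stage) TSV track into a dense per-TR label array.

    Rows may arrive in any order. TR indices absent from the file are
    marked unscored (and later excluded from decoding). Duplicate TR
    indices and stage tokens outside the vocabulary raise.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {df.shape[1]}")
    if not _is_float(df.iloc[0, 0]):  # tolerate a header row
        df = df.iloc[1:]
    tr_idx = df.iloc[:, 0].astype(int).to_numpy()
    stages = df.iloc[:, 1].str.strip().to_numpy()
    dup = pd.Series(tr_idx).duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate tr_index {tr_idx[dup.argmax()]}")
    bad = [s for s in np.unique(stages) if s not in vocabulary]
    if bad:
        raise ValueError(f"{path}: unknown stage token(s) {bad}")
    if np.any(tr_idx < 0):
        raise ValueError(f"{path}: negative tr_index")
    length = n_trs if n_trs is not None else int(tr_idx.max()) + 1
    if np.any(tr_idx >= length):
        raise ValueError(f"{path}: tr_index beyond series length {length}")
    labels = np.full(length, UNSCORED, dtype=object)
    labels[tr_idx] = stages
    return StageLabels(labels=labels, subject_id=subject_id)


def write_labels(path: str | Path, labels: StageLabels) -> None:
    with open(path, "w") as fh:
        fh.write("tr_index\tstage\n")
        for t, lab in enumerate(labels.labels):
            if lab != UNSCORED:
                fh.write(f"{t}\t{lab}\n")


def write_embedding(
    path: str | Path,
    embedding: ManifoldEmbedding,
    labels: StageLabels | None = None,
) -> None:
    """Write a (tr_index, dim_1..dim_d[, stage]) TSV table."""
    d = embedding.dim
    cols = {"tr_index": np.arange(embedding.n_trs)}
    for k in range(d):
        cols[f"dim_{k + 1}"] = embedding.coords[:, k]
    if labels is not None:
        cols["stage"] = labels.labels
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_embedding(path: str | Path) -> tuple[ManifoldEmbedding, StageLabels | None]:
    df = pd.read_csv(path, sep="\t")
    dim_cols = [c for c in df.columns if c.startswith("dim_")]
    coords = df[dim_cols].to_numpy(dtype=float)
    emb = ManifoldEmbedding(
        coords=coords,
        eigenvalues=np.full(len(dim_cols), np.nan),
        method="unknown",
    )
    labels = None
    if "stage" in df.columns:
        labels = StageLabels(labels=df["stage"].fillna(UNSCORED).to_numpy(dtype=object))
    return emb, labels


def write_edges(path: str | Path, graph: StateGraph) -> None:
    """Edge list as (i, j, weight) triples, MST edges first."""
    e = graph.edges
    w = graph.edge_weights()
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for (i, j), weight in zip(e, w):
            fh.write(f"{i}\t{j}\t{weight:.12g}\n")


def write_group_embedding(
    path: str | Path,
    embeddings: list[ManifoldEmbedding],
    labels_list: list[StageLabels],
) -> None:
    frames = []
    for emb, labels in zip(embeddings, labels_list):
        cols = {
            "subject_id": np.repeat(labels.subject_id, emb.n_trs),
            "tr_index": np.arange(emb.n_trs),
        }
        for k in range(emb.dim):
            cols[f"dim_{k + 1}"] = emb.coords[:, k]
        cols["stage"] = labels.labels
        frames.append(pd.DataFrame(cols))
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )
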