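"""Readers and writers for the pipeline's standard text formats.

Count tables travel as TSV (taxa rows, sample columns, first row =
timestamps in days) or BIOM 1.0 JSON; panels as long-format CSV
(label, time, value); distance matrices as labeled square CSV; spectra
as one CSV per series plus a JSON parameter header; dendrograms as
Newick with branch lengths derived from merge heights.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

import dendropy

from .clustering import Dendrogram, DistanceMatrix
from .cwt import WaveletSpectrum
from .series import CountTable, RegularSeriesSet, SampledSeries
from .significance import SignificanceMask

__all__ = [
    "write_count_table_tsv",
    "read_count_table_tsv",
    "read_count_table_biom_json",
    "read_count_table",
    "write_panel_csv",
    "write_series_set_csv",
    "read_series_set_csv",
    "write_distance_csv",
    "read_distance_csv",
    "write_spectrum_csv",
    "write_mask_csv",
    "write_newick",
    "read_newick",
]

_TIME_ROW = "#time_days"


def write_count_table_tsv(table: CountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TIME_ROW + "\t" + "\t".join(f"{t:.10g}" for t in table.sample_times) + "\n")
        for taxon, row in zip(table.taxa, table.counts):
            fh.write(taxon + "\t" + "\t".join(str(int(c)) for c in row) + "\n")


def read_count_table_tsv(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    if df.empty or df.index[0] != _TIME_ROW:
        raise ValueError(f"{path}: first row must be the {_TIME_ROW} timestamp row")
    times = df.iloc[0].to_numpy(dtype=float)
    counts = df.iloc[1:].to_numpy(dtype=float)
    taxa = tuple(str(t) for t in df.index[1:])
    if counts.size == 0:
        raise ValueError(f"{path}: table contains no taxa")
    return CountTable(taxa, times, counts)


def read_count_table_biom_json(
    path: str | Path, sample_times: dict[str, float] | None = None
) -> CountTable:
    """Read a BIOM 1.0 (JSON) table.  Collection days are taken from the
    ``sample_times`` mapping (sample id -> day) or, failing that, from a
    ``collection_day`` key in each sample's BIOM metadata.  Samples are
    sorted by time."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format", "").startswith("Biological Observation Matrix 2"):
        raise ValueError("BIOM 2.x (HDF5) is not supported; convert to "
                         "BIOM 1.0 JSON or TSV")
    obs_ids = [o["id"] for o in doc["rows"]]
    samp = doc["columns"]
    n_obs, n_samp = doc["shape"]
    data = np.zeros((n_obs, n_samp))
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            data[int(r), int(c)] = v
    else:
        data[:] = np.asarray(doc["data"], dtype=float)
    times = np.empty(n_samp)
    for j, col in enumerate(samp):
        if sample_times is not None:
            times[j] = sample_times[col["id"]]
        else:
            md = col.get("metadata") or {}
            if "collection_day" not in md:
                raise ValueError(f"sample {col['id']!r} has no collection_day "
                                 "metadata and no sample_times mapping was given")
            times[j] = float(md["collection_day"])
    order = np.argsort(times)
    return CountTable(tuple(obs_ids), times[order], np.round(data[:, order]))


def read_count_table(path: str | Path,
                     sample_times: dict[str, float] | None = None) -> CountTable:
    """Dispatch on file content: BIOM 1.0 JSON or timestamped TSV."""
    path = Path(path)
    head = path.read_text(encoding="utf-8", errors="replace")[:1]
    if head == "{":
        return read_count_table_biom_json(path, sample_times)
    return read_count_table_tsv(path)


def write_panel_csv(series_list, path: str | Path) -> None:
    """Long-format CSV (label, time, value) for a collection of series."""
    rows = []
    for s in series_list:
        for t, v in zip(s.times, s.values):
            rows.append((s.label, t, v))
    pd.DataFrame(rows, columns=["label", "time", "value"]).to_csv(path, index=False)


def write_series_set_csv(rs: RegularSeriesSet, path: str | Path) -> None:
    df = pd.DataFrame(rs.values, index=list(rs.labels),
                      columns=[f"{t:.10g}" for t in rs.grid_times])
    df.index.name = "label"
    df.to_csv(path)


def read_series_set_csv(path: str | Path) -> RegularSeriesSet:
    df = pd.read_csv(path, index_col=0)
    grid = np.asarray([float(c) for c in df.columns])
    return RegularSeriesSet(tuple(df.index), grid, df.to_numpy(dtype=float))


def write_distance_csv(dist: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dist.d, index=list(dist.labels), columns=list(dist.labels))
    df.index.name = dist.method
    df.to_csv(path)


def read_distance_csv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    method = df.index.name or "unknown"
    return DistanceMatrix(tuple(df.columns), df.to_numpy(dtype=float), method)


def write_spectrum_csv(spec: WaveletSpectrum, path: str | Path) -> None:
    """Spectrum power as CSV (rows = periods, columns = times) plus a JSON
    sidecar ``<path>.json`` holding the transform parameters and COI."""
    df = pd.DataFrame(spec.power, index=[f"{p:.10g}" for p in spec.periods],
                      columns=[f"{t:.10g}" for t in spec.times])
    df.index.name = "period_days"
    df.to_csv(path)
    header = dict(spec.params)
    header["label"] = spec.label
    header["coi"] = [float(c) for c in spec.coi]
    Path(str(path) + ".json").write_text(json.dumps(header, indent=1))


def write_mask_csv(spec: WaveletSpectrum, mask: SignificanceMask,
                   path: str | Path) -> None:
    df = pd.DataFrame(mask.mask.astype(int),
                      index=[f"{p:.10g}" for p in spec.periods],
                      columns=[f"{t:.10g}" for t in spec.times])
    df.index.name = f"confidence={mask.confidence:g}"
    df.to_csv(path)


def _newick_node(dend: Dendrogram, node: int, edge_length: float,
                 heights: np.ndarray) -> str:
    n = dend.n_leaves
    if node < n:
        return f"{dend.labels[node]}:{edge_length:.10g}"
    i = node - n
    a, b = int(dend.Z[i, 0]), int(dend.Z[i, 1])
    h = heights[node]
    left = _newick_node(dend, a, h - heights[a], heights)
    right = _newick_node(dend, b, h - heights[b], heights)
    return f"({left},{right}):{edge_length:.10g}"


def write_newick(dend: Dendrogram, path: str | Path) -> None:
    n = dend.n_leaves
    heights = np.concatenate([np.zeros(n), dend.Z[:, 2]])
    root = 2 * n - 2
    text = _newick_node(dend, root, 0.0, heights)
    Path(path).write_text(text.rsplit(":", 1)[0] + ";\n")


def read_newick(path: str | Path) -> Dendrogram:
    """Rebuild a merge tree from an ultrametric Newick file (as written by
    :func:`write_newick`).  Multifurcations are resolved into a sequence
    of equal-height binary merges."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    labels = tuple(leaves)
    index = {lab: i for i, lab in enumerate(labels)}
    # node height = distance to any descendant leaf (ultrametric)
    merges: list[tuple[float, list]] = []
    rep: dict = {}
    height: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            rep[node] = index[node.taxon.label]
            height[node] = 0.0
        else:
            child = node.child_nodes()[0]
            h = height[child] + (child.edge.length or 0.0)
            height[node] = h
            merges.append((h, node))
    merges.sort(key=lambda x: x[0])
    n = len(labels)
    Z = np.zeros((n - 1, 4))
    sizes = {i: 1 for i in range(n)}
    next_id = n
    row = 0
    for h, node in merges:
        kids = [rep[c] for c in node.child_nodes()]
        cur = kids[0]
        for other in kids[1:]:
            size = sizes[cur] + sizes[other]
            Z[row] = [cur, other, h, size]
            sizes[next_id] = size
            cur = next_id
            next_id += 1
            row += 1
        rep[node] = cur
    if row != n - 1:
        raise ValueError(f"{path}: not a valid rooted tree over {n} leaves")
    return Dendrogram(labels, Z)
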