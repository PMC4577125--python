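"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8 TSV with a header row and '.' decimals.  Matrices
have the feature id in the first column and sample ids in the header;
group labels are a two-column (sample, group) TSV; the interactome is a
three-column (node1, node2, reliability) edge list; pathway membership
is GMT with a parallel four-column (pathway, source, target, beta)
topology TSV; the miRNA target map is a two-column (mirna, gene) TSV.
Write-then-read round-trips preserve values to full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ConfigurationError, OmicsMatrix, PathwaySpec
from .simulate import SyntheticDataset

__all__ = [
    "read_matrix_tsv", "write_matrix_tsv",
    "read_group_labels", "write_group_labels",
    "read_omics_matrix", "write_omics_matrix",
    "read_gmt", "write_gmt",
    "read_topology_tsv", "write_topology_tsv",
    "read_pathways", "write_pathways",
    "read_edge_list", "write_edge_list",
    "read_target_map", "write_target_map",
    "write_dataset", "read_dataset",
    "write_graphml",
]

_FLOAT_FMT = "%.17g"


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", float_precision="round_trip", **kw)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ConfigurationError(f"{path}: malformed TSV ({exc})") from exc


def read_matrix_tsv(path) -> pd.DataFrame:
    """Feature x sample numeric matrix from TSV (first column = feature id)."""
    df = _read_tsv(path, index_col=0)
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][:3].tolist()
        raise ConfigurationError(f"{path}: duplicate feature ids {dup}")
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        for col in bad:
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:1].tolist()
            raise ConfigurationError(
                f"{path}: non-numeric cell in column {col!r}, row {row}")
    return df.astype(float)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature", float_format=_FLOAT_FMT)


def read_group_labels(path) -> pd.Series:
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ConfigurationError(f"{path}: expected columns 'sample', 'group'")
    return pd.Series(df["group"].to_numpy(), index=df["sample"])


def write_group_labels(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False)


def read_omics_matrix(matrix_path, labels_path) -> OmicsMatrix:
    return OmicsMatrix(read_matrix_tsv(matrix_path), read_group_labels(labels_path))


def write_omics_matrix(m: OmicsMatrix, matrix_path, labels_path) -> None:
    write_matrix_tsv(m.values, matrix_path)
    write_group_labels(m.groups, labels_path)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT membership: name<TAB>description<TAB>gene1<TAB>gene2..."""
    out: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ConfigurationError(f"{path}:{ln}: GMT line needs name, description, genes")
        out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def write_gmt(memberships: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in memberships.items():
            fh.write("\t".join([name, "synthetic"] + sorted(genes)) + "\n")


def read_topology_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    need = ["pathway", "source", "target", "beta"]
    if list(df.columns[:4]) != need:
        raise ConfigurationError(f"{path}: expected columns {need}")
    df["beta"] = pd.to_numeric(df["beta"], errors="raise")
    return df


def write_topology_tsv(pathways: Iterable[PathwaySpec], path) -> None:
    rows = [(p.pathway_id, s, t, b) for p in pathways for s, t, b in p.topology]
    pd.DataFrame(rows, columns=["pathway", "source", "target", "beta"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_pathways(gmt_path, topology_path=None) -> list[PathwaySpec]:
    members = read_gmt(gmt_path)
    topo: dict[str, list] = {name: [] for name in members}
    if topology_path is not None:
        for _, row in read_topology_tsv(topology_path).iterrows():
            if row["pathway"] not in members:
                raise ConfigurationError(
                    f"topology references unknown pathway {row['pathway']!r}")
            topo[row["pathway"]].append((row["source"], row["target"], row["beta"]))
    return [PathwaySpec.from_lists(name, genes, topo[name])
            for name, genes in members.items()]


def write_pathways(pathways: Iterable[PathwaySpec], gmt_path, topology_path) -> None:
    pathways = list(pathways)
    write_gmt({p.pathway_id: p.members for p in pathways}, gmt_path)
    write_topology_tsv(pathways, topology_path)


def read_edge_list(path) -> pd.DataFrame:
    df = _read_tsv(path)
    need = ["node1", "node2", "reliability"]
    if list(df.columns[:3]) != need:
        raise ConfigurationError(f"{path}: expected columns {need}")
    rel = pd.to_numeric(df["reliability"], errors="raise")
    if ((rel < 0) | (rel > 1)).any():
        bad = df.loc[(rel < 0) | (rel > 1)].index[0]
        raise ConfigurationError(f"{path}: reliability outside [0,1] at row {bad + 2}")
    df["reliability"] = rel
    return df


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def edge_list_to_graph(edges: pd.DataFrame) -> nx.Graph:
    G = nx.Graph()
    for _, row in edges.iterrows():
        G.add_edge(str(row["node1"]), str(row["node2"]),
                   reliability=float(row["reliability"]))
    return G


def read_target_map(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["mirna", "gene"]:
        raise ConfigurationError(f"{path}: expected columns 'mirna', 'gene'")
    return df


def write_target_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_graphml(G: nx.Graph, path) -> None:
    H = G.copy()
    for _, data in H.nodes(data=True):  # GraphML cannot carry None values
        for k in [k for k, v in data.items() if v is None]:
            del data[k]
    for _, _, data in H.edges(data=True):
        for k in [k for k, v in data.items() if v is None]:
            del data[k]
    nx.write_graphml(H, path)


# ---------------------------------------------------------------------------
# whole synthetic dataset round trip
# ---------------------------------------------------------------------------

_DATASET_FILES = {
    "expression": ("expression.tsv", "samples.tsv"),
    "methylation": ("methylation.tsv", "samples.tsv"),
    "mirna_expression": ("mirna_expression.tsv", "samples.tsv"),
    "mirna_methylation": ("mirna_methylation.tsv", "samples.tsv"),
}


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_group_labels(ds.expression.groups, out / "samples.tsv")
    for attr, (mat, _) in _DATASET_FILES.items():
        write_matrix_tsv(getattr(ds, attr).values, out / mat)
    write_edge_list(ds.interactome, out / "interactome.tsv")
    write_pathways(ds.pathways, out / "pathways.gmt", out / "pathway_topology.tsv")
    write_target_map(ds.target_map, out / "target_map.tsv")
    (out / "truth.json").write_text(json.dumps(ds.truth, indent=1, sort_keys=True))


def read_dataset(indir) -> dict:
    """Load a written dataset directory back into pipeline inputs."""
    d = Path(indir)
    groups = read_group_labels(d / "samples.tsv")
    layers = {attr: OmicsMatrix(read_matrix_tsv(d / mat), groups)
              for attr, (mat, _) in _DATASET_FILES.items()}
    return {
        **layers,
        "interactome": read_edge_list(d / "interactome.tsv"),
        "pathways": read_pathways(d / "pathways.gmt", d / "pathway_topology.tsv"),
        "target_map": read_target_map(d / "target_map.tsv"),
        "truth": json.loads((d / "truth.json").read_text()) if (d / "truth.json").exists() else None,
    }
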