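"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as GCT 1.2 or TSV, gene sets as GMT, interaction
graphs as SIF plus a node-role table, and everything else as headered TSV.
All writers emit deterministic byte streams for a given input (sorted where
order is not semantically meaningful, fixed float formatting), which is what
makes manifest checksums reproducible.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# GCT 1.2
# ---------------------------------------------------------------------------

def write_gct(df: pd.DataFrame, path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write a probe/gene x sample matrix as GCT version 1.2."""
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
        for name, row in df.iterrows():
            desc = descriptions.get(name, "na") if descriptions else "na"
            vals = "\t".join(FLOAT_FMT % v for v in row.to_numpy())
            fh.write(f"{name}\t{desc}\t{vals}\n")


def read_gct(path: str | os.PathLike) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2",):
            raise ValueError(f"unsupported GCT version line: {version!r}")
        nrow, ncol = map(int, fh.readline().split())
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"])
    if df.shape != (nrow, ncol):
        raise ValueError(f"GCT header promised {(nrow, ncol)}, got {df.shape}")
    return df


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def write_gmt(sets: Mapping[str, Iterable[str]], path: str | os.PathLike,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sets[name])
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# SIF + node roles
# ---------------------------------------------------------------------------

def write_sif(graph: nx.DiGraph, path: str | os.PathLike) -> None:
    """Edge list as source<TAB>edge_type<TAB>target, sorted for determinism."""
    rows = sorted(
        (u, d.get("etype", "interaction"), v) for u, v, d in graph.edges(data=True)
    )
    with open(path, "w") as fh:
        for u, etype, v in rows:
            fh.write(f"{u}\t{etype}\t{v}\n")


def write_node_roles(graph: nx.DiGraph, path: str | os.PathLike) -> None:
    rows = sorted((n, d.get("role", "target-gene")) for n, d in graph.nodes(data=True))
    pd.DataFrame(rows, columns=["node", "role"]).to_csv(path, sep="\t", index=False)


def read_sif(path: str | os.PathLike,
             roles_path: str | os.PathLike | None = None) -> nx.DiGraph:
    graph = nx.DiGraph()
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            u, etype, v = fields
            graph.add_edge(u, v, etype=etype, weight=1.0)
    if roles_path is not None:
        roles = pd.read_csv(roles_path, sep="\t")
        for _, row in roles.iterrows():
            if row["node"] not in graph:
                graph.add_node(row["node"])
            graph.nodes[row["node"]]["role"] = row["role"]
    return graph


# ---------------------------------------------------------------------------
# Generic TSV helpers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_tsv(path: str | os.PathLike, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
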