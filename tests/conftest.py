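"""Shared fixtures: small seeded synthetic bundles and textbook oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import nichecmap as nc


@pytest.fixture(scope="session")
def default_bundle():
    """Full synthetic bundle at the default study conditions (seed 7)."""
    return nc.generate_all(nc.SimConfig(seed=7))


@pytest.fixture(scope="session")
def toy_de_config():
    """Compendium with a single planted contrast, for exact-count DE checks."""
    return nc.SimConfig(
        n_genes=300, seed=13,
        planted_de={"dorsalization": nc.PlantedSignal(
            conditions=("dNSC", "dTAP"), n_genes=50)})


@pytest.fixture(scope="session")
def toy_de(toy_de_config):
    return nc.generate_compendium(toy_de_config)


@pytest.fixture(scope="session")
def small_db():
    """50-gene, 20-drug database with 3 strong mimics of one signature."""
    cfg = nc.SimConfig(
        n_genes=50, n_drugs=20, instances_per_drug=3, seed=21,
        planted_de={"s": nc.PlantedSignal(conditions=("dNSC",), n_genes=16)},
        planted_mimics={"s": nc.MimicSpec(n_drugs=3, strength=0.9)})
    _, truth = nc.generate_compendium(cfg)
    sig = nc.truth_signatures(truth)["s"]
    db, mimic_truth = nc.generate_drug_db(cfg, {"s": sig})
    return {"config": cfg, "signature": sig, "db": db,
            "mimic_truth": mimic_truth}


# ---------------------------------------------------------------------------
# Independent oracles (textbook routes, no package internals)
# ---------------------------------------------------------------------------

def pooled_t_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample pooled-variance t and two-sided p from the textbook formula."""
    from scipy.stats import t as tdist
    n1, n2 = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    if se == 0:
        return (0.0, 1.0) if x.mean() == y.mean() else (np.inf, 0.0)
    t = (x.mean() - y.mean()) / se
    return t, 2 * tdist.sf(abs(t), n1 + n2 - 2)


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """BH step-up: sort p, take the running minimum of p*m/rank from the bottom."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running = min(running, p[order[i]] * m / rank)
        adj[order[i]] = running
    return adj


def ks_oracle(tag_positions, n: int) -> float:
    """Signed KS by walking every position of the ranked list."""
    tags = set(int(v) for v in tag_positions)
    t = len(tags)
    a = b = -np.inf
    hits = 0
    for i in range(1, n + 1):
        before = hits
        if i in tags:
            hits += 1
        a = max(a, hits / t - i / n)
        b = max(b, i / n - before / t)
    return a if a > b else -b


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P[overlap >= k] by summing the PMF with exact integer combinatorics."""
    from math import comb
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / total


def average_linkage_oracle(dist: np.ndarray):
    """Agglomerate by recomputing cluster distances from the original matrix
    at every step (mean over all cross member pairs), smallest-pair ties."""
    n = dist.shape[0]
    members = {i: [i] for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        for a in sorted(members):
            for b in sorted(members):
                if b <= a:
                    continue
                d = np.mean([dist[i, j] for i in members[a] for j in members[b]])
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        new = n + step
        members[new] = members.pop(a) + members.pop(b)
        merges.append((a, b, d, len(members[new])))
    return merges


def all_shortest_paths_oracle(graph, source, target):
    """All minimum-weight simple paths by exhaustive DFS with pruning."""
    best = [np.inf]
    paths = []

    def dfs(node, length, path):
        if length > best[0]:
            return
        if node == target:
            if length < best[0]:
                best[0] = length
                paths.clear()
            if length == best[0]:
                paths.append(list(path))
            return
        for succ in graph.successors(node):
            if succ in path:
                continue
            w = graph.edges[node, succ].get("weight", 1)
            path.append(succ)
            dfs(succ, length + w, path)
            path.pop()

    dfs(source, 0.0, [source])
    return (best[0], paths) if paths else (np.inf, [])
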