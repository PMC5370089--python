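"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a germinal-zone
expression compendium and a drug-perturbation reference database: replicated
conditions spanning dorsal/lateral NSCs and TAPs, niche tissue, the
oligodendrocyte lineage and adult NSCs; several probes per gene with jittered
effect sizes so probe collapsing is non-trivial; condition-specific
differentially expressed genes planted per screen; and drug instances whose
gene rankings either ignore a signature (null drugs) or mimic/oppose it with
a tunable strength. Category annotations, drug-target tables and a typed
interaction graph round out the inputs so every downstream stage is testable
without any external download.

Every generator is a pure function of (config, seed): each draws from its own
RNG stream derived from the master seed by a fixed offset, so adding or
re-running one generator never perturbs another's output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import io
from .connectivity import DrugProfileDB
from .signatures import ExpressionMatrix, Signature

# fixed RNG stream offsets per generator
_STREAM_COMPENDIUM = 1
_STREAM_DRUG_DB = 2
_STREAM_ANNOTATIONS = 3
_STREAM_GRAPH = 4

DEFAULT_CONDITIONS = ("dNSC", "dTAP", "lNSC", "lTAP", "dSVZ", "lSVZ",
                      "OPC", "imOL", "mOL", "aNSC")

# category vocabulary mirroring the screens' pie charts
CATEGORY_NAMES = ("receptor_antagonist", "signaling", "metabolism",
                  "gene_regulation", "epigenetic", "cell_cycle",
                  "ion_transport", "cytoskeleton")

NODE_ROLES = ("ligand", "receptor", "kinase", "transcription-factor",
              "target-gene")
EDGE_TYPES = ("activation", "inhibition", "binding",
              "transcriptional-regulation")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSignal:
    """A block of DE genes planted for one screen contrast."""

    conditions: tuple[str, ...]      # conditions carrying the shift
    n_genes: int = 150
    log2_effect: float = 1.5
    frac_up: float = 0.7             # fraction shifted up (rest down)


@dataclass(frozen=True)
class MimicSpec:
    """Drugs planted to mimic (+) or oppose (-) one signature."""

    n_drugs: int = 5
    strength: float = 0.9            # rank displacement, 0 = null, 1 = extreme
    sign: int = 1


@dataclass(frozen=True)
class GraphSpec:
    n_nodes: int = 150
    n_edges: int = 450


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 1000
    probes_per_gene: tuple[int, int] = (1, 3)
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 3
    planted_de: dict[str, PlantedSignal] = field(default_factory=lambda: {
        "dorsalization": PlantedSignal(conditions=("dNSC", "dTAP")),
        "ventralization": PlantedSignal(conditions=("lNSC", "lTAP")),
        "oligodendrogenesis": PlantedSignal(conditions=("OPC", "imOL", "mOL")),
        "rejuvenation": PlantedSignal(conditions=("aNSC",)),
    })
    noise_sd: float = 0.25           # log2 units
    baseline_mean: float = 7.0       # log2 RMA-like intensity
    baseline_sd: float = 1.5
    effect_jitter: float = 0.2       # +/- fraction on per-probe effects
    n_drugs: int = 200
    instances_per_drug: int = 3
    planted_mimics: dict[str, MimicSpec] = field(default_factory=lambda: {
        "dorsalization": MimicSpec(),
        "ventralization": MimicSpec(),
        "oligodendrogenesis": MimicSpec(),
        "rejuvenation": MimicSpec(),
    })
    fold_scale: float = 1.0          # scales rank-implied log2 fold changes
    n_categories: int = 6
    n_proteins: int = 120
    targets_per_drug: tuple[int, int] = (1, 3)
    graph_spec: GraphSpec = field(default_factory=GraphSpec)
    seed: int = 0

    def validate(self) -> None:
        positive = {"n_genes": self.n_genes, "n_drugs": self.n_drugs,
                    "instances_per_drug": self.instances_per_drug,
                    "n_categories": self.n_categories,
                    "n_proteins": self.n_proteins,
                    "graph nodes": self.graph_spec.n_nodes,
                    "graph edges": self.graph_spec.n_edges}
        for name, value in positive.items():
            if value < 1:
                raise SimulationError(f"{name} must be positive, got {value}")
        if self.replicates_per_condition < 2:
            raise SimulationError(
                "replicates_per_condition must be >= 2 (t-tests impossible "
                "otherwise)")
        if not self.noise_sd > 0:
            raise SimulationError("noise_sd must be positive")
        if not (1 <= self.probes_per_gene[0] <= self.probes_per_gene[1]):
            raise SimulationError("probes_per_gene bounds invalid")
        for label, spec in self.planted_mimics.items():
            if not 0 <= spec.strength <= 1:
                raise SimulationError(
                    f"mimic strength for {label!r} must lie in [0, 1]")
            if spec.sign not in (1, -1):
                raise SimulationError(f"mimic sign for {label!r} must be +/-1")
        if sum(s.n_drugs for s in self.planted_mimics.values()) > self.n_drugs:
            raise SimulationError("more planted mimics than drugs")
        total_planted = sum(s.n_genes for s in self.planted_de.values())
        if total_planted > self.n_genes:
            raise SimulationError("more planted DE genes than genes")
        for label, spec in self.planted_de.items():
            unknown = set(spec.conditions) - set(self.conditions)
            if unknown:
                raise SimulationError(
                    f"planted contrast {label!r} names unknown conditions "
                    f"{sorted(unknown)}")
            if not 0 <= spec.frac_up <= 1:
                raise SimulationError(f"frac_up for {label!r} must be in [0, 1]")

    # -- derived naming ----------------------------------------------------
    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def drug_names(self) -> list[str]:
        return [f"drug_{i:03d}" for i in range(self.n_drugs)]

    @property
    def protein_names(self) -> list[str]:
        return [f"PROT{i:03d}" for i in range(self.n_proteins)]

    @property
    def category_names(self) -> list[str]:
        base = list(CATEGORY_NAMES)
        while len(base) < self.n_categories:
            base.append(f"category_{len(base):02d}")
        return base[: self.n_categories]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Expression compendium
# ---------------------------------------------------------------------------

def generate_compendium(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Probe x sample log2 matrix with planted condition-specific DE genes.

    Returns the matrix plus a ground-truth table listing every planted
    (gene, contrast, signed log2 effect, direction, conditions). DE gene sets
    of different contrasts are disjoint. All probes of a DE gene share its
    direction; per-probe effect magnitudes are jittered by +/-effect_jitter
    so the max-|FC| collapsing rule has something to choose between.
    """
    config.validate()
    rng = _rng(config, _STREAM_COMPENDIUM)

    genes = config.gene_names
    lo, hi = config.probes_per_gene
    probe_counts = rng.integers(lo, hi + 1, size=config.n_genes)
    probes, gene_of_probe = [], []
    for g, c in zip(genes, probe_counts):
        for j in range(c):
            probes.append(f"{g}.p{j + 1}")
            gene_of_probe.append(g)
    probe_to_gene = pd.Series(gene_of_probe, index=pd.Index(probes, name="probe"),
                              name="gene_symbol")

    samples, conditions_of = [], []
    for cond in config.conditions:
        for r in range(config.replicates_per_condition):
            samples.append(f"{cond}_r{r + 1}")
            conditions_of.append(cond)
    sample_to_condition = pd.Series(
        conditions_of, index=pd.Index(samples, name="sample_id"),
        name="condition")

    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=len(probes))
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(len(probes), len(samples)))

    # plant DE blocks on disjoint gene sets
    pool = list(rng.permutation(config.n_genes))
    cursor = 0
    probe_slices = {}
    start = 0
    for g, c in zip(genes, probe_counts):
        probe_slices[g] = slice(start, start + c)
        start += c
    sample_idx = {cond: [i for i, s in enumerate(samples)
                         if conditions_of[i] == cond]
                  for cond in config.conditions}
    truth_rows = []
    for label, spec in config.planted_de.items():
        chosen = pool[cursor: cursor + spec.n_genes]
        cursor += spec.n_genes
        n_up = int(round(spec.frac_up * spec.n_genes))
        directions = np.array([1] * n_up + [-1] * (spec.n_genes - n_up))
        cols = [i for cond in spec.conditions for i in sample_idx[cond]]
        for gi, direction in zip(chosen, directions):
            gene = genes[gi]
            sl = probe_slices[gene]
            n_probes = sl.stop - sl.start
            jitter = rng.uniform(1 - config.effect_jitter,
                                 1 + config.effect_jitter, size=n_probes)
            effect = direction * spec.log2_effect * jitter
            values[sl, :][:, cols] += effect[:, None] if spec.log2_effect else 0.0
            truth_rows.append({
                "gene": gene, "contrast": label,
                "log2_effect": direction * spec.log2_effect,
                "direction": int(direction),
                "conditions": ",".join(spec.conditions),
                "n_probes": n_probes})

    truth = pd.DataFrame(
        truth_rows, columns=["gene", "contrast", "log2_effect", "direction",
                             "conditions", "n_probes"])
    truth = truth[truth["log2_effect"] != 0].reset_index(drop=True)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_to_gene.index, columns=samples),
        probe_to_gene=probe_to_gene,
        sample_to_condition=sample_to_condition)
    return matrix, truth


def truth_signatures(truth: pd.DataFrame) -> dict[str, Signature]:
    """Planted ground truth recast as directional signatures, per contrast."""
    out = {}
    for label, block in truth.groupby("contrast"):
        entries = (block.set_index("gene")[["direction", "log2_effect"]]
                   .rename(columns={"log2_effect": "log2_fc"}).sort_index())
        out[label] = Signature(entries=entries, label=label)
    return out


# ---------------------------------------------------------------------------
# Drug-perturbation database
# ---------------------------------------------------------------------------

def generate_drug_db(config: SimConfig,
                     signatures: dict[str, Signature]) -> tuple[DrugProfileDB,
                                                                pd.DataFrame]:
    """Per-instance gene rankings with planted mimics of the given signatures.

    Null drugs get exchangeable random rankings. A mimic of strength s and
    sign + displaces the signature's up-genes toward rank 1 and down-genes
    toward rank n proportionally to s (at s = 1 every up-gene outranks every
    null gene, which outranks every down-gene); sign - swaps the roles.
    Fold changes are a fixed monotone-decreasing function of rank (a scaled
    normal quantile), hence consistent with the ranking by construction.
    """
    config.validate()
    for label in config.planted_mimics:
        if label not in signatures:
            raise SimulationError(
                f"planted mimic references unknown signature {label!r}")
    genes = config.gene_names
    gene_index = pd.Index(genes, name="gene")
    gene_pos = {g: i for i, g in enumerate(genes)}
    for label, sig in signatures.items():
        stray = [g for g in sig.genes if g not in gene_pos]
        if stray:
            raise SimulationError(
                f"signature {label!r} has genes outside the universe: "
                f"{stray[:5]}")

    rng = _rng(config, _STREAM_DRUG_DB)
    n = config.n_genes
    drugs = config.drug_names

    # assign mimic drugs in config order, the rest are null
    assignment: dict[str, tuple[str, float, int]] = {}
    next_drug = 0
    truth_rows = []
    for label, spec in config.planted_mimics.items():
        for _ in range(spec.n_drugs):
            drug = drugs[next_drug]
            next_drug += 1
            assignment[drug] = (label, spec.strength, spec.sign)
            truth_rows.append({"drug": drug, "signature": label,
                               "strength": spec.strength, "sign": spec.sign})

    # rank -> log2 fold change map, shared by all instances
    rank_to_fold = _stats.norm.ppf(
        (n - np.arange(1, n + 1) + 0.5) / n) * config.fold_scale

    meta_rows = []
    cell_lines = ("MCF7", "PC3", "HL60")
    rank_data = {}
    fold_data = {}
    for d_i, drug in enumerate(drugs):
        if drug in assignment:
            label, strength, sign = assignment[drug]
            sig = signatures[label]
            up = sig.up_genes if sign == 1 else sig.down_genes
            down = sig.down_genes if sign == 1 else sig.up_genes
            up_idx = np.array([gene_pos[g] for g in up], dtype=int)
            dn_idx = np.array([gene_pos[g] for g in down], dtype=int)
        else:
            strength = 0.0
            up_idx = dn_idx = np.array([], dtype=int)
        for k in range(config.instances_per_drug):
            iid = f"{drug}.i{k + 1}"
            u = rng.random(n)
            score = u.copy()
            if strength > 0:
                score[up_idx] = (1 - strength) * u[up_idx]
                score[dn_idx] = strength + (1 - strength) * u[dn_idx]
            order = np.lexsort((u, score))      # ascending score, u breaks ties
            rank = np.empty(n, dtype=int)
            rank[order] = np.arange(1, n + 1)
            rank_data[iid] = rank
            fold_data[iid] = rank_to_fold[rank - 1] + rng.normal(
                0.0, 0.05 * config.fold_scale, size=n)
            meta_rows.append({
                "instance_id": iid, "drug": drug,
                "cell_line": cell_lines[(d_i + k) % len(cell_lines)],
                "dose_um": float(10 ** (k - 1))})

    db = DrugProfileDB(
        ranks=pd.DataFrame(rank_data, index=gene_index),
        fold_changes=pd.DataFrame(fold_data, index=gene_index),
        instances=pd.DataFrame(meta_rows).set_index("instance_id"))
    truth = pd.DataFrame(truth_rows,
                         columns=["drug", "signature", "strength", "sign"])
    return db, truth


# ---------------------------------------------------------------------------
# Annotations: category GMT, drug targets, protein categories
# ---------------------------------------------------------------------------

def generate_annotations(config: SimConfig) -> dict:
    """Category gene sets (GMT), drug->protein targets, protein->category map.

    The gene sets partition the gene universe and the categories partition the
    protein universe: every protein belongs to exactly one general category,
    and every drug receives at least one protein target (in priority order).
    """
    config.validate()
    rng = _rng(config, _STREAM_ANNOTATIONS)
    categories = config.category_names

    gene_cat = rng.integers(0, config.n_categories, size=config.n_genes)
    gene_sets = {cat: [g for g, c in zip(config.gene_names, gene_cat)
                       if c == ci]
                 for ci, cat in enumerate(categories)}

    # partition proteins over categories, each category guaranteed non-empty
    # when there are enough proteins
    prot_cat = rng.integers(0, config.n_categories, size=config.n_proteins)
    if config.n_proteins >= config.n_categories:
        prot_cat[:config.n_categories] = np.arange(config.n_categories)
        prot_cat = rng.permutation(prot_cat)
    protein_category = pd.DataFrame(
        {"protein": config.protein_names,
         "category": [categories[c] for c in prot_cat]})

    lo, hi = config.targets_per_drug
    rows = []
    for drug in config.drug_names:
        n_targets = int(rng.integers(lo, hi + 1))
        targets = rng.choice(config.n_proteins, size=max(n_targets, 1),
                             replace=False)
        for priority, t in enumerate(targets, start=1):
            rows.append({"drug": drug, "protein": config.protein_names[t],
                         "priority": priority})
    drug_targets = pd.DataFrame(rows, columns=["drug", "protein", "priority"])
    return {"gene_sets": gene_sets, "drug_targets": drug_targets,
            "protein_category": protein_category}


def drug_target_map(drug_targets: pd.DataFrame) -> dict[str, list[str]]:
    """Drug -> ordered target list (priority order as listed)."""
    ordered = drug_targets.sort_values(["drug", "priority"], kind="mergesort")
    return {drug: list(block["protein"])
            for drug, block in ordered.groupby("drug", sort=False)}


# ---------------------------------------------------------------------------
# Interaction graph
# ---------------------------------------------------------------------------

def generate_graph(config: SimConfig) -> nx.DiGraph:
    """Directed typed interaction graph over a subset of the gene universe.

    Nodes carry roles from ligand/receptor/kinase/transcription-factor/
    target-gene; edges carry types and unit weights; no self-loops. Extra
    bridging edges are added until the largest weakly connected component
    covers at least 80% of the nodes.
    """
    config.validate()
    rng = _rng(config, _STREAM_GRAPH)
    spec = config.graph_spec
    n_nodes = min(spec.n_nodes, config.n_genes)
    node_ids = [config.gene_names[i]
                for i in sorted(rng.choice(config.n_genes, size=n_nodes,
                                           replace=False))]
    roles = rng.choice(len(NODE_ROLES), size=n_nodes,
                       p=(0.15, 0.2, 0.2, 0.2, 0.25))

    graph = nx.DiGraph()
    for node, role in zip(node_ids, roles):
        graph.add_node(node, role=NODE_ROLES[role])

    target_edges = min(spec.n_edges, n_nodes * (n_nodes - 1))
    while graph.number_of_edges() < target_edges:
        deficit = target_edges - graph.number_of_edges()
        us = rng.integers(0, n_nodes, size=2 * deficit + 8)
        vs = rng.integers(0, n_nodes, size=2 * deficit + 8)
        for u, v in zip(us, vs):
            if u == v or graph.number_of_edges() >= target_edges:
                continue
            a, b = node_ids[u], node_ids[v]
            if graph.has_edge(a, b):
                continue
            etype = EDGE_TYPES[rng.integers(0, len(EDGE_TYPES))]
            graph.add_edge(a, b, etype=etype, weight=1.0)

    # bridge small components into the giant one until >= 80% coverage
    while True:
        comps = sorted(nx.weakly_connected_components(graph), key=len,
                       reverse=True)
        if len(comps[0]) >= 0.8 * n_nodes:
            break
        giant = sorted(comps[0])
        other = sorted(comps[1])
        a = giant[int(rng.integers(0, len(giant)))]
        b = other[int(rng.integers(0, len(other)))]
        etype = EDGE_TYPES[rng.integers(0, len(EDGE_TYPES))]
        graph.add_edge(a, b, etype=etype, weight=1.0)
    return graph


# ---------------------------------------------------------------------------
# Bundle generation + on-disk layout
# ---------------------------------------------------------------------------

def generate_all(config: SimConfig) -> dict:
    """Every synthetic input in one call (compendium, DB, annotations, graph)."""
    matrix, de_truth = generate_compendium(config)
    signatures = truth_signatures(de_truth)
    db, mimic_truth = generate_drug_db(config, signatures)
    annotations = generate_annotations(config)
    graph = generate_graph(config)
    return {"matrix": matrix, "de_truth": de_truth,
            "truth_signatures": signatures, "db": db,
            "mimic_truth": mimic_truth, "annotations": annotations,
            "graph": graph, "config": config}


def write_inputs(bundle: dict, outdir: str | os.PathLike) -> list[str]:
    """Write the full synthetic bundle in its standard text formats."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    matrix: ExpressionMatrix = bundle["matrix"]
    db: DrugProfileDB = bundle["db"]
    ann = bundle["annotations"]

    paths = {}

    def _path(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    io.write_gct(matrix.values, _path("expression.gct"),
                 descriptions=matrix.probe_to_gene.to_dict())
    io.write_tsv(matrix.values.reset_index(), _path("expression.tsv"))
    io.write_tsv(matrix.probe_to_gene.reset_index(), _path("probe_annotation.tsv"))
    meta = matrix.sample_to_condition.reset_index()
    meta["replicate"] = meta["sample_id"].str.rsplit("_r", n=1).str[-1]
    io.write_tsv(meta, _path("sample_metadata.tsv"))
    io.write_tsv(bundle["de_truth"], _path("ground_truth_de.tsv"))
    io.write_tsv(db.ranks.reset_index(), _path("drug_ranks.tsv"))
    io.write_tsv(db.fold_changes.reset_index(), _path("drug_fold_changes.tsv"))
    io.write_tsv(db.instances.reset_index(), _path("drug_instances.tsv"))
    io.write_tsv(bundle["mimic_truth"], _path("ground_truth_mimics.tsv"))
    io.write_gmt(ann["gene_sets"], _path("categories.gmt"))
    io.write_tsv(ann["drug_targets"], _path("drug_targets.tsv"))
    io.write_tsv(ann["protein_category"], _path("protein_categories.tsv"))
    io.write_sif(bundle["graph"], _path("graph.sif"))
    io.write_node_roles(bundle["graph"], _path("node_roles.tsv"))
    return sorted(paths.values())


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
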