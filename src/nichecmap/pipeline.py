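"""End-to-end orchestration: simulate -> signature -> connect -> rank ->
annotate -> profile -> network, per screen, with a checksum manifest.

Each screen is a positive-range vs negative-range contrast (dorsalization,
ventralization, oligodendrogenesis, rejuvenation by default). Every stage
writes its intermediate as plain text, so any stage can be re-run standalone
from the files the pipeline leaves behind; the manifest records the seed and
a SHA-256 per output, and is byte-identical across runs with the same
(config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import annotation, connectivity, io, networks, profiling, ranking
from . import signatures as sigmod
from . import simulate

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class ScreenSpec:
    positive: tuple[str, ...]
    negative: tuple[str, ...]
    fc_threshold: float = 1.8
    fdr_threshold: float = 0.05
    enrichment_fdr: float = 0.02
    refinements: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = ()


DEFAULT_SCREENS: dict[str, ScreenSpec] = {
    "dorsalization": ScreenSpec(positive=("dNSC", "dTAP"),
                                negative=("lNSC", "lTAP", "dSVZ", "lSVZ")),
    "ventralization": ScreenSpec(positive=("lNSC", "lTAP"),
                                 negative=("dNSC", "dTAP", "dSVZ", "lSVZ")),
    "oligodendrogenesis": ScreenSpec(positive=("OPC", "imOL", "mOL"),
                                     negative=("dNSC", "dTAP")),
    "rejuvenation": ScreenSpec(positive=("aNSC",),
                               negative=("dNSC", "lNSC"),
                               enrichment_fdr=0.01),
}


@dataclass
class PipelineConfig:
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    screens: dict[str, ScreenSpec] = field(
        default_factory=lambda: dict(DEFAULT_SCREENS))
    scorer: str = "ks"
    aggregation: str = "mean"
    n_perm: int = 200
    target_gene_p: float = 0.05
    cap_min: int = 70
    cap_max: int = 80
    max_seeds: int = 12
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        sim_kwargs = raw.pop("simulate", {})
        if sim_kwargs:
            if "planted_de" in sim_kwargs:
                sim_kwargs["planted_de"] = {
                    k: simulate.PlantedSignal(
                        conditions=tuple(v["conditions"]),
                        n_genes=v.get("n_genes", 150),
                        log2_effect=v.get("log2_effect", 1.5),
                        frac_up=v.get("frac_up", 0.7))
                    for k, v in sim_kwargs["planted_de"].items()}
            if "planted_mimics" in sim_kwargs:
                sim_kwargs["planted_mimics"] = {
                    k: simulate.MimicSpec(**v)
                    for k, v in sim_kwargs["planted_mimics"].items()}
            if "graph_spec" in sim_kwargs:
                sim_kwargs["graph_spec"] = simulate.GraphSpec(
                    **sim_kwargs["graph_spec"])
            for key in ("probes_per_gene", "conditions", "targets_per_drug"):
                if key in sim_kwargs:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            cfg.sim = dataclasses.replace(cfg.sim, **sim_kwargs)
        if "screens" in raw:
            cfg.screens = {
                label: ScreenSpec(
                    positive=tuple(s["positive"]),
                    negative=tuple(s["negative"]),
                    fc_threshold=s.get("fc_threshold", 1.8),
                    fdr_threshold=s.get("fdr_threshold", 0.05),
                    enrichment_fdr=s.get("enrichment_fdr", 0.02))
                for label, s in raw.pop("screens").items()}
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise PipelineError("config", f"unknown key {key!r}")
            setattr(cfg, key, value)
        cfg.sim = simulate.with_seed(cfg.sim, cfg.seed)
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_screen(config: PipelineConfig, label: str, bundle: dict,
               outdir: str) -> dict[str, str]:
    """Run the stage chain for one screen; returns written file paths."""
    if label not in config.screens:
        raise PipelineError("config", f"unknown screen {label!r}")
    spec = config.screens[label]
    screen_dir = os.path.join(outdir, label)
    os.makedirs(screen_dir, exist_ok=True)
    written: dict[str, str] = {}

    def _save(name: str, df: pd.DataFrame, index: bool = False) -> str:
        path = os.path.join(screen_dir, name)
        io.write_tsv(df, path, index=index)
        written[name] = path
        return path

    matrix: sigmod.ExpressionMatrix = bundle["matrix"]
    db: connectivity.DrugProfileDB = bundle["db"]
    ann = bundle["annotations"]
    graph = bundle["graph"]

    # --- signature -------------------------------------------------------
    @_stage("signature")
    def _signature() -> sigmod.Signature:
        contrast = sigmod.ContrastSpec(
            positive_conditions=spec.positive, negative_conditions=spec.negative,
            fc_threshold=spec.fc_threshold, fdr_threshold=spec.fdr_threshold,
            label=label)
        probe_stats = sigmod.differential_expression(matrix, contrast)
        _save("probe_stats.tsv", probe_stats, index=True)
        gene_stats = sigmod.collapse_probes(probe_stats, matrix.probe_to_gene)
        _save("gene_stats.tsv", gene_stats, index=True)
        refs = []
        for pos, neg in spec.refinements:
            ref_contrast = sigmod.ContrastSpec(
                positive_conditions=tuple(pos), negative_conditions=tuple(neg),
                fc_threshold=spec.fc_threshold,
                fdr_threshold=spec.fdr_threshold)
            refs.append(sigmod.collapse_probes(
                sigmod.differential_expression(matrix, ref_contrast),
                matrix.probe_to_gene))
        sig = sigmod.build_signature(gene_stats, contrast, refs, label=label)
        tsv, gmt = sigmod.signature_to_frames(sig)
        _save("signature.tsv", tsv)
        gmt_path = os.path.join(screen_dir, "signature.gmt")
        io.write_gmt(gmt, gmt_path)
        written["signature.gmt"] = gmt_path
        return sig

    sig = _signature()

    # --- connectivity ----------------------------------------------------
    @_stage("connectivity")
    def _connect():
        inst = connectivity.score_instances(sig, db, scorer=config.scorer)
        _save("instance_scores.tsv", inst, index=True)
        pvals = connectivity.permutation_pvalue(
            sig, db, n_perm=config.n_perm, seed=config.seed,
            method=config.aggregation, scorer=config.scorer)
        result = connectivity.aggregate_instances(
            inst, method=config.aggregation, pvalues=pvals,
            scorer=config.scorer)
        _save("drug_scores.tsv", result.table, index=True)
        return result

    calls = _connect()

    # --- ranking ---------------------------------------------------------
    @_stage("ranking")
    def _rank():
        tsets = ranking.target_gene_sets(db, sig,
                                         p_threshold=config.target_gene_p)
        pos_rank, neg_rank = ranking.rank_drugs(tsets, calls, label=label)
        _save("ranking_positive.tsv", pos_rank.table)
        _save("ranking_negative.tsv", neg_rank.table)
        return tsets, pos_rank, neg_rank

    tsets, pos_rank, neg_rank = _rank()

    # --- annotation ------------------------------------------------------
    @_stage("annotation")
    def _annotate():
        targets_map = simulate.drug_target_map(ann["drug_targets"])
        cat_map = dict(zip(ann["protein_category"]["protein"],
                           ann["protein_category"]["category"]))
        if len(pos_rank):
            pie = annotation.classify_drug_targets(pos_rank, targets_map, cat_map)
            _save("pie_positive.tsv", pie)
        top = pos_rank.table["drug"].iloc[0] if len(pos_rank) else None
        if top is not None and tsets[top].count:
            tables = annotation.enrich_target_genes(
                tsets[top], ann["gene_sets"], config.sim.gene_names,
                fdr_threshold=spec.enrichment_fdr)
            _save("enrichment_up.tsv", tables["up"])
            _save("enrichment_down.tsv", tables["down"])
        return top

    top_drug = _annotate()

    # --- profiling -------------------------------------------------------
    @_stage("profiling")
    def _profile():
        if top_drug is None or tsets[top_drug].count < 2:
            return
        genes = list(tsets[top_drug].genes.index)
        gene_stats = io.read_tsv(written["gene_stats.tsv"], index_col=0)
        chosen_probes = gene_stats.loc[genes, "probe"]
        cond_means = matrix.condition_means()
        sub = cond_means.loc[chosen_probes]
        sub.index = genes
        result = profiling.cluster_profile(sub)
        _save("heatmap_z.tsv", result["z"], index=True)
        for axis in ("rows", "columns"):
            path = os.path.join(screen_dir, f"cluster_{axis}.nwk")
            with open(path, "w") as fh:
                fh.write(result[axis].to_newick() + "\n")
            written[f"cluster_{axis}.nwk"] = path
        _save("leaf_orders.tsv", pd.DataFrame({
            "axis": ["rows"] * len(result["rows"].leaf_order)
                    + ["columns"] * len(result["columns"].leaf_order),
            "label": result["rows"].leaf_order + result["columns"].leaf_order}))

    _profile()

    # --- network ---------------------------------------------------------
    @_stage("network")
    def _network():
        if top_drug is None:
            return
        targets = tsets[top_drug].genes
        seeds = [g for g in targets.index if g in graph]
        seeds = sorted(seeds,
                       key=lambda g: (-abs(targets.loc[g, "drug_log2_fc"]), g))
        seeds = seeds[: config.max_seeds]
        if len(seeds) < 2:
            logger.warning("screen %s: fewer than 2 target genes in the "
                           "graph; skipping network extraction", label)
            return
        sub = networks.extract_subnetwork(
            graph, seeds, cap_min=config.cap_min, cap_max=config.cap_max)
        sif_path = os.path.join(screen_dir, "subnetwork.sif")
        io.write_sif(sub.to_graph(graph), sif_path)
        written["subnetwork.sif"] = sif_path
        roles = dict(graph.nodes(data="role"))
        _save("subnetwork_nodes.tsv", pd.DataFrame(
            {"node": sorted(sub.nodes),
             "role": [roles.get(n, "") for n in sorted(sub.nodes)],
             "is_seed": [n in set(sub.seeds_in_graph)
                         for n in sorted(sub.nodes)]}))
        paths_path = os.path.join(screen_dir, "paths.json")
        payload = {f"{s}->{t}": paths for (s, t), paths
                   in sorted(sub.paths.items())}
        with open(paths_path, "w") as fh:
            json.dump({"paths": payload,
                       "below_cap_min": sub.below_cap_min,
                       "disconnected_pairs": [list(p) for p in
                                              sub.disconnected_pairs]},
                      fh, indent=1, sort_keys=True)
        written["paths.json"] = paths_path

    _network()
    return written


def run_all(config: PipelineConfig, outdir: str | os.PathLike,
            screens: list[str] | None = None) -> dict:
    """Generate inputs, run every screen, write the manifest. Returns it."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    config.sim = simulate.with_seed(config.sim, config.seed)

    try:
        bundle = simulate.generate_all(config.sim)
        input_paths = simulate.write_inputs(bundle,
                                            os.path.join(outdir, "inputs"))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc

    manifest: dict = {"seed": config.seed, "scorer": config.scorer,
                      "n_perm": config.n_perm, "files": {}}
    for path in input_paths:
        manifest["files"][os.path.relpath(path, outdir)] = _sha256(path)

    for label in screens or list(config.screens):
        written = run_screen(config, label, bundle, outdir)
        for name, path in sorted(written.items()):
            manifest["files"][os.path.relpath(path, outdir)] = _sha256(path)

    manifest["files"] = dict(sorted(manifest["files"].items()))
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["manifest_path"] = manifest_path
    return manifest
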