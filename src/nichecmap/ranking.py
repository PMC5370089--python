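"""Per-drug target genes and the target-gene-count drug ranking.

"Target genes" of a drug are the genes of the query signature that the drug
also perturbs. A gene counts as perturbed when its log2 fold changes across
the drug's instances differ from zero by a one-sample Student's t-test at
p <= 0.05 (replicates pooled); drugs are then split by the sign of their
connectivity call and, within each table, ranked by descending target-gene
count with an alphabetical tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityResult, DrugProfileDB
from .signatures import Signature, collapse_probes


class RankingError(ValueError):
    pass


@dataclass
class TargetGeneSet:
    """Intersection of a signature with the genes a drug perturbs."""

    drug: str
    genes: pd.DataFrame          # index gene; columns drug_log2_fc, direction

    @property
    def count(self) -> int:
        return len(self.genes)


@dataclass
class DrugRanking:
    """Table-1-shaped ranking: (rank, drug, n_target_genes, call)."""

    table: pd.DataFrame
    label: str = "custom"
    metadata: dict = field(default_factory=dict)

    def top(self, k: int) -> list[str]:
        return list(self.table["drug"].head(k))

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Perturbed / target genes
# ---------------------------------------------------------------------------

def derive_perturbed_genes(db: DrugProfileDB, drug: str,
                           p_threshold: float = 0.05,
                           single_instance_min_fc: float = 1.0,
                           probe_to_gene: pd.Series | None = None) -> pd.DataFrame:
    """Genes a drug perturbs: pooled fold change + one-sample t across instances.

    Returns a gene-indexed frame with ``log2_fc`` (mean over instances), ``t``,
    ``p`` and a boolean ``kept`` (p <= p_threshold). With a single instance no
    t-test exists; a |log2 FC| >= ``single_instance_min_fc`` fallback applies
    and is flagged in the ``t``/``p`` columns as NaN. When the profiles are
    probe-level, pass ``probe_to_gene`` to collapse by the biggest-|FC| rule.
    """
    inst = db.instances_of(drug)
    folds = db.fold_changes[inst]
    k = len(inst)
    if k >= 2:
        mean = folds.mean(axis=1).to_numpy()
        sd = folds.std(axis=1, ddof=1).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(k))
        t[(sd == 0) & (mean == 0)] = 0.0
        t[(sd == 0) & (mean != 0)] = np.sign(mean[(sd == 0) & (mean != 0)]) * np.inf
        p = 2 * stats.t.sf(np.abs(t), k - 1)
        table = pd.DataFrame({"log2_fc": mean, "t": t, "p": p},
                             index=folds.index)
        table["kept"] = table["p"] <= p_threshold
    else:
        table = pd.DataFrame({"log2_fc": folds.iloc[:, 0],
                              "t": np.nan, "p": np.nan}, index=folds.index)
        table["kept"] = table["log2_fc"].abs() >= single_instance_min_fc
    # perturbation must be a nonzero change, whatever the test says
    table.loc[table["log2_fc"] == 0, "kept"] = False

    if probe_to_gene is not None:
        stats_like = table.rename(columns={})
        stats_like["q"] = stats_like["p"]
        collapsed = collapse_probes(stats_like[["log2_fc", "p", "q"]],
                                    probe_to_gene)
        kept = table["kept"]
        collapsed["kept"] = [bool(kept[probe]) for probe in collapsed["probe"]]
        table = collapsed[["log2_fc", "p", "kept"]]
    table.index.name = "gene"
    return table


def derive_target_genes(perturbed: pd.DataFrame, sig: Signature,
                        drug: str = "") -> TargetGeneSet:
    """Signature genes that the drug also perturbs."""
    if len(sig) == 0:
        raise RankingError("signature is empty")
    kept = perturbed.index[perturbed["kept"]]
    common = [g for g in sig.genes if g in set(kept)]
    genes = pd.DataFrame(
        {"drug_log2_fc": perturbed.loc[common, "log2_fc"],
         "direction": sig.entries.loc[common, "direction"]},
        index=pd.Index(common, name="gene"))
    return TargetGeneSet(drug=drug, genes=genes)


def target_gene_sets(db: DrugProfileDB, sig: Signature,
                     p_threshold: float = 0.05,
                     **kwargs) -> dict[str, TargetGeneSet]:
    return {drug: derive_target_genes(
        derive_perturbed_genes(db, drug, p_threshold=p_threshold, **kwargs),
        sig, drug=drug) for drug in db.drugs}


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_drugs(target_sets: dict[str, TargetGeneSet],
               calls: ConnectivityResult,
               label: str = "custom") -> tuple[DrugRanking, DrugRanking]:
    """Positive- and negative-range rankings by descending target-gene count.

    Every drug must carry a connectivity call; null-called drugs appear in
    neither table. Ties in count are broken by drug name so the ranking is
    stable across runs.
    """
    missing = set(target_sets) - set(calls.table.index)
    if missing:
        raise RankingError(f"drugs without a connectivity call: {sorted(missing)}")

    def _build(sign: str) -> DrugRanking:
        drugs = [d for d in target_sets
                 if calls.table.loc[d, "call"] == sign]
        rows = pd.DataFrame(
            {"drug": drugs,
             "n_target_genes": [target_sets[d].count for d in drugs],
             "call": sign})
        rows = rows.sort_values(["n_target_genes", "drug"],
                                ascending=[False, True], kind="mergesort")
        rows.insert(0, "rank", np.arange(1, len(rows) + 1))
        return DrugRanking(table=rows.reset_index(drop=True), label=label)

    return _build("positive"), _build("negative")


def ranking_overlap(a: DrugRanking, b: DrugRanking, top_k: int) -> float:
    """Fraction of the top-k drug names shared by two rankings."""
    if top_k > min(len(a), len(b)):
        raise RankingError(
            f"top_k={top_k} exceeds ranking lengths ({len(a)}, {len(b)})")
    if top_k <= 0:
        raise RankingError("top_k must be positive")
    return len(set(a.top(top_k)) & set(b.top(top_k))) / top_k
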