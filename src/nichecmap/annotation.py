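"""GO-style characterization of screen hits.

Two views: (i) ranked drugs are classified by the general category of their
protein targets, yielding the pie-chart breakdown (each drug contributes to
exactly one slice, via its highest-priority target); (ii) the target genes of
a selected drug are tested for category over-representation with a one-sided
hypergeometric test, BH-corrected across categories, separately for up- and
down-regulated genes.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ranking import DrugRanking, TargetGeneSet

UNCHARACTERIZED = "uncharacterized"


class AnnotationError(ValueError):
    pass


def classify_drug_targets(ranking: DrugRanking,
                          drug_targets: Mapping[str, Sequence[str]],
                          target_category: Mapping[str, str]) -> pd.DataFrame:
    """Pie-chart breakdown of a ranking by protein-target category.

    Each drug counts once, toward the category of its highest-priority target
    (priority = the order targets appear in the input table); drugs with no
    mapped target fall into ``uncharacterized``. Rows are ordered by
    descending drug count, category name breaking ties; percentages are over
    all categorized drugs and sum to 100.
    """
    assigned = []
    for drug in ranking.table["drug"]:
        category = UNCHARACTERIZED
        for target in drug_targets.get(drug, ()):
            if target in target_category:
                category = target_category[target]
                break
        assigned.append(category)
    counts = pd.Series(assigned).value_counts()
    rows = (counts.rename_axis("category").reset_index(name="n_drugs")
            .sort_values(["n_drugs", "category"], ascending=[False, True],
                         kind="mergesort").reset_index(drop=True))
    rows["percentage"] = 100.0 * rows["n_drugs"] / rows["n_drugs"].sum()
    return rows


def enrich_categories(genes: Iterable[str],
                      gene_sets: Mapping[str, Iterable[str]],
                      universe: Iterable[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query gene list.

    For each category of size K within a universe of size N, with a query of
    size n and overlap k, p = P[X >= k] for X ~ Hypergeom(N, K, n). BH
    adjustment runs across categories; rows sort by p ascending with a
    category-name tie-break.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    query = [g for g in dict.fromkeys(genes)]
    if not query:
        raise AnnotationError("empty query gene list")
    stray = [g for g in query if g not in uni]
    if stray:
        raise AnnotationError(
            f"query genes outside the universe: {sorted(stray)[:5]}")
    n = len(query)
    N = len(universe)
    qset = set(query)

    rows = []
    for category in gene_sets:
        members = set(gene_sets[category]) & uni
        K = len(members)
        k = len(members & qset)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"category": category, "overlap": k, "category_size": K,
                     "universe_size": N, "query_size": n, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table = table.sort_values(["p", "category"], kind="mergesort")
    return table.reset_index(drop=True)


def enrich_target_genes(targets: TargetGeneSet,
                        gene_sets: Mapping[str, Iterable[str]],
                        universe: Iterable[str],
                        fdr_threshold: float = 0.02) -> dict[str, pd.DataFrame]:
    """Separate up-/down-regulated enrichment tables for a drug's target genes.

    Direction is the signature direction of each target gene. Each table
    carries a ``passes_fdr`` column at the requested threshold (2% or 1% in
    the screens this mirrors). Directions with no genes yield empty tables.
    """
    out: dict[str, pd.DataFrame] = {}
    for name, sign in (("up", 1), ("down", -1)):
        sub = list(targets.genes.index[targets.genes["direction"] == sign])
        if not sub:
            out[name] = pd.DataFrame(
                columns=["category", "overlap", "category_size",
                         "universe_size", "query_size", "p", "q", "passes_fdr"])
            continue
        table = enrich_categories(sub, gene_sets, universe)
        table["passes_fdr"] = table["q"] < fdr_threshold
        out[name] = table
    return out
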