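"""Connectivity scoring of a directional signature against drug profiles.

The reference database stores, per drug instance, a full ranking of the gene
universe (rank 1 = most up-regulated) and matching log2 fold changes. Two
scorers are provided:

* the classic two-sided Kolmogorov-Smirnov running-sum connectivity score
  (default): a signed KS statistic is computed separately for the up- and
  down-set of the signature against the instance ranking, and the combined
  score is ks_up - ks_down when the two statistics have opposite signs and 0
  otherwise, so it lies in [-2, 2] before normalization;
* a correlation score: Pearson correlation between the signature's +1/-1
  direction vector and the instance fold changes over the gene intersection.

Instance scores are aggregated per drug (mean by default), normalized by the
maximum absolute aggregate so drug scores lie in [-1, 1], and calibrated by a
permutation null of random signatures with identical up/down sizes.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import Signature

logger = logging.getLogger(__name__)


class ConnectivityError(ValueError):
    """Raised when a signature cannot be scored against an instance."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class DrugProfileDB:
    """Per-instance gene rank and fold-change profiles with drug metadata."""

    ranks: pd.DataFrame            # gene x instance, each column a permutation of 1..n
    fold_changes: pd.DataFrame     # gene x instance, log2 scale
    instances: pd.DataFrame        # index instance id; columns drug, ...

    def __post_init__(self) -> None:
        n = self.ranks.shape[0]
        expected = np.arange(1, n + 1)
        for col in self.ranks.columns:
            if not np.array_equal(np.sort(self.ranks[col].to_numpy()), expected):
                raise ConnectivityError(
                    f"instance {col!r}: ranks are not a permutation of 1..{n}")
        if set(self.ranks.columns) != set(self.instances.index):
            raise ConnectivityError("rank columns and instance metadata disagree")

    @property
    def gene_universe(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def drugs(self) -> list[str]:
        return list(dict.fromkeys(self.instances["drug"]))

    def instances_of(self, drug: str) -> list[str]:
        ids = list(self.instances.index[self.instances["drug"] == drug])
        if not ids:
            raise ConnectivityError(f"unknown drug {drug!r}")
        return ids


@dataclass
class InstanceScore:
    instance_id: str
    ks_up: float = 0.0
    ks_down: float = 0.0
    combined: float = 0.0
    correlation: float | None = None
    correlation_p: float | None = None
    one_sided: bool = False
    n_dropped: int = 0


@dataclass
class ConnectivityResult:
    """Per-drug aggregated connectivity with calls and optional permutation p."""

    table: pd.DataFrame            # index drug; score, n_instances, call[, p]
    scorer: str = "ks"
    method: str = "mean"
    norm_constant: float = 1.0     # divisor used for [-1, 1] normalization
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# KS running-sum statistic
# ---------------------------------------------------------------------------

def _ks_many(positions: np.ndarray, n: int) -> np.ndarray:
    """Signed two-sided KS statistic for each row of tag positions.

    ``positions`` is (m, t): for each of m cases the 1-based ranks of the t
    tag genes, sorted ascending within the row. With V(j) the j-th ordered
    position, a = max_j(j/t - V(j)/n) and b = max_j(V(j)/n - (j-1)/t); the
    statistic is a when a > b and -b otherwise.
    """
    positions = np.asarray(positions, dtype=float)
    m, t = positions.shape
    j = np.arange(1, t + 1, dtype=float)
    a = (j / t - positions / n).max(axis=1)
    b = (positions / n - (j - 1) / t).max(axis=1)
    return np.where(a > b, a, -b)


def _ks_one(positions: np.ndarray, n: int) -> float:
    return float(_ks_many(np.sort(np.asarray(positions))[None, :], n)[0])


def _combine(ks_up: np.ndarray, ks_down: np.ndarray) -> np.ndarray:
    """ks_up - ks_down where the signs differ, else 0."""
    diff_sign = np.sign(ks_up) * np.sign(ks_down) < 0
    return np.where(diff_sign, ks_up - ks_down, 0.0)


def ks_connectivity_score(sig: Signature, instance_ranks: pd.Series,
                          instance_id: str = "") -> InstanceScore:
    """Two-sided KS connectivity of a signature against one instance ranking."""
    n = len(instance_ranks)
    up = [g for g in sig.up_genes if g in instance_ranks.index]
    down = [g for g in sig.down_genes if g in instance_ranks.index]
    n_dropped = len(sig) - len(up) - len(down)
    if n_dropped:
        logger.warning("instance %s: dropped %d signature gene(s) absent from "
                       "the universe", instance_id, n_dropped)
    if not up and not down:
        raise ConnectivityError(
            f"instance {instance_id!r}: no signature gene in the universe")

    ks_up = _ks_one(instance_ranks[up].to_numpy(), n) if up else 0.0
    ks_down = _ks_one(instance_ranks[down].to_numpy(), n) if down else 0.0
    one_sided = not up or not down
    if one_sided:
        combined = ks_up if up else -ks_down
        logger.warning("instance %s: one-sided signature, combined score uses "
                       "the populated side only", instance_id)
    else:
        combined = float(_combine(np.array([ks_up]), np.array([ks_down]))[0])
    return InstanceScore(instance_id=instance_id, ks_up=ks_up, ks_down=ks_down,
                         combined=combined, one_sided=one_sided,
                         n_dropped=n_dropped)


def correlation_connectivity_score(sig: Signature, instance_folds: pd.Series,
                                   instance_id: str = "") -> InstanceScore:
    """Pearson correlation of the +1/-1 direction vector with fold changes."""
    common = [g for g in sig.genes if g in instance_folds.index]
    n_dropped = len(sig) - len(common)
    if len(common) < 3:
        raise ConnectivityError(
            f"instance {instance_id!r}: only {len(common)} overlapping gene(s); "
            "need at least 3")
    direction = sig.entries.loc[common, "direction"].to_numpy(dtype=float)
    folds = instance_folds[common].to_numpy(dtype=float)
    if np.ptp(folds) == 0 or np.ptp(direction) == 0:
        return InstanceScore(instance_id=instance_id, correlation=np.nan,
                             correlation_p=np.nan, combined=np.nan,
                             n_dropped=n_dropped)
    r, p = stats.pearsonr(direction, folds)
    return InstanceScore(instance_id=instance_id, correlation=float(r),
                         correlation_p=float(p), combined=float(r),
                         n_dropped=n_dropped)


def score_instances(sig: Signature, db: DrugProfileDB,
                    scorer: str = "ks") -> pd.DataFrame:
    """Score every instance of the database; returns an instance-level table."""
    rows = []
    for iid in db.ranks.columns:
        if scorer == "ks":
            s = ks_connectivity_score(sig, db.ranks[iid], iid)
        elif scorer == "corr":
            s = correlation_connectivity_score(sig, db.fold_changes[iid], iid)
        else:
            raise ConnectivityError(f"unknown scorer {scorer!r}")
        rows.append({"instance_id": iid, "drug": db.instances.loc[iid, "drug"],
                     "ks_up": s.ks_up, "ks_down": s.ks_down,
                     "combined": s.combined, "correlation": s.correlation,
                     "one_sided": s.one_sided})
    return pd.DataFrame(rows).set_index("instance_id")


# ---------------------------------------------------------------------------
# Aggregation and permutation null
# ---------------------------------------------------------------------------

def aggregate_instances(instance_scores: pd.DataFrame, method: str = "mean",
                        magnitude_floor: float = 0.0,
                        pvalues: pd.Series | None = None,
                        scorer: str = "ks") -> ConnectivityResult:
    """Aggregate instance scores to drugs and normalize into [-1, 1].

    Default aggregate is the mean of combined scores over a drug's instances
    (median by option); the normalized score divides by the maximum absolute
    aggregate over drugs. A drug is called positive/negative when its
    normalized score magnitude exceeds ``magnitude_floor``, else null.
    NaN instance scores (undefined correlations) aggregate to a null call.
    """
    if method not in ("mean", "median"):
        raise ConnectivityError(f"unknown aggregation method {method!r}")
    grouped = instance_scores.groupby("drug")["combined"]
    agg = grouped.mean() if method == "mean" else grouped.median()
    n_inst = grouped.size()
    max_abs = float(np.nanmax(np.abs(agg.to_numpy()))) if len(agg) else 1.0
    norm = max_abs if max_abs > 0 else 1.0
    score = agg / norm
    call = pd.Series("null", index=score.index)
    call[score > magnitude_floor] = "positive"
    call[score < -magnitude_floor] = "negative"
    call[score.isna()] = "null"
    table = pd.DataFrame({"score": score.fillna(0.0), "n_instances": n_inst,
                          "call": call})
    if pvalues is not None:
        table["p"] = pvalues.reindex(table.index)
    table = table.sort_index()
    return ConnectivityResult(table=table, scorer=scorer, method=method,
                              norm_constant=norm)


def _drug_rng(seed: int, drug: str) -> np.random.Generator:
    # CRC of the drug name keeps per-drug streams stable under reordering.
    return np.random.default_rng([seed, zlib.crc32(drug.encode())])


def permutation_pvalue(sig: Signature, db: DrugProfileDB, n_perm: int = 200,
                       seed: int = 0, method: str = "mean",
                       scorer: str = "ks",
                       tie_break: str = "random") -> pd.Series:
    """Per-drug permutation p-values from size-matched random signatures.

    For each drug, ``n_perm`` random signatures with the same up/down sizes
    are drawn from the gene universe and rescored against the drug's
    instances; p = (1 + #{|null| >= |observed|}) / (n_perm + 1). Each drug has
    its own seeded stream derived from (seed, drug name) so p-values do not
    depend on drug order.

    The combined KS statistic has an atom at exactly 0 (same-sign rule), so
    null and observed scores can tie with appreciable probability. With
    ``tie_break='random'`` (default) tied null scores are split by a seeded
    draw — the classic randomized-rank construction, which makes null
    p-values exactly uniform on the permutation grid and coincides with the
    plain formula whenever no tie occurs. ``tie_break='conservative'`` counts
    every tie against the observed score (so a drug whose observed score is 0
    gets p = 1).
    """
    if n_perm < 100:
        raise ConnectivityError("n_perm must be at least 100")
    if tie_break not in ("random", "conservative"):
        raise ConnectivityError(f"unknown tie_break {tie_break!r}")
    observed = aggregate_instances(score_instances(sig, db, scorer=scorer),
                                   method=method)
    # observed aggregate on the unnormalized scale for |null| >= |obs|
    obs_raw = observed.table["score"] * observed.norm_constant

    universe = db.gene_universe
    n = len(universe)
    up_idx = pd.Index(universe).get_indexer([g for g in sig.up_genes
                                             if g in db.ranks.index])
    dn_idx = pd.Index(universe).get_indexer([g for g in sig.down_genes
                                             if g in db.ranks.index])
    t_up, t_dn = len(up_idx), len(dn_idx)
    if t_up + t_dn == 0:
        raise ConnectivityError("no signature gene in the database universe")

    pvals = {}
    for drug in db.drugs:
        rng = _drug_rng(seed, drug)
        # n_perm random signatures: first t_up indices as up-set, next t_dn as down
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        perm_up = order[:, :t_up]
        perm_dn = order[:, t_up:t_up + t_dn]
        inst_ids = db.instances_of(drug)
        null_combined = np.zeros((n_perm, len(inst_ids)))
        for k, iid in enumerate(inst_ids):
            ranks = db.ranks[iid].to_numpy()
            if scorer == "ks":
                ks_u = (_ks_many(np.sort(ranks[perm_up], axis=1), n)
                        if t_up else np.zeros(n_perm))
                ks_d = (_ks_many(np.sort(ranks[perm_dn], axis=1), n)
                        if t_dn else np.zeros(n_perm))
                if t_up and t_dn:
                    null_combined[:, k] = _combine(ks_u, ks_d)
                else:
                    null_combined[:, k] = ks_u if t_up else -ks_d
            else:
                folds = db.fold_changes[iid].to_numpy()
                direction = np.concatenate(
                    [np.ones(t_up), -np.ones(t_dn)])
                idx = np.concatenate([perm_up, perm_dn], axis=1)
                x = folds[idx]                       # (n_perm, t)
                xc = x - x.mean(axis=1, keepdims=True)
                dc = direction - direction.mean()
                denom = np.sqrt((xc ** 2).sum(axis=1) * (dc ** 2).sum())
                with np.errstate(invalid="ignore", divide="ignore"):
                    null_combined[:, k] = (xc @ dc) / denom
        null_agg = (np.nanmean(null_combined, axis=1) if method == "mean"
                    else np.nanmedian(null_combined, axis=1))
        obs = abs(obs_raw[drug])
        greater = int(np.sum(np.abs(null_agg) > obs))
        ties = int(np.sum(np.abs(null_agg) == obs))
        if tie_break == "conservative":
            exceed = greater + ties
        else:
            exceed = greater + int(rng.integers(0, ties + 1))
        pvals[drug] = (1 + exceed) / (n_perm + 1)
    return pd.Series(pvals, name="p").sort_index()
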