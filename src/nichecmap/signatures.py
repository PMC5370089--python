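"""Differential expression and directional signature construction.

A signature here is the query object of a connectivity screen: the set of
gene symbols enriched in a "positive range" of conditions (e.g. dorsal
NSCs/TAPs) relative to a "negative range", each carrying a +1/-1 direction.
The module runs a per-probe pooled-variance two-sample t-test across the two
condition groups, controls the FDR by Benjamini-Hochberg, collapses probes to
genes by the biggest-absolute-fold-change rule, applies a linear fold-change
plus FDR filter (defaults 1.8-fold, FDR < 5%), and optionally removes genes
that are not specific to the positive range because they also pass in a
refinement contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class SignatureError(ValueError):
    """Raised for contrasts or signatures that cannot be used downstream."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2 probe x sample expression with probe->gene and sample->condition maps.

    The matrix is assumed already normalized (RMA-style); values are log2
    intensities. Probes without a gene symbol may carry NaN/None in
    ``probe_to_gene`` and are dropped at the collapsing step.
    """

    values: pd.DataFrame                    # probes x samples
    probe_to_gene: pd.Series                # probe -> gene symbol (may be NaN)
    sample_to_condition: pd.Series          # sample -> condition label

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise SignatureError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            raise SignatureError("duplicate probe ids in expression matrix")
        missing = set(self.values.columns) - set(self.sample_to_condition.index)
        if missing:
            raise SignatureError(f"samples without condition labels: {sorted(missing)}")

    def samples_for(self, conditions) -> list[str]:
        conditions = set(conditions)
        return [s for s in self.values.columns
                if self.sample_to_condition[s] in conditions]

    def condition_means(self, conditions=None) -> pd.DataFrame:
        """Per-condition mean expression (probes x conditions)."""
        conds = list(conditions) if conditions is not None else list(
            dict.fromkeys(self.sample_to_condition[self.values.columns]))
        return pd.DataFrame(
            {c: self.values[self.samples_for([c])].mean(axis=1) for c in conds})


@dataclass
class ContrastSpec:
    """A positive-range vs negative-range comparison with its thresholds."""

    positive_conditions: tuple[str, ...]
    negative_conditions: tuple[str, ...]
    fc_threshold: float = 1.8           # linear fold change
    fdr_threshold: float = 0.05
    label: str = ""

    def __post_init__(self) -> None:
        pos, neg = set(self.positive_conditions), set(self.negative_conditions)
        if not pos or not neg:
            raise SignatureError("contrast condition sets must be non-empty")
        if pos & neg:
            raise SignatureError(f"contrast condition sets overlap: {sorted(pos & neg)}")
        if not self.fc_threshold > 1:
            raise SignatureError("fc_threshold must exceed 1 (linear scale)")
        if not 0 < self.fdr_threshold < 1:
            raise SignatureError("fdr_threshold must lie in (0, 1)")

    @property
    def log2_fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold))


@dataclass
class Signature:
    """Directional gene set: entries index by gene with a +1/-1 direction."""

    entries: pd.DataFrame               # index gene; columns direction, log2_fc
    label: str = ""
    provenance: tuple[ContrastSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.entries.index.duplicated().any():
            raise SignatureError("signature lists a gene more than once")
        if not set(self.entries["direction"]).issubset({1, -1}):
            raise SignatureError("signature directions must be +1/-1")

    @property
    def genes(self) -> list[str]:
        return list(self.entries.index)

    @property
    def up_genes(self) -> list[str]:
        return list(self.entries.index[self.entries["direction"] == 1])

    @property
    def down_genes(self) -> list[str]:
        return list(self.entries.index[self.entries["direction"] == -1])

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def differential_expression(matrix: ExpressionMatrix,
                            contrast: ContrastSpec) -> pd.DataFrame:
    """Per-probe pooled-variance two-sample t-test, positive vs negative range.

    Returns a probe-indexed frame with ``log2_fc`` (mean_pos - mean_neg),
    ``t``, two-sided ``p`` and BH-adjusted ``q``. Probes with zero variance in
    both groups and equal means get t = 0, p = 1; with unequal means the
    difference is infinitely many pooled standard errors away, so p = 0.
    """
    for cond in (*contrast.positive_conditions, *contrast.negative_conditions):
        n = len(matrix.samples_for([cond]))
        if n < 2:
            raise SignatureError(
                f"condition {cond!r} has {n} replicate(s); need at least 2")

    pos = matrix.values[matrix.samples_for(contrast.positive_conditions)].to_numpy()
    neg = matrix.values[matrix.samples_for(contrast.negative_conditions)].to_numpy()
    n1, n2 = pos.shape[1], neg.shape[1]
    diff = pos.mean(axis=1) - neg.mean(axis=1)
    ss1 = pos.var(axis=1, ddof=1) * (n1 - 1)
    ss2 = neg.var(axis=1, ddof=1) * (n2 - 1)
    dof = n1 + n2 - 2
    pooled_se = np.sqrt((ss1 + ss2) / dof * (1 / n1 + 1 / n2))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / pooled_se
    zero_se = pooled_se == 0
    t[zero_se & (diff == 0)] = 0.0
    t[zero_se & (diff != 0)] = np.sign(diff[zero_se & (diff != 0)]) * np.inf
    p = 2 * stats.t.sf(np.abs(t), dof)
    q = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {"log2_fc": diff, "t": t, "p": p, "q": q}, index=matrix.values.index)


def passes_filter(stats_df: pd.DataFrame, contrast: ContrastSpec) -> pd.Series:
    """Boolean mask: linear |FC| >= fc_threshold AND q < fdr_threshold."""
    return (stats_df["log2_fc"].abs() >= contrast.log2_fc_threshold) & \
        (stats_df["q"] < contrast.fdr_threshold)


# ---------------------------------------------------------------------------
# Probe -> gene collapsing
# ---------------------------------------------------------------------------

def collapse_probes(probe_stats: pd.DataFrame,
                    probe_to_gene: pd.Series) -> pd.DataFrame:
    """Keep, per gene, the probe with the biggest absolute fold change.

    Ties broken by smaller p, then lexicographic probe id. Probes without a
    gene annotation are dropped. Returns a gene-indexed frame with columns
    ``probe``, ``log2_fc``, ``p``, ``q``.
    """
    df = probe_stats.copy()
    df["gene"] = probe_to_gene.reindex(df.index)
    df = df.dropna(subset=["gene"])
    df = df.reset_index(names="probe")
    df["_abs_fc"] = df["log2_fc"].abs()
    df = df.sort_values(["gene", "_abs_fc", "p", "probe"],
                        ascending=[True, False, True, True], kind="mergesort")
    best = df.drop_duplicates("gene", keep="first").set_index("gene")
    return best[["probe", "log2_fc", "p", "q"]].sort_index()


# ---------------------------------------------------------------------------
# Signature construction
# ---------------------------------------------------------------------------

def build_signature(primary: pd.DataFrame, contrast: ContrastSpec,
                    refinements: list[pd.DataFrame] | None = None,
                    label: str = "",
                    refinement_mode: str = "same-direction") -> Signature:
    """Directional signature from gene-level stats, refined for specificity.

    Genes passing the contrast's fold-change + FDR filter in ``primary`` enter
    with direction sign(log2 FC). A gene is then removed when any refinement
    gene-stats table shows it passing the same thresholds — in the same
    direction under ``refinement_mode='same-direction'`` (default), or in any
    direction under ``'any-direction'`` — i.e. it is not specific to the
    positive range. Entries are ordered by |log2 FC| descending (gene id
    breaking ties) so output is deterministic.
    """
    if refinement_mode not in ("same-direction", "any-direction"):
        raise SignatureError(f"unknown refinement mode {refinement_mode!r}")
    keep = passes_filter(primary, contrast)
    selected = primary.loc[keep].copy()
    selected["direction"] = np.sign(selected["log2_fc"]).astype(int)

    for ref in refinements or []:
        ref_pass = ref.loc[passes_filter(ref, contrast)]
        ref_dir = np.sign(ref_pass["log2_fc"]).astype(int)
        common = selected.index.intersection(ref_pass.index)
        if refinement_mode == "same-direction":
            drop = [g for g in common if ref_dir[g] == selected.loc[g, "direction"]]
        else:
            drop = list(common)
        selected = selected.drop(index=drop)

    if selected.empty:
        raise SignatureError("empty signature")

    selected["_abs_fc"] = selected["log2_fc"].abs()
    selected.index.name = "gene"
    selected = (selected.reset_index()
                .sort_values(["_abs_fc", "gene"], ascending=[False, True],
                             kind="mergesort")
                .set_index("gene"))
    return Signature(entries=selected[["direction", "log2_fc"]], label=label,
                     provenance=(contrast,))


def signature_to_frames(sig: Signature) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Signature as a (gene, direction) table and as a 2-set GMT payload."""
    tsv = sig.entries.reset_index()[["gene", "direction"]]
    gmt = {f"{sig.label or 'signature'}_UP": sig.up_genes,
           f"{sig.label or 'signature'}_DN": sig.down_genes}
    return tsv, gmt
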