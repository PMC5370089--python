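# Methods

This note documents the models, numerical conventions and design choices
behind `nichecmap`, and what the synthetic study conditions do and do not
establish about real data.

## Differential expression and signatures

Per-probe testing uses the two-sample Student's *t*-test with pooled
variance (not Welch), two-sided, across all samples of the positive versus
negative condition groups. Degenerate probes are given explicit conventions:
zero pooled variance with equal group means yields t = 0, p = 1; zero pooled
variance with unequal means yields t = ±∞, p = 0. Multiple testing is
controlled by Benjamini–Hochberg over all tested probes (q is therefore
monotone in p and never smaller than p).

A probe passes the signature filter when both |FC| ≥ the linear fold-change
threshold (default 1.8; the morphogen-style filter uses 1.65, i.e.
|log2 FC| ≥ log2 1.8 ≈ 0.847) and q < the FDR threshold (default 0.05).
Probes collapse to genes by the biggest **absolute** log2 fold change; ties
break by smaller p, then lexicographic probe id, so the chosen probe is a
deterministic function of the input. The absolute-value reading is required
for directional signatures (a signed maximum would systematically discard
down-regulated genes); a signed variant would be a one-line change but is
deliberately not offered.

Refinement removes a gene from the signature when any refinement gene-stats
table shows it passing the same thresholds in the same direction — i.e. the
gene is not specific to the positive range. The stricter any-direction
exclusion is available (`refinement_mode="any-direction"`). Signature
entries are ordered by |log2 FC| descending with a gene-id tie-break;
an empty signature is an error because an empty query is meaningless
downstream.

## Connectivity scoring

The default scorer is the classic two-sided KS running-sum connectivity
statistic, evaluated separately on the signature's up- and down-set against
each instance's ranking of the full gene universe (rank 1 = most
up-regulated): with t tag genes at ordered ranks V(j) in a universe of n,
a = max_j(j/t − V(j)/n), b = max_j(V(j)/n − (j−1)/t), ks = a if a > b else
−b, and combined = ks_up − ks_down when the signs differ, else 0. The
combined score lies in [−2, 2]; swapping the up- and down-sets exactly
negates it. Signature genes absent from an instance's universe are dropped
per instance with a logged count; an empty side makes the score one-sided
(flagged), and a signature entirely absent from the universe is an error.

The correlation scorer is the Pearson correlation between the signature's
±1 direction vector and the instance's log2 fold changes over the gene
intersection (≥ 3 genes required; zero-variance fold vectors are reported
as undefined/null). It mirrors regression-style profile matching and serves
as an independent second route in tests; both scorers ship because the
screen's behaviour should not hinge on one statistic.

Instance scores aggregate per drug by the mean (median by option), then all
drug aggregates are divided by the maximum absolute aggregate so scores lie
in [−1, 1] with exactly one drug at magnitude 1. Calls are positive/negative
by sign above a configurable magnitude floor (default 0: only an exactly
zero score is null).

### Permutation null and tie handling

Per-drug p-values come from rescoring n_perm (default 200, minimum 100)
random signatures with the same up/down sizes, drawn from the gene universe:
p = (1 + #exceed) / (n_perm + 1). Each drug draws from its own RNG stream
derived from (seed, CRC32 of the drug name), so p-values are independent of
drug order and of which other drugs are present.

The combined KS statistic has a genuine atom at exactly 0 (the same-sign
rule): for a 3-instance drug roughly (1/2)³ of null aggregates are exactly
zero. Counting these ties with the "≥" convention would pile ~12% of null
drugs at p = 1 and destroy the uniformity of null p-values. The default
therefore splits ties by a seeded randomized rank (the classic randomized
p-value construction), which is exactly uniform on the permutation grid
under exchangeability and coincides with the plain formula whenever no tie
occurs. `tie_break="conservative"` restores the strict "≥" convention
(a drug with observed score 0 then gets p = 1 by construction).

## Target genes and ranking

A gene counts as perturbed by a drug when the one-sample Student's *t*-test
of its per-instance log2 fold changes against 0 gives p ≤ 0.05 (replicates
pooled into the mean fold change that is reported). A gene with identically
zero fold change is never kept. With a single instance no test exists; a
flagged |log2 FC| ≥ 1 fallback applies. Probe-level profiles collapse by the
same biggest-|FC| rule as the expression side. Target genes are the
intersection of the perturbed set with the query signature; the per-drug
count is the ranking statistic. Rankings are per call sign, sorted by count
descending with an alphabetical tie-break, ranks consecutive from 1; the
overlap of two screens is |top-k name intersection| / k.

The count reported is |perturbed ∩ signature| (the target-gene definition);
the total perturbed-gene count is available from the perturbation table for
anyone who prefers the broader reading.

## Annotation

Drug pies: each drug contributes once, to the category of its
highest-priority protein target (priority = order in the input table);
drugs with no mapped target fall into `uncharacterized`. Percentages are
over all classified drugs and sum to 100; rows order by descending count
with an alphabetical tie-break. Enrichment of target genes (split by
signature direction) uses the one-sided hypergeometric tail
P[X ≥ k] with BH across categories — a standard over-representation test
substituted for proprietary network-statistic implementations, and
documented as such. Default FDR thresholds are 2% (up/down pathway tables)
and 1% for the rejuvenation screen.

## Clustering

Rows (genes) are z-scored (population sd; constant rows become all-zero and
are flagged). Both axes cluster agglomeratively with 1 − Pearson distance
and average linkage (complete linkage and Euclidean distance by flag).
The agglomeration is implemented in-package because deterministic
tie-breaking is part of the contract: among equidistant cluster pairs the
lexicographically smallest (id, id) pair merges first (ids follow the scipy
convention: originals 0..n−1, merge m creates id n+m). Distances update by
the Lance–Williams recurrences; average linkage is reducible, so merge
heights are non-decreasing. Leaf order follows the tighter-cluster-first
recursion (child with the smaller own merge height first, ids breaking
ties). Dendrograms export as Newick with branch lengths equal to height
differences.

## Networks

Dijkstra's algorithm (via networkx, all tied predecessors retained) gives
exact shortest distances over non-negative edge weights (unweighted graphs
get unit weights; negative weights are rejected). The subnetwork connecting
seed genes is the union of all tied shortest paths between ordered seed
pairs, added in ascending exact-path-length strata while the node union
stays within cap_max (default 80); a stratum is added whole or not at all,
which makes the extract order-independent and monotone in the cap (the node
set at cap 70 is a subset of the one at cap 80). A union below cap_min
(default 70) is returned as-is with a flag; disconnected seed pairs are
reported, never silently dropped. The optional signaling-to-transcription
filter keeps only seed pairs from {ligand, receptor, kinase} roles to
{transcription-factor, target-gene} roles.

## Synthetic study conditions

The generator emulates the statistical structure of an RMA-normalized
germinal-zone compendium plus a rank-based drug-perturbation database:

- **Conditions**: dNSC, dTAP, lNSC, lTAP, dorsal/lateral niche tissue
  (dSVZ, lSVZ), the oligodendrocyte lineage (OPC, imOL, mOL) and adult NSCs
  (aNSC), 3 replicates each.
- **Genes/probes**: 1,000 genes × 1–3 probes (uniform), baseline log2
  intensity N(7, 1.5²), i.i.d. Gaussian noise sd 0.25 log2 units — the
  simplest noise model consistent with RMA-normalized data.
- **Planted DE**: 150 genes per screen (dorsalization, ventralization,
  oligodendrogenesis, rejuvenation), disjoint across screens, log2 effect
  1.5 (6 × noise sd; the per-probe effect is jittered ±20% so the max-|FC|
  collapsing rule is non-trivial), 70% up / 30% down. The direction mix is
  load-bearing: a direction-pure gene set carries a constant between-gene
  pattern that per-gene z-scoring removes, leaving the column clustering
  with nothing but noise.
- **Drugs**: 200 drugs × 3 instances. Null instances get exchangeable random
  rankings. A mimic of strength s compresses the sampling scores of the
  signature's up-genes into [0, 1−s] and shifts its down-genes into [s, 1]
  (sign − swaps the roles), so rank displacement — and hence the expected KS
  score — is monotone in s, with full separation at s = 1. Fold changes are
  a scaled normal quantile of the rank plus small noise, hence consistent
  with the ranking. 5 mimic drugs per screen at strength 0.9 by default
  (0.75 in the spiked-recovery checks).
- **Annotations**: 6 GO-style categories partitioning both the gene universe
  (as GMT sets) and a 120-protein universe; every drug gets 1–3 prioritized
  protein targets.
- **Graph**: 150 nodes drawn from the gene universe with roles
  ligand/receptor/kinase/TF/target-gene, 450 typed directed unit-weight
  edges, no self-loops, bridged until the largest weak component covers
  ≥ 80% of nodes.

Every generator draws from its own RNG stream derived from the master seed
by a fixed offset, so generators are pure functions of (config, seed) and
adding one never perturbs another's output.

**What this does not show.** The generator has no batch effects, no
array-platform quirks, no probe cross-hybridization, no cell-line or dose
structure in the drug database (the real reference averages over both), no
correlated noise between genes, and category assignments are random rather
than biologically coherent. Passing tests therefore demonstrate the
correctness and calibration of the statistics on data with the declared
structure, not screen performance on real compendia, where effect sizes are
smaller, noise is structured and signatures are far less clean.

## Problem sizes

Defaults were chosen so a full four-screen pipeline run (including
200-permutation calibration for every drug) completes in well under a minute
on one CPU, while keeping the regimes of interest non-trivial: 1,000 genes
is enough for rank-based scores to concentrate, 200 drugs × 3 instances
exercises aggregation and calibration, and a 150-node graph with 70–80-node
caps makes the stratum rule bind. The null-calibration check uses a
300-gene, 500-drug database so the p-value histogram is informative without
dominating the runtime.

## Known limitations

- The pipeline orchestrator (`run_all`) always generates its inputs from the
  simulator; analysis of externally supplied files goes through the
  per-stage CLI subcommands, which consume exactly the files the pipeline
  writes.
- All-shortest-path enumeration retains every tied path; on dense graphs
  with many ties this can be large (fine at the packaged sizes, worth a cap
  for very dense inputs).
- The hypergeometric enrichment treats categories independently; no
  ontology structure or hierarchical redundancy correction is applied.
- The magnitude floor for connectivity calls defaults to 0, so any nonzero
  normalized score yields a directional call; screens wanting a stricter
  null band should raise the floor.
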