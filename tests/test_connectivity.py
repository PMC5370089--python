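"""KS / correlation connectivity scores, aggregation and permutation nulls."""

import numpy as np
import pandas as pd
import pytest

import nichecmap as nc
from nichecmap.connectivity import ConnectivityError, _ks_one
from conftest import ks_oracle


def _signature(up, down=()):
    genes = list(up) + list(down)
    entries = pd.DataFrame(
        {"direction": [1] * len(up) + [-1] * len(down),
         "log2_fc": [1.0] * len(up) + [-1.0] * len(down)},
        index=pd.Index(genes, name="gene"))
    return nc.Signature(entries=entries)


def _ranks(order):
    """Series gene -> rank from a gene list ordered most-up first."""
    return pd.Series(np.arange(1, len(order) + 1), index=order)


GENES10 = [f"g{i}" for i in range(10)]


class TestKsScore:
    def test_top_up_bottom_down_matches_enumeration_oracle(self):
        sig = _signature(up=GENES10[:2], down=GENES10[8:])
        score = nc.ks_connectivity_score(sig, _ranks(GENES10))
        assert score.combined > 0
        expected_up = ks_oracle([1, 2], 10)
        expected_down = ks_oracle([9, 10], 10)
        assert score.ks_up == pytest.approx(expected_up, abs=1e-12)
        assert score.ks_down == pytest.approx(expected_down, abs=1e-12)
        assert score.combined == pytest.approx(expected_up - expected_down,
                                               abs=1e-12)

    def test_same_sign_statistics_give_zero(self):
        sig = _signature(up=GENES10[:2], down=GENES10[2:4])
        score = nc.ks_connectivity_score(sig, _ranks(GENES10))
        assert np.sign(score.ks_up) == np.sign(score.ks_down)
        assert score.combined == 0

    def test_swapping_up_and_down_negates(self):
        sig = _signature(up=GENES10[:3], down=GENES10[7:])
        swapped = _signature(up=GENES10[7:], down=GENES10[:3])
        ranks = _ranks(GENES10)
        a = nc.ks_connectivity_score(sig, ranks).combined
        b = nc.ks_connectivity_score(swapped, ranks).combined
        assert a != 0
        assert b == pytest.approx(-a, abs=1e-12)

    def test_oracle_equivalence_on_random_small_universes(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(4, 21))
            genes = [f"g{i}" for i in range(n)]
            t_up = int(rng.integers(1, max(2, n // 2)))
            t_dn = int(rng.integers(1, max(2, n // 2)))
            picked = rng.choice(n, size=t_up + t_dn, replace=False)
            sig = _signature(up=[genes[i] for i in picked[:t_up]],
                             down=[genes[i] for i in picked[t_up:]])
            ranks = pd.Series(rng.permutation(n) + 1, index=genes)
            score = nc.ks_connectivity_score(sig, ranks)
            exp_up = ks_oracle(ranks[sig.up_genes], n)
            exp_dn = ks_oracle(ranks[sig.down_genes], n)
            expected = (exp_up - exp_dn
                        if np.sign(exp_up) != np.sign(exp_dn) else 0.0)
            assert score.combined == pytest.approx(expected, abs=1e-12)

    def test_missing_genes_dropped_and_empty_side_flagged(self):
        sig = _signature(up=["g0", "absent"], down=[])
        score = nc.ks_connectivity_score(sig, _ranks(GENES10))
        assert score.n_dropped == 1
        assert score.one_sided
        assert score.combined == score.ks_up == pytest.approx(
            _ks_one(np.array([1]), 10))
        with pytest.raises(ConnectivityError, match="no signature gene"):
            nc.ks_connectivity_score(_signature(up=["absent"]), _ranks(GENES10))

    def test_relabeling_genes_leaves_scores_unchanged(self, small_db):
        sig, db = small_db["signature"], small_db["db"]
        mapping = {g: f"X_{g}" for g in db.gene_universe}
        sig2 = nc.Signature(entries=sig.entries.rename(index=mapping))
        db2 = nc.DrugProfileDB(ranks=db.ranks.rename(index=mapping),
                               fold_changes=db.fold_changes.rename(index=mapping),
                               instances=db.instances)
        a = nc.score_instances(sig, db)["combined"]
        b = nc.score_instances(sig2, db2)["combined"]
        np.testing.assert_allclose(a, b, atol=0)


class TestCorrelationScore:
    def test_identity_and_negation(self):
        sig = _signature(up=GENES10[:4], down=GENES10[4:8])
        direction = sig.entries["direction"].astype(float)
        folds = pd.Series(0.0, index=GENES10)
        folds[direction.index] = direction
        assert nc.correlation_connectivity_score(sig, folds).correlation == \
            pytest.approx(1.0)
        assert nc.correlation_connectivity_score(sig, -folds).correlation == \
            pytest.approx(-1.0)

    def test_eight_gene_fixture_matches_pearson_formula(self):
        sig = _signature(up=GENES10[:4], down=GENES10[4:8])
        rng = np.random.default_rng(2)
        folds = pd.Series(rng.normal(size=10), index=GENES10)
        score = nc.correlation_connectivity_score(sig, folds)
        x = sig.entries["direction"].to_numpy(dtype=float)
        y = folds[sig.genes].to_numpy()
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert score.correlation == pytest.approx(r, abs=1e-12)

    def test_too_few_overlapping_genes_error(self):
        sig = _signature(up=["g0"], down=["g1"])
        with pytest.raises(ConnectivityError, match="overlapping"):
            nc.correlation_connectivity_score(sig, _ranks(GENES10).astype(float))

    def test_zero_variance_folds_give_null(self):
        sig = _signature(up=GENES10[:3], down=GENES10[3:6])
        folds = pd.Series(1.0, index=GENES10)
        score = nc.correlation_connectivity_score(sig, folds)
        assert np.isnan(score.correlation)


class TestAggregation:
    def _scores(self, rows):
        return pd.DataFrame(rows, columns=["drug", "combined"]).assign(
            instance_id=lambda d: [f"i{i}" for i in range(len(d))]
        ).set_index("instance_id")

    def test_single_instance_drug(self):
        res = nc.aggregate_instances(self._scores([("a", 0.5), ("b", -1.0)]))
        assert res.table.loc["a", "score"] == pytest.approx(0.5)
        assert res.table.loc["b", "score"] == pytest.approx(-1.0)

    def test_opposite_instances_cancel_to_null(self):
        res = nc.aggregate_instances(
            self._scores([("a", 0.8), ("a", -0.8), ("b", 0.4)]))
        assert res.table.loc["a", "score"] == 0
        assert res.table.loc["a", "call"] == "null"

    def test_normalization_puts_exactly_one_drug_at_unit_magnitude(self):
        rng = np.random.default_rng(4)
        rows = [(f"d{i}", float(rng.normal())) for i in range(20)]
        res = nc.aggregate_instances(self._scores(rows))
        scores = res.table["score"]
        assert (scores.abs() <= 1 + 1e-12).all()
        assert (scores.abs() == 1).sum() == 1

    def test_median_aggregation_flag(self):
        res = nc.aggregate_instances(
            self._scores([("a", 0.1), ("a", 0.2), ("a", 0.9)]),
            method="median")
        assert res.table.loc["a", "score"] == pytest.approx(1.0)  # 0.2 / max


class TestPermutationPvalue:
    def test_lower_bound_and_reproducibility(self, small_db):
        sig, db = small_db["signature"], small_db["db"]
        p1 = nc.permutation_pvalue(sig, db, n_perm=100, seed=3)
        p2 = nc.permutation_pvalue(sig, db, n_perm=100, seed=3)
        assert (p1 >= 1 / 101 - 1e-12).all()
        assert (p1 <= 1).all()
        pd.testing.assert_series_equal(p1, p2)
        # per-drug streams: restricting the DB to one drug leaves its p intact
        drug = db.drugs[5]
        keep = db.instances_of(drug)
        sub = nc.DrugProfileDB(ranks=db.ranks[keep],
                               fold_changes=db.fold_changes[keep],
                               instances=db.instances.loc[keep])
        p_sub = nc.permutation_pvalue(sig, sub, n_perm=100, seed=3)
        assert p_sub[drug] == p1[drug]

    def test_zero_observed_score_conservative_p_is_one(self):
        # up- and down-set both at the top -> same-sign KS -> observed 0
        genes = [f"g{i}" for i in range(12)]
        sig = _signature(up=genes[:2], down=genes[2:4])
        ranks = pd.DataFrame({"i1": np.arange(1, 13)}, index=genes)
        folds = pd.DataFrame({"i1": -np.arange(12, dtype=float)}, index=genes)
        inst = pd.DataFrame({"drug": ["d"]}, index=["i1"])
        db = nc.DrugProfileDB(ranks=ranks, fold_changes=folds, instances=inst)
        p_cons = nc.permutation_pvalue(sig, db, n_perm=100, seed=0,
                                       tie_break="conservative")
        assert p_cons["d"] == 1.0
        p_rand = nc.permutation_pvalue(sig, db, n_perm=100, seed=0)
        assert 1 / 101 - 1e-12 <= p_rand["d"] <= 1.0

    def test_planted_mimics_get_smallest_pvalues(self, small_db):
        sig, db = small_db["signature"], small_db["db"]
        pvals = nc.permutation_pvalue(sig, db, n_perm=100, seed=3)
        mimics = set(small_db["mimic_truth"]["drug"])
        assert pvals[sorted(mimics)].max() == pytest.approx(1 / 101)


def test_mean_score_monotone_in_mimic_strength():
    """Expected drug score is non-decreasing in planted strength, both scorers."""
    base = nc.SimConfig(
        n_genes=60, n_drugs=12, instances_per_drug=3, seed=31,
        planted_de={"s": nc.PlantedSignal(conditions=("dNSC",), n_genes=20)},
        planted_mimics={})
    _, truth = nc.generate_compendium(base)
    sig = nc.truth_signatures(truth)["s"]
    for scorer in ("ks", "corr"):
        means = []
        for strength in (0.0, 0.25, 0.5, 0.75, 1.0):
            import dataclasses
            cfg = dataclasses.replace(
                base,
                planted_mimics={"s": nc.MimicSpec(n_drugs=12,
                                                  strength=strength)})
            db, mtruth = nc.generate_drug_db(cfg, {"s": sig})
            inst = nc.score_instances(sig, db, scorer=scorer)
            res = nc.aggregate_instances(inst, scorer=scorer)
            raw = res.table["score"] * res.norm_constant
            means.append(raw[mtruth["drug"]].mean())
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:])), \
            f"{scorer}: {means}"
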