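"""DE statistics, probe collapsing and signature construction vs oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichecmap as nc
from nichecmap.signatures import SignatureError, passes_filter
from conftest import bh_oracle, pooled_t_oracle


def _matrix_from_array(values, genes=None, conditions=("A", "A", "A", "B", "B", "B")):
    values = np.asarray(values, dtype=float)
    probes = [f"p{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return nc.ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        probe_to_gene=pd.Series(genes, index=probes),
        sample_to_condition=pd.Series(list(conditions), index=samples))


CONTRAST = nc.ContrastSpec(positive_conditions=("A",), negative_conditions=("B",))


class TestDifferentialExpression:
    def test_identical_groups_nothing_passes(self):
        rng = np.random.default_rng(0)
        block = rng.normal(7, 1, size=(10, 3))
        matrix = _matrix_from_array(np.hstack([block, block]))
        stats = nc.differential_expression(matrix, CONTRAST)
        assert (stats["log2_fc"] == 0).all()
        assert not passes_filter(stats, CONTRAST).any()

    def test_twofold_difference_passes_fc_criterion(self):
        values = np.vstack([[4.0, 4.01, 3.99, 3.0, 3.01, 2.99]])
        stats = nc.differential_expression(_matrix_from_array(values), CONTRAST)
        assert 2 ** stats["log2_fc"].iloc[0] == pytest.approx(2.0, abs=0.02)
        assert stats["log2_fc"].iloc[0] >= CONTRAST.log2_fc_threshold

    def test_twelve_probe_fixture_matches_textbook_oracle(self):
        rng = np.random.default_rng(42)
        values = rng.normal(7, 1, size=(12, 6))
        values[:4, :3] += 1.5
        matrix = _matrix_from_array(values)
        stats = nc.differential_expression(matrix, CONTRAST)
        expected = np.array([pooled_t_oracle(row[:3], row[3:]) for row in values])
        np.testing.assert_allclose(stats["t"], expected[:, 0], atol=1e-10)
        np.testing.assert_allclose(stats["p"], expected[:, 1], atol=1e-10)
        np.testing.assert_allclose(stats["q"], bh_oracle(expected[:, 1]),
                                   atol=1e-10)

    def test_zero_variance_probe_conventions(self):
        values = np.array([[5.0] * 6, [5.0, 5.0, 5.0, 4.0, 4.0, 4.0]])
        stats = nc.differential_expression(_matrix_from_array(values), CONTRAST)
        assert stats["t"].iloc[0] == 0 and stats["p"].iloc[0] == 1
        assert np.isinf(stats["t"].iloc[1]) and stats["p"].iloc[1] == 0

    def test_single_replicate_condition_named_in_error(self):
        matrix = _matrix_from_array(np.zeros((2, 4)),
                                    conditions=("A", "A", "B", "C"))
        bad = nc.ContrastSpec(positive_conditions=("A",),
                              negative_conditions=("C",))
        with pytest.raises(SignatureError, match="'C'"):
            nc.differential_expression(matrix, bad)

    def test_q_dominates_p_and_is_monotone(self, toy_de):
        matrix, _ = toy_de
        contrast = nc.ContrastSpec(positive_conditions=("dNSC", "dTAP"),
                                   negative_conditions=("lNSC", "lTAP"))
        stats = nc.differential_expression(matrix, contrast)
        assert (stats["q"] >= stats["p"] - 1e-12).all()
        ordered = stats.sort_values("p")
        assert (ordered["q"].diff().dropna() >= -1e-12).all()


class TestCollapseProbes:
    def test_single_probe_identity(self):
        stats = pd.DataFrame({"log2_fc": [1.2], "p": [0.01], "q": [0.02]},
                             index=["p0"])
        out = nc.collapse_probes(stats, pd.Series({"p0": "g"}))
        assert out.loc["g", "probe"] == "p0"
        assert out.loc["g", "log2_fc"] == 1.2

    def test_max_absolute_fc_wins(self):
        stats = pd.DataFrame({"log2_fc": [1.1, -0.4], "p": [0.5, 0.001],
                              "q": [0.5, 0.01]}, index=["pa", "pb"])
        out = nc.collapse_probes(stats, pd.Series({"pa": "g", "pb": "g"}))
        assert out.loc["g", "probe"] == "pa"

    def test_ties_break_by_p_then_probe_id(self):
        stats = pd.DataFrame(
            {"log2_fc": [1.0, -1.0, 1.0, 1.0], "p": [0.5, 0.1, 0.3, 0.3],
             "q": [0.5, 0.1, 0.3, 0.3]}, index=["pz", "pa", "pc", "pb"])
        out = nc.collapse_probes(
            stats, pd.Series({"pz": "g1", "pa": "g1", "pc": "g2", "pb": "g2"}))
        assert out.loc["g1", "probe"] == "pa"    # smaller p
        assert out.loc["g2", "probe"] == "pb"    # lexicographic

    def test_unannotated_probes_dropped(self):
        stats = pd.DataFrame({"log2_fc": [1.0, 2.0], "p": [0.1, 0.1],
                              "q": [0.1, 0.1]}, index=["pa", "pb"])
        out = nc.collapse_probes(stats,
                                 pd.Series({"pa": "g", "pb": None}))
        assert list(out.index) == ["g"]

    def test_random_fixture_matches_group_scan_oracle(self):
        rng = np.random.default_rng(3)
        probes = [f"p{i:03d}" for i in range(150)]
        genes = [f"g{i:02d}" for i in rng.integers(0, 50, size=150)]
        stats = pd.DataFrame({"log2_fc": rng.normal(size=150),
                              "p": rng.random(150)}, index=probes)
        stats["q"] = stats["p"]
        out = nc.collapse_probes(stats, pd.Series(genes, index=probes))
        by_gene = {}
        for probe, gene in zip(probes, genes):
            row = (-abs(stats.loc[probe, "log2_fc"]), stats.loc[probe, "p"], probe)
            if gene not in by_gene or row < by_gene[gene]:
                by_gene[gene] = row
        assert len(out) == len(by_gene)
        for gene, (_, _, probe) in by_gene.items():
            assert out.loc[gene, "probe"] == probe


class TestBuildSignature:
    def _stats(self, fc, q):
        df = pd.DataFrame({"log2_fc": fc, "p": q, "q": q},
                          index=pd.Index([f"g{i}" for i in range(len(fc))],
                                         name="gene"))
        df["probe"] = df.index + ".p"
        return df

    def test_no_refinement_keeps_all_passing(self):
        primary = self._stats([2.0, -1.5, 0.1], [0.001, 0.001, 0.001])
        sig = nc.build_signature(primary, CONTRAST, [])
        assert set(sig.genes) == {"g0", "g1"}
        assert sig.entries.loc["g0", "direction"] == 1
        assert sig.entries.loc["g1", "direction"] == -1
        assert sig.genes[0] == "g0"              # ordered by |FC| descending

    def test_same_direction_refinement_excludes(self):
        primary = self._stats([2.0, 1.5, -1.7], [0.001, 0.001, 0.001])
        ref = self._stats([1.9, -1.5, 0.0], [0.001, 0.001, 0.9])
        sig = nc.build_signature(primary, CONTRAST, [ref])
        # g0 passes the refinement in the same direction -> excluded;
        # g1 passes in the opposite direction -> kept; g2 untouched
        assert set(sig.genes) == {"g1", "g2"}
        sig_any = nc.build_signature(primary, CONTRAST, [ref],
                                     refinement_mode="any-direction")
        assert set(sig_any.genes) == {"g2"}
        with pytest.raises(SignatureError, match="empty"):
            nc.build_signature(self._stats([2.0], [0.001]), CONTRAST,
                               [self._stats([2.0], [0.001])])

    def test_empty_signature_raises(self):
        primary = self._stats([0.1, 0.2], [0.9, 0.9])
        with pytest.raises(SignatureError, match="empty signature"):
            nc.build_signature(primary, CONTRAST, [])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        primary = self._stats(rng.normal(scale=1.5, size=60),
                              rng.random(60) * 0.2)
        base = nc.ContrastSpec(positive_conditions=("A",),
                               negative_conditions=("B",),
                               fc_threshold=1.5, fdr_threshold=0.1)
        sig = set(nc.build_signature(primary, base, []).genes)
        for fc, fdr in [(1.8, 0.1), (1.5, 0.05), (2.5, 0.01)]:
            tighter = nc.ContrastSpec(positive_conditions=("A",),
                                      negative_conditions=("B",),
                                      fc_threshold=fc, fdr_threshold=fdr)
            try:
                smaller = set(nc.build_signature(primary, tighter, []).genes)
            except SignatureError:
                smaller = set()
            assert smaller <= sig

    def test_direction_matches_fold_change_sign(self, toy_de):
        matrix, _ = toy_de
        contrast = nc.ContrastSpec(
            positive_conditions=("dNSC", "dTAP"),
            negative_conditions=tuple(
                c for c in nc.simulate.DEFAULT_CONDITIONS
                if c not in ("dNSC", "dTAP")))
        genes = nc.collapse_probes(
            nc.differential_expression(matrix, contrast), matrix.probe_to_gene)
        sig = nc.build_signature(genes, contrast)
        for gene in sig.genes:
            assert sig.entries.loc[gene, "direction"] == np.sign(
                genes.loc[gene, "log2_fc"])


@settings(derandomize=True, max_examples=40)
@given(st.integers(min_value=0, max_value=10**6))
def test_de_statistics_match_oracles_on_random_matrices(seed):
    """t, p and BH-q from the DE routine equal the textbook formulas."""
    rng = np.random.default_rng(seed)
    values = rng.normal(6, 1, size=(8, 5))
    matrix = _matrix_from_array(values, conditions=("A", "A", "B", "B", "B"))
    stats = nc.differential_expression(matrix, CONTRAST)
    expected = np.array([pooled_t_oracle(row[:2], row[2:]) for row in values])
    np.testing.assert_allclose(stats["t"], expected[:, 0], atol=1e-10)
    np.testing.assert_allclose(stats["p"], expected[:, 1], atol=1e-10)
    np.testing.assert_allclose(stats["q"], bh_oracle(expected[:, 1]), atol=1e-10)
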