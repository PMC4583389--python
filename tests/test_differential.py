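"""Paired group t-tests, probe collapse, fold-change matrices, RPPA screen."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_expression
from melsyn.containers import ValidationError
from melsyn.differential import (
    collapse_probes,
    foldchange_matrix,
    line_fold_changes,
    paired_group_ttest,
    protein_cytotox_correlation,
    spearman,
)
from melsyn.grouping import GroupAssignment
from melsyn.synthetic import default_truth, generate_rppa, single_drug_effect, PLX_DOSES
from oracles import spearman_midrank_oracle


def _paired_experiment(diffs_by_probe):
    """Two-line group with 3 pairs; controls 0, treated = requested differences."""
    meta, values = [], {}
    pair_slots = [("L1", 1), ("L1", 2), ("L2", 1)]
    for line, rep in pair_slots:
        values[f"{line}_control_{rep}"] = [0.0] * len(diffs_by_probe)
        meta.append((line, "control", rep))
    for i, (line, rep) in enumerate(pair_slots):
        values[f"{line}_treated_{rep}"] = [d[i] for d in diffs_by_probe]
        meta.append((line, "treated", rep))
    expr = make_expression(values, meta, features=[f"probe{j}" for j in range(len(diffs_by_probe))])
    groups = GroupAssignment(groups=pd.Series({"L1": "G1", "L2": "G1"}))
    return expr, groups


class TestPairedTTest:
    def test_symmetric_null(self):
        expr, groups = _paired_experiment([[-1.0, 0.0, 1.0]])
        res = paired_group_ttest(expr, groups)
        assert res.loc[0, "t"] == pytest.approx(0.0)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_hand_t_value(self):
        # differences (1, 2, 3): t = 2*sqrt(3), df 2, p ~ 0.0742
        expr, groups = _paired_experiment([[1.0, 2.0, 3.0]])
        res = paired_group_ttest(expr, groups)
        assert res.loc[0, "t"] == pytest.approx(2 * np.sqrt(3))
        assert res.loc[0, "df"] == 2
        assert res.loc[0, "p"] == pytest.approx(0.0742, abs=2e-4)
        assert res.loc[0, "fold_change"] == pytest.approx(2.0)

    def test_zero_variance_nonzero_flagged_degenerate(self):
        expr, groups = _paired_experiment([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        res = paired_group_ttest(expr, groups)
        row = res[res["feature"] == "probe0"].iloc[0]
        assert row["degenerate"]
        assert 0 < row["p"] < 1e-300
        assert row["q"] <= res[res["feature"] == "probe1"].iloc[0]["q"]

    def test_unmatched_sample_rejected(self):
        expr, groups = _paired_experiment([[1.0, 2.0, 3.0]])
        broken = expr.values.drop(columns=["L2_control_1"])
        from melsyn.containers import ExpressionExperiment

        exp2 = ExpressionExperiment(values=broken, samples=expr.samples.loc[broken.columns])
        with pytest.raises(ValidationError):
            paired_group_ttest(exp2, groups)

    def test_singleton_group_excluded(self, bundle, planted_assignment):
        res = paired_group_ttest(bundle.expression, planted_assignment, q_cutoff=0.01)
        assert "CGB" not in set(res["group"])
        assert set(res["group"]) == {"CGA", "CGC", "CGD", "CGE"}

    def test_planted_effects_recovered(self, bundle, planted_assignment, truth):
        res = paired_group_ttest(bundle.expression, planted_assignment, q_cutoff=0.01)
        for group in ("CGA", "CGC"):
            sub = res[res["group"] == group].set_index("feature")
            planted = truth.de_genes[group]
            sig = set(sub.index[sub["significant"]])
            assert len(sig & set(planted)) / len(planted) >= 0.9
            # recovered fold changes carry the planted sign
            for gene, sign in list(planted.items())[:20]:
                assert np.sign(sub.loc[gene, "fold_change"]) == sign


class TestCalibrationAndPower:
    def test_null_pvalues_uniform(self):
        """Paired-test p-values are uniform on null data (KS check)."""
        from scipy import stats

        from conftest import make_null_paired_experiment

        expr, groups = make_null_paired_experiment(10000, seed=31)
        res = paired_group_ttest(expr, groups, q_cutoff=0.01)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_power_at_moderate_effect(self):
        """Planted differences of 1.0 log2 units (sd 0.3, 8 pairs) are found at 1% FDR."""
        rng = np.random.default_rng(32)
        n_features, n_true = 1000, 100
        lines = ["A", "B", "C", "D"]
        values, meta = {}, []
        effect = np.zeros(n_features)
        effect[:n_true] = 1.0
        for line in lines:
            for rep in (1, 2):
                values[f"{line}_control_{rep}"] = np.zeros(n_features)
                meta.append((line, "control", rep))
                values[f"{line}_treated_{rep}"] = effect + rng.normal(0, 0.3, n_features)
                meta.append((line, "treated", rep))
        from conftest import make_expression

        expr = make_expression(values, meta, features=[f"f{i}" for i in range(n_features)])
        groups = GroupAssignment(groups=pd.Series({ln: "G" for ln in lines}))
        res = paired_group_ttest(expr, groups, q_cutoff=0.01).set_index("feature")
        sig = res["significant"]
        sensitivity = sig.iloc[:n_true].mean()
        assert sensitivity >= 0.9


class TestCollapseProbes:
    @pytest.fixture
    def toy_table(self):
        return pd.DataFrame(
            {
                "group": "G1",
                "feature": [f"pr{i}" for i in range(6)],
                "fold_change": [1.0, -2.0, 0.5, 0.5, 3.0, 1.0],
                "t": 1.0,
                "df": 3,
                "p": [0.001, 0.01, 0.02, 0.02, 0.5, 0.9],
                "q": [0.001, 0.01, 0.02, 0.02, 0.5, 0.9],
                "degenerate": False,
                "significant": [True, True, False, False, False, False],
            }
        )

    def test_lowest_q_probe_kept(self, toy_table):
        mapping = pd.Series(
            {"pr0": "geneA", "pr1": "geneA", "pr2": "geneB", "pr3": "geneB", "pr4": "geneC", "pr5": "geneD"}
        )
        out = collapse_probes(toy_table, mapping)
        assert len(out) == 4  # one row per distinct gene
        a = out[out["gene"] == "geneA"].iloc[0]
        assert a["probe"] == "pr0" and a["q"] == 0.001

    def test_tie_broken_by_abs_fold_change_then_label(self, toy_table):
        mapping = pd.Series({f"pr{i}": "geneX" for i in range(6)})
        tied = toy_table.assign(q=0.05, p=0.05)
        out = collapse_probes(tied, mapping)
        assert out.iloc[0]["probe"] == "pr4"  # |fc| = 3 wins

    def test_single_probe_genes_pass_through(self, toy_table):
        mapping = pd.Series({f"pr{i}": f"gene{i}" for i in range(6)})
        out = collapse_probes(toy_table, mapping)
        assert len(out) == 6
        assert set(out["probe"]) == set(toy_table["feature"])

    def test_unmapped_probe_kept_under_own_label(self, toy_table):
        mapping = pd.Series({"pr0": "geneA"})
        out = collapse_probes(toy_table, mapping)
        assert "pr5" in set(out["gene"])

    def test_never_increases_significant_genes(self, bundle, planted_assignment):
        res = paired_group_ttest(bundle.expression, planted_assignment, q_cutoff=0.01)
        out = collapse_probes(res, bundle.expression.feature_to_gene)
        for g in out["group"].unique():
            n_probes = int(res.loc[(res["group"] == g), "significant"].sum())
            n_genes = int(out.loc[(out["group"] == g), "significant"].sum())
            assert n_genes <= n_probes


class TestFoldchangeMatrix:
    def test_selection_and_columns(self):
        table = pd.DataFrame(
            {
                "group": ["G1", "G2", "G1", "G2"],
                "feature": ["a", "a", "b", "b"],
                "fold_change": [1.0, 0.2, 0.1, -0.1],
                "significant": [True, False, False, False],
            }
        )
        fc, sig = foldchange_matrix(table)
        assert list(fc.index) == ["a"]  # b significant nowhere
        assert list(fc.columns) == ["G1", "G2"]
        assert fc.loc["a", "G2"] == pytest.approx(0.2)  # all groups' fold changes kept
        assert sig.loc["a", "G1"] and not sig.loc["a", "G2"]

    def test_stable_under_group_reordering(self):
        table = pd.DataFrame(
            {
                "group": ["G1", "G2", "G1", "G2"],
                "feature": ["a", "a", "b", "b"],
                "fold_change": [1.0, 0.2, 0.4, -0.1],
                "significant": [True, False, True, False],
            }
        )
        fc1, _ = foldchange_matrix(table)
        fc2, _ = foldchange_matrix(table.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(fc1, fc2)


class TestSpearman:
    def test_monotone_and_reversed(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_ties_match_midrank_oracle(self, rng):
        for _ in range(50):
            x = rng.integers(0, 5, size=8).astype(float)
            y = rng.integers(0, 5, size=8).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman(x, y) == pytest.approx(spearman_midrank_oracle(x, y), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2, 3])


class TestProteinCytotoxCorrelation:
    @pytest.fixture
    def cytotox(self):
        lines = [f"L{i}" for i in range(6)]
        return pd.DataFrame(
            {"d1": np.arange(6) * 0.1, "d2": np.arange(6) * 0.12, "d3": np.arange(6) * 0.15},
            index=lines,
        )

    def test_perfectly_anticorrelated(self, cytotox):
        fc = pd.DataFrame({ln: [-i] for i, ln in enumerate(cytotox.index)}, index=["ep1"])
        res = protein_cytotox_correlation(fc, cytotox)
        assert res.loc["ep1", "mean_rho"] == pytest.approx(-1.0)
        assert res.loc["ep1", "rank"] == 1

    def test_constant_fold_change_degenerate(self, cytotox):
        fc = pd.DataFrame(
            {ln: [0.5, -i] for i, ln in enumerate(cytotox.index)}, index=["flat", "anti"]
        )
        res = protein_cytotox_correlation(fc, cytotox)
        assert res.loc["flat", "mean_rho"] == 0.0
        assert res.loc["flat", "degenerate"]

    def test_missing_dose_rejected(self, cytotox):
        fc = pd.DataFrame({ln: [1.0] for ln in cytotox.index}, index=["ep1"])
        with pytest.raises(ValueError):
            protein_cytotox_correlation(fc, cytotox.iloc[:, :0])

    def test_planted_epitope_ranks_first_noise_free(self, truth):
        rppa = generate_rppa(truth, within_sd=1e-6, seed=3)
        fc = line_fold_changes(rppa)
        cyto = pd.DataFrame(
            {d: {ln: single_drug_effect(truth, ln, "PLX4720", d) for ln in truth.line_ids} for d in PLX_DOSES}
        )
        res = protein_cytotox_correlation(fc, cyto)
        assert res.index[0] == truth.anti_epitope
        assert res.loc[truth.anti_epitope, "rank"] == 1
        # epitopes with no planted response scatter around 0
        null_eps = [e for e in res.index if e == "EP100" or e >= "EP050"]
        assert abs(res.loc[null_eps, "mean_rho"].mean()) < 0.2
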