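"""Synthetic panel generators: determinism, noise-free recovery, round-trips."""

import numpy as np
import pandas as pd
import pytest

from melsyn import io
from melsyn.enrichment import read_gmt, write_gmt
from melsyn.synergy import bliss_expected
from melsyn.synthetic import (
    default_truth,
    generate_dose_response,
    generate_expression,
    generate_gene_sets,
    generate_ic50_table,
    generate_rppa,
    generate_variant_table,
    single_drug_effect,
)


class TestTruth:
    def test_default_panel_structure(self, truth):
        assert len(truth.line_ids) == 12
        sizes = pd.Series(truth.true_groups).value_counts()
        assert sizes.to_dict() == {"CGC": 4, "CGA": 3, "CGD": 2, "CGE": 2, "CGB": 1}
        # every line in exactly one group, non-synergistic lines at 0
        for ln in truth.line_ids:
            if truth.true_groups[ln] in ("CGA", "CGB"):
                assert truth.true_synergy[ln] == 0.0

    def test_de_blocks_disjoint(self, truth):
        seen = set()
        for genes in truth.de_genes.values():
            assert seen.isdisjoint(genes)
            seen |= set(genes)

    def test_invariant_violation_rejected(self, truth):
        from melsyn.synthetic import SyntheticPanelTruth
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(truth, true_synergy={**truth.true_synergy, "MEL01": 0.3})


class TestDoseResponse:
    def test_noise_free_combos_equal_bliss_plus_excess(self, truth):
        panel = generate_dose_response(truth, noise_sd=0.0, seed=0)
        for line in ("MEL01", "MEL05", "MEL11"):
            excess = truth.true_synergy[line]
            grid = panel.combo_means(line)
            for da in grid.index:
                for db in grid.columns:
                    ca = single_drug_effect(truth, line, "PLX4720", da)
                    cb = single_drug_effect(truth, line, "lapatinib", db)
                    assert grid.loc[da, db] == pytest.approx(bliss_expected(ca, cb) + excess, abs=1e-12)

    def test_single_curves_monotone(self, truth):
        panel = generate_dose_response(truth, noise_sd=0.0, seed=0)
        for line in truth.line_ids:
            for drug in ("PLX4720", "lapatinib"):
                vals = panel.single_means(line, drug).to_numpy()
                assert np.all(np.diff(vals) > 0)

    def test_growth_groups_generate_negative_cytotoxicity(self, truth):
        panel = generate_dose_response(truth, noise_sd=0.0, seed=0)
        assert panel.single_means("MEL11", "lapatinib").iloc[0] < 0
        assert panel.single_means("MEL09", "lapatinib").iloc[0] < 0

    def test_seeded_determinism(self, truth):
        p1 = generate_dose_response(truth, seed=42)
        p2 = generate_dose_response(truth, seed=42)
        pd.testing.assert_frame_equal(p1.data, p2.data)
        p3 = generate_dose_response(truth, seed=43)
        assert not np.allclose(p1.data["cytotoxicity"], p3.data["cytotoxicity"])

    def test_replicates_differ_only_by_noise(self, truth):
        panel = generate_dose_response(truth, noise_sd=0.0, n_reps=3, seed=0)
        spread = panel.data.groupby(["line", "dose_a", "dose_b"])["cytotoxicity"].std()
        assert np.allclose(spread, 0.0)

    def test_parameter_validation(self, truth):
        with pytest.raises(ValueError):
            generate_dose_response(truth, n_reps=0)
        with pytest.raises(ValueError):
            generate_dose_response(truth, noise_sd=-0.1)
        with pytest.raises(ValueError):
            generate_dose_response(truth, doses_a=(100.0, 50.0, 10.0))


class TestExpression:
    def test_null_generator(self, truth):
        expr = generate_expression(truth, effect_size=0.0, seed=1)
        diffs = expr.paired_differences()
        assert abs(diffs.to_numpy().mean()) < 0.01

    def test_noise_free_limit_recovers_effect(self, truth):
        expr = generate_expression(truth, effect_size=2.0, within_sd=1e-9, seed=1)
        diffs = expr.paired_differences(lines=["MEL05"])  # CGC line
        for gene, sign in list(truth.de_genes["CGC"].items())[:10]:
            assert np.allclose(diffs.loc[gene], sign * 2.0, atol=1e-6)
        # genes planted for other groups stay flat in this line
        other = next(iter(truth.de_genes["CGA"]))
        assert np.allclose(diffs.loc[other], 0.0, atol=1e-6)

    def test_hub_targets_track_hub(self, truth):
        expr = generate_expression(truth, seed=2)
        basal = expr.line_means("control")
        hub = basal.loc[truth.hub_gene]
        for target in truth.hub_targets[:15]:
            r = np.corrcoef(hub, basal.loc[target])[0, 1]
            assert abs(r) >= 0.9

    def test_too_few_genes_rejected(self, truth):
        with pytest.raises(ValueError):
            generate_expression(truth, n_genes=100)

    def test_determinism(self, truth):
        e1 = generate_expression(truth, seed=5)
        e2 = generate_expression(truth, seed=5)
        pd.testing.assert_frame_equal(e1.values, e2.values)


class TestRppa:
    def test_panel_size_and_determinism(self, truth):
        r1 = generate_rppa(truth, seed=4)
        assert r1.values.shape[0] == 132
        r2 = generate_rppa(truth, seed=4)
        pd.testing.assert_frame_equal(r1.values, r2.values)

    def test_too_few_epitopes_rejected(self, truth):
        with pytest.raises(ValueError):
            generate_rppa(truth, n_epitopes=10)


class TestVariantsGenerator:
    def test_background_only_table_has_no_group_unique_drivers(self, truth, planted_assignment):
        from melsyn.variants import filter_novel_nonsynonymous, group_unique_variants

        table = generate_variant_table(truth, seed=8)
        planted_genes = {g for g, _, _ in truth.planted_variants.values()}
        background = table[~table["gene"].isin(planted_genes | {"BRAF"})]
        out = group_unique_variants(filter_novel_nonsynonymous(background), planted_assignment)
        # chance group-unique hits vanish as lines per group grows
        multi = [g for g, genes in out.items() if len(planted_assignment.members(g)) >= 3 and genes]
        assert multi == []

    def test_determinism(self, truth):
        t1 = generate_variant_table(truth, seed=3)
        t2 = generate_variant_table(truth, seed=3)
        pd.testing.assert_frame_equal(t1, t2)


class TestGeneSets:
    def test_planted_set_beats_median_decoy(self, bundle, truth):
        from melsyn.enrichment import ora

        res = ora(set(truth.de_genes["CGC"]), bundle.gene_sets)
        planted_p = res.loc["MOTIF_CGC", "p"]
        decoys = res.loc[[s for s in res.index if s.startswith("M0")], "p"]
        assert planted_p < decoys.median()

    def test_empty_universe_rejected(self, truth):
        import dataclasses

        bare = dataclasses.replace(truth, gene_universe=())
        with pytest.raises(ValueError):
            generate_gene_sets(bare, seed=0)

    def test_determinism(self, truth):
        s1 = generate_gene_sets(truth, seed=6)
        s2 = generate_gene_sets(truth, seed=6)
        assert s1.sets == s2.sets


class TestRoundTrips:
    def test_expression_round_trip(self, tmp_path, bundle):
        io.write_expression(bundle.expression, tmp_path / "e.tsv", tmp_path / "m.tsv", tmp_path / "p.tsv")
        back = io.read_expression(tmp_path / "e.tsv", tmp_path / "m.tsv", tmp_path / "p.tsv")
        pd.testing.assert_frame_equal(back.values, bundle.expression.values)
        pd.testing.assert_frame_equal(back.samples, bundle.expression.samples)

    def test_dose_response_round_trip(self, tmp_path, bundle):
        io.write_dose_response(bundle.dose_response, tmp_path / "d.csv")
        back = io.read_dose_response(tmp_path / "d.csv")
        pd.testing.assert_frame_equal(back.data, bundle.dose_response.data[back.data.columns])

    def test_variant_tsv_round_trip(self, tmp_path, bundle):
        io.write_variants_tsv(bundle.variants, tmp_path / "v.tsv")
        back = io.read_variants_tsv(tmp_path / "v.tsv")
        pd.testing.assert_frame_equal(back, bundle.variants)

    def test_variant_vcf_round_trip(self, tmp_path, bundle):
        sub = bundle.variants.head(50)
        io.write_variants_vcf(sub, tmp_path / "v.vcf")
        back = io.read_variants_vcf(tmp_path / "v.vcf")
        lhs = sub.sort_values(["chrom", "pos"]).reset_index(drop=True)
        rhs = back.sort_values(["chrom", "pos"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(lhs, rhs[lhs.columns])

    def test_gmt_round_trip(self, tmp_path, bundle):
        write_gmt(bundle.gene_sets, tmp_path / "s.gmt")
        back = read_gmt(tmp_path / "s.gmt", universe=bundle.gene_sets.universe)
        assert back.sets == bundle.gene_sets.sets

    def test_ic50_round_trip(self, tmp_path, bundle):
        io.write_ic50(bundle.ic50, tmp_path / "i.tsv")
        back = io.read_ic50(tmp_path / "i.tsv")
        pd.testing.assert_frame_equal(back, bundle.ic50)

    def test_truth_yaml_round_trip(self, tmp_path, truth):
        io.write_truth(truth, tmp_path / "t.yaml")
        back = io.read_truth(tmp_path / "t.yaml")
        assert back.true_groups == truth.true_groups
        assert back.de_genes == truth.de_genes
        assert back.planted_variants == truth.planted_variants
        assert back.gene_universe == truth.gene_universe


class TestIc50Generator:
    def test_heterozygous_shift(self, truth):
        panel = generate_ic50_table(truth, noise_sd=0.0, seed=0)
        hom = panel[(panel["zygosity"] == "hom") & (panel.index != "MEL04")]["ic50"]
        het = panel[panel["zygosity"] == "het"]["ic50"]
        assert np.log10(het.mean() / hom.mean()) == pytest.approx(truth.true_ic50_shift, abs=0.05)

    def test_outlier_line_is_resistant(self, truth):
        panel = generate_ic50_table(truth, noise_sd=0.0, seed=0)
        assert panel.loc["MEL04", "ic50"] == panel["ic50"].max()
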