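"""Generator contracts: determinism, planted structure, calibration."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from semnetrisk import synthetic_data as synth
from semnetrisk.interactome import qc_filter, score_pairs


class TestScenarioValidation:
    def test_ld_rho_one_rejected(self):
        with pytest.raises(ValueError, match="ld_rho"):
            synth.SyntheticScenario(ld_rho=1.0)

    def test_module_larger_than_pin_rejected(self):
        with pytest.raises(ValueError):
            synth.SyntheticScenario(n_genes=50, n_risk_genes=40, module_size=30,
                                    pin_size=20)

    def test_planted_overlap_exceeding_size_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synth.PathwayParams(planted_size=10, planted_overlap=11)

    def test_contamination_rates_bounded(self):
        with pytest.raises(ValueError):
            synth.EvidenceParams(taxid_contamination=0.5, pubmed_contamination=0.6)

    def test_module_subset_of_risk_subset_of_universe(self, small_scenario):
        sc = small_scenario
        assert sc.planted_module <= sc.risk_genes <= set(sc.gene_ids)


class TestGwasGenerator:
    def test_null_pvalues_uniform(self):
        sc = synth.SyntheticScenario(
            seed=21, n_genes=400, n_risk_genes=0, module_size=0, pin_size=300,
            ld_rho=0.0, snps_per_gene=(5, 5),
        )
        gwas = synth.gen_gwas(sc)
        assert stats.kstest(gwas.snps["P"], "uniform").pvalue > 0.01

    def test_high_ld_reproduces_generating_correlation(self):
        # many two-SNP genes at rho = 0.9: sample correlation of the
        # simulated z-scores must recover the parameter within 3 SE
        sc = synth.SyntheticScenario(
            seed=8, n_genes=600, n_risk_genes=0, module_size=0, pin_size=300,
            ld_rho=0.9, snps_per_gene=(2, 2),
        )
        gwas = synth.gen_gwas(sc)
        z = np.array([gwas.snp_z[g] for g in sc.gene_ids])
        r = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
        se = (1 - 0.9**2) / np.sqrt(len(z))  # delta-method SE of Pearson r
        assert abs(r - 0.9) < 3 * se

    def test_snps_inside_flanked_windows(self, small_scenario):
        gwas = synth.gen_gwas(small_scenario, flank=50_000)
        genes = gwas.genes.set_index("gene_id")
        for gene_id, ld in gwas.ld.items():
            row = genes.loc[gene_id]
            pos = gwas.snps.set_index("SNP").loc[list(ld.snp_ids), "BP"]
            assert ((pos >= row.start - 50_000) & (pos < row.end + 50_000)).all()

    def test_ld_matrices_are_symmetric_psd_unit_diagonal(self, small_scenario):
        gwas = synth.gen_gwas(small_scenario)
        for ld in gwas.ld.values():
            assert np.allclose(ld.r, ld.r.T)
            assert np.allclose(np.diag(ld.r), 1.0)
            assert np.linalg.eigvalsh(ld.r).min() >= -1e-8

    def test_same_seed_bit_identical(self, small_scenario):
        a = synth.gen_gwas(small_scenario)
        b = synth.gen_gwas(small_scenario)
        pd.testing.assert_frame_equal(a.snps, b.snps)
        pd.testing.assert_frame_equal(a.genes, b.genes)


class TestPinGenerator:
    def test_planted_module_is_connected(self, small_scenario):
        pin = synth.gen_pin(small_scenario)
        g = nx.from_pandas_edgelist(pin, "protA", "protB")
        module = small_scenario.planted_module
        assert module <= set(g.nodes)
        assert nx.is_connected(g.subgraph(module))

    def test_full_multi_pub_fraction_survives_filter(self):
        sc = synth.SyntheticScenario(seed=4, n_genes=100, n_risk_genes=10,
                                     module_size=5, pin_size=80, frac_multi_pub=1.0)
        pin = synth.gen_pin(sc)
        assert (pin["n_pubs"] >= 2).all()

    def test_no_self_loops_or_duplicate_edges(self, small_scenario):
        pin = synth.gen_pin(small_scenario)
        assert (pin["protA"] != pin["protB"]).all()
        keys = {tuple(sorted(t)) for t in zip(pin["protA"], pin["protB"])}
        assert len(keys) == len(pin)

    def test_same_seed_bit_identical(self, small_scenario):
        pd.testing.assert_frame_equal(
            synth.gen_pin(small_scenario), synth.gen_pin(small_scenario)
        )


class TestEvidenceGenerator:
    CLEAN = synth.EvidenceParams(
        pubs_rate=0.0, methods_rate=0.0,
        taxid_contamination=0.0, pubmed_contamination=0.0, method_contamination=0.0,
    )

    def test_clean_single_evidence_scores_exactly_two(self, small_scenario):
        import dataclasses
        sc = dataclasses.replace(small_scenario, evidence=self.CLEAN)
        ev = synth.gen_evidence(sc, [("A", "B"), ("C", "D")])
        clean, _ = qc_filter(list(ev.records))
        assert len(clean) == len(ev.records)
        scored = score_pairs(clean, min_score=0)
        assert all(sp.score == 2 for sp in scored.values())
        # ...and the default cutoff discards them all
        assert score_pairs(clean) == {}

    def test_requested_counts_aggregate_exactly(self, small_scenario):
        import dataclasses
        sc = dataclasses.replace(small_scenario, evidence=self.CLEAN)
        ev = synth.gen_evidence(sc, [("A", "B")], counts={("A", "B"): (3, 2)})
        clean, _ = qc_filter(list(ev.records))
        sp = score_pairs(clean, min_score=0)[("A", "B")]
        assert (sp.n_pubs, sp.n_methods) == (3, 2)

    def test_contaminated_records_all_fail_qc(self, small_scenario):
        pairs = [(f"A{i}", f"B{i}") for i in range(60)]
        ev = synth.gen_evidence(small_scenario, pairs)
        assert ev.contaminated  # rates > 0 ⇒ some contamination at 60 pairs
        for i in ev.contaminated:
            kept, _ = qc_filter([ev.records[i]])
            assert kept == []

    def test_empty_pairs_rejected(self, small_scenario):
        with pytest.raises(ValueError):
            synth.gen_evidence(small_scenario, [])


class TestPathwayGenerator:
    def test_planted_pathway_overlap_and_size(self, small_scenario):
        ps = synth.gen_pathways(small_scenario)
        members = ps.collection.sets[ps.planted_id][1]
        assert len(members) == small_scenario.pathways.planted_size
        overlap = members & small_scenario.risk_genes
        assert len(overlap) == small_scenario.pathways.planted_overlap

    def test_universe_contains_gene_ids(self, small_scenario):
        ps = synth.gen_pathways(small_scenario)
        assert set(small_scenario.gene_ids) <= (ps.collection.universe or set())
        assert len(ps.collection.universe) == small_scenario.pathways.universe_size

    def test_class_map_covers_every_pathway(self, small_scenario):
        ps = synth.gen_pathways(small_scenario)
        assert set(ps.class_map) == set(ps.collection.sets)


class TestExpressionGenerator:
    def test_null_fraction_of_small_pvalues_calibrated(self):
        from semnetrisk.expression import fit_all

        sc = synth.SyntheticScenario(
            seed=31, n_genes=100, n_risk_genes=0, module_size=0, pin_size=80,
            expression=synth.ExpressionParams(n_genes=2_000, n_de=0),
        )
        study, truth = synth.gen_expression(sc)
        assert truth == {}
        res = fit_all(study)
        frac = (res["p_raw"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert abs(frac - 0.05) < 3 * se

    def test_covariates_complete_and_groups_sized(self, small_scenario):
        study, _ = synth.gen_expression(small_scenario)
        xp = small_scenario.expression
        assert study.covariates["status"].sum() == xp.n_cases
        assert (study.covariates["status"] == 0).sum() == xp.n_controls
        assert not study.covariates.isna().any().any()

    def test_same_seed_identical_matrix(self, small_scenario):
        a, _ = synth.gen_expression(small_scenario)
        b, _ = synth.gen_expression(small_scenario)
        pd.testing.assert_frame_equal(a.values, b.values)


def test_manifest_lists_planted_truths(small_scenario):
    man = synth.manifest(small_scenario)
    assert set(man["planted_module"]) == small_scenario.planted_module
    assert set(man["risk_genes"]) == small_scenario.risk_genes
    assert man["planted_pathway"]["id"] == "PW0001"
    assert len(man["de_genes"]) == small_scenario.expression.n_de


def test_write_all_produces_expected_files(small_scenario, tmp_path):
    paths = synth.write_all(small_scenario, tmp_path / "inputs")
    import pathlib
    for key in ("summary_stats", "gene_models", "pin", "evidence", "gmt",
                "expression", "covariates", "manifest"):
        assert pathlib.Path(paths[key]).is_file(), key
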