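"""Evidence QC, pair scoring, seed interactome, hubs and core extraction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from semnetrisk.interactome import (
    EvidenceRecord,
    build_seed_interactome,
    core_density_comparison,
    extract_core,
    harmonize,
    hub_analysis,
    qc_filter,
    read_mitab,
    score_pairs,
    write_mitab,
)


def rec(a="P1", b="P2", tax_a="9606", tax_b="9606", pubmed=("11111",),
        method="MI:0018", db="intact"):
    return EvidenceRecord(id_a=a, id_b=b, taxid_a=tax_a, taxid_b=tax_b,
                          pubmed=pubmed, method=method, source_db=db)


class TestHarmonize:
    def test_identity_mapping_keeps_records(self):
        records = [rec()]
        kept, drops = harmonize(records, {"P1": "P1", "P2": "P2"})
        assert kept == records and not drops

    def test_one_to_many_mapping_dropped(self):
        kept, drops = harmonize([rec()], {"P1": ("Q1", "Q2"), "P2": "P2"})
        assert kept == [] and drops["ambiguous"] == 1

    def test_obsolete_or_chemical_dropped(self):
        kept, drops = harmonize([rec()], {"P1": None, "P2": "P2"})
        assert kept == [] and drops["obsolete_or_nonprotein"] == 1

    def test_unmapped_dropped(self):
        kept, drops = harmonize([rec()], {"P2": "P2"})
        assert kept == [] and drops["unmapped"] == 1


class TestQcFilter:
    def test_mouse_taxid_dropped(self):
        kept, drops = qc_filter([rec(tax_a="10090")])
        assert kept == [] and drops["non_human_taxid"] == 1

    def test_multiple_pubmed_dropped(self):
        kept, drops = qc_filter([rec(pubmed=("1", "2"))])
        assert kept == [] and drops["pubmed_count"] == 1

    def test_missing_pubmed_dropped(self):
        kept, _ = qc_filter([rec(pubmed=())])
        assert kept == []

    def test_missing_method_dropped(self):
        kept, drops = qc_filter([rec(method="")])
        assert kept == [] and drops["missing_method"] == 1

    def test_clean_record_kept(self):
        kept, drops = qc_filter([rec()])
        assert len(kept) == 1 and not drops


class TestScorePairs:
    def test_single_pub_single_method_discarded(self):
        assert score_pairs([rec()]) == {}

    def test_two_pubs_one_method_kept(self):
        records = [rec(pubmed=("1",)), rec(pubmed=("2",))]
        scored = score_pairs(records)
        assert scored[("P1", "P2")].score == 3

    def test_counts_aggregate_exactly(self):
        records = [
            rec(pubmed=("1",), method="MI:0018"),
            rec(pubmed=("2",), method="MI:0006"),
            rec(pubmed=("3",), method="MI:0018"),
        ]
        sp = score_pairs(records)[("P1", "P2")]
        assert (sp.n_pubs, sp.n_methods, sp.score) == (3, 2, 5)

    def test_order_independent(self, rng):
        records = [
            rec(pubmed=(str(rng.integers(5)),), method=f"MI:{rng.integers(3)}")
            for _ in range(40)
        ]
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert score_pairs(records) == score_pairs(shuffled)

    def test_adding_evidence_never_discards_a_kept_pair(self, rng):
        records = [rec(pubmed=("1",)), rec(pubmed=("2",))]
        kept_before = set(score_pairs(records))
        for extra in (rec(pubmed=("9",)), rec(method="MI:0099"),
                      rec(a="P3", b="P4")):
            kept_after = set(score_pairs(records + [extra]))
            assert kept_before <= kept_after


def chain_pairs(*pairs):
    return {tuple(sorted(p)): _scored(*sorted(p)) for p in pairs}


def _scored(a, b):
    from semnetrisk.interactome import ScoredPair
    return ScoredPair(a=a, b=b, n_pubs=2, n_methods=1)


class TestSeedInteractome:
    def test_disconnected_seed_reported_not_dropped(self):
        pairs = chain_pairs(("S1", "X"))
        inter = build_seed_interactome(
            ["S1", "S2"], pairs, evidence_universe={"S1", "S2", "X"}
        )
        assert inter.disconnected_seeds == frozenset({"S2"})
        assert "S2" in inter.graph.nodes

    def test_seed_missing_from_universe_is_unmapped(self):
        pairs = chain_pairs(("S1", "X"))
        inter = build_seed_interactome(["S1", "GONE"], pairs,
                                       evidence_universe={"S1", "X"})
        assert inter.unmapped_seeds == frozenset({"GONE"})

    def test_shared_interactor_bridges_two_seeds(self):
        pairs = chain_pairs(("S1", "H"), ("S2", "H"))
        inter = build_seed_interactome(["S1", "S2"], pairs)
        report = hub_analysis(inter, threshold=0.15)
        assert report.bridged["H"] == 2

    def test_excluded_node_stays_in_graph_but_never_hub(self):
        pairs = chain_pairs(("S1", "UBC"), ("S2", "UBC"), ("S3", "UBC"))
        inter = build_seed_interactome(["S1", "S2", "S3"], pairs, exclusions=["UBC"])
        assert "UBC" in inter.graph.nodes
        assert inter.graph.nodes["UBC"]["excluded"]
        report = hub_analysis(inter, threshold=0.15)
        assert "UBC" not in report.iihs
        assert report.connection_degree["UBC"] == 1.0

    def test_empty_surviving_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_seed_interactome(["S1"], {})


def star_interactome(n_seeds, bridged):
    """n_seeds seeds each connected to one private node; 'hub' bridges the
    first *bridged* seeds."""
    pairs = {}
    for i in range(n_seeds):
        pairs.update(chain_pairs((f"S{i}", f"X{i}")))
    for i in range(bridged):
        pairs.update(chain_pairs((f"S{i}", "HUB")))
    return build_seed_interactome([f"S{i}" for i in range(n_seeds)], pairs)


class TestHubBoundary:
    def test_exactly_fifteen_percent_is_not_a_hub(self):
        inter = star_interactome(20, 3)   # 3/20 = 0.15
        report = hub_analysis(inter, threshold=0.15)
        assert "HUB" not in report.iihs

    def test_above_fifteen_percent_is_a_hub(self):
        inter = star_interactome(20, 4)   # 4/20 = 0.20
        report = hub_analysis(inter, threshold=0.15)
        assert "HUB" in report.iihs

    def test_seed_relabeling_leaves_iih_set_invariant(self):
        inter = star_interactome(10, 4)
        relabeled = build_seed_interactome(
            [f"S{i}" for i in reversed(range(10))],
            {p: sp for p, sp in _pairs_of(inter).items()},
        )
        a = hub_analysis(inter, threshold=0.15).iihs
        b = hub_analysis(relabeled, threshold=0.15).iihs
        assert a == b

    def test_bridged_count_double_counting_identity(self):
        inter = star_interactome(12, 5)
        report = hub_analysis(inter)
        lhs = sum(report.bridged.values())
        rhs = sum(
            len(s & set(inter.graph.nodes)) for s in inter.interactomes.values()
        )
        assert lhs == rhs


def _pairs_of(inter):
    from semnetrisk.interactome import ScoredPair
    return {
        tuple(sorted((a, b))): ScoredPair(
            a=min(a, b), b=max(a, b),
            n_pubs=d["n_pubs"], n_methods=d["n_methods"],
        )
        for a, b, d in inter.graph.edges(data=True)
    }


class TestCore:
    def test_star_core_counts(self):
        pairs = chain_pairs(*[("IIH", f"X{i}") for i in range(5)])
        inter = build_seed_interactome(["IIH"], pairs)
        core = extract_core(inter, ["IIH"])
        assert (core.n_nodes, core.n_edges) == (6, 5)
        assert core.avg_neighbors == pytest.approx(2 * 5 / 6, abs=5e-3)

    def test_overlapping_interactors_counted_once(self):
        pairs = chain_pairs(("A", "X"), ("B", "X"), ("A", "B"))
        inter = build_seed_interactome(["A", "B"], pairs)
        core = extract_core(inter, ["A", "B"])
        assert core.n_nodes == 3

    def test_induced_subgraph_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            g = nx.gnp_random_graph(25, 0.15, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, str)
            if g.number_of_edges() == 0:
                continue
            pairs = {
                tuple(sorted(e)): _scored(*sorted(e)) for e in g.edges
            }
            seeds = [str(i) for i in range(5)]
            inter = build_seed_interactome(seeds, pairs)
            iihs = list(inter.graph.nodes)[:3]
            core = extract_core(inter, iihs)
            want_nodes = set(iihs) | {
                v for h in iihs for v in inter.graph.neighbors(h)
            }
            want_edges = {
                frozenset(e)
                for e in itertools.combinations(sorted(want_nodes), 2)
                if inter.graph.has_edge(*e)
            }
            assert set(core.graph.nodes) == want_nodes
            assert {frozenset(e) for e in core.graph.edges} == want_edges

    def test_core_is_subgraph_and_superset_of_iihs(self):
        inter = star_interactome(10, 4)
        report = hub_analysis(inter)
        core = extract_core(inter, report.iihs or ["HUB"])
        assert set(core.iihs) <= set(core.graph.nodes) <= set(inter.graph.nodes)

    def test_density_comparison_validates_inputs(self):
        inter = star_interactome(5, 2)
        core = extract_core(inter, ["HUB"])
        with pytest.raises(ValueError):
            core_density_comparison(inter, core, n_samples=0)

    def test_planted_dense_core_ranks_high(self):
        # clique of 8 inside a sparse 60-node graph
        g = nx.gnp_random_graph(60, 0.03, seed=5)
        g = nx.relabel_nodes(g, str)
        clique = [str(i) for i in range(8)]
        g.add_edges_from(itertools.combinations(clique, 2))
        pairs = {tuple(sorted(e)): _scored(*sorted(e)) for e in g.edges}
        inter = build_seed_interactome(clique, pairs)
        core = extract_core(inter, clique[:3])
        pct, _ = core_density_comparison(inter, core, n_samples=500, seed=2)
        assert pct >= 99.0


def test_mitab_roundtrip(tmp_path):
    records = [
        rec(),
        rec(a="Q1", b="Q2", tax_a="10090", pubmed=("1", "2"), method="", db="mint"),
        rec(a="R1", b="R2", pubmed=()),
    ]
    path = tmp_path / "ev.mitab"
    write_mitab(records, path)
    assert read_mitab(path) == records
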