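"""End-to-end orchestration with a single config and a run manifest.

``run_all`` executes the stages in dependency order — synthetic-input
generation, gene-based association, significant-subnetwork extraction with
permutation testing, interactome construction with hub/core detection,
pathway enrichment with block retention, and differential expression —
writing every artifact under one output directory plus a ``manifest.json``
recording the config, per-file checksums, seeds and wall-clock times.

Stages checkpoint at stage granularity: a completed stage whose config
hash matches is skipped on re-run, so a failed run resumes where it
stopped. The Monte-Carlo gene test dominates runtime, which is why its
simulation staging is part of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import enrichment as enr
from . import expression as expr
from . import gene_association as ga
from . import interactome as ia
from . import network_extraction as net
from . import synthetic_data as synth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "gene_test", "network", "interactome", "enrich", "dge")


@dataclass(frozen=True)
class RunConfig:
    """All thresholds and sizes of one pipeline run.

    Every constant of the analysis is a config field so sensitivity
    analyses are one-line changes; the defaults are the standard settings
    (50 kb flank, alpha 0.05, >= 2 publications, interaction score >= 3,
    15% hub threshold, 12% retention threshold, FDR 0.05).
    """

    seed: int = 0
    out_dir: str = "runs/demo"
    flank: int = 50_000
    alpha: float = 0.05
    min_pubs: int = 2
    n_perm: int = 1_000
    min_score: int = 3
    hub_threshold: float = 0.15
    retention_threshold: float = 0.12
    enrich_alpha: float = 0.05
    fdr_alpha: float = 0.05
    sim_stages: tuple[tuple[int, float | None], ...] = ((1_000, 0.1), (10_000, 0.001), (100_000, None))
    density_samples: int = 1_000
    exclusions: tuple[str, ...] = ()
    scenario: synth.SyntheticScenario = field(default_factory=synth.SyntheticScenario)

    def __post_init__(self) -> None:
        for name, value in (
            ("alpha", self.alpha), ("hub_threshold", self.hub_threshold),
            ("retention_threshold", self.retention_threshold),
            ("enrich_alpha", self.enrich_alpha), ("fdr_alpha", self.fdr_alpha),
        ):
            if not 0 < value <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.min_pubs < 1 or self.min_score < 1:
            raise ValueError("min_pubs and min_score must be >= 1")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML key/value tree."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    scenario_raw = raw.pop("scenario", {})
    for nested, cls in (
        ("evidence", synth.EvidenceParams),
        ("pathways", synth.PathwayParams),
        ("expression", synth.ExpressionParams),
    ):
        if nested in scenario_raw:
            scenario_raw[nested] = cls(**scenario_raw[nested])
    if "snps_per_gene" in scenario_raw:
        scenario_raw["snps_per_gene"] = tuple(scenario_raw["snps_per_gene"])
    scenario = synth.SyntheticScenario(**scenario_raw)
    if "sim_stages" in raw:
        raw["sim_stages"] = tuple((int(n), t) for n, t in raw["sim_stages"])
    if "exclusions" in raw:
        raw["exclusions"] = tuple(raw["exclusions"])
    return RunConfig(scenario=scenario, **raw)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(_config_dict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.data: dict = {
            "version": __version__,
            "config": _config_dict(config),
            "config_hash": _config_hash(config),
            "stages": {},
        }
        self.out = Path(config.out_dir)

    def record(self, stage: str, outputs: dict[str, str], elapsed: float) -> None:
        self.data["stages"][stage] = {
            "outputs": {
                name: {"path": p, "sha256": _sha256(p) if Path(p).is_file() else None}
                for name, p in outputs.items()
            },
            "wall_seconds": round(elapsed, 3),
        }
        self.write()

    def write(self) -> None:
        (self.out / "manifest.json").write_text(
            json.dumps(self.data, indent=2) + "\n"
        )


def _checkpoint(out: Path, stage: str, config_hash: str) -> Path:
    return out / f".{stage}.done.{config_hash}"


def run_all(config: RunConfig, resume: bool = True) -> dict:
    """Run every stage; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    man = _Manifest(config)
    scenario = config.scenario

    def stage_done(stage: str) -> bool:
        return resume and _checkpoint(out, stage, chash).exists()

    def mark_done(stage: str) -> None:
        _checkpoint(out, stage, chash).write_text("done\n")

    # ----- simulate -------------------------------------------------------
    sim_dir = out / "synthetic"
    t0 = time.perf_counter()
    paths = synth.write_all(scenario, sim_dir, flank=config.flank)
    man.record("simulate", paths, time.perf_counter() - t0)
    mark_done("simulate")

    # ----- gene test ------------------------------------------------------
    gene_results_path = out / "gene_results.tsv"
    t0 = time.perf_counter()
    if not (stage_done("gene_test") and gene_results_path.exists()):
        snps = ga.read_summary_stats(paths["summary_stats"])
        genes = ga.read_bed(paths["gene_models"])
        ld = ga.read_ld_dir(paths["ld_dir"])
        results = ga.run_gene_tests(
            snps, genes, ld, flank=config.flank, seed=config.seed,
            stages=config.sim_stages,
        )
        ga.write_results(results, gene_results_path)
        mark_done("gene_test")
    man.record("gene_test", {"gene_results": str(gene_results_path)},
               time.perf_counter() - t0)

    gene_results = pd.read_csv(gene_results_path, sep="\t")
    gene_p = dict(zip(gene_results["gene_id"], gene_results["empirical_p"]))

    # ----- network --------------------------------------------------------
    t0 = time.perf_counter()
    edges = net.read_edge_list(paths["pin"])
    background = net.build_background(edges, min_pubs=config.min_pubs)
    subnet = net.significant_subnetwork(background, gene_p, alpha=config.alpha)
    comps = net.components(subnet)
    null = net.permutation_test(
        background, gene_p, alpha=config.alpha,
        n_perm=config.n_perm, seed=config.seed,
    )
    net_outputs = {
        "subnetwork_edges": str(out / "subnetwork.tsv"),
        "subnetwork_graphml": str(out / "subnetwork.graphml"),
        "components": str(out / "components.tsv"),
        "permutation_null": str(out / "permutation_null.tsv"),
        "permutation_summary": str(out / "permutation_summary.json"),
    }
    net.write_edge_list(subnet, net_outputs["subnetwork_edges"])
    net.write_graphml(subnet, net_outputs["subnetwork_graphml"])
    net.write_component_report(comps, net_outputs["components"])
    net.write_permutation_summary(
        null, net_outputs["permutation_null"], net_outputs["permutation_summary"]
    )
    man.record("network", net_outputs, time.perf_counter() - t0)
    mark_done("network")

    if not comps:
        raise RuntimeError(
            "no significant component found; cannot seed the interactome stage"
        )
    seeds = sorted(comps[0].members)

    # ----- interactome ----------------------------------------------------
    t0 = time.perf_counter()
    records = ia.read_mitab(paths["evidence"])
    id_map = ia.read_id_map(paths["id_map"])
    harmonized, _ = ia.harmonize(records, id_map)
    clean, _ = ia.qc_filter(harmonized)
    scored = ia.score_pairs(clean, min_score=config.min_score)
    inter = ia.build_seed_interactome(
        seeds, scored, exclusions=config.exclusions,
        evidence_universe={r.id_a for r in harmonized} | {r.id_b for r in harmonized},
    )
    hubs = ia.hub_analysis(inter, threshold=config.hub_threshold)
    if hubs.iihs:
        core = ia.extract_core(inter, hubs.iihs)
        density_pct, _ = ia.core_density_comparison(
            inter, core, n_samples=config.density_samples, seed=config.seed
        )
        core_nodes = sorted(core.graph.nodes)
    else:
        core = None
        density_pct = float("nan")
        core_nodes = []
    ia_outputs = {
        "scored_pairs": str(out / "scored_pairs.tsv"),
        "interactome_graphml": str(out / "interactome.graphml"),
        "hub_report": str(out / "hub_report.tsv"),
        "interactome_summary": str(out / "interactome_summary.json"),
    }
    ia.write_scored_pairs(scored, ia_outputs["scored_pairs"])
    net.write_graphml(inter.graph, ia_outputs["interactome_graphml"])
    ia.write_hub_report(hubs, ia_outputs["hub_report"])
    if core is not None:
        ia_outputs["core_graphml"] = str(out / "core.graphml")
        net.write_graphml(core.graph, ia_outputs["core_graphml"])
        ia.write_summary(inter, hubs, core, density_pct, config.seed,
                         ia_outputs["interactome_summary"])
    else:
        Path(ia_outputs["interactome_summary"]).write_text(
            json.dumps({"iihs": [], "note": "no IIH above threshold"}) + "\n"
        )
    man.record("interactome", ia_outputs, time.perf_counter() - t0)
    mark_done("interactome")

    # ----- enrichment + block retention ----------------------------------
    t0 = time.perf_counter()
    pathways = synth.gen_pathways(scenario)
    collection = pathways.collection
    full_res = enr.enrich(seeds, collection)
    enr_outputs = {"enrichment_full": str(out / "enrichment_full.tsv")}
    enr.write_results(full_res, enr_outputs["enrichment_full"])
    full_sig = [r.set_id for r in full_res if r.p_adj < config.enrich_alpha]
    core_in_universe = [
        n for n in core_nodes
        if collection.universe is None or n in collection.universe
    ]
    core_sig: list[str] = []
    if core_in_universe:
        core_res = enr.enrich(core_in_universe, collection)
        enr_outputs["enrichment_core"] = str(out / "enrichment_core.tsv")
        enr.write_results(core_res, enr_outputs["enrichment_core"])
        core_sig = [r.set_id for r in core_res if r.p_adj < config.enrich_alpha]
    report = enr.block_retention(
        full_sig, core_sig, pathways.class_map,
        threshold=config.retention_threshold,
    )
    enr_outputs["block_retention"] = str(out / "block_retention.json")
    Path(enr_outputs["block_retention"]).write_text(
        json.dumps(
            {
                "retention": report.retention,
                "flagged": report.flagged,
                "undefined_blocks": list(report.undefined_blocks),
                "threshold": report.threshold,
            },
            indent=2,
        )
        + "\n"
    )
    man.record("enrich", enr_outputs, time.perf_counter() - t0)
    mark_done("enrich")

    # ----- differential expression ---------------------------------------
    t0 = time.perf_counter()
    study = expr.read_expression(
        paths["expression"], paths["covariates"], paths["probe_map"]
    )
    network_probes = [
        p for p in study.values.index
        if study.probe_map and study.probe_map[p] in set(seeds)
    ]
    if network_probes:
        study = expr.ExpressionStudy(
            values=study.values.loc[network_probes],
            covariates=study.covariates,
            probe_map=study.probe_map,
        )
    dge = expr.run_dge(study, fdr_alpha=config.fdr_alpha)
    dge_out = {"dge_results": str(out / "dge_results.tsv")}
    expr.write_results(dge, dge_out["dge_results"])
    man.record("dge", dge_out, time.perf_counter() - t0)
    mark_done("dge")

    man.write()
    return man.data
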