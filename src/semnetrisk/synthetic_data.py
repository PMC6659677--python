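"""Seeded, planted-truth synthetic inputs for every pipeline stage.

Real analyses of this kind start from restricted inputs: GWAS summary
statistics, a curated background protein-interaction network, multi-source
interaction evidence, pathway annotation and a post-mortem expression
cohort. This module generates structurally comparable stand-ins with known
planted truths so each stage's recovery behaviour can be validated:

* per-gene SNP blocks whose z-scores follow a zero-mean multivariate
  normal with AR(1) correlation ``rho^|i-j|`` (risk genes receive a mean
  shift, the non-centrality per SNP);
* a preferential-attachment background network with a planted connected
  module of risk genes and per-edge publication counts;
* multi-database evidence records with controllable publication/method
  multiplicity and record-level contamination (non-human taxids,
  missing/multiple PubMed ids, missing detection methods);
* a pathway collection with one planted set over-sampling the risk genes;
* a case-control expression matrix with planted effects and sex/age/
  post-mortem-interval covariates.

Every generator is a pure function of the scenario: the same scenario
yields bit-identical outputs. Planted truths are collected in a
machine-readable manifest so recovery tests never re-derive them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSetCollection, write_gmt
from .expression import ExpressionStudy
from .gene_association import LdMatrix
from .interactome import EvidenceRecord, write_mitab

# RNG stream offsets: one independent child stream per generator so adding
# a stage never perturbs another stage's output.
_STREAM_SELECT = 0
_STREAM_GWAS = 1
_STREAM_PIN = 2
_STREAM_EVIDENCE = 3
_STREAM_PATHWAYS = 4
_STREAM_EXPRESSION = 5

_METHOD_VOCAB = (
    "MI:0018", "MI:0006", "MI:0007", "MI:0019", "MI:0055",
    "MI:0096", "MI:0114", "MI:0402", "MI:0676", "MI:0686",
    "MI:0004", "MI:0030",
)
_SEMANTIC_CLASSES = (
    ("transcription", "RNA metabolism"),
    ("splicing", "RNA metabolism"),
    ("apoptosis", "cell death"),
    ("autophagy", "cell death"),
    ("oxidative stress", "stress"),
    ("unfolded protein response", "stress"),
    ("signal transduction", "signaling"),
    ("immune response", "immunity"),
    # deliberately generic classes that downstream retention analysis drops
    ("general", "general"),
    ("metabolism", "general"),
    ("enzymes", "general"),
)


@dataclass(frozen=True)
class EvidenceParams:
    """Distributions for per-pair evidence multiplicity and contamination.

    Extra publications and methods beyond the guaranteed one are Poisson;
    contamination rates act per record, mutually exclusively.
    """

    pubs_rate: float = 1.5
    methods_rate: float = 0.8
    taxid_contamination: float = 0.05
    pubmed_contamination: float = 0.05
    method_contamination: float = 0.05
    source_dbs: tuple[str, ...] = ("intact", "biogrid", "mint", "innatedb", "apid")

    def __post_init__(self) -> None:
        rates = (self.taxid_contamination, self.pubmed_contamination, self.method_contamination)
        if any(r < 0 for r in rates) or sum(rates) > 1:
            raise ValueError("contamination rates must be >= 0 and sum to <= 1")
        if self.pubs_rate < 0 or self.methods_rate < 0:
            raise ValueError("multiplicity rates must be >= 0")


@dataclass(frozen=True)
class PathwayParams:
    """Pathway-collection shape; one planted set over-samples risk genes."""

    universe_size: int = 20_650
    n_pathways: int = 200
    size_range: tuple[int, int] = (10, 200)
    planted_size: int = 23
    planted_overlap: int = 8

    def __post_init__(self) -> None:
        if self.planted_overlap > self.planted_size:
            raise ValueError("planted overlap cannot exceed the planted pathway size")
        if self.size_range[0] < 1 or self.size_range[0] > self.size_range[1]:
            raise ValueError("invalid pathway size range")
        if self.universe_size < max(self.size_range[1], self.planted_size):
            raise ValueError("universe must be at least as large as the largest pathway")
        if self.n_pathways < 1:
            raise ValueError("need at least one pathway")


@dataclass(frozen=True)
class ExpressionParams:
    """Case-control expression cohort with planted effects.

    Defaults mirror a small post-mortem brain cohort: 10 cases, 11
    controls, log2-scale intensities with gene baselines near 8 and
    residual noise SD 0.5. ``effect_size`` is the planted status
    coefficient (cases minus controls) for the differentially expressed
    genes.
    """

    n_cases: int = 10
    n_controls: int = 11
    n_genes: int = 600
    n_de: int = 15
    effect_size: float = -1.5
    noise_sd: float = 0.5
    sex_effect: float = 0.3
    age_effect: float = 0.02
    pmi_effect: float = 0.05
    frac_two_probes: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.frac_two_probes <= 1:
            raise ValueError("frac_two_probes must lie in [0, 1]")
        if self.n_de > self.n_genes:
            raise ValueError("cannot plant more DE genes than genes")


@dataclass(frozen=True)
class SyntheticScenario:
    """Complete configuration of one synthetic study.

    The planted module is a connected subgraph of risk genes inside the
    background network; risk genes receive the per-SNP mean shift
    ``risk_effect`` in the GWAS stage.
    """

    seed: int = 0
    n_genes: int = 600
    snps_per_gene: tuple[int, int] = (1, 10)
    ld_rho: float = 0.5
    n_risk_genes: int = 64
    module_size: int = 24
    risk_effect: float = 4.0
    pin_size: int = 500
    pin_attachment: int = 2
    frac_multi_pub: float = 0.7
    evidence: EvidenceParams = field(default_factory=EvidenceParams)
    pathways: PathwayParams = field(default_factory=PathwayParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ValueError(
                "ld_rho must lie in [0, 1): AR(1) correlation is positive "
                "definite only on that range"
            )
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.snps_per_gene
        if lo < 1 or lo > hi:
            raise ValueError("snps_per_gene must be a positive (lo, hi) range")
        if not 0 <= self.module_size <= self.n_risk_genes <= self.n_genes:
            raise ValueError("need planted module <= risk genes <= gene universe")
        if self.risk_effect < 0:
            raise ValueError("risk_effect must be >= 0")
        if not self.module_size <= self.pin_size <= self.n_genes:
            raise ValueError("need module size <= pin_size <= n_genes")
        if not 1 <= self.pin_attachment < self.pin_size:
            raise ValueError("pin_attachment must be in [1, pin_size)")
        if not 0 <= self.frac_multi_pub <= 1:
            raise ValueError("frac_multi_pub must lie in [0, 1]")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(f"G{i:04d}" for i in range(1, self.n_genes + 1))

    @property
    def risk_genes(self) -> frozenset[str]:
        rng = self._rng(_STREAM_SELECT)
        idx = rng.choice(self.n_genes, size=self.n_risk_genes, replace=False)
        ids = self.gene_ids
        return frozenset(ids[i] for i in idx)

    @property
    def planted_module(self) -> frozenset[str]:
        rng = self._rng(_STREAM_SELECT)
        idx = rng.choice(self.n_genes, size=self.n_risk_genes, replace=False)
        module_idx = rng.choice(self.n_risk_genes, size=self.module_size, replace=False)
        ids = self.gene_ids
        risk = [ids[i] for i in idx]
        return frozenset(risk[i] for i in module_idx)


@dataclass(frozen=True)
class GwasData:
    snps: pd.DataFrame                 # SNP, CHR, BP, P
    genes: pd.DataFrame                # chrom, start, end, gene_id, symbol
    ld: Mapping[str, LdMatrix]
    snp_z: Mapping[str, np.ndarray]    # per-gene simulated z-scores (truth)


@dataclass(frozen=True)
class EvidenceSet:
    records: tuple[EvidenceRecord, ...]
    contaminated: frozenset[int]       # indices into records
    pair_counts: Mapping[tuple[str, str], tuple[int, int]]  # pair -> (pubs, methods)


@dataclass(frozen=True)
class PathwaySet:
    collection: GeneSetCollection
    planted_id: str
    class_map: Mapping[str, tuple[str, str]]  # set id -> (semantic class, block)


def _ar1_matrix(k: int, rho: float) -> np.ndarray:
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def gen_gwas(scenario: SyntheticScenario, flank: int = 50_000) -> GwasData:
    """SNP summary statistics, gene models and per-gene AR(1) LD matrices.

    Genes are laid out on 22 chromosomes with enough spacing that flanked
    windows never overlap; each gene's SNPs land inside its flanked window.
    Null z-scores are MVN(0, Sigma) with Sigma the AR(1) matrix; risk-gene
    SNPs get the scenario's mean shift. p-values are two-sided normal tails.
    """
    rng = scenario._rng(_STREAM_GWAS)
    risk = scenario.risk_genes
    lo, hi = scenario.snps_per_gene
    gene_rows = []
    snp_rows = []
    ld: dict[str, LdMatrix] = {}
    snp_z: dict[str, np.ndarray] = {}
    spacing = 2 * flank + 150_000
    n_chrom = 22
    snp_counter = 0
    for g_idx, gene_id in enumerate(scenario.gene_ids):
        chrom = str(g_idx % n_chrom + 1)
        slot = g_idx // n_chrom
        start = flank + 1_000 + slot * spacing
        length = int(rng.integers(5_000, 100_000))
        end = start + length
        gene_rows.append(
            {"chrom": chrom, "start": start, "end": end,
             "gene_id": gene_id, "symbol": gene_id}
        )
        k = int(rng.integers(lo, hi + 1))
        pos = np.sort(rng.integers(start - flank, end + flank, size=k))
        sigma = _ar1_matrix(k, scenario.ld_rho)
        chol = np.linalg.cholesky(sigma) if scenario.ld_rho > 0 else np.eye(k)
        mu = scenario.risk_effect if gene_id in risk else 0.0
        z = mu + chol @ rng.standard_normal(k)
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
        ids = []
        for j in range(k):
            snp_counter += 1
            ids.append(f"rs{snp_counter:07d}")
            snp_rows.append(
                {"SNP": ids[-1], "CHR": chrom, "BP": int(pos[j]), "P": float(p[j])}
            )
        ld[gene_id] = LdMatrix(snp_ids=tuple(ids), r=sigma)
        snp_z[gene_id] = z
    return GwasData(
        snps=pd.DataFrame(snp_rows),
        genes=pd.DataFrame(gene_rows),
        ld=ld,
        snp_z=snp_z,
    )


def gen_pin(scenario: SyntheticScenario) -> pd.DataFrame:
    """Scale-free background network with the planted module wired in.

    A preferential-attachment graph over ``pin_size`` proteins (a subset of
    the gene universe containing every risk gene) is augmented with a
    random spanning tree over the planted module so the module is one
    connected subgraph. Module edges always carry >= 2 publications so they
    survive the publication filter; other edges carry >= 2 publications
    with probability ``frac_multi_pub``.
    """
    rng = scenario._rng(_STREAM_PIN)
    ids = scenario.gene_ids
    risk = sorted(scenario.risk_genes)
    module = sorted(scenario.planted_module)
    others = [g for g in ids if g not in scenario.risk_genes]
    extra = rng.choice(len(others), size=scenario.pin_size - len(risk), replace=False)
    proteins = risk + [others[i] for i in sorted(extra)]
    perm = rng.permutation(len(proteins))
    ba = nx.barabasi_albert_graph(
        scenario.pin_size, scenario.pin_attachment,
        seed=int(rng.integers(2**31)),
    )
    relabel = {i: proteins[perm[i]] for i in ba.nodes}
    g = nx.relabel_nodes(ba, relabel)
    # random spanning tree over the planted module
    order = list(rng.permutation(module))
    for i in range(1, len(order)):
        j = int(rng.integers(i))
        g.add_edge(order[i], order[j])
    module_set = set(module)
    rows = []
    for a, b in sorted(g.edges()):
        a, b = sorted((a, b))
        if a in module_set and b in module_set:
            n_pubs = 2 + int(rng.poisson(1.0))
        elif rng.random() < scenario.frac_multi_pub:
            n_pubs = 2 + int(rng.poisson(1.0))
        else:
            n_pubs = 1
        rows.append({"protA": a, "protB": b, "n_pubs": n_pubs})
    return pd.DataFrame(rows)


def gen_evidence(
    scenario: SyntheticScenario,
    pairs: Sequence[tuple[str, str]],
    counts: Mapping[tuple[str, str], tuple[int, int]] | None = None,
) -> EvidenceSet:
    """Evidence records for the given protein pairs.

    Each pair receives ``max(n_pubs, n_methods)`` records cycling through
    ``n_pubs`` distinct PubMed ids and ``n_methods`` distinct detection
    methods, spread across source databases; so the aggregated distinct
    counts are exactly ``(n_pubs, n_methods)``. Contamination is injected
    at the record level with the configured per-record rates; the indices
    of contaminated records are reported so QC recovery is testable.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    ep = scenario.evidence
    rng = scenario._rng(_STREAM_EVIDENCE)
    records: list[EvidenceRecord] = []
    contaminated: set[int] = set()
    pair_counts: dict[tuple[str, str], tuple[int, int]] = {}
    pub_counter = 0
    for pair in pairs:
        key = tuple(sorted(pair))
        if counts is not None and key in counts:
            n_pubs, n_methods = counts[key]
        else:
            n_pubs = 1 + int(rng.poisson(ep.pubs_rate))
            n_methods = 1 + int(rng.poisson(ep.methods_rate))
        n_methods = min(n_methods, len(_METHOD_VOCAB))
        pair_counts[key] = (n_pubs, n_methods)
        method_idx = rng.choice(len(_METHOD_VOCAB), size=n_methods, replace=False)
        methods = [_METHOD_VOCAB[i] for i in method_idx]
        pubs = []
        for _ in range(n_pubs):
            pub_counter += 1
            pubs.append(str(10_000_000 + pub_counter))
        for i in range(max(n_pubs, n_methods)):
            rec = EvidenceRecord(
                id_a=key[0],
                id_b=key[1],
                taxid_a="9606",
                taxid_b="9606",
                pubmed=(pubs[i % n_pubs],),
                method=methods[i % n_methods],
                source_db=str(ep.source_dbs[int(rng.integers(len(ep.source_dbs)))]),
            )
            u = rng.random()
            if u < ep.taxid_contamination:
                side = rng.random() < 0.5
                rec = dataclasses.replace(
                    rec,
                    taxid_a="10090" if side else rec.taxid_a,
                    taxid_b=rec.taxid_b if side else "10090",
                )
                contaminated.add(len(records))
            elif u < ep.taxid_contamination + ep.pubmed_contamination:
                pub_counter += 1
                new_pubmed = () if rng.random() < 0.5 else (
                    rec.pubmed[0], str(10_000_000 + pub_counter)
                )
                rec = dataclasses.replace(rec, pubmed=new_pubmed)
                contaminated.add(len(records))
            elif u < (ep.taxid_contamination + ep.pubmed_contamination
                      + ep.method_contamination):
                rec = dataclasses.replace(rec, method="")
                contaminated.add(len(records))
            records.append(rec)
    return EvidenceSet(
        records=tuple(records),
        contaminated=frozenset(contaminated),
        pair_counts=pair_counts,
    )


def gen_pathways(scenario: SyntheticScenario) -> PathwaySet:
    """Pathway collection over a large annotation universe.

    The universe contains the scenario's gene ids padded with filler ids.
    One planted pathway contains ``planted_overlap`` risk genes (so a
    candidate list drawn from the risk genes is strongly enriched for it);
    the remaining pathways sample the universe uniformly. Each pathway is
    assigned a semantic class and functional block for retention analysis.
    """
    pp = scenario.pathways
    rng = scenario._rng(_STREAM_PATHWAYS)
    gene_ids = list(scenario.gene_ids)
    if pp.universe_size < len(gene_ids):
        raise ValueError("pathway universe smaller than the gene universe")
    fillers = [f"U{i:06d}" for i in range(1, pp.universe_size - len(gene_ids) + 1)]
    universe = gene_ids + fillers
    risk = sorted(scenario.risk_genes)
    if pp.planted_overlap > len(risk):
        raise ValueError("planted overlap larger than the risk-gene set")
    non_risk_universe = [u for u in universe if u not in scenario.risk_genes]

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    class_map: dict[str, tuple[str, str]] = {}
    # prefer module genes so the pathway overlaps the recoverable subnetwork
    module = sorted(scenario.planted_module)
    n_from_module = min(pp.planted_overlap, len(module))
    planted_members = {
        module[i] for i in rng.choice(len(module), size=n_from_module, replace=False)
    }
    rest = [g for g in risk if g not in planted_members]
    if pp.planted_overlap > n_from_module:
        extra = rng.choice(len(rest), size=pp.planted_overlap - n_from_module,
                           replace=False)
        planted_members |= {rest[i] for i in extra}
    fill_idx = rng.choice(
        len(non_risk_universe), size=pp.planted_size - pp.planted_overlap, replace=False
    )
    planted_members |= {non_risk_universe[i] for i in fill_idx}
    planted_id = "PW0001"
    sets[planted_id] = ("planted risk pathway", frozenset(planted_members))
    class_map[planted_id] = _SEMANTIC_CLASSES[0]
    for i in range(2, pp.n_pathways + 1):
        size = int(rng.integers(pp.size_range[0], pp.size_range[1] + 1))
        member_idx = rng.choice(len(universe), size=size, replace=False)
        set_id = f"PW{i:04d}"
        sets[set_id] = (f"random pathway {i}", frozenset(universe[j] for j in member_idx))
        class_map[set_id] = _SEMANTIC_CLASSES[int(rng.integers(len(_SEMANTIC_CLASSES)))]
    collection = GeneSetCollection(
        universe_size=pp.universe_size, sets=sets, universe=frozenset(universe)
    )
    return PathwaySet(collection=collection, planted_id=planted_id, class_map=class_map)


def gen_expression(
    scenario: SyntheticScenario,
) -> tuple[ExpressionStudy, dict[str, float]]:
    """Expression matrix with planted case-control effects.

    Model per probe of gene g and sample s:
    ``baseline_g + beta_g * status_s + covariate effects + N(0, noise_sd)``.
    Planted genes are drawn from the risk genes present in the expression
    gene list (padded from the rest when too few). Returns the study plus
    the planted gene -> beta truth map.
    """
    xp = scenario.expression
    rng = scenario._rng(_STREAM_EXPRESSION)
    gene_ids = list(scenario.gene_ids[: xp.n_genes])
    for i in range(len(gene_ids) + 1, xp.n_genes + 1):
        gene_ids.append(f"X{i:05d}")
    n = xp.n_cases + xp.n_controls
    samples = [f"S{i:03d}" for i in range(1, n + 1)]
    status = np.array([0] * xp.n_controls + [1] * xp.n_cases)
    sex = rng.integers(0, 2, size=n)
    if sex.min() == sex.max():  # degenerate draws would break the regression
        sex[0] = 1 - sex[0]
    age = rng.normal(70.0, 8.0, size=n)
    pmi = np.clip(rng.normal(12.0, 4.0, size=n), 1.0, None)
    covariates = pd.DataFrame(
        {"status": status, "sex": sex, "age": age, "pmi": pmi}, index=samples
    )
    covariates.index.name = "sample"

    risk_present = [g for g in gene_ids if g in scenario.risk_genes]
    pool = risk_present + [g for g in gene_ids if g not in scenario.risk_genes]
    de_genes = pool[: xp.n_de]
    truth = {g: xp.effect_size for g in de_genes}

    probes = []
    probe_map = {}
    two_probe = rng.random(len(gene_ids)) < xp.frac_two_probes
    for g, two in zip(gene_ids, two_probe):
        probes.append(f"{g}_p1")
        probe_map[probes[-1]] = g
        if two:
            probes.append(f"{g}_p2")
            probe_map[probes[-1]] = g

    baseline = rng.normal(8.0, 2.0, size=len(probes))
    beta = np.array([truth.get(probe_map[p], 0.0) for p in probes])
    mean = (
        baseline[:, None]
        + beta[:, None] * status[None, :]
        + xp.sex_effect * sex[None, :]
        + xp.age_effect * (age[None, :] - age.mean())
        + xp.pmi_effect * (pmi[None, :] - pmi.mean())
    )
    values = mean + rng.normal(0.0, xp.noise_sd, size=mean.shape)
    matrix = pd.DataFrame(values, index=probes, columns=samples)
    matrix.index.name = "probe"
    study = ExpressionStudy(values=matrix, covariates=covariates, probe_map=probe_map)
    return study, truth


def manifest(scenario: SyntheticScenario) -> dict:
    """Machine-readable planted-truth manifest for the scenario."""
    pathways = gen_pathways(scenario)
    _, de_truth = gen_expression(scenario)
    return {
        "seed": scenario.seed,
        "n_genes": scenario.n_genes,
        "risk_genes": sorted(scenario.risk_genes),
        "planted_module": sorted(scenario.planted_module),
        "risk_effect": scenario.risk_effect,
        "ld_rho": scenario.ld_rho,
        "planted_pathway": {
            "id": pathways.planted_id,
            "members": sorted(pathways.collection.sets[pathways.planted_id][1]),
        },
        "de_genes": de_truth,
    }


def write_all(scenario: SyntheticScenario, out_dir: str | Path, flank: int = 50_000) -> dict[str, str]:
    """Generate every input and write it under *out_dir*; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    gwas = gen_gwas(scenario, flank=flank)
    paths["summary_stats"] = str(out / "summary_stats.tsv")
    gwas.snps.to_csv(paths["summary_stats"], sep="\t", index=False)
    paths["gene_models"] = str(out / "genes.bed")
    with open(paths["gene_models"], "w") as fh:
        for row in gwas.genes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t{row.symbol}\n")
    ld_dir = out / "ld"
    ld_dir.mkdir(exist_ok=True)
    for gene_id, mat in gwas.ld.items():
        df = pd.DataFrame(mat.r, index=mat.snp_ids, columns=mat.snp_ids)
        df.to_csv(ld_dir / f"{gene_id}.ld.tsv", sep="\t")
    paths["ld_dir"] = str(ld_dir)

    pin = gen_pin(scenario)
    paths["pin"] = str(out / "pin.tsv")
    pin.to_csv(paths["pin"], sep="\t", index=False)

    pairs = [(row.protA, row.protB) for row in pin.itertuples(index=False)]
    evidence = gen_evidence(scenario, pairs)
    paths["evidence"] = str(out / "evidence.mitab")
    write_mitab(evidence.records, paths["evidence"])
    ids = sorted({rec.id_a for rec in evidence.records} | {rec.id_b for rec in evidence.records})
    paths["id_map"] = str(out / "id_map.tsv")
    with open(paths["id_map"], "w") as fh:
        for raw in ids:
            fh.write(f"{raw}\t{raw}\n")

    pathways = gen_pathways(scenario)
    paths["gmt"] = str(out / "pathways.gmt")
    write_gmt(pathways.collection, paths["gmt"])
    paths["universe"] = str(out / "universe.txt")
    with open(paths["universe"], "w") as fh:
        fh.write("\n".join(sorted(pathways.collection.universe or ())) + "\n")
    paths["class_map"] = str(out / "class_map.tsv")
    with open(paths["class_map"], "w") as fh:
        fh.write("term\tsemantic_class\tfunctional_block\n")
        for term, (cls, block) in sorted(pathways.class_map.items()):
            fh.write(f"{term}\t{cls}\t{block}\n")

    study, _ = gen_expression(scenario)
    paths["expression"] = str(out / "expression.tsv")
    study.values.to_csv(paths["expression"], sep="\t")
    paths["covariates"] = str(out / "covariates.tsv")
    study.covariates.to_csv(paths["covariates"], sep="\t")
    paths["probe_map"] = str(out / "probe_map.tsv")
    with open(paths["probe_map"], "w") as fh:
        fh.write("probe\tgene\n")
        for probe, gene in (study.probe_map or {}).items():
            fh.write(f"{probe}\t{gene}\n")

    paths["manifest"] = str(out / "truth_manifest.json")
    Path(paths["manifest"]).write_text(json.dumps(manifest(scenario), indent=2) + "\n")
    return paths
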