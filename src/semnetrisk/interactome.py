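"""Evidence-weighted seed interactome construction and core extraction.

Protein-interaction evidence records exported from multiple curated
databases are merged, harmonised to canonical identifiers, quality
controlled (human-only taxids, exactly one PubMed id, a stated detection
method), and aggregated per unordered protein pair. Each pair is scored as

    score = (# distinct publications) + (# distinct detection methods)

and pairs scoring <= 2 — i.e. supported by a single publication with a
single method — are discarded to limit false positives.

The surviving pairs are expanded around a set of seed proteins into a
first-layer interactome. A node bridging strictly more than a threshold
fraction (default 15%) of the seeds' interactomes is an inter-interactome
hub (IIH); the IIHs together with their direct interactors form the core
network, whose edge density is compared against randomly sampled node
subsets of the same size.

Known promiscuous binders (e.g. ubiquitin-C-like proteins that tag targets
for degradation) can be excluded from hub statistics without being removed
from the graph.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HUMAN_TAXID = "9606"


@dataclass(frozen=True)
class EvidenceRecord:
    """One database annotation of a protein pair (PSI-MITAB subset)."""

    id_a: str
    id_b: str
    taxid_a: str
    taxid_b: str
    pubmed: tuple[str, ...]
    method: str
    source_db: str

    def __post_init__(self) -> None:
        if not self.id_a or not self.id_b:
            raise ValueError("interactor ids must be non-empty")


@dataclass(frozen=True)
class ScoredPair:
    """Aggregated evidence for one unordered protein pair."""

    a: str
    b: str
    n_pubs: int
    n_methods: int

    @property
    def score(self) -> int:
        return self.n_pubs + self.n_methods

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


@dataclass
class SeedInteractome:
    seeds: frozenset[str]
    graph: nx.Graph
    interactomes: dict[str, frozenset[str]]  # seed -> seed + first-layer interactors
    disconnected_seeds: frozenset[str]
    unmapped_seeds: frozenset[str]
    exclusions: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class HubReport:
    bridged: dict[str, int]            # node -> number of seed interactomes containing it
    connection_degree: dict[str, float]  # node -> bridged / n_seeds
    iihs: frozenset[str]
    threshold: float
    n_seeds: int


@dataclass(frozen=True)
class CoreNetwork:
    graph: nx.Graph
    iihs: frozenset[str]
    n_nodes: int
    n_edges: int
    avg_neighbors: float
    avg_neighbors_no_excluded: float | None = None


def harmonize(
    records: Iterable[EvidenceRecord],
    id_map: Mapping[str, str | Sequence[str] | None],
) -> tuple[list[EvidenceRecord], Counter]:
    """Convert raw interactor ids to canonical ids, dropping bad mappings.

    *id_map* maps each raw id to a canonical id; ``None`` marks an obsolete
    or non-protein entry, a sequence of several ids marks an ambiguous
    (one-to-many) mapping, and absence means unmapped. Records touching any
    of those are dropped; per-reason counts are returned.
    """
    kept: list[EvidenceRecord] = []
    drops: Counter = Counter()

    def resolve(raw: str) -> str | None:
        if raw not in id_map:
            drops["unmapped"] += 1
            return None
        target = id_map[raw]
        if target is None:
            drops["obsolete_or_nonprotein"] += 1
            return None
        if not isinstance(target, str):
            if len(target) == 1:
                return str(target[0])
            drops["ambiguous"] += 1
            return None
        return target

    for rec in records:
        a = resolve(rec.id_a)
        if a is None:
            continue
        b = resolve(rec.id_b)
        if b is None:
            continue
        kept.append(
            EvidenceRecord(
                id_a=a, id_b=b, taxid_a=rec.taxid_a, taxid_b=rec.taxid_b,
                pubmed=rec.pubmed, method=rec.method, source_db=rec.source_db,
            )
        )
    if drops:
        logger.info("harmonization drops: %s", dict(drops))
    return kept, drops


def qc_filter(records: Iterable[EvidenceRecord]) -> tuple[list[EvidenceRecord], Counter]:
    """Keep records with both taxids human, exactly one PubMed id, a method."""
    kept: list[EvidenceRecord] = []
    drops: Counter = Counter()
    for rec in records:
        if rec.taxid_a != HUMAN_TAXID or rec.taxid_b != HUMAN_TAXID:
            drops["non_human_taxid"] += 1
        elif len(rec.pubmed) != 1:
            drops["pubmed_count"] += 1
        elif not rec.method:
            drops["missing_method"] += 1
        else:
            kept.append(rec)
    if drops:
        logger.info("QC drops: %s", dict(drops))
    return kept, drops


def score_pairs(
    records: Iterable[EvidenceRecord], min_score: int = 3
) -> dict[tuple[str, str], ScoredPair]:
    """Aggregate records per unordered pair and apply the score cutoff.

    ``score = n_distinct_publications + n_distinct_methods``; pairs scoring
    below *min_score* (default: discard score <= 2) are removed.
    """
    pubs: dict[tuple[str, str], set[str]] = {}
    methods: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        if rec.id_a == rec.id_b:
            continue
        pair = tuple(sorted((rec.id_a, rec.id_b)))
        pubs.setdefault(pair, set()).update(rec.pubmed)
        methods.setdefault(pair, set()).add(rec.method)
    out: dict[tuple[str, str], ScoredPair] = {}
    for pair in pubs:
        sp = ScoredPair(a=pair[0], b=pair[1], n_pubs=len(pubs[pair]), n_methods=len(methods[pair]))
        if sp.score >= min_score:
            out[pair] = sp
    return out


def build_seed_interactome(
    seeds: Iterable[str],
    scored_pairs: Mapping[tuple[str, str], ScoredPair],
    exclusions: Iterable[str] = (),
    evidence_universe: Iterable[str] | None = None,
) -> SeedInteractome:
    """First-layer interactome around the seeds.

    Nodes are the seeds plus every protein sharing a surviving pair with a
    seed; edges are all surviving pairs connecting two member nodes. Seeds
    without any surviving pair are reported as disconnected (or unmapped,
    when *evidence_universe* is given and does not contain them) rather
    than silently dropped. Exclusion-listed nodes stay in the graph but are
    flagged and later ignored by hub statistics.
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("seed list is empty")
    exclusions = frozenset(exclusions)

    neighbors: dict[str, set[str]] = {}
    for a, b in scored_pairs:
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)

    universe = set(neighbors) if evidence_universe is None else set(evidence_universe)
    unmapped = frozenset(s for s in seeds if s not in universe)
    disconnected = frozenset(s for s in seeds - unmapped if not neighbors.get(s))

    nodes: set[str] = set(seeds - unmapped)
    for s in seeds:
        nodes.update(neighbors.get(s, ()))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (a, b), sp in scored_pairs.items():
        if a in nodes and b in nodes:
            g.add_edge(a, b, n_pubs=sp.n_pubs, n_methods=sp.n_methods, score=sp.score)
    if g.number_of_edges() == 0:
        raise ValueError("no interaction survived filtering; interactome is empty")
    for n in g.nodes:
        g.nodes[n]["is_seed"] = n in seeds
        g.nodes[n]["excluded"] = n in exclusions

    interactomes = {
        s: frozenset({s} | neighbors.get(s, set()))
        for s in seeds - unmapped
    }
    return SeedInteractome(
        seeds=seeds,
        graph=g,
        interactomes=interactomes,
        disconnected_seeds=disconnected,
        unmapped_seeds=unmapped,
        exclusions=exclusions,
    )


def hub_analysis(
    interactome: SeedInteractome,
    threshold: float = 0.15,
    exclusions: Iterable[str] | None = None,
) -> HubReport:
    """Identify inter-interactome hubs.

    A node's bridged-seed count is the number of seeds whose interactome
    (seed plus first-layer interactors) contains it; its connection degree
    is that count divided by the number of seeds with an interactome. IIHs
    are nodes with connection degree strictly above *threshold*;
    exclusion-listed nodes are never IIHs.
    """
    if not interactome.interactomes:
        raise ValueError("no seed has an interactome")
    excl = interactome.exclusions if exclusions is None else frozenset(exclusions)
    n_seeds = len(interactome.interactomes)
    bridged: dict[str, int] = {}
    for node in interactome.graph.nodes:
        bridged[node] = sum(1 for s in interactome.interactomes.values() if node in s)
    degree = {n: c / n_seeds for n, c in bridged.items()}
    iihs = frozenset(
        n for n, d in degree.items() if d > threshold and n not in excl
    )
    return HubReport(
        bridged=bridged, connection_degree=degree, iihs=iihs,
        threshold=threshold, n_seeds=n_seeds,
    )


def extract_core(
    interactome: SeedInteractome,
    iihs: Iterable[str],
    exclusions: Iterable[str] | None = None,
) -> CoreNetwork:
    """Core network: the IIHs plus their direct interactors, induced edges.

    The average neighbor count 2E/V is reported both for the full core and
    (when an exclusion list is in play) with excluded nodes removed.
    """
    iihs = frozenset(iihs)
    if not iihs:
        raise ValueError("IIH set is empty")
    g = interactome.graph
    nodes = set(iihs)
    for h in iihs:
        nodes.update(g.neighbors(h))
    core = g.subgraph(nodes).copy()
    v, e = core.number_of_nodes(), core.number_of_edges()
    excl = interactome.exclusions if exclusions is None else frozenset(exclusions)
    avg_excl = None
    trimmed_nodes = nodes - excl
    if trimmed_nodes != nodes:
        trimmed = g.subgraph(trimmed_nodes)
        tv = trimmed.number_of_nodes()
        avg_excl = 2.0 * trimmed.number_of_edges() / tv if tv else 0.0
    return CoreNetwork(
        graph=core, iihs=iihs, n_nodes=v, n_edges=e,
        avg_neighbors=2.0 * e / v if v else 0.0,
        avg_neighbors_no_excluded=avg_excl,
    )


def core_density_comparison(
    interactome: SeedInteractome,
    core: CoreNetwork,
    n_samples: int = 1_000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Percentile of the core's edge density among random same-size subsets.

    Density of a node set is ``2E/(V(V-1))`` of its induced subgraph. The
    percentile is ``100 * #{samples strictly below core} / n_samples``.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    g = interactome.graph
    v = core.n_nodes
    if v > g.number_of_nodes():
        raise ValueError("core larger than the interactome")
    if v < 2:
        raise ValueError("core must have at least 2 nodes")
    rng = np.random.default_rng(seed)
    all_nodes = np.array(sorted(g.nodes))
    denom = comb(v, 2)
    core_density = core.n_edges / denom
    densities = np.empty(n_samples)
    adj = {n: set(g.neighbors(n)) for n in g.nodes}
    for i in range(n_samples):
        sample = all_nodes[rng.choice(len(all_nodes), size=v, replace=False)]
        s = set(sample)
        e = sum(len(adj[n] & s) for n in sample) // 2
        densities[i] = e / denom
    percentile = 100.0 * float(np.count_nonzero(densities < core_density)) / n_samples
    return percentile, densities


# ---------------------------------------------------------------------------
# PSI-MITAB 2.7 subset I/O
# ---------------------------------------------------------------------------
# Only columns 1-2 (interactor ids), 7 (detection method), 9 (publication
# ids), 10-11 (taxids) and 13 (source database) are interpreted; the others
# are carried as '-'.

_MITAB_COLUMNS = 15


def _strip_prefix(token: str) -> str:
    """'uniprotkb:P12345' -> 'P12345'; 'taxid:9606(human)' -> '9606'."""
    if token in ("-", ""):
        return ""
    value = token.split(":", 1)[1] if ":" in token else token
    return value.split("(", 1)[0].strip('"')


def read_mitab(path: str | Path) -> list[EvidenceRecord]:
    records: list[EvidenceRecord] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 13:
            raise ValueError(f"{path}:{ln}: expected >= 13 tab-separated columns")
        pubmed = tuple(
            _strip_prefix(tok) for tok in cols[8].split("|") if _strip_prefix(tok)
        )
        records.append(
            EvidenceRecord(
                id_a=_strip_prefix(cols[0]),
                id_b=_strip_prefix(cols[1]),
                taxid_a=_strip_prefix(cols[9]),
                taxid_b=_strip_prefix(cols[10]),
                pubmed=pubmed,
                method=_strip_prefix(cols[6]),
                source_db=_strip_prefix(cols[12]),
            )
        )
    return records


def write_mitab(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            cols = ["-"] * _MITAB_COLUMNS
            cols[0] = f"uniprotkb:{rec.id_a}"
            cols[1] = f"uniprotkb:{rec.id_b}"
            cols[6] = f"psi-mi:{rec.method}" if rec.method else "-"
            cols[8] = "|".join(f"pubmed:{p}" for p in rec.pubmed) if rec.pubmed else "-"
            cols[9] = f"taxid:{rec.taxid_a}"
            cols[10] = f"taxid:{rec.taxid_b}"
            cols[12] = f"psi-mi:{rec.source_db}"
            fh.write("\t".join(cols) + "\n")


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    return [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


def read_id_map(path: str | Path) -> dict[str, str | None | tuple[str, ...]]:
    """TSV raw_id -> canonical id; '-' marks obsolete/non-protein, several
    comma-separated targets mark an ambiguous mapping."""
    out: dict[str, str | None | tuple[str, ...]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        raw, target = ln.split("\t")[:2]
        if target == "-":
            out[raw] = None
        elif "," in target:
            out[raw] = tuple(target.split(","))
        else:
            out[raw] = target
    return out


def write_scored_pairs(pairs: Mapping[tuple[str, str], ScoredPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"a": sp.a, "b": sp.b, "n_pubs": sp.n_pubs,
             "n_methods": sp.n_methods, "score": sp.score}
            for _, sp in sorted(pairs.items())
        ]
    ).to_csv(path, sep="\t", index=False)


def write_hub_report(report: HubReport, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"node": n, "bridged_seeds": report.bridged[n],
             "connection_degree": report.connection_degree[n],
             "is_iih": n in report.iihs}
            for n in sorted(report.bridged, key=lambda n: (-report.bridged[n], n))
        ]
    ).to_csv(path, sep="\t", index=False)


def write_summary(
    interactome: SeedInteractome,
    hubs: HubReport,
    core: CoreNetwork,
    density_percentile: float,
    seed: int,
    path: str | Path,
) -> None:
    summary = {
        "n_seeds": len(interactome.seeds),
        "n_nodes": interactome.graph.number_of_nodes(),
        "n_edges": interactome.graph.number_of_edges(),
        "disconnected_seeds": sorted(interactome.disconnected_seeds),
        "unmapped_seeds": sorted(interactome.unmapped_seeds),
        "iihs": sorted(hubs.iihs),
        "hub_threshold": hubs.threshold,
        "core_nodes": core.n_nodes,
        "core_edges": core.n_edges,
        "core_avg_neighbors": core.avg_neighbors,
        "core_avg_neighbors_no_excluded": core.avg_neighbors_no_excluded,
        "core_density_percentile": density_percentile,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
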