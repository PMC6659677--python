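"""Gene-set over-representation analysis.

Implements the classical hypergeometric (one-tailed Fisher) test for a
candidate gene list against a gene-set collection, the fold-enrichment
statistic (k/n)/(K/N), Bonferroni and Benjamini-Hochberg adjustment, and a
functional-block retention comparison between two enrichment runs (full
network versus its core).

Notation follows the usual over-representation setup: the annotation
universe holds ``N`` genes, a gene set annotates ``K`` of them, the
candidate list holds ``n`` genes of which ``k`` fall in the set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Semantic classes considered too generic to be informative; terms mapped
#: to these classes are removed before computing block retention.
DEFAULT_DROP_CLASSES = frozenset(
    {"general", "metabolism", "enzymes", "protein modification", "physiology"}
)


@dataclass(frozen=True)
class GeneSetCollection:
    """A named collection of gene sets over a fixed annotation universe.

    Parameters
    ----------
    universe_size
        Number of annotated genes ``N`` used as the statistical domain.
    sets
        Mapping from set id to ``(name, members)``.
    universe
        Optional explicit universe membership; when given, candidate genes
        outside it are dropped (with a log message) before testing.
    """

    universe_size: int
    sets: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValueError("universe_size must be >= 1")
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {set_id!r} is empty")
            if len(members) > self.universe_size:
                raise ValueError(
                    f"gene set {set_id!r} larger than the universe "
                    f"({len(members)} > {self.universe_size})"
                )
        if self.universe is not None and len(self.universe) != self.universe_size:
            raise ValueError("explicit universe does not match universe_size")


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation outcome."""

    set_id: str
    name: str
    K: int
    k: int
    n: int
    N: int
    fold: float
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class FunctionalBlockReport:
    """Per-block term retention between a full and a core enrichment."""

    retention: dict[str, float]       # block -> percentage in [0, 100]
    flagged: dict[str, bool]          # block -> retention strictly > threshold
    undefined_blocks: tuple[str, ...]  # blocks with no full-network terms
    unmapped_terms: tuple[str, ...]   # terms missing from the class map
    threshold: float
    dropped_classes: frozenset[str] = field(default=DEFAULT_DROP_CLASSES)


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Observed/expected overlap ratio ``(k/n) / (K/N)``.

    Computed in exact rational arithmetic; round only for display.
    """
    if n < 1 or K < 1 or N < 1:
        raise ValueError("n, K and N must all be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if K > N or n > N:
        raise ValueError("set size K and candidate size n cannot exceed N")
    if k > min(K, n):
        raise ValueError("overlap k cannot exceed min(K, n)")
    return float(Fraction(k, n) / Fraction(K, N))


def overrepresentation_p(k: int, n: int, K: int, N: int) -> float:
    """Hypergeometric upper tail ``P(X >= k)`` for X ~ Hypergeom(N, K, n).

    Identical to the one-tailed Fisher exact test on the 2x2 overlap table.
    """
    if n < 1 or K < 1 or N < 1:
        raise ValueError("n, K and N must all be >= 1")
    if k < 0 or K > N or n > N or k > min(K, n):
        raise ValueError("invalid hypergeometric configuration")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust(pvals: Sequence[float], method: str = "bonferroni") -> list[float]:
    """Multiple-testing adjustment: ``bonferroni`` or ``bh`` (step-up FDR)."""
    pvals = list(pvals)
    if not pvals:
        return []
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}; use 'bonferroni' or 'bh'")
    return list(multipletests(pvals, method=key)[1])


def enrich(
    candidates: Iterable[str],
    collection: GeneSetCollection,
    method: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Test every set in *collection* against the candidate list.

    Duplicate candidates are collapsed. Candidates outside an explicit
    universe are dropped from ``n`` (and logged) rather than raising: they
    correspond to genes without annotation coverage.

    Results are sorted by adjusted p, then by descending fold enrichment.
    """
    cand = set(candidates)
    if not cand:
        raise ValueError("empty candidate list")
    if collection.universe is not None:
        outside = cand - collection.universe
        if outside:
            logger.info(
                "dropping %d candidate gene(s) outside the annotation universe", len(outside)
            )
            cand -= outside
        if not cand:
            raise ValueError("no candidate gene is in the annotation universe")
    n = len(cand)
    N = collection.universe_size
    rows: list[EnrichmentResult] = []
    raw: list[float] = []
    for set_id, (name, members) in collection.sets.items():
        K = len(members)
        k = len(cand & members)
        rows.append(
            EnrichmentResult(
                set_id=set_id,
                name=name,
                K=K,
                k=k,
                n=n,
                N=N,
                fold=fold_enrichment(k, n, K, N),
                p_raw=overrepresentation_p(k, n, K, N),
                p_adj=float("nan"),
            )
        )
        raw.append(rows[-1].p_raw)
    adjusted = adjust(raw, method=method)
    rows = [
        EnrichmentResult(
            set_id=r.set_id, name=r.name, K=r.K, k=r.k, n=r.n, N=r.N,
            fold=r.fold, p_raw=r.p_raw, p_adj=a,
        )
        for r, a in zip(rows, adjusted)
    ]
    rows.sort(key=lambda r: (r.p_adj, -r.fold, r.set_id))
    return rows


def block_retention(
    full_terms: Iterable[str],
    core_terms: Iterable[str],
    class_map: Mapping[str, tuple[str, str]],
    threshold: float = 0.12,
    drop_classes: frozenset[str] = DEFAULT_DROP_CLASSES,
) -> FunctionalBlockReport:
    """Per-functional-block retention of enriched terms in the core.

    *class_map* assigns each term a ``(semantic class, functional block)``
    pair. Terms whose semantic class is in *drop_classes* are removed from
    both lists first. For every block observed in the full-network list,
    retention is ``100 * |core terms in block| / |full terms in block|`` and
    the block is flagged iff retention exceeds ``100 * threshold`` strictly.
    Blocks appearing only in the core list are reported as undefined, not 0.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    full = set(full_terms)
    core = set(core_terms)
    unmapped = tuple(sorted((full | core) - set(class_map)))
    full -= set(unmapped)
    core -= set(unmapped)

    def keep(term: str) -> bool:
        return class_map[term][0] not in drop_classes

    full = {t for t in full if keep(t)}
    core = {t for t in core if keep(t)}

    full_by_block: dict[str, set[str]] = {}
    for t in full:
        full_by_block.setdefault(class_map[t][1], set()).add(t)
    core_blocks = {class_map[t][1] for t in core}

    retention: dict[str, float] = {}
    flagged: dict[str, bool] = {}
    for block, terms in full_by_block.items():
        kept = sum(1 for t in core if class_map[t][1] == block and t in full)
        pct = 100.0 * kept / len(terms)
        retention[block] = pct
        flagged[block] = pct > 100.0 * threshold
    undefined = tuple(sorted(core_blocks - set(full_by_block)))
    return FunctionalBlockReport(
        retention=retention,
        flagged=flagged,
        undefined_blocks=undefined,
        unmapped_terms=unmapped,
        threshold=threshold,
        dropped_classes=drop_classes,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe_size: int, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (set id, description, then member ids, tab-separated)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = (parts[1], frozenset(parts[2:]))
    return GeneSetCollection(
        universe_size=universe_size,
        sets=sets,
        universe=frozenset(universe) if universe is not None else None,
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (name, members) in collection.sets.items():
            fh.write("\t".join([set_id, name, *sorted(members)]) + "\n")


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id, "name": r.name, "K": r.K, "k": r.k,
                "n": r.n, "N": r.N, "fold": r.fold,
                "p_raw": r.p_raw, "p_adj": r.p_adj,
            }
            for r in results
        ]
    )


def write_results(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
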