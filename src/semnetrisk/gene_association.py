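"""Gene-based association testing with an LD-aware Monte-Carlo null.

Each gene's statistic is the sum over its assigned SNPs of the 1-df
chi-square quantiles of the SNP p-values, ``T = sum_i Q(1 - p_i)``. Under
the null the SNP z-scores are correlated through linkage disequilibrium
(LD), so the null distribution of ``T`` is obtained by simulating
``z ~ MVN(0, Sigma)`` with Sigma the gene's LD (correlation) matrix and
accumulating ``sum z_i^2``. The empirical p-value is the fraction of null
draws at least as large as the observed statistic, with a +1 correction so
that no gene reports p = 0.

SNPs are assigned to a gene when they fall inside the gene body extended by
a flank (default 50 kb) on each side, capturing regulatory regions and SNPs
in LD with the gene. Coordinates are 0-based half-open throughout (BED
convention); 1-based inputs must be converted at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger(__name__)

#: Simulation staging: run the first count, and escalate to the next stage
#: whenever the current empirical p-value is <= the stage's threshold.
DEFAULT_STAGES: tuple[tuple[int, float | None], ...] = (
    (1_000, 0.1),
    (10_000, 0.001),
    (1_000_000, None),
)


@dataclass(frozen=True)
class LdMatrix:
    """An LD (correlation) matrix over an ordered list of SNP ids."""

    snp_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if r.shape != (k, k):
            raise ValueError(f"LD matrix shape {r.shape} does not match {k} SNPs")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if np.any(np.abs(r) > 1 + 1e-8):
            raise ValueError("LD entries must lie in [-1, 1]")
        object.__setattr__(self, "r", r)


@dataclass(frozen=True)
class GeneAssociationResult:
    gene_id: str
    n_snps: int
    statistic: float
    n_sims: int
    empirical_p: float


def repair_psd(r: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone and restore unit diagonal.

    Sample LD matrices estimated from small reference panels are routinely
    indefinite; negative eigenvalues are floored at zero and the diagonal is
    renormalised to 1 so the result is again a correlation matrix.
    """
    r = np.asarray(r, dtype=float)
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    if w.min() >= -tol and abs(np.diag(r) - 1.0).max() < 1e-12:
        return r
    w = np.clip(w, 0.0, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def assign_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 50_000,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Map each gene to the SNPs in its flanked window.

    A SNP at position ``pos`` is assigned to every gene whose half-open
    window ``[start - flank, end + flank)`` contains it; SNPs in overlapping
    windows are assigned to all such genes. Returns the mapping plus the
    list of genes with zero SNPs (untested).

    Raises ``ValueError`` when the two inputs share no chromosome name,
    which almost always indicates a naming-convention mismatch
    (e.g. ``chr1`` versus ``1``).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    snp_chroms = set(snps["CHR"].astype(str))
    gene_chroms = set(genes["chrom"].astype(str))
    if snp_chroms and gene_chroms and not (snp_chroms & gene_chroms):
        raise ValueError(
            "no chromosome name shared between SNPs and genes; "
            f"SNP chromosomes: {sorted(snp_chroms)[:5]}, "
            f"gene chromosomes: {sorted(gene_chroms)[:5]}"
        )
    mapping: dict[str, pd.DataFrame] = {}
    untested: list[str] = []
    by_chrom = {str(c): g for c, g in snps.groupby(snps["CHR"].astype(str))}
    for row in genes.itertuples(index=False):
        chrom = str(row.chrom)
        pool = by_chrom.get(chrom)
        if pool is None:
            untested.append(row.gene_id)
            continue
        lo = max(0, int(row.start) - flank)
        hi = int(row.end) + flank
        hit = pool[(pool["BP"] >= lo) & (pool["BP"] < hi)]
        if len(hit):
            mapping[row.gene_id] = hit.reset_index(drop=True)
        else:
            untested.append(row.gene_id)
    return mapping, untested


def gene_statistic(pvals: Sequence[float]) -> float:
    """Sum of 1-df chi-square quantiles of the SNP p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; clamp zeros upstream")
    return float(np.sum(chi2.isf(p, df=1)))


def simulate_null_statistics(
    ld: LdMatrix, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` null statistics ``sum z_i^2`` with ``z ~ MVN(0, Sigma)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = repair_psd(ld.r)
    k = sigma.shape[0]
    # Eigen-factorisation handles the singular (perfect-LD) case that
    # Cholesky rejects.
    w, v = np.linalg.eigh(sigma)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal(size=(n, k)) @ root.T
    return np.einsum("ij,ij->i", z, z)


def empirical_p(t_obs: float, draws: np.ndarray) -> float:
    """``(1 + #{draws >= T_obs}) / (1 + n)`` — never exactly zero."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("draws must be non-empty")
    return float((1 + np.count_nonzero(draws >= t_obs)) / (1 + draws.size))


def adaptive_gene_test(
    gene_id: str,
    pvals: Sequence[float],
    ld: LdMatrix,
    seed: int | np.random.Generator,
    stages: Sequence[tuple[int, float | None]] = DEFAULT_STAGES,
) -> GeneAssociationResult:
    """Staged Monte-Carlo test for one gene.

    Runs the first stage's simulation count; whenever the empirical p-value
    is at or below the stage threshold, escalates to the next (larger)
    stage so that small p-values are resolved with adequate precision.
    """
    if len(pvals) != len(ld.snp_ids):
        raise ValueError(
            f"{gene_id}: {len(pvals)} p-values but LD matrix for {len(ld.snp_ids)} SNPs"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs = gene_statistic(pvals)
    p = 1.0
    n_sims = 0
    for n_stage, threshold in stages:
        draws = simulate_null_statistics(ld, n_stage, rng)
        p = empirical_p(t_obs, draws)
        n_sims = n_stage
        if threshold is None or p > threshold:
            break
    return GeneAssociationResult(
        gene_id=gene_id, n_snps=len(pvals), statistic=t_obs,
        n_sims=n_sims, empirical_p=p,
    )


def run_gene_tests(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    ld: Mapping[str, LdMatrix],
    flank: int = 50_000,
    seed: int = 0,
    stages: Sequence[tuple[int, float | None]] = DEFAULT_STAGES,
) -> pd.DataFrame:
    """Assign SNPs to genes and test every gene with SNP data.

    Genes absent from *ld* fall back to an identity LD matrix (independent
    SNPs). Each gene receives an independent child seed so results do not
    depend on gene order.
    """
    mapping, untested = assign_snps_to_genes(snps, genes, flank=flank)
    if untested:
        logger.info("%d gene(s) without SNPs reported as untested", len(untested))
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(mapping))
    for child, (gene_id, snp_df) in zip(children, sorted(mapping.items())):
        snp_ids = tuple(snp_df["SNP"])
        gene_ld = ld.get(gene_id)
        if gene_ld is None:
            gene_ld = LdMatrix(snp_ids=snp_ids, r=np.eye(len(snp_ids)))
        res = adaptive_gene_test(
            gene_id, snp_df["P"].to_numpy(), gene_ld,
            np.random.default_rng(child), stages=stages,
        )
        rows.append(
            {
                "gene_id": res.gene_id, "n_snps": res.n_snps,
                "statistic": res.statistic, "n_sims": res.n_sims,
                "empirical_p": res.empirical_p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a summary-statistics TSV with columns SNP, CHR, BP, P.

    p-values of exactly 0 are clamped to the smallest positive float with a
    warning: a zero would map to an infinite chi-square quantile.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    missing = {"SNP", "CHR", "BP", "P"} - set(df.columns)
    if missing:
        raise ValueError(f"summary-statistics file missing columns: {sorted(missing)}")
    zeros = df["P"] <= 0
    if zeros.any():
        logger.warning("clamping %d p-value(s) of 0 to the smallest positive float", int(zeros.sum()))
        df.loc[zeros, "P"] = np.nextafter(0.0, 1.0)
    if (df["P"] > 1).any():
        raise ValueError("p-values greater than 1 in summary statistics")
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read gene models from BED (chrom, start, end, name[, symbol...])."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: BED line needs at least 4 columns")
        chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        if start >= end:
            raise ValueError(f"{path}:{ln}: start must be < end")
        rows.append(
            {"chrom": chrom, "start": start, "end": end, "gene_id": name,
             "symbol": parts[4] if len(parts) > 4 else name}
        )
    return pd.DataFrame(rows)


def read_ld_dir(path: str | Path) -> dict[str, LdMatrix]:
    """Read per-gene LD matrices: ``<gene_id>.ld.tsv`` square TSVs with a
    SNP-id header row and index column."""
    out: dict[str, LdMatrix] = {}
    for f in sorted(Path(path).glob("*.ld.tsv")):
        gene_id = f.name[: -len(".ld.tsv")]
        df = pd.read_csv(f, sep="\t", index_col=0)
        out[gene_id] = LdMatrix(snp_ids=tuple(df.columns), r=df.to_numpy(dtype=float))
    return out


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)
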