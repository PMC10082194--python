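"""Genomic deletions inferred from same-chromosome fusion transcripts.

A fusion joining two genes on the same chromosome can arise from a
genomic deletion of the region between the breakpoints.  Candidates are
restricted to fusions touching a DNA-damage-response gene (as a partner
or inside the spanned region) and confirmed by expression depletion on a
median-of-ratios-normalized count matrix:

* criterion A — the candidate sample's summed normalized count over the
  region's genes lies at or below the 10th percentile of the same region
  sum across all samples;
* criterion B — each region gene's normalized count in the candidate
  sample lies at or below the 10th percentile of that gene's counts in
  the other samples.

The verdict is pass iff both criteria hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomicInterval
from .variants import GeneList

DEFAULT_QUANTILE = 0.10


@dataclass(frozen=True)
class FusionCall:
    sample_id: str
    gene_a: str
    chrom_a: str
    pos_a: int
    gene_b: str
    chrom_b: str
    pos_b: int
    junction_reads: int = 1

    def __post_init__(self) -> None:
        if self.junction_reads < 1:
            raise ValueError("junction read count must be >= 1")


@dataclass
class DeletionCandidate:
    sample_id: str
    fusion: FusionCall
    region: GenomicInterval
    genes: list[str]
    verdict: bool | None = None
    details: dict = field(default_factory=dict)


def read_fusions(path: str | Path) -> list[FusionCall]:
    """Fusion TSV: sample, geneA, chromA, posA, geneB, chromB, posB, junction_reads."""
    df = pd.read_csv(path, sep="\t", dtype={"chromA": str, "chromB": str})
    return [
        FusionCall(
            str(r.sample), str(r.geneA), str(r.chromA), int(r.posA),
            str(r.geneB), str(r.chromB), int(r.posB),
            int(getattr(r, "junction_reads", 1)),
        )
        for r in df.itertuples(index=False)
    ]


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Gene coordinate BED (chrom, start, end, gene), tab-separated, no header."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str},
    )


def candidate_deletions(
    fusions: list[FusionCall],
    gene_coords: pd.DataFrame,
    ddr_list: GeneList,
) -> list[DeletionCandidate]:
    """Same-chromosome fusions whose span or partners touch a DDR gene.

    Inter-chromosomal fusions are silently excluded.  The region is the
    interval between the two breakpoints; genes inside it are found by
    coordinate overlap against ``gene_coords`` (chrom, start, end, gene).
    """
    out = []
    for f in fusions:
        if f.chrom_a != f.chrom_b:
            continue
        lo, hi = sorted((f.pos_a, f.pos_b))
        if lo == hi:
            continue
        region = GenomicInterval(f.chrom_a, lo, hi)
        inside = gene_coords[
            (gene_coords["chrom"] == region.chrom)
            & (gene_coords["end"] > region.start)
            & (gene_coords["start"] < region.end)
        ]["gene"].tolist()
        touched = set(inside) | {f.gene_a, f.gene_b}
        if not any(g.upper() in ddr_list.genes for g in touched):
            continue
        out.append(DeletionCandidate(f.sample_id, f, region, inside))
    return out


def median_of_ratios_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Depth normalization by median-of-ratios size factors.

    ``counts`` is genes x samples.  For each sample the size factor is the
    median, over genes with a positive geometric mean across samples, of
    the ratio count/geometric-mean; normalized counts divide by it.
    Returns (normalized matrix, size factors).
    """
    if counts.shape[1] < 2:
        raise ValueError("median-of-ratios needs at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log = np.log(arr)
    valid = np.all(arr > 0, axis=1)
    if not valid.any():
        raise ValueError("no gene with non-zero counts in every sample")
    geomean = np.exp(log[valid].mean(axis=1))
    size_factors = pd.Series(
        np.median(arr[valid] / geomean[:, None], axis=0),
        index=counts.columns,
        name="size_factor",
    )
    normalized = counts / size_factors
    return normalized, size_factors


def test_deletion(
    candidate: DeletionCandidate,
    normalized: pd.DataFrame,
    quantile: float = DEFAULT_QUANTILE,
    exclude_self_region: bool = False,
    exclude_self_gene: bool = True,
) -> DeletionCandidate:
    """Verdict a deletion candidate against a normalized expression matrix.

    Quantiles use the inclusive convention (<= the linearly interpolated
    empirical quantile).  Criterion A keeps the candidate sample in the
    region-sum reference distribution; criterion B excludes it from each
    gene's reference — both per their own literal definitions, and both
    overridable.
    """
    sample = candidate.sample_id
    genes = [g for g in candidate.genes if g in normalized.index]
    if not genes:
        candidate.verdict = False
        candidate.details = {"reason": "no_genes"}
        return candidate
    sub = normalized.loc[genes]
    region_sums = sub.sum(axis=0)
    ref_a = region_sums.drop(sample) if exclude_self_region else region_sums
    thr_a = float(np.quantile(ref_a.to_numpy(), quantile))
    crit_a = float(region_sums[sample]) <= thr_a

    crit_b = True
    per_gene = {}
    for g in genes:
        row = sub.loc[g]
        ref = row.drop(sample) if exclude_self_gene else row
        thr = float(np.quantile(ref.to_numpy(), quantile))
        ok = float(row[sample]) <= thr
        per_gene[g] = {"value": float(row[sample]), "threshold": thr, "pass": ok}
        crit_b &= ok

    candidate.verdict = bool(crit_a and crit_b)
    candidate.details = {
        "region_sum": float(region_sums[sample]),
        "region_sum_threshold": thr_a,
        "criterion_a": crit_a,
        "criterion_b": crit_b,
        "per_gene": per_gene,
    }
    return candidate


def call_fusion_deletions(
    fusions: list[FusionCall],
    counts: pd.DataFrame,
    gene_coords: pd.DataFrame,
    ddr_list: GeneList,
    quantile: float = DEFAULT_QUANTILE,
) -> list[DeletionCandidate]:
    """Normalize, build candidates and verdict them in one pass."""
    normalized, _ = median_of_ratios_normalize(counts)
    cands = candidate_deletions(fusions, gene_coords, ddr_list)
    return [test_deletion(c, normalized, quantile=quantile) for c in cands]
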