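"""Coverage-based abundance measures.

Gene relative abundance in a metagenome is each gene's average read coverage
divided by the summed average coverage of all genes in that sample, so every
sample column sums to 1. KO-level abundance aggregates gene abundances over
the annotation; a gene carrying several KOs contributes its full abundance
to each (duplication rather than splitting — conservative-complete for
marker-gene panels, flagged in the result attrs when it occurs). MAG
abundance is standardized to "genome copies per million reads": the mean
member-feature coverage scaled by 1e6 over the sample's total read count.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "gene_relative_abundance",
    "ko_relative_abundance",
    "mag_abundance",
    "SUM_TO_ONE_RTOL",
]

#: relative tolerance for the sum-to-one invariant on gene-level columns
SUM_TO_ONE_RTOL = 1e-9


def gene_relative_abundance(coverage: pd.DataFrame) -> pd.DataFrame:
    """Per-sample gene relative abundance from a long coverage table.

    Parameters
    ----------
    coverage
        Long table with columns gene_id, sample_id, avg_coverage (>= 0).

    Returns
    -------
    Gene x sample matrix; each column sums to 1 (within 1e-9 relative).
    Genes absent from a sample count as coverage 0.

    Raises
    ------
    ValueError
        If any coverage is negative or a sample's total coverage is 0
        (relative abundance is undefined there).
    """
    if (coverage["avg_coverage"] < 0).any():
        bad = coverage.loc[coverage["avg_coverage"] < 0].iloc[0]
        raise ValueError(
            f"negative coverage for gene {bad['gene_id']!r} "
            f"in sample {bad['sample_id']!r}"
        )
    wide = coverage.pivot_table(
        index="gene_id", columns="sample_id", values="avg_coverage",
        aggfunc="sum", fill_value=0.0,
    ).sort_index()
    totals = wide.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"all-zero coverage in sample {zero.index[0]!r}: "
            "relative abundance undefined"
        )
    out = wide / totals
    out.attrs["level"] = "gene"
    return out


def ko_relative_abundance(
    gene_matrix: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """KO x sample abundance by summing member-gene relative abundances.

    ``annotations`` is a long (gene_id, ko_id) table. Every annotated gene
    must exist in the gene matrix. With multi-KO genes the KO column total
    can exceed 1; ``result.attrs["multi_ko_genes"]`` counts them.
    """
    unknown = set(annotations["gene_id"]) - set(gene_matrix.index)
    if unknown:
        raise ValueError(
            f"annotation references unknown gene(s), e.g. {sorted(unknown)[:3]}"
        )
    ann = annotations.drop_duplicates(["gene_id", "ko_id"])
    joined = ann.join(gene_matrix, on="gene_id")
    out = joined.groupby("ko_id")[list(gene_matrix.columns)].sum().sort_index()
    out.index.name = "ko_id"
    out.attrs["level"] = "ko"
    out.attrs["multi_ko_genes"] = int(
        (ann.groupby("gene_id").size() > 1).sum()
    )
    return out


def mag_abundance(
    member_coverages: Sequence[float],
    sample_read_count: int,
    lengths: Sequence[float] | None = None,
) -> float:
    """Genome copies per million reads for one MAG in one sample.

    The unweighted mean of member-feature coverages (contigs or genes),
    scaled by 1e6 and divided by the sample's total read count. Passing
    ``lengths`` switches to a length-weighted mean.
    """
    cov = np.asarray(member_coverages, dtype=float)
    if cov.size == 0:
        raise ValueError("MAG has no member features")
    if (cov < 0).any():
        raise ValueError("negative member coverage")
    if sample_read_count <= 0:
        raise ValueError("sample_read_count must be > 0")
    if lengths is not None:
        w = np.asarray(lengths, dtype=float)
        if w.shape != cov.shape or (w <= 0).any():
            raise ValueError("lengths must be positive and match coverages")
        mean_cov = float(np.average(cov, weights=w))
    else:
        mean_cov = float(cov.mean())
    return mean_cov * 1e6 / sample_read_count
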