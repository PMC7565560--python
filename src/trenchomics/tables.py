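"""Table I/O and annotation-acceptance filters.

Readers for the plain-TSV tables the pipeline consumes (per-sample gene
coverage, gene->KO annotations, MAG quality tables, sample sheets), a
BLAST tabular (outfmt-6 dialect) reader, and the two acceptance rules used
when assigning genes to reference databases:

* BLAST hits are kept only with e-value <= 1e-5, percent identity >= 30 and
  query coverage >= 50 (defaults; all thresholds inclusive), and then reduced
  to the single best surviving hit per query (highest bitscore, ties broken
  by lowest e-value, then lexicographic subject id);
* CAZyme calls are confirmed only when at least two of the three search
  tools (HMM-based, alignment-based, peptide-pattern) agree.

All identifiers are case-sensitive opaque strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "BlastHit",
    "CazymeEvidence",
    "TableValidationError",
    "DEFAULT_MAX_EVALUE",
    "DEFAULT_MIN_IDENTITY",
    "DEFAULT_MIN_QCOV",
    "CAZYME_TOOLS",
    "read_blast_table",
    "filter_blast_hits",
    "confirm_cazymes",
    "read_coverage_table",
    "read_annotation_table",
    "read_mag_table",
    "read_sample_sheet",
]

DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_QCOV = 50.0

#: the three dbCAN-style search strategies
CAZYME_TOOLS = ("hmm", "alignment", "peptide")


class TableValidationError(ValueError):
    """A consumed table failed validation; message names the offending row."""


@dataclass(frozen=True)
class BlastHit:
    """One row of a tabular protein-search result."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    query_coverage_pct: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue} for {self.query_id}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"identity {self.percent_identity} outside [0, 100] for {self.query_id}"
            )
        if not 0.0 <= self.query_coverage_pct <= 100.0:
            raise ValueError(
                f"query coverage {self.query_coverage_pct} outside [0, 100] "
                f"for {self.query_id}"
            )


@dataclass(frozen=True)
class CazymeEvidence:
    """A candidate CAZyme family assignment with per-tool support flags."""

    gene_id: str
    family_label: str  # e.g. GH13, GT2, PL7, CE1, CBM50, AA3
    tool_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.tool_flags) - set(CAZYME_TOOLS)
        if unknown:
            raise ValueError(f"unknown tool flags {sorted(unknown)} for {self.gene_id}")
        if not self.tool_flags:
            raise ValueError(f"no tool evidence for {self.gene_id}/{self.family_label}")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

_OUTFMT6_COLS = 12


def read_blast_table(
    path: str | PathLike,
    query_lengths: Mapping[str, int] | None = None,
) -> list[BlastHit]:
    """Read a 12- or 13-column BLAST tabular file.

    With 13 columns the last is taken as query coverage percent (``qcovs``
    dialect). With the standard 12 columns, query coverage is computed as
    alignment length / query length x 100, which requires ``query_lengths``.

    Malformed rows (wrong column count, non-numeric fields) are reported
    with their line number.
    """
    hits: list[BlastHit] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (_OUTFMT6_COLS, _OUTFMT6_COLS + 1):
                raise TableValidationError(
                    f"{path}: line {lineno}: expected 12 or 13 columns, "
                    f"got {len(fields)}"
                )
            try:
                identity = float(fields[2])
                aln_len = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
                qcov = float(fields[12]) if len(fields) == 13 else None
            except ValueError as exc:
                raise TableValidationError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            query, subject = fields[0], fields[1]
            if qcov is None:
                if query_lengths is None or query not in query_lengths:
                    raise TableValidationError(
                        f"{path}: line {lineno}: 12-column input needs a query "
                        f"length for {query!r} to compute coverage"
                    )
                qcov = min(100.0, 100.0 * aln_len / query_lengths[query])
            try:
                hits.append(
                    BlastHit(
                        query_id=query,
                        subject_id=subject,
                        percent_identity=identity,
                        evalue=evalue,
                        query_coverage_pct=qcov,
                        bitscore=bitscore,
                    )
                )
            except ValueError as exc:
                raise TableValidationError(f"{path}: line {lineno}: {exc}") from None
    return hits


def filter_blast_hits(
    hits: Iterable[BlastHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_qcov: float = DEFAULT_MIN_QCOV,
) -> list[BlastHit]:
    """Apply acceptance thresholds, then keep the best surviving hit per query.

    Thresholds are inclusive: a hit at exactly the e-value ceiling or the
    identity/coverage floor survives. "Best" means highest bitscore; ties go
    to the lowest e-value, then the lexicographically smallest subject id.
    Output is ordered by query id.
    """
    if max_evalue < 0:
        raise ValueError("max_evalue must be >= 0")
    if not 0 <= min_identity <= 100 or not 0 <= min_qcov <= 100:
        raise ValueError("identity/coverage thresholds must be in [0, 100]")

    best: dict[str, BlastHit] = {}
    for h in hits:
        if h.evalue > max_evalue:
            continue
        if h.percent_identity < min_identity or h.query_coverage_pct < min_qcov:
            continue
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return [best[q] for q in sorted(best)]


def confirm_cazymes(
    evidence: Iterable[CazymeEvidence], min_tools: int = 2
) -> list[CazymeEvidence]:
    """Keep CAZyme assignments supported by at least ``min_tools`` of the
    three search strategies (default 2, the dbCAN consensus rule)."""
    if min_tools < 1:
        raise ValueError("min_tools must be >= 1")
    return [e for e in evidence if len(e.tool_flags) >= min_tools]


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing column(s) {missing}")


def _no_duplicate_keys(df: pd.DataFrame, keys: Sequence[str], path) -> None:
    dup = df.duplicated(subset=list(keys))
    if dup.any():
        row = int(df.index[dup][0]) + 2  # 1-based, plus header line
        raise TableValidationError(
            f"{path}: duplicate {tuple(keys)} key at line {row}"
        )


def read_coverage_table(path: str | PathLike) -> pd.DataFrame:
    """Long-format per-sample gene coverage: gene_id, sample_id, avg_coverage."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    _require_columns(df, ["gene_id", "sample_id", "avg_coverage"], path)
    df["avg_coverage"] = pd.to_numeric(df["avg_coverage"], errors="raise")
    neg = df["avg_coverage"] < 0
    if neg.any():
        row = int(df.index[neg][0]) + 2
        raise TableValidationError(f"{path}: negative avg_coverage at line {row}")
    _no_duplicate_keys(df, ["gene_id", "sample_id"], path)
    return df


def read_annotation_table(path: str | PathLike) -> pd.DataFrame:
    """Gene -> KO assignments: gene_id, ko_id (one row per assignment)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["gene_id", "ko_id"], path)
    _no_duplicate_keys(df, ["gene_id", "ko_id"], path)
    if df[["gene_id", "ko_id"]].isna().any().any():
        raise TableValidationError(f"{path}: empty gene_id/ko_id field")
    return df


def read_mag_table(path: str | PathLike) -> pd.DataFrame:
    """CheckM-style MAG quality table."""
    df = pd.read_csv(path, sep="\t", dtype={"mag_id": str, "stratum": str, "lineage": str})
    _require_columns(
        df,
        ["mag_id", "stratum", "completeness_pct", "contamination_pct",
         "genome_size_bp", "gc_pct", "lineage"],
        path,
    )
    _no_duplicate_keys(df, ["mag_id"], path)
    bad = (df["completeness_pct"] < 0) | (df["completeness_pct"] > 100) | (
        df["contamination_pct"] < 0
    )
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise TableValidationError(
            f"{path}: completeness/contamination out of range at line {row}"
        )
    return df


def read_sample_sheet(path: str | PathLike) -> pd.DataFrame:
    """Sample metadata: sample_id, depth_m, fraction, stratum, read_count."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "fraction": str, "stratum": str})
    _require_columns(df, ["sample_id", "depth_m", "fraction", "stratum"], path)
    _no_duplicate_keys(df, ["sample_id"], path)
    if (df["depth_m"] < 0).any():
        raise TableValidationError(f"{path}: negative depth")
    if "read_count" in df.columns and (df["read_count"] <= 0).any():
        raise TableValidationError(f"{path}: non-positive read_count")
    return df
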