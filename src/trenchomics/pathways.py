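"""Pathway definitions over KEGG Orthology (KO) identifiers.

A pathway is an ordered list of *steps* (reactions); each step is satisfied by
one of several *alternatives*; each alternative is an enzyme complex, i.e. an
AND-set of KOs that must all be present for the route to function.

Two quantities are derived from a definition:

* **relative abundance** of the pathway in a metagenome, from a KO-level
  relative-abundance profile: a complex is limited by its scarcest subunit
  (min over the AND-set), substitutable routes add (sum over alternatives),
  and the pathway value is the mean over its steps;
* **completeness** of the pathway in a single genome, from the genome's KO
  set: the fraction of steps for which at least one alternative complex is
  fully encoded.

Both evaluators are monotone: adding a KO to a genome, or increasing a KO's
abundance, can never decrease any pathway value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PathwayDef",
    "CompletenessRecord",
    "PathwayParseError",
    "parse_pathway_library",
    "load_default_library",
    "load_ko_symbols",
    "step_abundance",
    "pathway_abundance",
    "pathway_abundance_matrix",
    "genome_pathway_completeness",
    "completeness_matrix",
    "MEAN_OVER_STEPS",
    "MIN_OVER_STEPS",
    "MEDIAN_OVER_STEPS",
]

_KO_RE = re.compile(r"^K\d{5}$")
_ID_RE = re.compile(r"^[A-Za-z0-9_.-]+$")


class PathwayParseError(ValueError):
    """Raised on malformed pathway-definition text; carries line/column."""

    def __init__(self, message: str, line: int, column: int | None = None):
        loc = f"line {line}" + (f", column {column}" if column is not None else "")
        super().__init__(f"{message} ({loc})")
        self.line = line
        self.column = column


@dataclass(frozen=True)
class PathwayDef:
    """One pathway: ordered steps of alternative KO complexes."""

    pathway_id: str
    display_name: str
    # steps -> alternatives -> AND-set of KOs
    steps: tuple[tuple[frozenset[str], ...], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"pathway {self.pathway_id!r} has no steps")
        for step in self.steps:
            if not step or any(len(alt) == 0 for alt in step):
                raise ValueError(
                    f"pathway {self.pathway_id!r} has an empty step or alternative"
                )

    @property
    def ko_ids(self) -> frozenset[str]:
        """All KOs appearing anywhere in the definition."""
        return frozenset(ko for step in self.steps for alt in step for ko in alt)


@dataclass(frozen=True)
class CompletenessRecord:
    mag_id: str
    pathway_id: str
    completeness: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError(f"completeness {self.completeness} outside [0, 1]")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^(?P<id>[A-Za-z0-9_.-]+)\s*(?:\((?P<name>[^)]*)\))?\s*$")


def _parse_definition(pathway_id: str, text: str, lineno: int, offset: int):
    steps: list[tuple[frozenset[str], ...]] = []
    pos = offset
    for step_txt in text.split(";"):
        alternatives: list[frozenset[str]] = []
        for alt_txt in step_txt.split("|"):
            kos = [k.strip() for k in alt_txt.split("+")]
            if any(not k for k in kos):
                raise PathwayParseError(
                    f"empty KO term in definition of {pathway_id!r}", lineno, pos
                )
            for k in kos:
                if not _KO_RE.match(k):
                    raise PathwayParseError(
                        f"invalid KO identifier {k!r} in {pathway_id!r}", lineno, pos
                    )
            alternatives.append(frozenset(kos))
        if not alternatives:
            raise PathwayParseError(f"empty step in {pathway_id!r}", lineno, pos)
        steps.append(tuple(alternatives))
        pos += len(step_txt) + 1
    if not steps:
        raise PathwayParseError(f"pathway {pathway_id!r} has no steps", lineno)
    return tuple(steps)


def parse_pathway_library(text: str) -> list[PathwayDef]:
    """Parse a pathway-library file.

    Grammar (per non-comment line)::

        pathway_id [(Display Name)] : step (';' step)*
        step := alt ('|' alt)*
        alt  := KO ('+' KO)*

    Raises
    ------
    PathwayParseError
        On any syntax error (with line/column) or duplicate pathway_id.
    """
    defs: list[PathwayDef] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise PathwayParseError("expected 'pathway_id: definition'", lineno)
        # definitions contain no ':', display names may (e.g. quinone
        # oxidoreductase EC-style names) — split at the last colon
        head, _, body = line.rpartition(":")
        m = _HEADER_RE.match(head.strip())
        if not m:
            raise PathwayParseError(f"malformed pathway header {head.strip()!r}", lineno, 1)
        pid = m.group("id")
        name = (m.group("name") or pid).strip()
        if pid in seen:
            raise PathwayParseError(f"duplicate pathway_id {pid!r}", lineno)
        seen.add(pid)
        if not body.strip():
            raise PathwayParseError(f"pathway {pid!r} has an empty definition", lineno)
        steps = _parse_definition(pid, body, lineno, len(head) + 2)
        defs.append(PathwayDef(pathway_id=pid, display_name=name, steps=steps))
    return defs


def load_default_library() -> list[PathwayDef]:
    """The shipped marker-gene library (C fixation, central C, oxidases,
    fermentation, N cycle, S cycle panels)."""
    text = (
        resources.files("trenchomics.data")
        .joinpath("pathway_library.txt")
        .read_text(encoding="utf-8")
    )
    return parse_pathway_library(text)


def load_ko_symbols() -> pd.DataFrame:
    """Static KO -> gene-symbol/product table shipped with the package."""
    with resources.files("trenchomics.data").joinpath("ko_symbols.tsv").open("rb") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# abundance evaluation
# ---------------------------------------------------------------------------

# Pluggable step combiner: alternative schemes can be swapped without
# touching callers (mean is the default; min/median are stricter variants).
StepReducer = Callable[[Iterable[float]], float]

MEAN_OVER_STEPS: StepReducer = lambda xs: float(np.mean(list(xs)))
MIN_OVER_STEPS: StepReducer = lambda xs: float(np.min(list(xs)))
MEDIAN_OVER_STEPS: StepReducer = lambda xs: float(np.median(list(xs)))


def step_abundance(
    step: tuple[frozenset[str], ...], ko_abundance: Mapping[str, float]
) -> float:
    """Abundance of one step: sum over alternative complexes of the minimum
    KO abundance within each complex. Absent KOs count as 0."""
    return float(
        sum(min(ko_abundance.get(ko, 0.0) for ko in alt) for alt in step)
    )


def pathway_abundance(
    pathway: PathwayDef,
    ko_abundance: Mapping[str, float],
    step_reducer: StepReducer = MEAN_OVER_STEPS,
) -> float:
    """Relative abundance of a pathway in one sample from its KO profile."""
    return step_reducer(step_abundance(s, ko_abundance) for s in pathway.steps)


def pathway_abundance_matrix(
    library: Iterable[PathwayDef],
    ko_matrix: pd.DataFrame,
    step_reducer: StepReducer = MEAN_OVER_STEPS,
) -> pd.DataFrame:
    """Pathway x sample abundance matrix from a KO x sample matrix.

    KOs shared between pathways count fully in each pathway (no mass
    splitting), so pathway values are not additive across the library.
    """
    library = list(library)
    out = pd.DataFrame(
        0.0,
        index=pd.Index([p.pathway_id for p in library], name="pathway_id"),
        columns=ko_matrix.columns,
    )
    for sample in ko_matrix.columns:
        profile = ko_matrix[sample].to_dict()
        for p in library:
            out.at[p.pathway_id, sample] = pathway_abundance(p, profile, step_reducer)
    return out


# ---------------------------------------------------------------------------
# genome completeness
# ---------------------------------------------------------------------------


def genome_pathway_completeness(
    pathway: PathwayDef, ko_set: Iterable[str], mag_id: str = ""
) -> CompletenessRecord:
    """Fraction of steps for which the genome encodes at least one complete
    alternative complex (AND-set fully contained in the genome's KO set)."""
    kos = set(ko_set)
    satisfied = sum(
        1 for step in pathway.steps if any(alt <= kos for alt in step)
    )
    return CompletenessRecord(
        mag_id=mag_id,
        pathway_id=pathway.pathway_id,
        completeness=satisfied / len(pathway.steps),
    )


def completeness_matrix(
    library: Iterable[PathwayDef], mag_ko_sets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """MAG x pathway completeness matrix (values in [0, 1])."""
    library = list(library)
    mags = sorted(mag_ko_sets)
    out = pd.DataFrame(
        0.0,
        index=pd.Index(mags, name="mag_id"),
        columns=pd.Index([p.pathway_id for p in library], name="pathway_id"),
    )
    for mag in mags:
        kos = set(mag_ko_sets[mag])
        for p in library:
            out.at[mag, p.pathway_id] = genome_pathway_completeness(p, kos, mag).completeness
    return out
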