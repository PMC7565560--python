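"""Synthetic hadal-metagenome cohort generator.

Emulates the study design the downstream statistics assume: 16 seawater
metagenomes spanning seven depths (0, 2000, 4000, 8000, 9600, 10,400 and
10,500 m) in two filter size fractions (0.22 um free-living, 3 um
particle-associated), a shared non-redundant gene catalog with KO
annotations drawn from the shipped marker-gene library, per-sample gene
coverages, and a MAG inventory with CheckM-style quality values.

Statistical structure:

* per-gene average coverage is log-normal, independent across genes and
  samples (heavy-tailed, as observed for metagenomic gene coverage);
* configured enrichment effects multiply the raw coverage of all genes
  annotated to a target pathway's KOs, in all samples of the target
  stratum, *before* any normalization — so relative-abundance effects are
  diluted by the rest of the catalog, as they would be in real data;
* MAG completeness/contamination are drawn within quality-tier regions so
  that expected tier proportions match the configuration;
* each sample owns an independent RNG stream derived from (seed, sample
  index), so any sample can be regenerated alone and the whole cohort is
  byte-reproducible.

The default configuration mirrors the Challenger Deep profile: per-depth
sample counts {0 m: 3, 2000 m: 2, 4000 m: 4, 8000 m: 2, 9600 m: 1,
10,400 m: 2, 10,500 m: 2} (the unique grid consistent with the reported
per-sample MAG means), per-stratum MAG counts 87/77/224/122/71/145, and
high:medium tier proportions 254:472.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pathways import PathwayDef, load_default_library
from .stats import DEEPEST_STRATUM, STRATUM_ORDER, stratum_label

__all__ = [
    "SimConfig",
    "SimConfigError",
    "SimulatedCohort",
    "EnrichmentEffect",
    "DEFAULT_SAMPLE_PLAN",
    "DEFAULT_MAG_COUNTS",
    "DEFAULT_TIER_PROPORTIONS",
    "default_config",
    "generate_cohort",
    "write_cohort",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


#: (depth_m, fraction) per sample — reconstruction of the 16-sample profile
DEFAULT_SAMPLE_PLAN: tuple[tuple[float, str], ...] = (
    (0, "0.22um"), (0, "3um"), (0, "0.22um"),
    (2000, "0.22um"), (2000, "3um"),
    (4000, "0.22um"), (4000, "3um"), (4000, "0.22um"), (4000, "3um"),
    (8000, "0.22um"), (8000, "3um"),
    (9600, "0.22um"),
    (10400, "0.22um"), (10400, "3um"),
    (10500, "0.22um"), (10500, "3um"),
)

#: per-stratum MAG counts of the profile the generator emulates
DEFAULT_MAG_COUNTS: dict[str, int] = {
    "0 m": 87, "2000 m": 77, "4000 m": 224,
    "8000 m": 122, "9600 m": 71, DEEPEST_STRATUM: 145,
}

#: high / medium / low quality proportions (254 high + 472 medium of 726)
DEFAULT_TIER_PROPORTIONS: tuple[float, float, float] = (254 / 726, 472 / 726, 0.0)

_PHYLA = (
    "Alphaproteobacteria", "Gammaproteobacteria", "Actinobacteria",
    "Bacteroidetes", "Chloroflexi", "Planctomycetes", "Verrucomicrobia",
    "Nitrospirae", "Thaumarchaeota", "Firmicutes",
)


@dataclass(frozen=True)
class EnrichmentEffect:
    """Multiply coverages of one pathway's KO-annotated genes in one stratum."""

    pathway_id: str
    stratum: str
    fold: float


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one synthetic cohort."""

    n_samples: int = 16
    depth_layers: tuple[float, ...] = (0, 2000, 4000, 8000, 9600, 10400, 10500)
    fractions: tuple[str, ...] = ("0.22um", "3um")
    sample_plan: tuple[tuple[float, str], ...] = DEFAULT_SAMPLE_PLAN
    genes_per_sample: int = 2000
    coverage_lognormal_mu: float = 2.0
    coverage_lognormal_sigma: float = 1.0
    enrichment_effects: tuple[EnrichmentEffect, ...] = ()
    mag_count_per_stratum: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MAG_COUNTS)
    )
    quality_tier_proportions: tuple[float, float, float] = DEFAULT_TIER_PROPORTIONS
    seed: int = 0
    # catalog composition
    genes_per_ko: int = 2
    background_ko_count: int = 200
    annotated_background_fraction: float = 0.5
    # functional-tag shares of the catalog (ratio statistics); at the
    # default 2,000 genes these give 100/100/12/30 tagged genes
    peptidase_fraction: float = 0.05
    cazyme_fraction: float = 0.05
    alkane_fraction: float = 0.006
    aromatic_fraction: float = 0.015
    # per-MAG trait model
    trait_prevalence: float = 0.3

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.genes_per_sample <= 0:
            raise SimConfigError("counts must be positive")
        if self.genes_per_ko <= 0:
            raise SimConfigError("genes_per_ko must be positive")
        if self.coverage_lognormal_sigma <= 0:
            raise SimConfigError("coverage_lognormal_sigma must be > 0")
        if len(self.sample_plan) != self.n_samples:
            raise SimConfigError(
                f"sample_plan has {len(self.sample_plan)} entries, "
                f"n_samples is {self.n_samples}"
            )
        for depth, frac in self.sample_plan:
            if depth not in self.depth_layers:
                raise SimConfigError(f"plan depth {depth} not in depth_layers")
            if frac not in self.fractions:
                raise SimConfigError(f"plan fraction {frac!r} not in fractions")
        if abs(sum(self.quality_tier_proportions) - 1.0) > 1e-9:
            raise SimConfigError("quality_tier_proportions must sum to 1")
        if any(p < 0 for p in self.quality_tier_proportions):
            raise SimConfigError("tier proportions must be >= 0")
        for eff in self.enrichment_effects:
            if eff.fold <= 0:
                raise SimConfigError(f"fold must be > 0 (got {eff.fold})")
        if any(n < 0 for n in self.mag_count_per_stratum.values()):
            raise SimConfigError("MAG counts must be >= 0")


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default Challenger Deep study-profile configuration."""
    return replace(SimConfig(seed=seed), **overrides)


@dataclass
class SimulatedCohort:
    """Everything one simulated study produces, as typed tables."""

    config: SimConfig
    samples: pd.DataFrame        # sample_id, depth_m, fraction, stratum, read_count
    coverage: pd.DataFrame       # gene_id, sample_id, avg_coverage (long)
    annotations: pd.DataFrame    # gene_id, ko_id
    gene_tags: pd.DataFrame      # gene_id, tag
    mags: pd.DataFrame           # mag_id, stratum, completeness_pct, ...
    mag_annotations: pd.DataFrame  # mag_id, ko_id
    library: list[PathwayDef]


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one sample."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(sample_index,))
    )


def _aux_rng(seed: int, channel: int) -> np.random.Generator:
    # channels >= 10_000 are reserved for non-sample streams (catalog, MAGs)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(10_000 + channel,))
    )


def _build_catalog(cfg: SimConfig, library: Sequence[PathwayDef]):
    """Gene ids, their KO annotations and functional tags (deterministic)."""
    lib_kos = sorted({ko for p in library for ko in p.ko_ids})
    n_lib_genes = len(lib_kos) * cfg.genes_per_ko
    if n_lib_genes > cfg.genes_per_sample:
        raise SimConfigError(
            f"genes_per_sample={cfg.genes_per_sample} too small for "
            f"{len(lib_kos)} library KOs x {cfg.genes_per_ko} genes"
        )
    n_total = cfg.genes_per_sample
    gene_ids = [f"gene_{i + 1:06d}" for i in range(n_total)]

    ann_rows: list[tuple[str, str]] = []
    g = 0
    for ko in lib_kos:
        for _ in range(cfg.genes_per_ko):
            ann_rows.append((gene_ids[g], ko))
            g += 1
    # background genes: a fixed fraction carries a background KO (round-robin)
    n_bg = n_total - n_lib_genes
    n_bg_annot = int(round(n_bg * cfg.annotated_background_fraction))
    for j in range(n_bg_annot):
        ko = f"K9{j % cfg.background_ko_count:04d}"
        ann_rows.append((gene_ids[g + j], ko))
    annotations = pd.DataFrame(ann_rows, columns=["gene_id", "ko_id"])

    # functional tags carved out of the tail of the background pool
    tag_counts = [
        max(1, round(frac * n_total))
        for frac in (cfg.peptidase_fraction, cfg.cazyme_fraction,
                     cfg.alkane_fraction, cfg.aromatic_fraction)
    ]
    need = sum(tag_counts)
    if need > n_bg:
        raise SimConfigError("not enough background genes for functional tags")
    tag_rows: list[tuple[str, str]] = []
    cursor = n_total - need
    for count, tag_fmt in (
        (tag_counts[0], lambda i: f"peptidase:M{i % 20 + 1}"),
        (tag_counts[1], lambda i: f"cazyme:GH{i % 30 + 1}"),
        (tag_counts[2], lambda i: "alkane"),
        (tag_counts[3], lambda i: "aromatic"),
    ):
        for i in range(count):
            tag_rows.append((gene_ids[cursor], tag_fmt(i)))
            cursor += 1
    gene_tags = pd.DataFrame(tag_rows, columns=["gene_id", "tag"])
    return gene_ids, annotations, gene_tags


def _tier_bounds(tier: str) -> tuple[tuple[float, float], tuple[float, float]]:
    """(completeness range, contamination range) interior to each tier."""
    return {
        "high": ((90.5, 99.9), (0.0, 4.9)),
        "medium": ((50.0, 90.0), (0.0, 9.9)),
        "low": ((20.0, 49.9), (0.0, 15.0)),
    }[tier]


def generate_cohort(
    cfg: SimConfig, library: Sequence[PathwayDef] | None = None
) -> SimulatedCohort:
    """Generate one complete synthetic cohort.

    Raises
    ------
    SimConfigError
        On invalid configuration, including enrichment effects referencing a
        pathway id absent from the library or a stratum absent from the
        sample plan.
    """
    library = list(library) if library is not None else load_default_library()
    lib_by_id = {p.pathway_id: p for p in library}
    plan_strata = {stratum_label(d) for d, _ in cfg.sample_plan}
    for eff in cfg.enrichment_effects:
        if eff.pathway_id not in lib_by_id:
            raise SimConfigError(f"unknown pathway_id {eff.pathway_id!r} in effects")
        if eff.stratum not in plan_strata:
            raise SimConfigError(f"effect stratum {eff.stratum!r} has no samples")

    gene_ids, annotations, gene_tags = _build_catalog(cfg, library)
    ko_of_gene = annotations.set_index("gene_id")["ko_id"]

    # precompute per-gene fold multipliers per stratum
    fold_by_stratum: dict[str, np.ndarray] = {}
    for eff in cfg.enrichment_effects:
        target_kos = lib_by_id[eff.pathway_id].ko_ids
        mask = np.isin(
            gene_ids, ko_of_gene.index[ko_of_gene.isin(target_kos)].to_numpy()
        )
        mult = fold_by_stratum.setdefault(
            eff.stratum, np.ones(len(gene_ids))
        )
        mult[mask] *= eff.fold

    # samples and coverage
    sample_rows = []
    cov_frames = []
    counters: dict[tuple[float, str], int] = {}
    for i, (depth, frac) in enumerate(cfg.sample_plan):
        counters[(depth, frac)] = counters.get((depth, frac), 0) + 1
        rep = chr(ord("a") + counters[(depth, frac)] - 1)
        sid = f"MT{int(depth):05d}_{frac}_{rep}"
        stratum = stratum_label(depth)
        rng = _sample_rng(cfg.seed, i)
        cov = rng.lognormal(cfg.coverage_lognormal_mu, cfg.coverage_lognormal_sigma,
                            len(gene_ids))
        if stratum in fold_by_stratum:
            cov = cov * fold_by_stratum[stratum]
        read_count = int(rng.integers(95_000_000, 125_000_000))
        sample_rows.append((sid, depth, frac, stratum, read_count))
        cov_frames.append(
            pd.DataFrame({"gene_id": gene_ids, "sample_id": sid, "avg_coverage": cov})
        )
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "depth_m", "fraction", "stratum", "read_count"]
    )
    coverage = pd.concat(cov_frames, ignore_index=True)

    # MAG inventory
    rng_m = _aux_rng(cfg.seed, 1)
    tiers = ("high", "medium", "low")
    mag_rows = []
    mag_ann_rows: list[tuple[str, str]] = []
    mag_no = 0
    strata_order = [s for s in STRATUM_ORDER if s in cfg.mag_count_per_stratum] + sorted(
        set(cfg.mag_count_per_stratum) - set(STRATUM_ORDER)
    )
    for stratum in strata_order:
        deep = stratum not in ("0 m", "2000 m")
        for _ in range(int(cfg.mag_count_per_stratum[stratum])):
            mag_no += 1
            mid = f"MAG{mag_no:04d}"
            tier = tiers[rng_m.choice(3, p=cfg.quality_tier_proportions)]
            (c_lo, c_hi), (x_lo, x_hi) = _tier_bounds(tier)
            completeness = float(rng_m.uniform(c_lo, c_hi))
            contamination = float(rng_m.uniform(x_lo, x_hi))
            size = float(rng_m.lognormal(np.log(3.2e6), 0.25))
            if deep:
                size *= 1.1  # deep genomes run slightly larger
            gc = float(np.clip(rng_m.normal(45.0, 8.0), 25.0, 75.0))
            lineage = _PHYLA[rng_m.integers(len(_PHYLA))]
            mag_rows.append(
                (mid, stratum, round(completeness, 2), round(contamination, 2),
                 int(size), round(gc, 1), lineage)
            )
            # encoded pathways: prevalence gate, then per-step retention tied
            # to CheckM completeness so genome quality and pathway
            # completeness co-vary
            for p in library:
                if rng_m.random() >= cfg.trait_prevalence:
                    continue
                for step in p.steps:
                    if rng_m.random() < completeness / 100.0:
                        alt = list(step)[rng_m.integers(len(step))]
                        mag_ann_rows.extend((mid, ko) for ko in sorted(alt))
    mags = pd.DataFrame(
        mag_rows,
        columns=["mag_id", "stratum", "completeness_pct", "contamination_pct",
                 "genome_size_bp", "gc_pct", "lineage"],
    )
    mag_annotations = (
        pd.DataFrame(mag_ann_rows, columns=["mag_id", "ko_id"])
        .drop_duplicates()
        .reset_index(drop=True)
    )

    return SimulatedCohort(
        config=cfg,
        samples=samples,
        coverage=coverage,
        annotations=annotations,
        gene_tags=gene_tags,
        mags=mags,
        mag_annotations=mag_annotations,
        library=library,
    )


def write_cohort(
    cohort: SimulatedCohort, outdir: str | Path, fasta: bool = False
) -> dict[str, Path]:
    """Write all cohort tables as TSV (byte-deterministic for a given seed).

    Returns a name -> path map. With ``fasta=True`` also emits a synthetic
    nucleotide catalog with gene ids in the headers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
        paths[name] = p

    _write("samples", cohort.samples)
    _write("coverage", cohort.coverage)
    _write("annotations", cohort.annotations)
    _write("gene_tags", cohort.gene_tags)
    _write("mags", cohort.mags)
    _write("mag_annotations", cohort.mag_annotations)

    if fasta:
        rng = _aux_rng(cohort.config.seed, 2)
        p = outdir / "gene_catalog.fasta"
        bases = np.array(list("ACGT"))
        with open(p, "wt", encoding="utf-8") as fh:
            for gid in sorted(cohort.coverage["gene_id"].unique()):
                seq = "".join(bases[rng.integers(0, 4, 90)])
                fh.write(f">{gid}\n{seq}\n")
        paths["gene_catalog"] = p
    return paths
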