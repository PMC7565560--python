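"""Cohort-level statistics for depth-stratified MAG and gene inventories.

Covers MIMAG-style genome quality tiering, per-stratum inventory summaries,
trait fractions with printed-precision formatting, the two-sample Wilcoxon
rank-sum test (exact by enumeration where feasible, normal approximation
with tie and continuity corrections otherwise), tag-based abundance ratios
(e.g. peptidase:CAZyme, alkane:aromatic) and a per-feature enrichment screen
between sample groups.

Depth strata follow the study design: {0 m, 2000 m, 4000 m, 8000 m, 9600 m,
>10,000 m}, the two deepest casts (10,400 and 10,500 m) being merged into a
single ">10,000 m" stratum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "STRATUM_ORDER",
    "DEEPEST_STRATUM",
    "stratum_label",
    "mimag_tier",
    "tier_table",
    "inventory_by_stratum",
    "inventory_from_counts",
    "TraitFraction",
    "trait_fraction",
    "format_percent",
    "ComparisonResult",
    "wilcoxon_rank_sum",
    "exact_test_size",
    "ratio_statistic",
    "enrichment_screen",
    "EXACT_ENUMERATION_LIMIT",
]

#: canonical stratum labels, shallow to deep
STRATUM_ORDER = ("0 m", "2000 m", "4000 m", "8000 m", "9600 m", ">10,000 m")
DEEPEST_STRATUM = ">10,000 m"

#: switch from exact enumeration to the normal approximation above this
#: many group labelings
EXACT_ENUMERATION_LIMIT = 20_000


def stratum_label(depth_m: float) -> str:
    """Map a sampling depth (m) to its stratum label."""
    if depth_m < 0:
        raise ValueError("depth must be >= 0")
    return DEEPEST_STRATUM if depth_m > 10_000 else f"{depth_m:g} m"


# ---------------------------------------------------------------------------
# MAG quality tiers and inventory
# ---------------------------------------------------------------------------


def mimag_tier(completeness_pct: float, contamination_pct: float) -> str:
    """Quality tier of one genome.

    high:   completeness > 90 and contamination < 5
    medium: completeness >= 50 and contamination < 10 (and not high)
    low:    everything else

    Tiers are exclusive with high taking precedence, so every genome maps to
    exactly one tier.
    """
    if not 0.0 <= completeness_pct <= 100.0:
        raise ValueError(f"completeness {completeness_pct} outside [0, 100]")
    if contamination_pct < 0.0:
        raise ValueError(f"negative contamination {contamination_pct}")
    if completeness_pct > 90.0 and contamination_pct < 5.0:
        return "high"
    if completeness_pct >= 50.0 and contamination_pct < 10.0:
        return "medium"
    return "low"


def tier_table(mags: pd.DataFrame) -> pd.DataFrame:
    """Append a ``tier`` column to a MAG quality table."""
    out = mags.copy()
    out["tier"] = [
        mimag_tier(c, x)
        for c, x in zip(out["completeness_pct"], out["contamination_pct"])
    ]
    return out


def inventory_from_counts(
    mag_counts: Mapping[str, int], sample_counts: Mapping[str, int]
) -> pd.DataFrame:
    """Per-stratum inventory from pre-tabulated counts.

    Returns a stratum-indexed frame with n_mags, n_samples and
    mean_mags_per_sample, plus ``attrs["total_mags"]``.
    """
    orphan = set(mag_counts) - set(sample_counts)
    if orphan:
        raise ValueError(f"stratum {sorted(orphan)[0]!r} absent from sample sheet")
    strata = [s for s in STRATUM_ORDER if s in mag_counts] + sorted(
        set(mag_counts) - set(STRATUM_ORDER)
    )
    rows = []
    for s in strata:
        n_mags = int(mag_counts[s])
        n_samples = int(sample_counts[s])
        if n_mags < 0 or n_samples <= 0:
            raise ValueError(f"invalid counts for stratum {s!r}")
        rows.append((s, n_mags, n_samples, n_mags / n_samples))
    out = pd.DataFrame(
        rows, columns=["stratum", "n_mags", "n_samples", "mean_mags_per_sample"]
    ).set_index("stratum")
    out.attrs["total_mags"] = int(out["n_mags"].sum())
    return out


def inventory_by_stratum(
    mags: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Per-stratum MAG counts and per-sample means from record tables.

    ``mags`` needs a ``stratum`` column; ``samples`` needs ``sample_id`` and
    ``stratum``. Every MAG stratum must appear in the sample sheet.
    """
    sample_counts = samples.groupby("stratum")["sample_id"].nunique().to_dict()
    mag_counts = mags.groupby("stratum")["mag_id"].size().to_dict()
    for s in sample_counts:
        mag_counts.setdefault(s, 0)
    return inventory_from_counts(mag_counts, sample_counts)


# ---------------------------------------------------------------------------
# trait fractions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitFraction:
    """n-of-N trait prevalence, kept at full precision until formatting."""

    n_with_trait: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_with_trait / self.n_total

    @property
    def percent(self) -> float:
        return 100.0 * self.n_with_trait / self.n_total

    def percent_str(self, decimals: int = 1) -> str:
        """Exact-rational percent, rounded half away from zero."""
        q = Decimal(100 * self.n_with_trait) / Decimal(self.n_total)
        return str(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def trait_fraction(n_with_trait: int, n_total: int) -> TraitFraction:
    """Fraction of genomes (or genes) carrying a trait."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_with_trait <= n_total:
        raise ValueError("need 0 <= n_with_trait <= n_total")
    return TraitFraction(n_with_trait, n_total)


def format_percent(value: float, decimals: int = 1) -> str:
    """Round a percentage half away from zero to ``decimals`` places."""
    return str(
        Decimal(repr(value)).quantize(
            Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP
        )
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-group rank-sum comparison."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    direction: str  # which group has the larger median: 'a', 'b' or 'tie'
    median_a: float
    median_b: float
    method: str  # 'exact' or 'normal-approx'

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")
        if not -1e-9 <= self.u_statistic <= self.n_a * self.n_b + 1e-9:
            raise ValueError("U outside [0, n_a * n_b]")


def _rank_sum_null_distribution(ranks: np.ndarray, n_a: int) -> np.ndarray:
    """Rank sums of group A over every labeling of n_a of len(ranks) items."""
    idx = np.fromiter(
        itertools.chain.from_iterable(
            itertools.combinations(range(ranks.size), n_a)
        ),
        dtype=np.intp,
    ).reshape(-1, n_a)
    return ranks[idx].sum(axis=1)


def wilcoxon_rank_sum(
    values_a: Sequence[float],
    values_b: Sequence[float],
    group_a: str = "a",
    group_b: str = "b",
    exact_threshold: int = EXACT_ENUMERATION_LIMIT,
) -> ComparisonResult:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    Ties receive midranks. When the number of group labelings
    C(n_a + n_b, n_a) is at most ``exact_threshold`` the two-sided p-value is
    computed exactly by full enumeration of labelings (the tail mass of rank
    sums at least as far from the null mean as observed); otherwise the
    normal approximation with tie correction and a 0.5 continuity correction
    is used. The method actually applied is recorded on the result.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = rankdata(np.concatenate([a, b]))
    w_a = float(ranks[:n_a].sum())
    u_a = w_a - n_a * (n_a + 1) / 2.0

    if comb(n, n_a) <= exact_threshold:
        dist = _rank_sum_null_distribution(ranks, n_a)
        mu = dist.mean()
        # tail mass at least as extreme as observed; tolerance absorbs
        # floating error from midranks
        p = float(np.mean(np.abs(dist - mu) >= abs(w_a - mu) - 1e-9))
        method = "exact"
    else:
        mu_u = n_a * n_b / 2.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            z = (abs(u_a - mu_u) - 0.5) / np.sqrt(var_u)
            p = float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
        method = "normal-approx"

    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = "tie" if med_a == med_b else ("a" if med_a > med_b else "b")
    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        n_a=n_a,
        n_b=n_b,
        u_statistic=u_a,
        p_value=max(p, np.finfo(float).tiny),
        direction=direction,
        median_a=med_a,
        median_b=med_b,
        method=method,
    )


def exact_test_size(n_a: int, n_b: int, alpha: float) -> float:
    """True size of the exact two-sided rank-sum test at level ``alpha``
    for untied data: the probability, under the null, of a p-value < alpha.

    Because the exact null distribution is discrete, this is the largest
    attainable level below ``alpha`` and is generally smaller than alpha.
    """
    ranks = np.arange(1, n_a + n_b + 1, dtype=float)
    dist = _rank_sum_null_distribution(ranks, n_a)
    mu = dist.mean()
    dev = np.abs(dist - mu)
    # p-value of each outcome, then mass of outcomes with p < alpha
    order = np.sort(dev)
    p_of = 1.0 - np.searchsorted(order, dev - 1e-9, side="left") / dist.size
    return float(np.mean(p_of < alpha))


# ---------------------------------------------------------------------------
# tag-based ratios
# ---------------------------------------------------------------------------


def ratio_statistic(
    gene_matrix: pd.DataFrame,
    tags: pd.DataFrame,
    numerator_tags: Iterable[str],
    denominator_tags: Iterable[str],
) -> pd.Series:
    """Per-sample ratio of summed abundances of two tag groups.

    ``tags`` is a long (gene_id, tag) table. A gene carrying at least one
    numerator (denominator) tag contributes its full abundance once to the
    numerator (denominator). Samples with zero denominator mass get NaN —
    a flagged missing value, not a failure.
    """
    num_set, den_set = set(numerator_tags), set(denominator_tags)
    num_genes = sorted(
        set(tags.loc[tags["tag"].isin(num_set), "gene_id"]) & set(gene_matrix.index)
    )
    den_genes = sorted(
        set(tags.loc[tags["tag"].isin(den_set), "gene_id"]) & set(gene_matrix.index)
    )
    num = gene_matrix.loc[num_genes].sum(axis=0)
    den = gene_matrix.loc[den_genes].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[den <= 0] = np.nan
    out.name = "ratio"
    return out


# ---------------------------------------------------------------------------
# enrichment screen
# ---------------------------------------------------------------------------


def enrichment_screen(
    matrix: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    correction: str | None = None,
    exact_threshold: int = EXACT_ENUMERATION_LIMIT,
) -> pd.DataFrame:
    """Per-feature rank-sum comparisons between all pairs of sample groups.

    Parameters
    ----------
    matrix
        Feature x sample abundance matrix.
    groups
        sample_id -> group label for every column of ``matrix``.
    alpha
        Raw-p significance level for the ``significant`` flag (a
        ``significant_01`` flag at 0.01 is always included).
    correction
        ``None`` (raw p, the default reporting mode) or ``"bh"`` to append a
        Benjamini-Hochberg adjusted column ``p_adjusted``.

    A feature constant across both groups yields p = 1, not an error.
    """
    groups = dict(groups)
    missing = [s for s in matrix.columns if s not in groups]
    if missing:
        raise ValueError(f"no group label for sample(s) {missing[:3]}")
    labels = sorted(set(groups[s] for s in matrix.columns))
    if len(labels) < 2:
        raise ValueError("need at least two sample groups")
    by_label = {
        g: [s for s in matrix.columns if groups[s] == g] for g in labels
    }

    rows = []
    for feature, values in matrix.iterrows():
        for g_a, g_b in itertools.combinations(labels, 2):
            res = wilcoxon_rank_sum(
                values[by_label[g_a]].to_numpy(),
                values[by_label[g_b]].to_numpy(),
                group_a=g_a,
                group_b=g_b,
                exact_threshold=exact_threshold,
            )
            direction = {"a": g_a, "b": g_b, "tie": "tie"}[res.direction]
            rows.append(
                {
                    "feature_id": feature,
                    "group_a": g_a,
                    "group_b": g_b,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "u_statistic": res.u_statistic,
                    "p_value": res.p_value,
                    "direction": direction,
                    "median_a": res.median_a,
                    "median_b": res.median_b,
                    "method": res.method,
                }
            )
    out = pd.DataFrame(rows)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    pcol = "p_adjusted" if correction == "bh" else "p_value"
    out["significant"] = out[pcol] < alpha
    out["significant_01"] = out[pcol] < 0.01
    return out
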