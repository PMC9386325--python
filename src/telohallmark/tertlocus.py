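"""TERT-promoter methylation and hotspot-mutation analysis.

Per-CpG bisulfite methylation percentages, region means over the analysed
promoter (39 CpGs: 29 THOR + 10 proximal to the TSS) and the 5-CpG UTSS
subregion, 16.1% dichotomization, unsupervised pattern clustering, C228T /
C250T hotspot calling from base counts, and the per-tumour alteration
co-occurrence summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import stattests
from .stattests import ContingencyTable2x2, TestResult

logger = logging.getLogger(__name__)

#: The five UTSS CpG sites (opaque site identifiers)
UTSS_SITES = ("1295586", "1295590", "1295593", "1295605", "1295618")

#: Dichotomization threshold (% methylation)
METHYLATION_CUTOFF = 16.1

#: Hotspot position labels: c.-124 (C228T) and c.-146 (C250T); both C>T
HOTSPOT_POSITIONS = ("c.-124", "c.-146")
HOTSPOT_ALIASES = {"c.-124": "C228T", "c.-146": "C250T"}


@dataclass(frozen=True)
class PromoterRegions:
    """Site-id masks for the analysed promoter region.

    ``full`` is the 39-CpG analysed region, ``thor`` its 29 THOR sites and
    ``utss`` the 5-site subregion; UTSS must be contained in THOR.
    """

    full: tuple[str, ...]
    thor: tuple[str, ...]
    utss: tuple[str, ...] = UTSS_SITES

    def __post_init__(self) -> None:
        if not set(self.utss) <= set(self.thor):
            raise ValueError("UTSS sites must be a subset of THOR sites")
        if not set(self.thor) <= set(self.full):
            raise ValueError("THOR sites must be a subset of the full region")


def default_regions(
    n_thor: int = 29, n_proximal: int = 10
) -> PromoterRegions:
    """Site layout mirroring the analysed promoter: THOR sites named
    CpG_THOR_*, proximal sites CpG_PROX_*, with the five real UTSS ids
    embedded in THOR."""
    thor = list(UTSS_SITES) + [f"CpG_THOR_{i:02d}" for i in range(n_thor - len(UTSS_SITES))]
    prox = [f"CpG_PROX_{i:02d}" for i in range(n_proximal)]
    return PromoterRegions(full=tuple(thor + prox), thor=tuple(thor))


@dataclass
class PromoterMethylProfile:
    """Per-CpG methylated/unmethylated read counts for one specimen."""

    specimen: str
    sites: pd.DataFrame  # index site_id; columns n_meth, n_unmeth
    regions: PromoterRegions

    def __post_init__(self) -> None:
        if (self.sites[["n_meth", "n_unmeth"]].values < 0).any():
            raise ValueError("negative read counts")

    @property
    def depth(self) -> pd.Series:
        return self.sites["n_meth"] + self.sites["n_unmeth"]


@dataclass
class PromoterSummary:
    specimen: str
    mean_full: float  # % over covered sites of the 39-CpG region
    mean_utss: float  # % over covered UTSS sites (NaN when uncovered)
    coverage_full: float  # fraction of region sites with depth > 0
    coverage_utss: float
    status: Literal["methylated", "non_methylated"]
    pattern: Literal["high", "moderate", "low", "unassigned"] = "unassigned"


@dataclass
class HotspotCall:
    position: str
    base_counts: Mapping[str, int]
    depth: int
    alt_fraction: float
    call: Literal["mutant", "wildtype", "low_depth"]


@dataclass
class LocusAlterationProfile:
    """Boolean (or None = missing) TERT-locus alteration flags per tumour."""

    specimen: str
    promoter_mutation: bool | None
    promoter_methylation: bool | None
    tert_expression: bool | None
    copy_gain: bool | None = None  # imported as data; not computed here

    def event_count(self) -> int:
        return sum(
            bool(f)
            for f in (
                self.promoter_mutation,
                self.promoter_methylation,
                self.tert_expression,
                self.copy_gain,
            )
            if f is not None
        )


def methylation_percent(profile: PromoterMethylProfile) -> pd.Series:
    """Per-site % methylation: 100 * C / (C + T) over covered sites.

    Zero-depth sites are dropped with a warning; raises if no site has
    coverage.
    """
    depth = profile.depth
    covered = depth > 0
    if not covered.any():
        raise ValueError(f"{profile.specimen}: all sites have zero depth")
    dropped = depth.index[~covered]
    if len(dropped):
        logger.warning(
            "%s: %d zero-depth sites dropped", profile.specimen, len(dropped)
        )
    pct = 100.0 * profile.sites.loc[covered, "n_meth"] / depth[covered]
    pct.name = "pct_methylation"
    return pct


def summarize_promoter(
    profile: PromoterMethylProfile, cutoff: float = METHYLATION_CUTOFF
) -> PromoterSummary:
    """Region means (unweighted over covered sites) + dichotomized status."""
    pct = methylation_percent(profile)

    def region_mean(sites: Sequence[str]) -> tuple[float, float]:
        sites = [s for s in sites if s in profile.sites.index]
        covered = [s for s in sites if s in pct.index]
        frac = len(covered) / len(sites) if sites else 0.0
        mean = float(pct[covered].mean()) if covered else float("nan")
        return mean, frac

    mean_full, cov_full = region_mean(profile.regions.full)
    mean_utss, cov_utss = region_mean(profile.regions.utss)
    summary = PromoterSummary(
        specimen=profile.specimen,
        mean_full=mean_full,
        mean_utss=mean_utss,
        coverage_full=cov_full,
        coverage_utss=cov_utss,
        status="non_methylated",
    )
    return dichotomize(summary, cutoff=cutoff)


def dichotomize(
    summary: PromoterSummary, cutoff: float = METHYLATION_CUTOFF
) -> PromoterSummary:
    """Methylated when either the UTSS or the full-region mean is >= cutoff."""
    means = [m for m in (summary.mean_utss, summary.mean_full) if np.isfinite(m)]
    if not means:
        raise ValueError(f"{summary.specimen}: no region mean computable")
    summary.status = (
        "methylated" if any(m >= cutoff for m in means) else "non_methylated"
    )
    return summary


def cluster_patterns(
    profiles_pct: pd.DataFrame, k: int = 3
) -> pd.Series:
    """Unsupervised methylation-pattern labels from per-CpG % profiles.

    Agglomerative hierarchical clustering (average linkage, Euclidean) on
    the specimen x CpG percentage matrix, tree cut at ``k`` clusters, and
    clusters labelled high / moderate / low by descending cluster-mean
    methylation.  Specimens with incomplete profiles (any NaN) are labelled
    ``unassigned``.
    """
    complete = profiles_pct.dropna(axis=0)
    labels = pd.Series("unassigned", index=profiles_pct.index, dtype=object)
    if len(complete) < k:
        raise ValueError(f"need >= {k} complete profiles, got {len(complete)}")
    # deterministic: sort specimens so the linkage order never depends on
    # input order
    complete = complete.sort_index()
    z = linkage(complete.values, method="average", metric="euclidean")
    cut = fcluster(z, t=k, criterion="maxclust")
    n_eff = len(np.unique(cut))
    if n_eff < k:
        logger.warning("degenerate clustering: %d effective clusters", n_eff)
    cluster_means = (
        pd.Series(complete.mean(axis=1).values)
        .groupby(cut)
        .mean()
        .sort_values(ascending=False)
    )
    names = ["high", "moderate", "low", *[f"extra_{i}" for i in range(max(0, k - 3))]]
    name_of = {cl: names[i] for i, cl in enumerate(cluster_means.index)}
    labels[complete.index] = [name_of[c] for c in cut]
    return labels


def call_hotspots(
    basecounts: Mapping[str, Mapping[str, int]],
    min_depth: int = 100,
    min_alt_fraction: float = 0.05,
) -> dict[str, HotspotCall]:
    """C>T hotspot calls at the two promoter positions.

    ``basecounts``: position label -> {A, C, G, T} read counts.  Mutant when
    depth >= ``min_depth`` and the T-allele fraction >= ``min_alt_fraction``;
    wildtype otherwise at sufficient depth; low_depth below it.
    """
    calls: dict[str, HotspotCall] = {}
    for pos, counts in basecounts.items():
        counts = {b: int(counts.get(b, 0)) for b in "ACGT"}
        if any(v < 0 for v in counts.values()):
            raise ValueError(f"{pos}: negative base counts")
        depth = sum(counts.values())
        alt = counts["T"]
        frac = alt / depth if depth > 0 else 0.0
        if depth < min_depth:
            call = "low_depth"
        elif frac >= min_alt_fraction:
            call = "mutant"
        else:
            call = "wildtype"
        calls[pos] = HotspotCall(
            position=pos, base_counts=counts, depth=depth, alt_fraction=frac, call=call
        )
    return calls


@dataclass
class CooccurrenceSummary:
    tables: dict[str, ContingencyTable2x2]
    tests: dict[str, TestResult]
    event_counts: pd.Series


def _table_from_flags(rows: pd.Series, cols: pd.Series) -> ContingencyTable2x2:
    both = pd.concat([rows, cols], axis=1, keys=["r", "c"]).dropna()
    r = both["r"].astype(bool)
    c = both["c"].astype(bool)
    return ContingencyTable2x2(
        int((r & c).sum()),
        int((r & ~c).sum()),
        int((~r & c).sum()),
        int((~r & ~c).sum()),
    )


def cooccurrence_summary(
    profiles: Sequence[LocusAlterationProfile],
    cohorts: Mapping[str, str],
) -> CooccurrenceSummary:
    """Association of TERT-locus alterations with expression and cohort.

    Builds 2x2 tables: any-promoter-alteration x TERT expression,
    mutation x cohort and methylation x cohort, and tests each with a
    two-sided Fisher exact test; also returns the per-tumour count of
    co-occurring alterations.
    """
    if sum(p.promoter_mutation is not None for p in profiles) < 2:
        raise ValueError("need >= 2 tumours with alteration flags")
    idx = [p.specimen for p in profiles]
    mut = pd.Series([p.promoter_mutation for p in profiles], index=idx, dtype=object)
    meth = pd.Series([p.promoter_methylation for p in profiles], index=idx, dtype=object)
    expr = pd.Series([p.tert_expression for p in profiles], index=idx, dtype=object)
    any_prom = pd.Series(
        [
            None
            if (p.promoter_mutation is None and p.promoter_methylation is None)
            else bool(p.promoter_mutation) or bool(p.promoter_methylation)
            for p in profiles
        ],
        index=idx,
        dtype=object,
    )
    aggressive = pd.Series(
        {s: cohorts.get(s) == "aggressive" for s in idx}, dtype=object
    )
    spec = {
        "promoter_alteration_x_expression": (any_prom, expr),
        "mutation_x_cohort": (aggressive, mut),
        "methylation_x_cohort": (aggressive, meth),
    }
    tables: dict[str, ContingencyTable2x2] = {}
    tests: dict[str, TestResult] = {}
    for name, (r, c) in spec.items():
        try:
            tables[name] = _table_from_flags(r, c)
            tests[name] = stattests.fisher_exact(tables[name], "two_sided")
        except ValueError as exc:
            logger.warning("co-occurrence table %s degenerate: %s", name, exc)
    counts = pd.Series({p.specimen: p.event_count() for p in profiles})
    return CooccurrenceSummary(tables=tables, tests=tests, event_counts=counts)
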