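"""Telomere-position-effect analysis.

The genome is segmented into 5-Mb windows anchored at each chromosome-arm
telomere and tiled inward to the centromere.  Per-gene differential
expression between short- and normal-telomere tumours uses a moderated
t-statistic (empirical-Bayes variance shrinkage with a scaled-inverse-
chi-square prior fitted by method of moments on the log sample variances).
Each window with enough expressed genes is then tested by preranked
running-sum enrichment (weighted Kolmogorov-Smirnov statistic, gene-label
permutation null, NES and pooled-null FDR), and the subtelomeric
(telomere-adjacent) compartment is compared with the interior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from . import stattests
from .stattests import ContingencyTable2x2, TestResult

logger = logging.getLogger(__name__)

WINDOW_SIZE = 5_000_000  # bp
MIN_GENES = 15
WINDOW_FDR = 0.1


# ---------------------------------------------------------------------------
# Genome windows
# ---------------------------------------------------------------------------


def validate_chrom_table(chrom: pd.DataFrame) -> pd.DataFrame:
    """Chromosome table: name, length, cen_start, cen_end, acrocentric."""
    required = {"name", "length", "cen_start", "cen_end"}
    if not required <= set(chrom.columns):
        raise ValueError(f"chromosome table needs columns {sorted(required)}")
    chrom = chrom.copy()
    if "acrocentric" not in chrom.columns:
        chrom["acrocentric"] = False
    bad = ~(
        (0 < chrom["cen_start"])
        & (chrom["cen_start"] < chrom["cen_end"])
        & (chrom["cen_end"] < chrom["length"])
    )
    if bad.any():
        raise ValueError(f"invalid centromere intervals: {list(chrom.loc[bad, 'name'])}")
    return chrom


def build_windows(
    chrom: pd.DataFrame, window_size: int = WINDOW_SIZE
) -> pd.DataFrame:
    """Tile each chromosome arm with telomere-anchored windows.

    p-arms are tiled from position 0 inward to the centromere start; q-arms
    from the chromosome end inward to the centromere end, so window index 0
    always touches the telomere.  The centromere-proximal window may be
    partial.  Acrocentric p-arms are skipped.  Coordinates are 0-based
    half-open.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    chrom = validate_chrom_table(chrom)
    rows = []
    for _, c in chrom.iterrows():
        if not c["acrocentric"]:
            pos, idx = 0, 0
            while pos < c["cen_start"]:
                end = min(pos + window_size, c["cen_start"])
                rows.append((c["name"], "p", idx, pos, end))
                pos, idx = end, idx + 1
        pos, idx = int(c["length"]), 0
        while pos > c["cen_end"]:
            start = max(pos - window_size, c["cen_end"])
            rows.append((c["name"], "q", idx, start, pos))
            pos, idx = start, idx + 1
    win = pd.DataFrame(rows, columns=["chrom", "arm", "index", "start", "end"])
    win["subtelomeric"] = win["index"] == 0
    win["window_id"] = (
        win["chrom"].astype(str) + win["arm"] + "_w" + win["index"].astype(str)
    )
    return win.set_index("window_id")


def assign_genes(
    genes: pd.DataFrame,
    windows: pd.DataFrame,
    chrom: pd.DataFrame,
    expressed: Sequence[str] | None = None,
    min_genes: int = MIN_GENES,
    by: Literal["midpoint", "tss"] = "midpoint",
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign each gene to the window containing its midpoint (or TSS).

    Returns the window table augmented with gene counts and the retained
    flag (>= ``min_genes`` expressed genes), plus a gene_id -> window_id
    Series (NaN for genes on skipped arms or inside the centromere).
    """
    chrom = validate_chrom_table(chrom).set_index("name")
    genes = genes.copy()
    beyond = genes["end"] > genes["chrom"].map(chrom["length"])
    if beyond.any():
        raise ValueError(
            f"genes beyond chromosome end: {list(genes.loc[beyond, 'gene_id'])[:5]}"
        )
    if by == "midpoint":
        anchor = (genes["start"] + genes["end"]) / 2
    else:
        anchor = np.where(
            genes.get("strand", pd.Series("+", index=genes.index)) == "-",
            genes["end"] - 1,
            genes["start"],
        )
    genes["anchor"] = anchor
    assignment = pd.Series(pd.NA, index=genes["gene_id"], dtype=object)
    for wid, w in windows.iterrows():
        inside = (
            (genes["chrom"] == w["chrom"])
            & (genes["anchor"] >= w["start"])
            & (genes["anchor"] < w["end"])
        )
        assignment[genes.loc[inside, "gene_id"]] = wid
    expressed_set = set(expressed) if expressed is not None else set(genes["gene_id"])
    win = windows.copy()
    counts = assignment.dropna().value_counts()
    expr_counts = assignment[assignment.index.isin(expressed_set)].dropna().value_counts()
    win["n_genes"] = counts.reindex(win.index).fillna(0).astype(int)
    win["n_expressed"] = expr_counts.reindex(win.index).fillna(0).astype(int)
    win["retained"] = win["n_expressed"] >= min_genes
    return win, assignment


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------


@dataclass
class ModeratedTModel:
    table: pd.DataFrame
    # per gene: lfc, s2, df, s2_post, t_ordinary, t_moderated, p
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the log-convex scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Models s2_g ~ s0^2 * F(df, d0): on the log scale the mean and variance
    of log s2_g involve digamma/trigamma terms of df/2 and d0/2, which are
    matched to the empirical moments.  Returns d0 = inf (complete
    shrinkage) when the residual spread of log s2 is at or below what
    sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need >= 2 positive sample variances")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def moderated_t(
    expr: pd.DataFrame,
    groups: Sequence[str] | pd.Series,
    d0_override: float | None = None,
) -> ModeratedTModel:
    """Two-group moderated t per gene (short minus normal).

    Per-gene pooled variance s2_g with df = n1 + n2 - 2 is shrunk towards
    the fitted prior: s2_post = (d0*s0^2 + df*s2_g)/(d0 + df); the
    moderated t uses s2_post and d0 + df degrees of freedom.  Setting
    ``d0_override=0`` disables shrinkage (ordinary t).
    """
    groups = pd.Series(np.asarray(groups), index=expr.columns)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    # convention: 'short' minus the other level when present
    if "short" in levels:
        g1, g2 = "short", [l for l in levels if l != "short"][0]
    else:
        g1, g2 = levels[1], levels[0]
    x1 = expr.loc[:, groups == g1]
    x2 = expr.loc[:, groups == g2]
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    df = n1 + n2 - 2
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)) / df
    c = np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = lfc / (np.sqrt(s2) * c)
    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = (
            fit_variance_prior(s2.values, df) if d0 > 0 else (None, float(np.mean(s2)))
        )
        if d0 == 0:
            s0_sq = float(np.mean(s2))  # irrelevant: zero weight
    else:
        d0, s0_sq = fit_variance_prior(s2.values, df)
    if np.isinf(d0):
        s2_post = pd.Series(s0_sq, index=s2.index)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    t_mod = lfc / (np.sqrt(s2_post) * c)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    table = pd.DataFrame(
        {
            "lfc": lfc,
            "s2": s2,
            "df": float(df),
            "s2_post": s2_post,
            "t_ordinary": t_ord,
            "t_moderated": t_mod,
            "p": p,
        }
    )
    return ModeratedTModel(table=table, d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# Preranked enrichment
# ---------------------------------------------------------------------------


def running_sum_es(
    ranked_stats: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0
) -> float:
    """Enrichment score: extremum of the weighted KS running sum.

    ``ranked_stats`` must already be sorted in descending order;
    ``hit_mask`` marks set members at each rank.  Hit steps are
    proportional to |stat|^weight, miss steps uniform.
    """
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = hit_mask.size
    n_hit = int(hit_mask.sum())
    n_miss = n - n_hit
    if n_hit == 0 or n_miss == 0:
        return np.nan
    w = np.abs(ranked_stats) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hit_mask.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~hit_mask) / n_miss
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per retained window: size, es, nes, p, q
    n_perm: int
    seed: int | None


def preranked_enrichment(
    gene_stats: pd.Series,
    windows: pd.DataFrame,
    membership: pd.Series,
    n_perm: int = 1000,
    seed: int | None = 0,
    weight: float = 1.0,
    fdr_method: Literal["pooled_nes", "bh_nominal"] = "pooled_nes",
) -> EnrichmentResult:
    """Window enrichment on a preranked gene statistic.

    Genes are ranked by the statistic (descending); each retained window is
    scored by the weighted running-sum ES.  The null is gene-label
    permutation preserving set size; NES divides ES by the mean |null ES|
    of matching sign, nominal p is the same-sign null tail, and FDR follows
    the pooled-NES procedure (a BH-on-nominal-p alternative is available).
    """
    gene_stats = gene_stats.dropna()
    order = np.argsort(-gene_stats.values, kind="mergesort")
    ranked = gene_stats.values[order]
    ranked_genes = pd.Index(gene_stats.index[order])
    n = ranked_genes.size
    rng = np.random.default_rng(seed)
    retained = windows.index[windows["retained"]] if "retained" in windows else windows.index
    rows = {}
    null_by_size: dict[int, np.ndarray] = {}
    for wid in retained:
        members = set(membership.index[membership == wid]) & set(ranked_genes)
        size = len(members)
        if size == 0:
            continue
        if size >= n:
            logger.warning("window %s spans the whole gene universe; ES undefined", wid)
            rows[wid] = (size, np.nan, np.nan, np.nan)
            continue
        hit = ranked_genes.isin(members)
        es = running_sum_es(ranked, hit, weight)
        if size not in null_by_size:
            null = np.empty(n_perm)
            for i in range(n_perm):
                idx = rng.choice(n, size=size, replace=False)
                mask = np.zeros(n, dtype=bool)
                mask[idx] = True
                null[i] = running_sum_es(ranked, mask, weight)
            null_by_size[size] = null
        null = null_by_size[size]
        same = null[null * np.sign(es) >= 0] if es != 0 else null
        if same.size == 0:
            nes, p = np.nan, np.nan
        else:
            nes = es / np.mean(np.abs(same))
            p = float(np.mean(np.abs(same) >= abs(es)))
        rows[wid] = (size, es, nes, p)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["size", "es", "nes", "p"]
    )
    table.index.name = "window_id"
    # FDR
    if fdr_method == "bh_nominal":
        ok = table["p"].notna()
        table["q"] = np.nan
        table.loc[ok, "q"] = stattests.bh_fdr(table.loc[ok, "p"].values)
    else:
        table["q"] = _pooled_nes_fdr(table, null_by_size)
    return EnrichmentResult(table=table, n_perm=n_perm, seed=seed)


def _pooled_nes_fdr(
    table: pd.DataFrame, null_by_size: dict[int, np.ndarray]
) -> pd.Series:
    """Pooled-NES FDR of the standard preranked procedure.

    Every null ES is normalized by the mean |same-sign null| of its own
    size class; observed and null NES are then pooled and, for each
    observed NES*, q = [fraction of same-sign null NES at least as extreme]
    / [fraction of same-sign observed NES at least as extreme], clipped to
    [0, 1].
    """
    null_nes_all = []
    for size, null in null_by_size.items():
        pos = null[null >= 0]
        neg = null[null < 0]
        mean_pos = np.mean(pos) if pos.size else np.nan
        mean_neg = np.mean(np.abs(neg)) if neg.size else np.nan
        nn = np.where(null >= 0, null / mean_pos, null / mean_neg)
        null_nes_all.append(nn[np.isfinite(nn)])
    null_nes = np.concatenate(null_nes_all) if null_nes_all else np.array([])
    obs = table["nes"].dropna().values
    q = pd.Series(np.nan, index=table.index)
    for wid, nes in table["nes"].items():
        if not np.isfinite(nes) or null_nes.size == 0:
            continue
        if nes >= 0:
            frac_null = np.mean(null_nes[null_nes >= 0] >= nes) if (null_nes >= 0).any() else 0.0
            frac_obs = np.mean(obs[obs >= 0] >= nes) if (obs >= 0).any() else 1.0
        else:
            frac_null = np.mean(null_nes[null_nes < 0] <= nes) if (null_nes < 0).any() else 0.0
            frac_obs = np.mean(obs[obs < 0] <= nes) if (obs < 0).any() else 1.0
        q[wid] = min(1.0, frac_null / max(frac_obs, 1e-12))
    return q


# ---------------------------------------------------------------------------
# Compartment comparison
# ---------------------------------------------------------------------------


@dataclass
class CompartmentComparison:
    median_subtelomeric: float
    median_interior: float
    wilcoxon_paired: TestResult | None
    mann_whitney_unpaired: TestResult | None
    fisher_windows: TestResult | None
    window_counts: ContingencyTable2x2 | None
    arm_medians: pd.DataFrame  # per arm: subtelomeric and interior median t


def compare_compartments(
    model: ModeratedTModel,
    windows: pd.DataFrame,
    membership: pd.Series,
    enrichment: EnrichmentResult | None = None,
    fdr_threshold: float = WINDOW_FDR,
) -> CompartmentComparison:
    """Subtelomeric vs interior comparison of the per-gene statistics.

    Medians of the moderated t over genes in index-0 (telomere-adjacent)
    windows vs all interior windows; a paired Wilcoxon across arms (each
    arm contributes its subtelomeric median minus its interior median,
    arms lacking either side are excluded); an unpaired Mann-Whitney
    alternative; and, when enrichment results are supplied, a Fisher exact
    test on significant-window counts (FDR < threshold) by compartment.
    """
    t = model.table["t_moderated"]
    gene_window = membership.dropna()
    sub_wids = set(windows.index[windows["subtelomeric"]])
    in_sub = gene_window.isin(sub_wids)
    t_sub = t.reindex(gene_window.index[in_sub]).dropna()
    t_int = t.reindex(gene_window.index[~in_sub]).dropna()
    if t_sub.empty or t_int.empty:
        raise ValueError("a compartment has no genes with statistics")
    # arm-level pairing
    win_arm = windows["chrom"].astype(str) + windows["arm"]
    arm_of_gene = gene_window.map(win_arm)
    rows = []
    for arm in sorted(win_arm.unique()):
        genes_on_arm = gene_window.index[arm_of_gene == arm]
        sub_genes = [g for g in genes_on_arm if gene_window[g] in sub_wids]
        int_genes = [g for g in genes_on_arm if gene_window[g] not in sub_wids]
        if not sub_genes or not int_genes:
            logger.info("arm %s lacks a compartment; excluded from pairing", arm)
            continue
        rows.append(
            (arm, float(t.reindex(sub_genes).median()), float(t.reindex(int_genes).median()))
        )
    arm_medians = pd.DataFrame(rows, columns=["arm", "subtelomeric", "interior"]).set_index("arm")
    wilcoxon = None
    if len(arm_medians) >= 1:
        diffs = (arm_medians["subtelomeric"] - arm_medians["interior"]).values
        try:
            wilcoxon = stattests.wilcoxon_signed_rank(diffs, "two_sided")
        except ValueError as exc:
            logger.warning("paired Wilcoxon degenerate: %s", exc)
    mw = stattests.mann_whitney(t_sub.values, t_int.values, "two_sided")
    fisher = counts = None
    if enrichment is not None:
        etab = enrichment.table.dropna(subset=["q"])
        is_sub = etab.index.isin(sub_wids)
        sig = etab["q"] < fdr_threshold
        try:
            counts = ContingencyTable2x2(
                int((is_sub & sig).sum()),
                int((is_sub & ~sig).sum()),
                int((~is_sub & sig).sum()),
                int((~is_sub & ~sig).sum()),
            )
            fisher = stattests.fisher_exact(counts, "two_sided")
        except ValueError as exc:
            logger.warning("window-count Fisher degenerate: %s", exc)
    return CompartmentComparison(
        median_subtelomeric=float(t_sub.median()),
        median_interior=float(t_int.median()),
        wilcoxon_paired=wilcoxon,
        mann_whitney_unpaired=mw,
        fisher_windows=fisher,
        window_counts=counts,
        arm_medians=arm_medians,
    )
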