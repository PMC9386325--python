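"""Targeted-panel expression processing.

QC on aligned-read totals, seeded hypergeometric down-sampling to a common
depth, log2CPM normalization, preservation-batch adjustment, exclusion of
FFPE samples dominated by extreme values, reference-cohort outlier fences
(Tukey and median±IQR), per-gene differential expression (Mann-Whitney +
BH, plus the twofold outlier-frequency route) and the TERT
expression-negativity rule.

The reference cohort throughout is the disease-free tumour set: fences are
computed on its expression dispersion and outliers in the aggressive
cohort are scored against them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stattests

logger = logging.getLogger(__name__)

TERT_GENE = "TERT"

Cohort = Literal["disease_free", "aggressive"]
FenceType = Literal["tukey", "median_iqr"]
Direction = Literal["high", "low", "both"]


@dataclass
class ExpressionStudy:
    """Probe x sample counts with per-sample metadata.

    ``counts``: DataFrame indexed by probe id, columns sample ids.
    ``probe_to_gene``: Series mapping probe id -> gene symbol (a gene may
    be covered by several probes; TERT has four).
    ``samples``: DataFrame indexed by sample id with at least ``cohort``
    (disease_free/aggressive) and ``preservation`` (frozen/FFPE); commonly
    also ``origin`` and ``age_at_dx``.
    """

    counts: pd.DataFrame
    probe_to_gene: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.probe_to_gene.index)
        if len(missing):
            raise ValueError(f"probes without gene mapping: {list(missing)[:5]}")
        for col in ("cohort", "preservation"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing column {col!r}")
        if not self.counts.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return pd.Index(sorted(self.probe_to_gene.unique()))

    def gene_counts(self) -> pd.DataFrame:
        """Counts summed over the probes of each gene."""
        return self.counts.groupby(self.probe_to_gene.loc[self.counts.index].values).sum()


@dataclass
class Log2CpmMatrix:
    """log2 counts-per-million with normalization provenance."""

    values: pd.DataFrame  # gene-or-probe x sample
    target_total: int | None
    pseudocount: float
    batch_adjusted: bool = False
    level: Literal["probe", "gene"] = "probe"


@dataclass
class GeneFences:
    """Per-gene outlier fences from the disease-free reference set."""

    table: pd.DataFrame  # index gene: median, q1, q3, iqr, lower, upper
    fence_type: FenceType
    direction: Direction = "both"


@dataclass
class OutlierPrint:
    flags: pd.DataFrame  # gene x sample boolean
    event_count: pd.Series  # per sample, over the candidate gene set


@dataclass
class DEResult:
    table: pd.DataFrame
    # columns: p, q, freq_reference, freq_aggressive, outlier_ratio,
    #          candidate, reason


def qc_filter_samples(
    study: ExpressionStudy, min_total: int = 170_000
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Discard samples with fewer aligned reads than ``min_total``.

    Returns the filtered study and a log of discarded samples with totals.
    """
    totals = study.counts.sum(axis=0)
    keep = totals >= min_total
    discarded = pd.DataFrame(
        {"total_reads": totals[~keep], "reason": f"total < {min_total}"}
    )
    if not keep.any():
        raise ValueError("empty study: all samples below the read threshold")
    for sid in discarded.index:
        logger.info("QC discard %s: %d aligned reads", sid, discarded.at[sid, "total_reads"])
    kept = replace(
        study,
        counts=study.counts.loc[:, keep],
        samples=study.samples.loc[keep],
    )
    return kept, discarded


def downsample_counts(
    study: ExpressionStudy, target_total: int = 170_000, seed: int | None = 0
) -> ExpressionStudy:
    """Down-sample every sample to exactly ``target_total`` reads.

    Reads are drawn without replacement from the probe-labelled pool
    (multivariate hypergeometric), so column totals are conserved exactly.
    """
    rng = np.random.default_rng(seed)
    totals = study.counts.sum(axis=0)
    low = totals[totals < target_total]
    if len(low):
        raise ValueError(
            f"samples below target total (run qc_filter_samples first): {list(low.index)[:5]}"
        )
    out = study.counts.copy()
    for sid in study.counts.columns:
        col = study.counts[sid].to_numpy(dtype=np.int64)
        if col.sum() == target_total:
            continue
        out[sid] = rng.multivariate_hypergeometric(col, target_total)
    return replace(study, counts=out)


def log2cpm(
    study: ExpressionStudy,
    pseudocount: float = 0.5,
    level: Literal["probe", "gene"] = "probe",
) -> Log2CpmMatrix:
    """log2((count + c) / (total + 2c) * 1e6) per cell."""
    counts = study.counts if level == "probe" else study.gene_counts()
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero-total sample")
    vals = np.log2((counts + pseudocount) / (totals + 2 * pseudocount) * 1e6)
    return Log2CpmMatrix(
        values=vals, target_total=None, pseudocount=pseudocount, level=level
    )


def remove_batch_effect(
    m: Log2CpmMatrix, batch: Sequence[str] | pd.Series
) -> Log2CpmMatrix:
    """Equalize per-gene batch means (location-only, grand mean preserved).

    Batch levels with fewer than two samples are passed through unadjusted
    with a warning.
    """
    batch = pd.Series(np.asarray(batch), index=m.values.columns)
    vals = m.values.copy()
    sizes = batch.value_counts()
    adjustable = sizes[sizes >= 2].index
    for lvl in sizes[sizes < 2].index:
        logger.warning("batch level %r has <2 samples; passed through", lvl)
    cols = batch.index[batch.isin(adjustable)]
    grand = vals[cols].mean(axis=1)
    for lvl in adjustable:
        sub = batch.index[batch == lvl]
        vals[sub] = vals[sub].sub(vals[sub].mean(axis=1) - grand, axis=0)
    return replace(m, values=vals, batch_adjusted=True)


def flag_ffpe_extremes(
    m: Log2CpmMatrix,
    metadata: pd.DataFrame,
    max_extreme_genes: int = 125,
    decile: float = 0.10,
) -> list[str]:
    """FFPE samples dominated by extreme values across the series.

    A sample is extreme for a gene when its value lies strictly below the
    ``decile`` quantile or strictly above the ``1-decile`` quantile of the
    whole series (frozen + FFPE); FFPE samples extreme for more than
    ``max_extreme_genes`` genes are listed for exclusion.
    """
    if m.values.shape[1] < 10:
        raise ValueError("need at least 10 samples to define deciles")
    lo = m.values.quantile(decile, axis=1)
    hi = m.values.quantile(1 - decile, axis=1)
    extreme = m.values.lt(lo, axis=0) | m.values.gt(hi, axis=0)
    n_extreme = extreme.sum(axis=0)
    ffpe = metadata.index[metadata["preservation"] == "FFPE"]
    excluded = [
        s for s in m.values.columns if s in ffpe and n_extreme[s] > max_extreme_genes
    ]
    for s in excluded:
        logger.info("FFPE extreme-value exclusion %s: %d extreme genes", s, n_extreme[s])
    return excluded


def compute_fences(
    m: Log2CpmMatrix,
    reference: Sequence[str],
    fence_type: FenceType = "tukey",
    direction: Direction = "both",
) -> GeneFences:
    """Outlier fences per gene from the disease-free reference samples.

    Quantiles by linear interpolation between order statistics.  Tukey:
    (Q1 - 1.5 IQR, Q3 + 1.5 IQR); median_iqr: (median - IQR, median + IQR).
    """
    reference = list(reference)
    if len(reference) < 4:
        raise ValueError("reference set must have >= 4 samples")
    ref = m.values[reference]
    q1 = ref.quantile(0.25, axis=1)
    q3 = ref.quantile(0.75, axis=1)
    med = ref.quantile(0.5, axis=1)
    iqr = q3 - q1
    if fence_type == "tukey":
        lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    elif fence_type == "median_iqr":
        lower, upper = med - iqr, med + iqr
    else:
        raise ValueError(f"unknown fence type {fence_type!r}")
    table = pd.DataFrame(
        {"median": med, "q1": q1, "q3": q3, "iqr": iqr, "lower": lower, "upper": upper}
    )
    return GeneFences(table=table, fence_type=fence_type, direction=direction)


def outlier_flags(
    m: Log2CpmMatrix, fences: GeneFences, direction: Direction | None = None
) -> pd.DataFrame:
    """Boolean gene x sample outlier matrix (strict fence comparisons)."""
    direction = direction or fences.direction
    common = m.values.index.intersection(fences.table.index)
    vals = m.values.loc[common]
    ftab = fences.table.loc[common]
    high = vals.gt(ftab["upper"], axis=0)
    low = vals.lt(ftab["lower"], axis=0)
    if direction == "high":
        return high
    if direction == "low":
        return low
    return high | low


def outlier_print(
    m: Log2CpmMatrix,
    gene_fences: Mapping[str, GeneFences],
    gene_directions: Mapping[str, Direction],
) -> OutlierPrint:
    """Directional per-gene outlier print over a candidate gene set.

    Each candidate gene carries its own fence type and direction (e.g.
    median+IQR high fences for the telomerase-complex genes, a Tukey upper
    fence for TINF2 and a Tukey lower fence for POT1).  Values exactly on a
    fence are not flagged.
    """
    rows = {}
    for gene, direction in gene_directions.items():
        if gene not in gene_fences:
            raise ValueError(f"no fence for candidate gene {gene!r}")
        fences = gene_fences[gene]
        if gene not in fences.table.index or gene not in m.values.index:
            raise ValueError(f"gene {gene!r} missing from matrix or fences")
        row = m.values.loc[gene]
        ftab = fences.table.loc[gene]
        if direction == "high":
            rows[gene] = row > ftab["upper"]
        elif direction == "low":
            rows[gene] = row < ftab["lower"]
        else:
            rows[gene] = (row > ftab["upper"]) | (row < ftab["lower"])
    flags = pd.DataFrame(rows).T.astype(bool)
    return OutlierPrint(flags=flags, event_count=flags.sum(axis=0))


def differential_expression(
    m: Log2CpmMatrix,
    cohorts: pd.Series,
    p_threshold: float = 0.05,
    q_threshold: float = 0.15,
    ratio_threshold: float = 2.0,
    min_ratio_outliers: int = 2,
) -> DEResult:
    """Per-gene disease-free vs aggressive comparison.

    Two routes flag a candidate gene: (i) two-tailed Mann-Whitney p <
    ``p_threshold`` with BH-adjusted q < ``q_threshold``, or (ii) at least
    a twofold higher frequency of extreme outliers (Tukey fences of the
    disease-free reference) in the aggressive cohort.  When the reference
    frequency is zero the ratio route requires at least
    ``min_ratio_outliers`` aggressive outliers.
    """
    cohorts = pd.Series(cohorts, index=m.values.columns)
    ref_ids = list(cohorts.index[cohorts == "disease_free"])
    agg_ids = list(cohorts.index[cohorts == "aggressive"])
    if len(ref_ids) < 3 or len(agg_ids) < 3:
        raise ValueError("each cohort needs >= 3 samples")
    fences = compute_fences(m, ref_ids, fence_type="tukey", direction="both")
    flags = outlier_flags(m, fences)
    pvals = pd.Series(
        {
            g: stattests.mann_whitney(
                m.values.loc[g, agg_ids], m.values.loc[g, ref_ids], "two_sided"
            ).p_value
            for g in m.values.index
        }
    )
    qvals = pd.Series(stattests.bh_fdr(pvals.values), index=pvals.index)
    freq_ref = flags[ref_ids].mean(axis=1)
    freq_agg = flags[agg_ids].mean(axis=1)
    n_agg_out = flags[agg_ids].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = freq_agg / freq_ref
    nonzero = (freq_ref > 0).values
    ratio_route = pd.Series(
        np.where(
            nonzero,
            ratio.values >= ratio_threshold,
            (freq_agg.values > 0) & (n_agg_out.values >= min_ratio_outliers),
        ),
        index=pvals.index,
    )
    mw_route = (pvals < p_threshold) & (qvals < q_threshold)
    candidate = mw_route | ratio_route
    reason = np.where(
        mw_route, "mw_significant", np.where(ratio_route, "outlier_ratio", "")
    )
    table = pd.DataFrame(
        {
            "p": pvals,
            "q": qvals,
            "freq_reference": freq_ref,
            "freq_aggressive": freq_agg,
            "outlier_ratio": ratio,
            "candidate": candidate,
            "reason": reason,
        }
    )
    return DEResult(table=table)


def tert_status(
    study: ExpressionStudy,
    min_reads: int = 3,
    rule: Literal["per_probe", "sum"] = "per_probe",
) -> pd.Series:
    """TERT expression call per sample from the four TERT probes.

    Negative when every TERT probe carries fewer than ``min_reads``
    normalized (post-down-sampling) reads; ``rule='sum'`` instead compares
    the summed TERT reads against the threshold.
    """
    tert_probes = study.probe_to_gene.index[study.probe_to_gene == TERT_GENE]
    if len(tert_probes) == 0:
        raise ValueError("no TERT probes in the study")
    sub = study.counts.loc[tert_probes]
    if rule == "per_probe":
        negative = (sub < min_reads).all(axis=0)
    elif rule == "sum":
        negative = sub.sum(axis=0) < min_reads
    else:
        raise ValueError(f"unknown TERT rule {rule!r}")
    return pd.Series(
        np.where(negative, "negative", "positive"), index=study.counts.columns
    )
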