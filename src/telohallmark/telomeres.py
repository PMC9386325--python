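"""Q-FISH telomere-length post-processing.

Telomere length is estimated as the mean telomere fluorescence intensity
per nucleus (arbitrary units of fluorescence, a.u.f.).  A panel of normal
thyroids defines a reference range (mean +/- 2 SD of the pooled
per-nucleus means); tumours whose specimen median falls at or below the
lower bound are called short, and specimens with a heavy tail of
ultra-bright signals are flagged as suspect for alternative lengthening of
telomeres (ALT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stattests
from .stattests import ContingencyTable2x2, LogisticFit, TestResult

logger = logging.getLogger(__name__)

#: Fraction-of-signals cut-off used for the "% shortest telomeres" readout
SHORTEST_CUTOFF_AUF = 20.0


@dataclass
class TelomereProfile:
    """Per-nucleus (and optionally per-signal) intensities for a specimen."""

    specimen: str
    label: Literal["normal_thyroid", "tumour"]
    nucleus_means: np.ndarray  # a.u.f., one entry per nucleus
    signal_intensities: np.ndarray | None = None  # a.u.f., per telomere signal

    def __post_init__(self) -> None:
        self.nucleus_means = np.asarray(self.nucleus_means, dtype=float)
        if self.nucleus_means.size == 0:
            raise ValueError(f"{self.specimen}: empty profile")
        if (self.nucleus_means <= 0).any():
            raise ValueError(f"{self.specimen}: intensities must be positive")
        if self.signal_intensities is not None:
            self.signal_intensities = np.asarray(self.signal_intensities, dtype=float)

    @property
    def median(self) -> float:
        """Specimen median of the per-nucleus mean intensities."""
        return float(np.median(self.nucleus_means))


@dataclass
class ReferenceRange:
    lower: float
    upper: float
    mean: float
    sd: float
    source: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("invalid reference range (lower > upper)")
        if self.lower == self.upper:
            logger.warning("zero-width reference range: any deviation is an outlier")


@dataclass
class AltRule:
    """Ultra-bright signal rule for flagging ALT-suspect specimens."""

    k: float = 5.0  # signal counts as ultra-bright above k x specimen median
    min_fraction: float = 0.01


@dataclass
class TelomereClass:
    specimen: str
    telomere_class: Literal["short", "normal", "long"]
    median: float
    alt_suspect: bool = False
    percent_shortest: float | None = None


def reference_range(
    normals: Sequence[TelomereProfile],
    level: Literal["nucleus", "specimen"] = "nucleus",
) -> ReferenceRange:
    """Normal-thyroid reference range: mean +/- 2 SD.

    By default pooled over the per-nucleus means of all normal specimens
    (``level='nucleus'``); ``level='specimen'`` uses specimen medians
    instead.
    """
    if len(normals) < 3:
        raise ValueError("need >= 3 normal specimens")
    if level == "nucleus":
        values = np.concatenate([p.nucleus_means for p in normals])
    elif level == "specimen":
        values = np.array([p.median for p in normals])
    else:
        raise ValueError(f"unknown level {level!r}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return ReferenceRange(
        lower=mean - 2 * sd,
        upper=mean + 2 * sd,
        mean=mean,
        sd=sd,
        source=tuple(p.specimen for p in normals),
    )


def classify_specimen(
    profile: TelomereProfile,
    ref: ReferenceRange,
    alt_rule: AltRule | None = None,
) -> TelomereClass:
    """Short / normal / long call from the specimen median.

    Short when median <= lower bound (inclusive), long when median >=
    upper bound.  When per-signal intensities are available the ALT rule
    flags specimens whose fraction of ultra-bright signals (> k x median)
    exceeds ``min_fraction``, and the percent of shortest telomeres is
    reported.
    """
    alt_rule = alt_rule or AltRule()
    med = profile.median
    if med <= ref.lower:
        cls = "short"
    elif med >= ref.upper:
        cls = "long"
    else:
        cls = "normal"
    alt = False
    pct = None
    if profile.signal_intensities is not None and profile.signal_intensities.size:
        bright = np.mean(profile.signal_intensities > alt_rule.k * med)
        alt = bool(bright > alt_rule.min_fraction)
        pct = percent_shortest(profile)
    return TelomereClass(
        specimen=profile.specimen,
        telomere_class=cls,
        median=med,
        alt_suspect=alt,
        percent_shortest=pct,
    )


def percent_shortest(
    profile: TelomereProfile, cutoff: float = SHORTEST_CUTOFF_AUF
) -> float:
    """% of telomere signals strictly below ``cutoff`` a.u.f."""
    if profile.signal_intensities is None or profile.signal_intensities.size == 0:
        raise ValueError(f"{profile.specimen}: no per-signal intensities")
    return float(100.0 * np.mean(profile.signal_intensities < cutoff))


@dataclass
class TelomereAssociations:
    fisher_short_x_cohort: TestResult | None
    logistic_cohort: LogisticFit | None
    pearson_median_vs_shortest: TestResult | None
    table_short_x_cohort: ContingencyTable2x2 | None = None


def telomere_associations(
    classes: Mapping[str, TelomereClass],
    cohorts: Mapping[str, str],
    ages: Mapping[str, float] | None = None,
) -> TelomereAssociations:
    """Association statistics of the telomere classification.

    Fisher exact on the short x cohort 2x2 table; binary logistic
    regression of cohort on specimen median (adjusted for age at diagnosis
    when provided); Pearson correlation of specimen median with the
    percent of shortest telomeres.  Degenerate sub-analyses are reported
    as None while the rest proceed.
    """
    ids = [s for s in classes if s in cohorts]
    short = pd.Series({s: classes[s].telomere_class == "short" for s in ids})
    aggr = pd.Series({s: cohorts[s] == "aggressive" for s in ids})
    fisher = table = None
    try:
        table = ContingencyTable2x2(
            int((aggr & short).sum()),
            int((aggr & ~short).sum()),
            int((~aggr & short).sum()),
            int((~aggr & ~short).sum()),
        )
        fisher = stattests.fisher_exact(table, "two_sided")
    except ValueError as exc:
        logger.warning("short x cohort Fisher failed: %s", exc)
    logistic = None
    try:
        medians = np.array([classes[s].median for s in ids])
        X = medians[:, None]
        if ages is not None:
            X = np.column_stack([medians, [ages[s] for s in ids]])
        logistic = stattests.logistic_fit(aggr[ids].astype(int).values, X)
    except ValueError as exc:
        logger.warning("logistic fit failed: %s", exc)
    corr = None
    try:
        with_pct = [s for s in ids if classes[s].percent_shortest is not None]
        if len(with_pct) >= 3:
            corr = stattests.pearson(
                [classes[s].median for s in with_pct],
                [classes[s].percent_shortest for s in with_pct],
            )
    except ValueError as exc:
        logger.warning("median vs %%-shortest correlation failed: %s", exc)
    return TelomereAssociations(
        fisher_short_x_cohort=fisher,
        logistic_cohort=logistic,
        pearson_median_vs_shortest=corr,
        table_short_x_cohort=table,
    )
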