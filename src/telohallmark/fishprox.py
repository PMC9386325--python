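"""5p-end / TERT co-FISH proximity analysis.

Each nucleus carries one red (TERT locus) / green (5p subtelomere) probe
pair; pairs at most 0.7 um apart are adjacent, farther pairs separated.
Per-tumour summaries report the percentage of separated pairs (with a
sufficiency flag at the 200-nucleus counting rule) and are tested against
telomere shortening and TERT promoter alteration status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Mapping

import numpy as np

from . import stattests
from .stattests import TestResult

logger = logging.getLogger(__name__)

ADJACENCY_CUTOFF_UM = 0.7
MIN_NUCLEI = 200


@dataclass
class SignalPairSet:
    """Per-nucleus probe-pair records for one specimen.

    Distance mode stores the red-green pair distance in micrometres; label
    mode stores pre-scored adjacent/separated labels (the visual scoring
    route).
    """

    specimen: str
    mode: Literal["distance", "label"]
    distances_um: np.ndarray | None = None
    labels: np.ndarray | None = None  # strings "adjacent"/"separated"

    def __post_init__(self) -> None:
        if self.mode == "distance":
            self.distances_um = np.asarray(self.distances_um, dtype=float)
            if (self.distances_um < 0).any():
                raise ValueError(f"{self.specimen}: negative distances")
        elif self.mode == "label":
            self.labels = np.asarray(self.labels, dtype=object)
            bad = set(self.labels) - {"adjacent", "separated"}
            if bad:
                raise ValueError(f"{self.specimen}: unknown labels {bad}")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_nuclei(self) -> int:
        arr = self.distances_um if self.mode == "distance" else self.labels
        return int(arr.size)


@dataclass
class SeparationSummary:
    specimen: str
    percent_separated: float
    n_nuclei: int
    sufficient: bool
    mode: str


def classify_pairs(
    pairs: SignalPairSet, cutoff: float = ADJACENCY_CUTOFF_UM
) -> SignalPairSet:
    """Label each pair: adjacent when distance <= cutoff (inclusive)."""
    if pairs.mode != "distance":
        raise ValueError("classify_pairs requires distance mode")
    labels = np.where(pairs.distances_um <= cutoff, "adjacent", "separated").astype(
        object
    )
    return replace(pairs, mode="label", labels=labels, distances_um=pairs.distances_um)


def separation_summary(
    pairs: SignalPairSet, min_nuclei: int = MIN_NUCLEI
) -> SeparationSummary:
    """% separated pairs with the counting-sufficiency flag."""
    if pairs.mode != "label":
        pairs = classify_pairs(pairs)
    n = pairs.n_nuclei
    if n == 0:
        raise ValueError(f"{pairs.specimen}: empty pair set")
    pct = float(100.0 * np.mean(pairs.labels == "separated"))
    return SeparationSummary(
        specimen=pairs.specimen,
        percent_separated=pct,
        n_nuclei=n,
        sufficient=n >= min_nuclei,
        mode=pairs.mode,
    )


@dataclass
class ProximityAssociations:
    mw_by_telomere_class: TestResult | None
    pearson_vs_shortest: TestResult | None
    mw_by_promoter_alteration: TestResult | None


def proximity_associations(
    summaries: Mapping[str, SeparationSummary],
    telomere_class: Mapping[str, str] | None = None,
    percent_shortest: Mapping[str, float] | None = None,
    promoter_altered: Mapping[str, bool] | None = None,
) -> ProximityAssociations:
    """Association of % separated pairs with telomere and TERT-locus state.

    Mann-Whitney of % separated between short and normal telomere classes,
    Pearson correlation with the % of shortest telomeres, and Mann-Whitney
    by promoter-alteration status.  Sub-analyses without matched specimens
    are returned as None.
    """
    pct = {s: m.percent_separated for s, m in summaries.items()}
    mw_class = corr = mw_alt = None
    if telomere_class:
        short = [pct[s] for s in pct if telomere_class.get(s) == "short"]
        normal = [pct[s] for s in pct if telomere_class.get(s) == "normal"]
        if len(short) >= 2 and len(normal) >= 2:
            mw_class = stattests.mann_whitney(short, normal, "two_sided")
    if percent_shortest:
        matched = [s for s in pct if s in percent_shortest]
        if len(matched) < 3:
            raise ValueError("need >= 3 matched specimens for correlation")
        corr = stattests.pearson(
            [percent_shortest[s] for s in matched], [pct[s] for s in matched]
        )
    if promoter_altered:
        with_alt = [pct[s] for s in pct if promoter_altered.get(s) is True]
        without = [pct[s] for s in pct if promoter_altered.get(s) is False]
        if len(with_alt) >= 2 and len(without) >= 2:
            mw_alt = stattests.mann_whitney(with_alt, without, "two_sided")
    return ProximityAssociations(
        mw_by_telomere_class=mw_class,
        pearson_vs_shortest=corr,
        mw_by_promoter_alteration=mw_alt,
    )
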