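"""Seeded generators for every input table of the pipeline.

Each generator emulates the statistical structure its analysis stage
assumes: a two-cohort targeted expression panel with planted per-gene
outlier tumours, binomially sampled bisulfite reads at known methylation
rates, log-normal Q-FISH nucleus intensities per telomere class, a toy
genome with a planted subtelomeric up-regulation in short-telomere
tumours, and probe-pair distances that increase with telomere shortening.

Every generator draws from its own RNG stream spawned from the master
seed, so adding or re-running one generator never perturbs another, and
output is byte-identical across runs at a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .fishprox import SignalPairSet
from .panelexpr import ExpressionStudy
from .telomeres import TelomereProfile
from .tertlocus import PromoterMethylProfile, default_regions

_STREAMS = {
    "expression": 0,
    "bisulfite": 1,
    "telomere": 2,
    "genome": 3,
    "fish_pairs": 4,
}

#: telomere-maintenance genes covered by the panel
TELOMERE_GENES = (
    "TERT", "TERC", "DKC1", "GAR1", "NOP10", "NHP2", "NAT10", "TCAB1",
    "TEP1", "POT1", "TERF1", "TERF2", "TERF2IP", "TINF2", "ACD", "ATRX",
    "DAXX", "MKRN1", "NFX1", "YLPM1", "MCRS1", "TNKS", "FBXO4", "RLIM",
    "SMG5", "SMG6",
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class OutlierGeneSpec:
    """A planted outlier gene: direction, log2 effect and the fraction of
    aggressive tumours that express the outlier."""

    gene: str
    direction: Literal["high", "low"]
    effect_log2: float
    penetrance: float

    def __post_init__(self) -> None:
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must lie in [0, 1]")
        if not np.isfinite(self.effect_log2):
            raise ValueError("effect size must be finite")


def default_outlier_genes() -> tuple[OutlierGeneSpec, ...]:
    """The seven-gene candidate structure: five telomerase-holoenzyme genes
    up-regulated in a large fraction of aggressive tumours (the rank-test
    route) and the two shelterin genes altered in a minority (the
    outlier-frequency route)."""
    return (
        OutlierGeneSpec("TERT", "high", 8.0, 0.5),
        OutlierGeneSpec("TERC", "high", 2.0, 0.5),
        OutlierGeneSpec("DKC1", "high", 1.5, 0.5),
        OutlierGeneSpec("TCAB1", "high", 1.5, 0.5),
        OutlierGeneSpec("NAT10", "high", 1.5, 0.5),
        OutlierGeneSpec("TINF2", "high", 3.0, 0.25),
        OutlierGeneSpec("POT1", "low", -3.0, 0.25),
    )


@dataclass
class ExpressionParams:
    n_disease_free: int = 58
    n_aggressive: int = 48
    n_genes: int = 187
    n_probes: int = 227
    total_reads: int = 250_000
    low_depth_fraction: float = 0.0  # fraction of samples emitted below QC
    low_depth_reads: int = 150_000
    ffpe_fraction: float = 0.33
    dirichlet_alpha: float = 0.5
    #: planted genes get this fraction of the average probe weight, so an
    #: outlier multiplication perturbs the panel composition only mildly
    planted_weight_factor: float = 0.3
    #: TERT is essentially silent outside outlier tumours: its probes get a
    #: weight yielding < 3 expected reads at the down-sampling depth, so
    #: non-outlier samples score TERT-expression negative
    tert_baseline_weight: float = 2e-6
    outlier_genes: tuple[OutlierGeneSpec, ...] = field(
        default_factory=default_outlier_genes
    )


@dataclass
class MethylationParams:
    #: per-pattern true methylation fraction (applied to every CpG site)
    class_rates: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.60, "moderate": 0.25, "low": 0.05}
    )
    #: specimens per pattern (cohort-scale default)
    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"high": 15, "moderate": 39, "low": 34}
    )
    coverage: int = 1000
    n_thor: int = 29
    n_proximal: int = 10


@dataclass
class TelomereParams:
    """Arithmetic mean/SD of per-nucleus intensity (a.u.f.) per class."""

    normal_mean: float = 28.5
    normal_sd: float = 2.75
    short_mean: float = 15.0
    short_sd: float = 3.0
    n_normal_specimens: int = 9
    n_tumours_normal: int = 10
    n_tumours_short: int = 8
    n_tumours_alt: int = 0
    #: specimen-level spread, nested inside the class SD (the class SD is
    #: the total spread of nucleus means across the class)
    between_specimen_sd: float = 0.5
    nuclei_per_specimen: int = 100
    signals_per_nucleus: int = 30
    signal_sd: float = 8.0
    alt_bright_fraction: float = 0.02
    alt_bright_factor: float = 10.0


@dataclass
class GenomeParams:
    n_chromosomes: int = 4
    chrom_length: int = 60_000_000
    centromere: tuple[int, int] = (28_000_000, 32_000_000)
    genes_per_window: int = 40
    window_size: int = 5_000_000
    delta_log2: float = 0.5  # planted subtelomeric shift in short tumours
    gene_sd: float = 1.0
    n_short: int = 10
    n_normal: int = 5
    affected_arms: Literal["all"] | tuple[str, ...] = "all"


@dataclass
class PairParams:
    base_distance_um: float = 0.45
    slope_um_per_pct: float = 0.008  # distance increase per % shortest
    noise_sd_um: float = 0.30
    nuclei_per_specimen: int = 220


@dataclass
class SynthConfig:
    seed: int = 0
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    methylation: MethylationParams = field(default_factory=MethylationParams)
    telomere: TelomereParams = field(default_factory=TelomereParams)
    genome: GenomeParams = field(default_factory=GenomeParams)
    pairs: PairParams = field(default_factory=PairParams)


# ---------------------------------------------------------------------------
# Expression cohort
# ---------------------------------------------------------------------------


def _panel_layout(p: ExpressionParams) -> tuple[list[str], pd.Series]:
    """Gene list and probe->gene map; TERT gets four probes, remaining
    probes are spread over the other genes."""
    named = [g for g in TELOMERE_GENES if p.n_genes >= len(TELOMERE_GENES)]
    generic = [f"G{i:03d}" for i in range(p.n_genes - len(named))]
    genes = list(named) + generic
    if len(genes) != p.n_genes:
        genes = genes[: p.n_genes]
    extra = p.n_probes - p.n_genes - 3  # TERT takes 3 extra probes
    if extra < 0:
        raise ValueError("n_probes must be >= n_genes + 3 (four TERT probes)")
    probes: dict[str, str] = {}
    n_tert = 4 if "TERT" in genes else 1
    for k in range(n_tert):
        probes[f"TERT_p{k+1}"] = "TERT"
    doubled = [g for g in genes if g != "TERT"][:extra]
    for g in genes:
        if g == "TERT":
            continue
        probes[f"{g}_p1"] = g
        if g in doubled:
            probes[f"{g}_p2"] = g
    return genes, pd.Series(probes, name="gene")


def gen_expression_cohort(
    cfg: SynthConfig,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Two-cohort targeted-panel counts with planted outlier tumours.

    Counts per sample are multinomial over probes with Dirichlet-drawn
    panel weights; a planted outlier multiplies the weights of the gene's
    probes by 2^effect in a penetrance-fraction of aggressive samples.
    Returns the study plus a truth table of (gene, sample) planted
    outliers.
    """
    p = cfg.expression
    rng = _rng(cfg.seed, "expression")
    genes, probe_to_gene = _panel_layout(p)
    probe_ids = list(probe_to_gene.index)
    base_w = rng.dirichlet(np.full(len(probe_ids), p.dirichlet_alpha))
    base_w = np.maximum(base_w, 1e-6)
    planted_gene_names = {s.gene for s in p.outlier_genes}
    for i, pr in enumerate(probe_ids):
        g = probe_to_gene[pr]
        if g == "TERT":
            base_w[i] = p.tert_baseline_weight
        elif g in planted_gene_names:
            base_w[i] = p.planted_weight_factor / len(probe_ids)
    base_w /= base_w.sum()
    sample_ids = [f"DF_{i+1:03d}" for i in range(p.n_disease_free)] + [
        f"AG_{i+1:03d}" for i in range(p.n_aggressive)
    ]
    cohort = ["disease_free"] * p.n_disease_free + ["aggressive"] * p.n_aggressive
    origin = ["primary"] * p.n_disease_free + [
        "metastasis" if rng.random() < 0.3 else "primary"
        for _ in range(p.n_aggressive)
    ]
    preservation = np.where(
        rng.random(len(sample_ids)) < p.ffpe_fraction, "FFPE", "frozen"
    )
    age = np.clip(rng.normal(48, 15, len(sample_ids)).round(1), 18, 90)
    low_depth = rng.random(len(sample_ids)) < p.low_depth_fraction
    truth_rows = []
    gene_probe_idx = {
        g: [i for i, pr in enumerate(probe_ids) if probe_to_gene[pr] == g]
        for g in genes
    }
    counts = np.zeros((len(probe_ids), len(sample_ids)), dtype=np.int64)
    aggressive_ids = [s for s, c in zip(sample_ids, cohort) if c == "aggressive"]
    planted: dict[str, list[str]] = {}
    for spec in p.outlier_genes:
        n_hit = int(round(spec.penetrance * len(aggressive_ids)))
        hits = list(
            rng.choice(aggressive_ids, size=n_hit, replace=False)
        ) if n_hit else []
        planted[spec.gene] = hits
        truth_rows += [
            {"gene": spec.gene, "sample": s, "direction": spec.direction} for s in hits
        ]
    effect_of = {s.gene: s.effect_log2 for s in p.outlier_genes}
    for j, sid in enumerate(sample_ids):
        w = base_w.copy()
        for gene, hits in planted.items():
            if sid in hits:
                w[gene_probe_idx[gene]] *= 2.0 ** effect_of[gene]
        w /= w.sum()
        total = p.low_depth_reads if low_depth[j] else p.total_reads
        counts[:, j] = rng.multinomial(total, w)
    study = ExpressionStudy(
        counts=pd.DataFrame(counts, index=probe_ids, columns=sample_ids),
        probe_to_gene=probe_to_gene,
        samples=pd.DataFrame(
            {
                "cohort": cohort,
                "origin": origin,
                "preservation": preservation,
                "age_at_dx": age,
            },
            index=sample_ids,
        ),
    )
    truth = pd.DataFrame(truth_rows, columns=["gene", "sample", "direction"])
    return study, truth


# ---------------------------------------------------------------------------
# Bisulfite counts
# ---------------------------------------------------------------------------


def gen_bisulfite_counts(
    cfg: SynthConfig,
) -> tuple[list[PromoterMethylProfile], pd.DataFrame]:
    """Binomially sampled per-CpG methylation counts at known rates.

    Each specimen belongs to a methylation pattern (class) with a true
    per-site methylation fraction; methylated read counts are
    Binomial(coverage, rate).  Returns profiles plus the truth table of
    per-specimen classes and rates.
    """
    p = cfg.methylation
    if p.coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng = _rng(cfg.seed, "bisulfite")
    regions = default_regions(p.n_thor, p.n_proximal)
    sites = list(regions.full)
    profiles, rows = [], []
    for cls in sorted(p.class_sizes):
        rate = float(p.class_rates[cls])
        if not 0 <= rate <= 1:
            raise ValueError(f"rate for class {cls!r} outside [0,1]")
        for i in range(p.class_sizes[cls]):
            sid = f"{cls.upper()}_{i+1:03d}"
            n_meth = rng.binomial(p.coverage, rate, size=len(sites))
            tab = pd.DataFrame(
                {"n_meth": n_meth, "n_unmeth": p.coverage - n_meth}, index=sites
            )
            profiles.append(
                PromoterMethylProfile(specimen=sid, sites=tab, regions=regions)
            )
            rows.append({"specimen": sid, "pattern": cls, "true_rate": rate})
    return profiles, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Telomere Q-FISH profiles
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def gen_telomere_profiles(
    cfg: SynthConfig,
) -> tuple[list[TelomereProfile], pd.DataFrame]:
    """Log-normal per-nucleus Q-FISH intensities per telomere class.

    Normal thyroids and normal-telomere tumours share the normal-class
    parameters; short-telomere tumours use the short-class parameters;
    ALT-class specimens additionally replace a fraction of signals with
    ultra-bright values.  Per-signal intensities scatter around each
    nucleus mean.  Returns profiles plus the class truth table.
    """
    p = cfg.telomere
    if min(p.normal_mean, p.normal_sd, p.short_mean, p.short_sd) <= 0:
        raise ValueError("telomere class parameters must be positive")
    rng = _rng(cfg.seed, "telomere")
    profiles, rows = [], []

    def make(sid: str, label: str, cls: str, mean: float, sd: float, alt: bool):
        between = min(p.between_specimen_sd, 0.9 * sd)
        within = float(np.sqrt(sd**2 - between**2))
        shift = rng.normal(0.0, between)
        mu, sigma = _lognormal_params(max(mean + shift, 1.0), within)
        nuclei = rng.lognormal(mu, sigma, size=p.nuclei_per_specimen)
        signals = np.abs(
            rng.normal(
                np.repeat(nuclei, p.signals_per_nucleus),
                p.signal_sd,
            )
        )
        signals = np.maximum(signals, 0.1)
        if alt:
            n_bright = int(round(p.alt_bright_fraction * signals.size))
            idx = rng.choice(signals.size, size=n_bright, replace=False)
            signals[idx] = p.alt_bright_factor * np.median(nuclei)
        profiles.append(
            TelomereProfile(
                specimen=sid,
                label=label,
                nucleus_means=nuclei,
                signal_intensities=signals,
            )
        )
        rows.append({"specimen": sid, "true_class": cls, "alt": alt})

    for i in range(p.n_normal_specimens):
        make(f"NT_{i+1:02d}", "normal_thyroid", "normal", p.normal_mean, p.normal_sd, False)
    for i in range(p.n_tumours_normal):
        make(f"TU_N_{i+1:02d}", "tumour", "normal", p.normal_mean, p.normal_sd, False)
    for i in range(p.n_tumours_short):
        make(f"TU_S_{i+1:02d}", "tumour", "short", p.short_mean, p.short_sd, False)
    for i in range(p.n_tumours_alt):
        make(f"TU_A_{i+1:02d}", "tumour", "alt", p.normal_mean, p.normal_sd, True)
    return profiles, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Toy genome with planted subtelomeric effect
# ---------------------------------------------------------------------------


def gen_toy_genome(
    cfg: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Toy chromosomes, a uniform gene catalog and two-group expression
    with a planted subtelomeric log2 shift.

    Genes are placed uniformly along each chromosome (outside the
    centromere); genes whose midpoint lies within one window of an
    affected arm's telomeric end receive a mean shift of ``delta_log2`` in
    the short-telomere group.  Returns (chrom table, gene BED-like table,
    expression matrix, group labels, per-gene truth).
    """
    g = cfg.genome
    if g.chrom_length <= 2 * g.window_size:
        raise ValueError("chromosome length must exceed twice the window size")
    rng = _rng(cfg.seed, "genome")
    chrom = pd.DataFrame(
        {
            "name": [f"chr{i+1}" for i in range(g.n_chromosomes)],
            "length": g.chrom_length,
            "cen_start": g.centromere[0],
            "cen_end": g.centromere[1],
            "acrocentric": False,
        }
    )
    density = g.genes_per_window / g.window_size  # genes per bp
    rows = []
    gi = 0
    for _, c in chrom.iterrows():
        for arm_start, arm_end in (
            (0, c["cen_start"]),
            (c["cen_end"], c["length"]),
        ):
            n_genes = int(round(density * (arm_end - arm_start)))
            starts = np.sort(
                rng.integers(arm_start, arm_end - 10_000, size=n_genes)
            )
            for s in starts:
                length = int(rng.integers(1_000, 9_000))
                rows.append(
                    {
                        "chrom": c["name"],
                        "start": int(s),
                        "end": int(min(s + length, arm_end)),
                        "gene_id": f"TG{gi:05d}",
                        "strand": "+" if rng.random() < 0.5 else "-",
                    }
                )
                gi += 1
    genes = pd.DataFrame(rows)
    mid = (genes["start"] + genes["end"]) / 2
    arm = np.where(mid < chrom.set_index("name").loc[genes["chrom"], "cen_start"].values, "p", "q")
    dist_to_end = np.where(
        arm == "p", mid, g.chrom_length - mid
    )
    subtel = dist_to_end < g.window_size
    arm_name = genes["chrom"].astype(str) + arm
    if g.affected_arms == "all":
        affected = subtel
    else:
        affected = subtel & arm_name.isin(g.affected_arms).values
    n_samples = g.n_short + g.n_normal
    sample_ids = [f"S_{i+1:02d}" for i in range(g.n_short)] + [
        f"N_{i+1:02d}" for i in range(g.n_normal)
    ]
    groups = pd.Series(
        ["short"] * g.n_short + ["normal"] * g.n_normal, index=sample_ids
    )
    baseline = rng.normal(5.0, 1.5, size=len(genes))
    expr = rng.normal(
        baseline[:, None], g.gene_sd, size=(len(genes), n_samples)
    )
    expr[np.ix_(np.flatnonzero(affected), np.arange(g.n_short))] += g.delta_log2
    expr = pd.DataFrame(expr, index=genes["gene_id"].values, columns=sample_ids)
    truth = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "arm": arm_name,
            "subtelomeric": subtel,
            "affected": affected,
        }
    ).set_index("gene_id")
    return chrom, genes, expr, groups, truth


# ---------------------------------------------------------------------------
# Co-FISH probe-pair distances
# ---------------------------------------------------------------------------


def gen_fish_pairs(
    cfg: SynthConfig, percent_shortest: Mapping[str, float]
) -> dict[str, SignalPairSet]:
    """Per-nucleus 5p-end/TERT pair distances per tumour.

    The mean distance of a tumour increases linearly with its percentage
    of shortest telomeres (configured slope); per-nucleus distances are
    normal around that mean, truncated at zero.
    """
    p = cfg.pairs
    rng = _rng(cfg.seed, "fish_pairs")
    out = {}
    for sid in sorted(percent_shortest):
        mu = p.base_distance_um + p.slope_um_per_pct * float(percent_shortest[sid])
        d = rng.normal(mu, p.noise_sd_um, size=p.nuclei_per_specimen)
        d = np.maximum(d, 0.0)
        out[sid] = SignalPairSet(specimen=sid, mode="distance", distances_um=d)
    return out
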