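"""Synthetic cohorts, promoters, peak sets and annotation tables.

The simulators emulate the statistical structure the analysis assumes so
that every downstream stage is testable without any external download:

* ``simulate_cohort`` — negative-binomial counts for a tumor cohort with an
  amplified subgroup; the driver gene and a planted set of driver-responsive
  target genes have their mean shifted by ``2**log2fc`` in amplified samples.
* ``simulate_genome`` — random promoter sequences on one synthetic
  chromosome, with an exact CACGTG planted at a recorded offset in a truth
  subset of genes.
* ``simulate_chip`` — narrowPeak-level peak sets per cell line: amplified
  lines get peaks covering the planted E-boxes, non-amplified lines only
  decoy peaks at random positions.
* ``simulate_annotations`` — COMPARTMENTS-style localization scores and a
  GTEx-style normal-tissue table with planted membrane / CNS-restricted /
  secreted flags.

Every simulator is fully deterministic under its seed, and every planted
truth set is returned so recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .io_formats import (
    MYCN_AMPLIFIED,
    MYCN_NON_AMPLIFIED,
    ConfigError,
    ExpressionMatrix,
    GeneAnnotationRecord,
    GenomicInterval,
    LocalizationRecord,
    Peak,
    RAW_COUNTS,
    SampleAnnotation,
    TissueExpressionProfile,
)
from .regulatory import CANONICAL_EBOX, PromoterWindow, promoter_window

__all__ = [
    "CohortSimConfig",
    "GenomeSimConfig",
    "ChipSimConfig",
    "GenomeSim",
    "AnnotationSim",
    "simulate_cohort",
    "simulate_genome",
    "simulate_chip",
    "simulate_annotations",
    "PERIPHERAL_TISSUES",
]

DEFAULT_DRIVER = "MYCN"

#: Non-CNS tissues of the simulated normal-tissue panel.
PERIPHERAL_TISSUES = ("liver", "lung", "heart", "kidney", "whole_blood", "skin")


@dataclass
class CohortSimConfig:
    """Negative-binomial tumor-cohort simulation parameters.

    Defaults mirror the discovery setting the pipeline addresses: a cohort
    on the order of 10^2 tumors with ~40% carrying the amplification, target
    genes planted at log2 fold change 1.5 (comfortably past the screen's
    ``log_fc > 1`` threshold), moderate NB dispersion, and a driver gene
    planted at log2fc 3 so that status-based and quantile-based
    stratification select concordant groups.
    """

    n_genes: int = 2000
    n_samples: int = 60
    amplified_fraction: float = 0.4
    driver_gene_id: str = DEFAULT_DRIVER
    n_target_genes: int = 50
    target_log2fc: float = 1.5
    driver_log2fc: float = 3.0
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target_genes >= self.n_genes:
            raise ConfigError("n_target_genes must be < n_genes")
        if not (0.0 < self.amplified_fraction < 1.0):
            raise ConfigError("amplified_fraction must be in (0, 1)")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ConfigError("nb_dispersion and baseline_mean must be > 0")
        n_amp = round(self.amplified_fraction * self.n_samples)
        if n_amp < 2 or self.n_samples - n_amp < 2:
            raise ConfigError(
                "amplified_fraction must leave >= 2 samples in each group"
            )


@dataclass
class GenomeSimConfig:
    """Synthetic chromosome / promoter simulation parameters."""

    n_genes: int = 2000
    chrom_length: int = 3_000_000
    promoter_len: int = 400
    ebox_plant_probability: float = 0.5
    background_gc: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        if self.promoter_len < 6:
            raise ConfigError("promoter_len must be >= 6 to fit the motif")
        if not (0.0 < self.background_gc < 1.0):
            raise ConfigError("background_gc must be in (0, 1)")
        spacing = self.chrom_length // (self.n_genes + 1)
        if spacing <= self.promoter_len + 2:
            raise ConfigError(
                "chrom_length too short: promoters would overlap "
                f"(spacing {spacing} vs promoter {self.promoter_len})"
            )


@dataclass
class ChipSimConfig:
    """ChIP peak-set simulation parameters (narrowPeak-level, no reads)."""

    n_cell_lines: int = 3
    amplified_flags: Sequence[bool] = (True, True, True)
    peak_q_at_planted_sites: float = 0.001
    decoy_peak_rate: float = 0.0
    peak_halfwidth: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.amplified_flags) != self.n_cell_lines:
            raise ConfigError(
                f"amplified_flags has {len(self.amplified_flags)} entries for "
                f"{self.n_cell_lines} cell lines"
            )
        if not (0.0 < self.peak_q_at_planted_sites < 1.0):
            raise ConfigError("peak_q_at_planted_sites must be in (0, 1)")
        if self.decoy_peak_rate < 0:
            raise ConfigError("decoy_peak_rate must be >= 0")


class GenomeSim(NamedTuple):
    """Output of :func:`simulate_genome`."""

    records: list[GeneAnnotationRecord]
    promoters: dict[str, str]           # gene_id -> sequence, 5'->3' on gene strand
    windows: dict[str, PromoterWindow]
    truth: set[str]                     # genes with a planted E-box
    planted_sites: dict[str, GenomicInterval]  # genomic interval of each plant
    chrom_length: int


class AnnotationSim(NamedTuple):
    """Output of :func:`simulate_annotations`."""

    localizations: list[LocalizationRecord]
    profiles: list[TissueExpressionProfile]
    truth: dict[str, tuple[bool, bool, bool]]  # gene -> (membrane, cns_only, secreted)


def default_gene_ids(n_genes: int, driver: str = DEFAULT_DRIVER) -> list[str]:
    """Driver first, then zero-padded synthetic identifiers."""
    return [driver] + [f"G{i:05d}" for i in range(1, n_genes)]


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], set[str]]:
    """Draw a negative-binomial count cohort with planted driver targets.

    Counts for gene g, sample s are NB with mean ``mu_g * 2**lfc_g`` in
    amplified samples (``lfc_g`` = ``target_log2fc`` for planted targets,
    ``driver_log2fc`` for the driver, 0 otherwise) and variance
    ``mu + dispersion * mu**2``. Per-gene baseline means are log-normal
    around ``baseline_mean`` so a mean-variance trend exists for the
    precision-weight fit to find. Returns the matrix (raw counts), sample
    annotations with amplification status, and the planted target set
    (driver excluded).
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = default_gene_ids(config.n_genes, config.driver_gene_id)
    sample_ids = [f"T{j:04d}" for j in range(config.n_samples)]

    n_amp = round(config.amplified_fraction * config.n_samples)
    amp_idx = rng.choice(config.n_samples, size=n_amp, replace=False)
    amplified = np.zeros(config.n_samples, dtype=bool)
    amplified[amp_idx] = True

    targets = set(
        rng.choice(gene_ids[1:], size=config.n_target_genes, replace=False).tolist()
    )

    base = rng.lognormal(
        mean=math.log(config.baseline_mean), sigma=1.0, size=config.n_genes
    )
    lfc = np.zeros(config.n_genes)
    for i, g in enumerate(gene_ids):
        if g == config.driver_gene_id:
            lfc[i] = config.driver_log2fc
        elif g in targets:
            lfc[i] = config.target_log2fc

    mu = base[:, None] * np.where(amplified[None, :], 2.0 ** lfc[:, None], 1.0)
    size = 1.0 / config.nb_dispersion  # NB "n" parameter; var = mu + phi*mu^2
    counts = rng.negative_binomial(size, size / (size + mu)).astype(float)

    matrix = ExpressionMatrix(gene_ids, sample_ids, counts, RAW_COUNTS)
    annotations = [
        SampleAnnotation(
            sample_id=s,
            mycn_status=MYCN_AMPLIFIED if amplified[j] else MYCN_NON_AMPLIFIED,
        )
        for j, s in enumerate(sample_ids)
    ]
    return matrix, annotations, targets


# ---------------------------------------------------------------------------
# Genome / promoters
# ---------------------------------------------------------------------------


def simulate_genome(
    config: GenomeSimConfig, gene_ids: Sequence[str] | None = None
) -> GenomeSim:
    """Lay genes along one synthetic chromosome and plant E-boxes.

    TSSs are evenly spaced so promoter windows never overlap; strands are
    random. Each gene's promoter is an i.i.d. background sequence at the
    configured GC content; with probability ``ebox_plant_probability`` one
    exact CACGTG is planted at a uniform offset and the gene enters the
    truth set. Background occurrences of the motif can still arise by chance
    and are deliberately left in place (the scanner reports them; only
    planted sites get simulated peaks).
    """
    if gene_ids is None:
        gene_ids = default_gene_ids(config.n_genes)
    if len(gene_ids) != config.n_genes:
        raise ConfigError(
            f"{len(gene_ids)} gene ids supplied for n_genes={config.n_genes}"
        )
    rng = np.random.default_rng(config.seed)
    spacing = config.chrom_length // (config.n_genes + 1)
    up = config.promoter_len // 2
    down = config.promoter_len - up

    gc = config.background_gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))

    records: list[GeneAnnotationRecord] = []
    promoters: dict[str, str] = {}
    windows: dict[str, PromoterWindow] = {}
    truth: set[str] = set()
    planted_sites: dict[str, GenomicInterval] = {}

    for i, gene_id in enumerate(gene_ids):
        tss_pos = spacing * (i + 1)
        strand = "+" if rng.random() < 0.5 else "-"
        record = GeneAnnotationRecord(
            gene_id=gene_id,
            tss=GenomicInterval("chrSim", tss_pos, tss_pos + 1, strand),
            strand=strand,
        )
        window = promoter_window(record, upstream_bp=up, downstream_bp=down)
        seq = rng.choice(alphabet, size=config.promoter_len, p=probs)

        if rng.random() < config.ebox_plant_probability:
            offset = int(rng.integers(0, config.promoter_len - 6 + 1))
            seq[offset : offset + 6] = list(CANONICAL_EBOX)
            truth.add(gene_id)
            iv = window.interval
            if strand == "-":
                g_end = iv.end - offset
                site = GenomicInterval(iv.chrom, g_end - 6, g_end, strand)
            else:
                site = GenomicInterval(iv.chrom, iv.start + offset, iv.start + offset + 6, strand)
            planted_sites[gene_id] = site

        records.append(record)
        promoters[gene_id] = "".join(seq)
        windows[gene_id] = window

    return GenomeSim(records, promoters, windows, truth, planted_sites, config.chrom_length)


# ---------------------------------------------------------------------------
# ChIP peak sets
# ---------------------------------------------------------------------------


def simulate_chip(config: ChipSimConfig, genome: GenomeSim) -> dict[str, list[Peak]]:
    """Emit per-cell-line peak sets concentrated at the planted E-boxes.

    Amplified cell lines get one peak per planted site, centered on the
    motif and extending ``peak_halfwidth`` each side, with
    ``q = peak_q_at_planted_sites``. Every line additionally receives a
    Poisson(``decoy_peak_rate``) number of 200-bp decoy peaks at uniform
    random positions with q uniform in (0.001, 0.05).
    """
    rng = np.random.default_rng(config.seed)
    out: dict[str, list[Peak]] = {}
    for k in range(config.n_cell_lines):
        line = f"CL{k + 1}"
        peaks: list[Peak] = []
        if config.amplified_flags[k]:
            for gene_id in sorted(genome.planted_sites):
                site = genome.planted_sites[gene_id]
                start = max(0, site.start - config.peak_halfwidth)
                end = site.end + config.peak_halfwidth
                peaks.append(
                    Peak(
                        interval=GenomicInterval(site.chrom, start, end),
                        signal=float(rng.uniform(5.0, 50.0)),
                        q_value=config.peak_q_at_planted_sites,
                        summit_offset=(site.start + site.end) // 2 - start,
                    )
                )
        n_decoys = int(rng.poisson(config.decoy_peak_rate))
        for _ in range(n_decoys):
            start = int(rng.integers(0, genome.chrom_length - 200))
            peaks.append(
                Peak(
                    interval=GenomicInterval("chrSim", start, start + 200),
                    signal=float(rng.uniform(1.0, 10.0)),
                    q_value=float(rng.uniform(0.001, 0.05)),
                )
            )
        out[line] = peaks
    return out


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------


def simulate_annotations(
    gene_ids: Sequence[str],
    membrane_fraction: float = 0.3,
    cns_only_fraction: float = 0.2,
    secreted_fraction: float = 0.1,
    seed: int = 0,
    expr_threshold: float = 1.0,
) -> AnnotationSim:
    """Plant localization scores and tissue profiles with known truth flags.

    Each gene independently draws (membrane, cns_only, secreted) Bernoulli
    flags at the given fractions. Membrane genes get their argmax compartment
    score >= 3 on "Plasma membrane"; non-membrane genes either score the
    membrane label below 3 or are dominated by another compartment. CNS-only
    genes express above ``expr_threshold`` exclusively in CNS tissues; other
    genes get at least one peripheral tissue well above it.
    """
    from .annotation_filters import DEFAULT_CNS_TISSUES

    for name, frac in (
        ("membrane_fraction", membrane_fraction),
        ("cns_only_fraction", cns_only_fraction),
        ("secreted_fraction", secreted_fraction),
    ):
        if not (0.0 <= frac <= 1.0):
            raise ConfigError(f"{name} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    tissues = list(DEFAULT_CNS_TISSUES) + list(PERIPHERAL_TISSUES)
    cns = frozenset(DEFAULT_CNS_TISSUES)

    localizations: list[LocalizationRecord] = []
    profiles: list[TissueExpressionProfile] = []
    truth: dict[str, tuple[bool, bool, bool]] = {}

    for gene_id in gene_ids:
        is_membrane = bool(rng.random() < membrane_fraction)
        is_cns_only = bool(rng.random() < cns_only_fraction)
        is_secreted = bool(rng.random() < secreted_fraction)
        truth[gene_id] = (is_membrane, is_cns_only, is_secreted)

        if is_membrane:
            mem_score = int(rng.integers(3, 6))
            other = int(rng.integers(0, mem_score + 1))
            scores = {"Plasma membrane": mem_score, "Nucleus": other}
        elif rng.random() < 0.5:
            # membrane label present but below the confidence cutoff
            scores = {"Plasma membrane": int(rng.integers(0, 3)), "Nucleus": 2}
        else:
            # another compartment strictly dominates the membrane label
            dom = int(rng.integers(3, 6))
            scores = {"Nucleus": dom, "Plasma membrane": int(rng.integers(0, dom))}
        localizations.append(
            LocalizationRecord(gene_id=gene_id, scores=scores, secreted=is_secreted)
        )

        values: dict[str, float] = {}
        for t in tissues:
            if t in cns:
                values[t] = float(rng.uniform(5.0, 50.0))
            else:
                values[t] = float(rng.uniform(0.0, 0.9 * expr_threshold))
        if not is_cns_only:
            hot = rng.choice(len(PERIPHERAL_TISSUES))
            values[PERIPHERAL_TISSUES[hot]] = float(rng.uniform(5.0, 50.0))
        profiles.append(
            TissueExpressionProfile(
                gene_id=gene_id, tissue_values=values, cns_tissues=cns
            )
        )

    return AnnotationSim(localizations, profiles, truth)
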