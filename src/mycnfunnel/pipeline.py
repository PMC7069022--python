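"""End-to-end orchestration on synthetic inputs.

Runs the whole nomination funnel — dual-platform differential screen,
promoter E-box scan, peak filtering and occupancy, annotation filters,
matrix assembly, funnel, ranking — on one set of simulated inputs, and
returns the report together with the planted full-criteria truth set so
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import annotation_filters, diffexpr, funnel, regulatory, synthetic_data
from .diffexpr import ScreenThresholds, StratificationConfig
from .io_formats import NORMALIZED_INTENSITY, ExpressionMatrix

__all__ = ["SyntheticRunResult", "run_synthetic_funnel"]


@dataclass
class SyntheticRunResult:
    report: funnel.FunnelReport
    rows: list[funnel.CandidateRow]
    truth_final: set[str]          # genes planted to satisfy every criterion
    truth_targets: set[str]        # DE truth (planted driver-responsive genes)
    rnaseq_survivors: set[str]
    array_survivors: set[str]

    @property
    def final_set(self) -> set[str]:
        return self.report.survivors_per_stage[-1]

    def sensitivity(self) -> float:
        if not self.truth_final:
            return float("nan")
        return len(self.final_set & self.truth_final) / len(self.truth_final)

    def false_discovery_proportion(self) -> float:
        if not self.final_set:
            return 0.0
        return len(self.final_set - self.truth_final) / len(self.final_set)


def run_synthetic_funnel(
    seed: int,
    cohort: synthetic_data.CohortSimConfig | None = None,
    genome: synthetic_data.GenomeSimConfig | None = None,
    chip: synthetic_data.ChipSimConfig | None = None,
    membrane_fraction: float = 0.3,
    cns_only_fraction: float = 0.2,
    secreted_fraction: float = 0.1,
    thresholds: ScreenThresholds = ScreenThresholds(),
    quantile_fraction: float = 0.15,
    q_threshold: float = 0.05,
) -> SyntheticRunResult:
    """Simulate a full study under one seed and run the complete funnel.

    The same NB cohort serves both platforms: raw counts go through the
    RNA-seq screen stratified by amplification status, and the log-CPM
    matrix, re-declared as normalized intensities, goes through the array
    screen stratified by the top/bottom driver-expression quantile. Derived
    seeds for the component simulators are spawned deterministically from
    ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_cohort, s_genome, s_chip, s_annot = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )

    cohort = replace(cohort or synthetic_data.CohortSimConfig(), seed=s_cohort)
    matrix, annotations, truth_targets = synthetic_data.simulate_cohort(cohort)

    genome_cfg = replace(
        genome or synthetic_data.GenomeSimConfig(n_genes=cohort.n_genes),
        seed=s_genome,
    )
    gsim = synthetic_data.simulate_genome(genome_cfg, gene_ids=matrix.gene_ids)

    chip_cfg = replace(chip or synthetic_data.ChipSimConfig(), seed=s_chip)
    peaks_by_line = synthetic_data.simulate_chip(chip_cfg, gsim)

    asim = synthetic_data.simulate_annotations(
        matrix.gene_ids,
        membrane_fraction=membrane_fraction,
        cns_only_fraction=cns_only_fraction,
        secreted_fraction=secreted_fraction,
        seed=s_annot,
    )

    # RNA-seq-style screen: counts, status stratification
    rnaseq_survivors, rnaseq_de, _ = diffexpr.run_screen(
        matrix,
        annotations,
        StratificationConfig(mode="by_status"),
        thresholds,
    )

    # array-style screen: log-CPM re-exported as intensities, quantile strata
    logcpm = diffexpr.log_cpm(matrix)
    intensities = ExpressionMatrix(
        list(logcpm.gene_ids),
        list(logcpm.sample_ids),
        logcpm.values,
        NORMALIZED_INTENSITY,
    )
    array_survivors, array_de, _ = diffexpr.run_screen(
        intensities,
        annotations,
        StratificationConfig(
            mode="by_quantile",
            driver_gene_id=cohort.driver_gene_id,
            quantile_fraction=quantile_fraction,
        ),
        thresholds,
    )

    # regulatory evidence
    hits = regulatory.scan_promoters(gsim.promoters, gsim.windows)
    filtered = {
        line: regulatory.filter_peaks(peaks, q_threshold)
        for line, peaks in peaks_by_line.items()
    }
    _, consensus = regulatory.call_occupancy(filtered, gsim.windows, hits)

    # annotation filters
    verdicts = annotation_filters.evaluate_filters(asim.localizations, asim.profiles)

    rows = funnel.assemble_matrix(
        rnaseq_de,
        array_de,
        verdicts,
        occupancy_consensus=consensus,
        motif_genes={g for g, h in hits.items() if h},
        thresholds=thresholds,
    )
    report = funnel.apply_funnel(rows)
    report = funnel.rank_candidates(report, rows)

    # full-criteria truth: planted DE effect (driver included — it genuinely
    # is overexpressed), planted E-box, and planted annotation flags
    truth_final = {
        g
        for g in (truth_targets | {cohort.driver_gene_id}) & gsim.truth
        if asim.truth[g][0] and asim.truth[g][1] and not asim.truth[g][2]
    }

    return SyntheticRunResult(
        report=report,
        rows=rows,
        truth_final=truth_final,
        truth_targets=truth_targets,
        rnaseq_survivors=rnaseq_survivors,
        array_survivors=array_survivors,
    )
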