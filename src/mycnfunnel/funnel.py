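"""Candidate matrix assembly, the attrition funnel, ranking and reporting.

The funnel is the ordered conjunction of filters applied to genes that are
differentially overexpressed on both expression platforms and encode
predicted plasma-membrane proteins:

1. membership in the candidate matrix (dual-platform DE + membrane list);
2. an E-box near the TSS;
3. MYCN bound near the TSS (ChIP-seq peak on the promoter);
4. the E-box itself occupied by MYCN;
5. normal-tissue expression limited to the CNS;
6. product not secreted.

Because the stages are conjunctive, their order changes only the per-stage
survivor counts, never the final set; survivor sets are nested by
construction. A packaged fixture encodes the published candidate matrix
(14 genes, attrition 14 -> 11 -> 10 -> 8 -> 3 -> 2, CAMKV and NME1
surviving all stages).

Ranking note: among final survivors the published nomination (CAMKV) has
the larger RNA-seq log-FC (1.73 vs 1.00) but not the smaller adjusted p
(2.02e-6 vs NME1's 1.17e-6), so an adjusted-p ranking and a log-FC ranking
disagree on this very matrix. The default ranks by descending RNA-seq
log-FC (ties: ascending adj p, then gene id), matching the published
choice; ``key="adj_p"`` gives the significance-first ordering, and the
report flags whenever the two orderings differ.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_filters import FilterVerdict
from .diffexpr import DEResult, ScreenThresholds
from .io_formats import DataError, ExpressionMatrix

__all__ = [
    "CandidateRow",
    "FunnelReport",
    "CorrelationResult",
    "STAGE_NAMES",
    "table1_rows",
    "assemble_matrix",
    "apply_funnel",
    "rank_candidates",
    "correlate",
    "report_to_frame",
    "rows_to_frame",
    "rows_from_frame",
]

STAGE_NAMES = (
    "candidate_matrix",
    "ebox_near_tss",
    "mycn_bound_near_tss",
    "ebox_occupied",
    "limited_normal_expression",
    "not_secreted",
)


@dataclass(frozen=True)
class CandidateRow:
    """One gene's Boolean filter profile plus DE statistics on both platforms.

    ``array_log_fc`` may be NaN: a gene whose array fold change was not
    reported still enters the matrix when its array adjusted p passes.
    """

    gene_id: str
    array_log_fc: float
    array_adj_p: float
    rnaseq_log_fc: float
    rnaseq_adj_p: float
    tm_list: bool
    ebox_near_tss: bool
    mycn_bound_near_tss: bool
    ebox_occupied: bool
    limited_normal_expression: bool
    not_secreted: bool

    def __post_init__(self) -> None:
        if self.ebox_occupied and not self.mycn_bound_near_tss:
            raise DataError(
                f"{self.gene_id}: occupied E-box implies binding near the TSS"
            )


@dataclass
class FunnelReport:
    """Ordered survivor sets per stage plus the final ranked nominations."""

    stage_names: tuple[str, ...]
    survivors_per_stage: list[set[str]]
    final_ranked: list[tuple[str, float, float]] = field(default_factory=list)
    ranking_note: str = ""

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.survivors_per_stage)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two genes' expression vectors."""

    gene_a: str
    gene_b: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise DataError("|r| must be <= 1")
        if self.n < 3:
            raise DataError("correlation needs n >= 3 samples")


# ---------------------------------------------------------------------------
# Packaged fixture: the published candidate matrix
# ---------------------------------------------------------------------------

# gene, array logFC (blank = not reported), array adj p, RNA-seq logFC,
# RNA-seq adj p, then the six flags in funnel order.
_TABLE1_TSV = """\
gene_id\tarray_log_fc\tarray_adj_p\trnaseq_log_fc\trnaseq_adj_p\ttm_list\tebox_near_tss\tmycn_bound_near_tss\tebox_occupied\tlimited_normal_expression\tnot_secreted
CAMKV\t1.47\t1.04e-06\t1.73\t2.02e-06\t1\t1\t1\t1\t1\t1
CPNE7\t1.38\t1.32e-09\t2.75\t1.33e-07\t1\t1\t1\t1\t0\t0
GLRA2\t1.52\t0.0013487\t2.80\t1.27e-05\t1\t1\t0\t0\t0\t0
HHIP\t1.38\t1.52e-05\t1.89\t2.05e-06\t1\t1\t1\t1\t0\t0
KCNH5\t1.45\t0.0001737\t2.11\t0.005154\t1\t1\t1\t0\t0\t0
LGR5\t1.26\t0.000363\t2.38\t1.43e-06\t1\t0\t0\t0\t0\t0
TMEM131L\t1.06\t3.31e-06\t1.05\t4.23e-11\t1\t1\t1\t1\t0\t0
LRRC7\t1.29\t0.0017533\t2.02\t2.54e-05\t1\t1\t1\t1\t1\t0
NME1\t\t2.00e-08\t1.00\t1.17e-06\t1\t1\t1\t1\t1\t1
SLC30A3\t1.10\t6.26e-08\t4.06\t2.64e-10\t1\t0\t0\t0\t0\t0
SLC16A1\t1.37\t1.06e-07\t1.08\t9.40e-10\t1\t1\t1\t1\t0\t0
SLCO5A1\t1.84\t8.96e-13\t2.08\t3.93e-10\t1\t1\t1\t1\t0\t0
TMEM97\t1.89\t3.49e-11\t1.56\t9.48e-14\t1\t1\t1\t0\t0\t0
SLC44A5\t1.42\t1.01e-05\t1.33\t0.002541\t1\t0\t0\t0\t0\t0
"""


def table1_rows() -> list[CandidateRow]:
    """The packaged 14-gene candidate-matrix fixture."""
    return rows_from_frame(pd.read_csv(io.StringIO(_TABLE1_TSV), sep="\t"))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _passes(log_fc: float, adj_p: float, thresholds: ScreenThresholds) -> bool:
    """Screen pass with the missing-fold-change carve-out.

    A NaN log-FC (stat not reported on that platform) defers to the adjusted
    p alone, mirroring how a matrix row with an empty fold-change cell is
    still retained when its significance passes.
    """
    if not adj_p < thresholds.max_adj_p:
        return False
    return math.isnan(log_fc) or log_fc > thresholds.min_log_fc


def assemble_matrix(
    rnaseq_de: Sequence[DEResult],
    array_de: Sequence[DEResult],
    verdicts: Sequence[FilterVerdict],
    occupancy_consensus: Mapping[str, tuple[bool, bool]] | None = None,
    motif_genes: set[str] | None = None,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[CandidateRow]:
    """Build one CandidateRow per gene passing both screens and the TM list.

    Genes absent from a flag source simply get that flag False; a duplicate
    gene within a DE table is a data error.
    """
    rnaseq = _index_de(rnaseq_de, "RNA-seq")
    array = _index_de(array_de, "array")
    verdict_by_gene = {v.gene_id: v for v in verdicts}
    occupancy_consensus = occupancy_consensus or {}
    motif_genes = motif_genes or set()

    rows: list[CandidateRow] = []
    for gene_id, rn in rnaseq.items():
        ar = array.get(gene_id)
        if ar is None:
            continue
        verdict = verdict_by_gene.get(gene_id)
        membrane = verdict.membrane if verdict else False
        if not (
            _passes(rn.log_fc, rn.adj_p, thresholds)
            and _passes(ar.log_fc, ar.adj_p, thresholds)
            and membrane
        ):
            continue
        bound, occupied = occupancy_consensus.get(gene_id, (False, False))
        rows.append(
            CandidateRow(
                gene_id=gene_id,
                array_log_fc=ar.log_fc,
                array_adj_p=ar.adj_p,
                rnaseq_log_fc=rn.log_fc,
                rnaseq_adj_p=rn.adj_p,
                tm_list=True,
                ebox_near_tss=gene_id in motif_genes,
                mycn_bound_near_tss=bound or occupied,
                ebox_occupied=occupied,
                limited_normal_expression=(
                    verdict.limited_normal_expression if verdict else False
                ),
                not_secreted=verdict.not_secreted if verdict else False,
            )
        )
    return rows


def _index_de(results: Sequence[DEResult], what: str) -> dict[str, DEResult]:
    out: dict[str, DEResult] = {}
    for r in results:
        if r.gene_id in out:
            raise DataError(f"duplicate gene {r.gene_id!r} in {what} DE table")
        out[r.gene_id] = r
    return out


# ---------------------------------------------------------------------------
# The funnel
# ---------------------------------------------------------------------------

_STAGE_FLAGS = (
    None,  # stage 1 = membership in the matrix
    "ebox_near_tss",
    "mycn_bound_near_tss",
    "ebox_occupied",
    "limited_normal_expression",
    "not_secreted",
)


def apply_funnel(rows: Sequence[CandidateRow]) -> FunnelReport:
    """Apply the six conjunctive stages in fixed order; survivor sets nest."""
    seen: set[str] = set()
    for row in rows:
        if row.gene_id in seen:
            raise DataError(f"duplicate gene {row.gene_id!r} in candidate matrix")
        seen.add(row.gene_id)

    survivors: list[set[str]] = []
    current = list(rows)
    for flag in _STAGE_FLAGS:
        if flag is not None:
            current = [r for r in current if getattr(r, flag)]
        survivors.append({r.gene_id for r in current})
    return FunnelReport(stage_names=STAGE_NAMES, survivors_per_stage=survivors)


def rank_candidates(
    report: FunnelReport,
    rows: Sequence[CandidateRow],
    key: str = "log_fc",
) -> FunnelReport:
    """Rank the final survivors and attach the ordering to the report.

    ``key="log_fc"`` (default): descending RNA-seq log-FC, ties broken by
    ascending RNA-seq adjusted p, then gene id. ``key="adj_p"``: ascending
    adjusted p first, ties by descending log-FC, then gene id. When the two
    orderings disagree the report carries a note naming both leaders.
    """
    if key not in ("log_fc", "adj_p"):
        raise DataError(f"unknown ranking key {key!r}")
    final = report.survivors_per_stage[-1]
    pool = [r for r in rows if r.gene_id in final]

    def by_lfc(r: CandidateRow):
        return (-r.rnaseq_log_fc, r.rnaseq_adj_p, r.gene_id)

    def by_p(r: CandidateRow):
        return (r.rnaseq_adj_p, -r.rnaseq_log_fc, r.gene_id)

    order_lfc = sorted(pool, key=by_lfc)
    order_p = sorted(pool, key=by_p)
    chosen = order_lfc if key == "log_fc" else order_p

    note = ""
    if order_lfc and order_p and order_lfc[0].gene_id != order_p[0].gene_id:
        note = (
            f"ranking keys disagree: log-FC puts {order_lfc[0].gene_id} first "
            f"while adjusted p puts {order_p[0].gene_id} first; "
            f"ranked by {key}"
        )

    report.final_ranked = [
        (r.gene_id, r.rnaseq_adj_p, r.rnaseq_log_fc) for r in chosen
    ]
    report.ranking_note = note
    return report


# ---------------------------------------------------------------------------
# Driver-candidate co-expression
# ---------------------------------------------------------------------------


def correlate(
    matrix: ExpressionMatrix, gene_a: str, gene_b: str
) -> CorrelationResult:
    """Pearson correlation between two genes across samples.

    p is the two-sided value from the t transform with n - 2 degrees of
    freedom; a zero-variance vector is a data error.
    """
    x = matrix.row(gene_a)
    y = matrix.row(gene_b)
    n = x.size
    if n < 3:
        raise DataError("correlation needs at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero-variance expression vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(gene_a=gene_a, gene_b=gene_b, r=float(r), p=float(p), n=n)


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------


def report_to_frame(report: FunnelReport) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stage": report.stage_names,
            "n_survivors": [len(s) for s in report.survivors_per_stage],
            "gene_ids": [
                ",".join(sorted(s)) for s in report.survivors_per_stage
            ],
        }
    )


def rows_to_frame(rows: Sequence[CandidateRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "array_log_fc": [r.array_log_fc for r in rows],
            "array_adj_p": [r.array_adj_p for r in rows],
            "rnaseq_log_fc": [r.rnaseq_log_fc for r in rows],
            "rnaseq_adj_p": [r.rnaseq_adj_p for r in rows],
            "tm_list": [int(r.tm_list) for r in rows],
            "ebox_near_tss": [int(r.ebox_near_tss) for r in rows],
            "mycn_bound_near_tss": [int(r.mycn_bound_near_tss) for r in rows],
            "ebox_occupied": [int(r.ebox_occupied) for r in rows],
            "limited_normal_expression": [
                int(r.limited_normal_expression) for r in rows
            ],
            "not_secreted": [int(r.not_secreted) for r in rows],
        }
    )


def rows_from_frame(df: pd.DataFrame) -> list[CandidateRow]:
    rows = []
    for rec in df.itertuples():
        rows.append(
            CandidateRow(
                gene_id=str(rec.gene_id),
                array_log_fc=float(rec.array_log_fc)
                if not pd.isna(rec.array_log_fc)
                else math.nan,
                array_adj_p=float(rec.array_adj_p),
                rnaseq_log_fc=float(rec.rnaseq_log_fc),
                rnaseq_adj_p=float(rec.rnaseq_adj_p),
                tm_list=bool(int(rec.tm_list)),
                ebox_near_tss=bool(int(rec.ebox_near_tss)),
                mycn_bound_near_tss=bool(int(rec.mycn_bound_near_tss)),
                ebox_occupied=bool(int(rec.ebox_occupied)),
                limited_normal_expression=bool(int(rec.limited_normal_expression)),
                not_secreted=bool(int(rec.not_secreted)),
            )
        )
    return rows
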