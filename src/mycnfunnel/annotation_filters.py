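"""Annotation-based candidate filters: membrane, normal-tissue, secretion.

Three pure predicates, one per Table-1-style flag column:

* ``membrane_designation`` — the gene's maximum compartment confidence score
  is attained by a plasma-membrane category and is >= 3;
* ``normal_tissue_filter`` — expression outside the declared CNS tissue set
  never exceeds the threshold (CNS tissues are unconstrained, since
  antibody-scale biologics do not cross the blood-brain barrier);
* ``secretion_filter`` — the gene's product is not secreted.

Being predicates, they commute: filtering sequentially in any order equals
filtering by their conjunction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import DataError, LocalizationRecord, TissueExpressionProfile

__all__ = [
    "FilterVerdict",
    "MEMBRANE_CATEGORIES",
    "DEFAULT_CNS_TISSUES",
    "DEFAULT_EXPR_THRESHOLD",
    "membrane_designation",
    "normal_tissue_filter",
    "secretion_filter",
    "evaluate_filters",
]

#: Compartment labels counted as "plasma membrane"; matched case-insensitively
#: because exported label capitalization varies.
MEMBRANE_CATEGORIES = ("Plasma membrane", "Cell surface")

#: Default CNS tissue panel for the normal-tissue restriction.
DEFAULT_CNS_TISSUES = (
    "brain_cortex",
    "brain_cerebellum",
    "brain_hippocampus",
    "brain_basal_ganglia",
    "spinal_cord",
)

#: Default "limited expression" cutoff in TPM-like units.
DEFAULT_EXPR_THRESHOLD = 1.0

#: Minimum confidence score for a membrane designation.
MEMBRANE_MIN_SCORE = 3


@dataclass(frozen=True)
class FilterVerdict:
    """One gene's outcome on the three annotation filters (never tri-state)."""

    gene_id: str
    membrane: bool
    limited_normal_expression: bool
    not_secreted: bool


def membrane_designation(
    record: LocalizationRecord,
    membrane_categories: Sequence[str] = MEMBRANE_CATEGORIES,
) -> bool:
    """True iff the max compartment score is membrane-attained and >= 3.

    A tie between a membrane and a non-membrane category passes: the rule
    constrains only which categories attain the maximum, not exclusivity.
    """
    wanted = {c.lower() for c in membrane_categories}
    max_score = max(record.scores.values())
    if max_score < MEMBRANE_MIN_SCORE:
        return False
    return any(
        label.lower() in wanted and score == max_score
        for label, score in record.scores.items()
    )


def normal_tissue_filter(
    profile: TissueExpressionProfile,
    expr_threshold: float = DEFAULT_EXPR_THRESHOLD,
) -> bool:
    """True iff every non-CNS tissue's expression is <= the threshold."""
    if expr_threshold < 0:
        raise DataError("expression threshold must be >= 0")
    if not profile.tissue_values:
        raise DataError(f"empty tissue map for {profile.gene_id}")
    return all(
        value <= expr_threshold
        for tissue, value in profile.tissue_values.items()
        if tissue not in profile.cns_tissues
    )


def secretion_filter(record: LocalizationRecord) -> bool:
    """True iff the gene's product is not secreted."""
    return not record.secreted


def evaluate_filters(
    localizations: Iterable[LocalizationRecord],
    profiles: Iterable[TissueExpressionProfile],
    expr_threshold: float = DEFAULT_EXPR_THRESHOLD,
    membrane_categories: Sequence[str] = MEMBRANE_CATEGORIES,
) -> list[FilterVerdict]:
    """Evaluate all three filters for every gene with a localization record.

    Genes without a tissue profile fail the normal-tissue filter (absence of
    evidence of restriction is not restriction).
    """
    profile_by_gene = {p.gene_id: p for p in profiles}
    verdicts = []
    for rec in localizations:
        profile = profile_by_gene.get(rec.gene_id)
        verdicts.append(
            FilterVerdict(
                gene_id=rec.gene_id,
                membrane=membrane_designation(rec, membrane_categories),
                limited_normal_expression=(
                    normal_tissue_filter(profile, expr_threshold)
                    if profile is not None
                    else False
                ),
                not_secreted=secretion_filter(rec),
            )
        )
    return verdicts
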