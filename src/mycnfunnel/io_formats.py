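"""File formats and domain types shared across the pipeline.

Everything the pipeline reads or writes — gene-by-sample expression TSVs,
ENCODE narrowPeak, BED3, promoter FASTA, localization and tissue tables,
and the report TSVs — goes through this module, so coordinate and unit
conventions are fixed in exactly one place:

* genomic coordinates are 0-based half-open ``[start, end)`` (BED convention);
* narrowPeak column 9 is ``-log10(q)`` per the ENCODE specification and is
  decoded to the linear scale on read;
* expression matrices carry an explicit unit tag, and operations that need
  raw counts refuse anything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "DataError",
    "ConfigError",
    "RAW_COUNTS",
    "FPKM",
    "NORMALIZED_INTENSITY",
    "ExpressionMatrix",
    "SampleAnnotation",
    "GenomicInterval",
    "Peak",
    "GeneAnnotationRecord",
    "LocalizationRecord",
    "TissueExpressionProfile",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_sample_annotation",
    "write_sample_annotation",
    "read_tss_table",
    "write_tss_table",
    "read_localization_tsv",
    "write_localization_tsv",
    "read_tissue_tsv",
    "write_tissue_tsv",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class DataError(ValueError):
    """Validated input is semantically unusable for the requested operation."""


class ConfigError(ValueError):
    """A configuration value is out of its admissible range."""


#: Unit tags for :class:`ExpressionMatrix`.
RAW_COUNTS = "raw_counts"
FPKM = "fpkm"
NORMALIZED_INTENSITY = "normalized_intensity"
_VALID_UNITS = frozenset({RAW_COUNTS, FPKM, NORMALIZED_INTENSITY})

MYCN_AMPLIFIED = "amplified"
MYCN_NON_AMPLIFIED = "non_amplified"
MYCN_UNKNOWN = "unknown"
_VALID_STATUS = frozenset({MYCN_AMPLIFIED, MYCN_NON_AMPLIFIED, MYCN_UNKNOWN})

GROUP_HIGH = "high"
GROUP_LOW = "low"
GROUP_EXCLUDED = "excluded"
_VALID_GROUPS = frozenset({GROUP_HIGH, GROUP_LOW, GROUP_EXCLUDED})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-by-sample quantification with an explicit unit tag.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    values
        Non-negative float matrix of shape ``(len(gene_ids), len(sample_ids))``.
    unit
        One of ``raw_counts``, ``fpkm``, ``normalized_intensity``.
    library_sizes
        Optional per-sample library sizes. Populated by the log-CPM transform
        so downstream precision-weight fitting can map log-CPM back to the
        count scale; absent for matrices that never were counts.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str
    library_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in _VALID_UNITS:
            raise ConfigError(f"unknown expression unit {self.unit!r}")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")
        if self.unit != NORMALIZED_INTENSITY and np.any(self.values < 0):
            raise FormatError("expression values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise DataError(f"gene {gene_id!r} not present in matrix") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        lib = self.library_sizes[idx] if self.library_sizes is not None else None
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, idx],
            self.unit, lib,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def require_unit(self, unit: str) -> None:
        if self.unit != unit:
            raise DataError(
                f"operation requires unit {unit!r} but matrix is {self.unit!r}"
            )


@dataclass
class SampleAnnotation:
    """Amplification status (and, once stratified, group label) of one sample."""

    sample_id: str
    mycn_status: str = MYCN_UNKNOWN
    group_label: str | None = None

    def __post_init__(self) -> None:
        if self.mycn_status not in _VALID_STATUS:
            raise ConfigError(f"unknown MYCN status {self.mycn_status!r}")
        if self.group_label is not None and self.group_label not in _VALID_GROUPS:
            raise ConfigError(f"unknown group label {self.group_label!r}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open, 0-based genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative start {self.start}")
        if self.end <= self.start:
            raise FormatError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A called peak: interval plus signal-per-million and linear-scale q."""

    interval: GenomicInterval
    signal: float
    q_value: float
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise FormatError(f"negative peak signal {self.signal}")
        if not (0.0 < self.q_value <= 1.0):
            raise FormatError(f"peak q-value {self.q_value} outside (0, 1]")


@dataclass(frozen=True)
class GeneAnnotationRecord:
    """A gene's transcription start site as a width-1 interval plus strand."""

    gene_id: str
    tss: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if len(self.tss) != 1:
            raise FormatError(f"TSS interval for {self.gene_id} must have width 1")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class LocalizationRecord:
    """Per-gene subcellular compartment confidence scores (0-5 per GO label)."""

    gene_id: str
    scores: Mapping[str, int]
    secreted: bool

    def __post_init__(self) -> None:
        if not self.scores:
            raise FormatError(f"no compartment scores for {self.gene_id}")
        for label, score in self.scores.items():
            if not (0 <= int(score) <= 5):
                raise FormatError(
                    f"score {score} for {self.gene_id}/{label} outside [0, 5]"
                )


@dataclass(frozen=True)
class TissueExpressionProfile:
    """Per-gene normal-tissue expression with a declared CNS tissue subset."""

    gene_id: str
    tissue_values: Mapping[str, float]
    cns_tissues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        extra = set(self.cns_tissues) - set(self.tissue_values)
        if extra:
            raise FormatError(
                f"CNS tissues {sorted(extra)} absent from tissue map of {self.gene_id}"
            )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} identifier {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene_id, header of sample ids).

    Row and column order are preserved from the file. Duplicate identifiers,
    negative values and non-numeric cells raise :class:`FormatError`; the
    error for a bad cell names the offending gene and sample.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric cell {raw[i, j]!r} at gene {gene_ids[i]!r}, "
                    f"sample {sample_ids[j]!r} in {path}"
                ) from None
    if unit != NORMALIZED_INTENSITY and np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(gene_ids, sample_ids, values, unit)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a gene-by-sample TSV at 6 significant digits."""
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# narrowPeak / BED
# ---------------------------------------------------------------------------


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read an ENCODE narrowPeak file (10 columns, column 9 = -log10 q).

    q-values are decoded to the linear scale; the column-10 summit offset is
    kept when ``>= 0`` and dropped when ``-1``.
    """
    peaks: list[Peak] = []
    for lineno, fields in _iter_tab_lines(path):
        if len(fields) < 10:
            raise FormatError(
                f"{path}:{lineno}: narrowPeak needs 10 columns, found {len(fields)}"
            )
        chrom, start, end = fields[0], _int(fields[1], path, lineno), _int(fields[2], path, lineno)
        if end <= start:
            raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
        strand = fields[5] if fields[5] in ("+", "-", ".") else "."
        signal = float(fields[6])
        neg_log10_q = float(fields[8])
        q = 10.0 ** (-neg_log10_q)
        summit = _int(fields[9], path, lineno)
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, end, strand),
                signal=signal,
                q_value=q,
                summit_offset=summit if summit >= 0 else None,
            )
        )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path, name_prefix: str = "peak") -> None:
    """Write peaks in narrowPeak format, re-encoding q as -log10 at 6 digits."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, start=1):
            iv = p.interval
            neg_log10_q = -math.log10(p.q_value)
            summit = p.summit_offset if p.summit_offset is not None else -1
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        f"{name_prefix}_{i}",
                        "0",
                        iv.strand,
                        f"{p.signal:.6g}",
                        "-1",
                        f"{neg_log10_q:.6g}",
                        str(summit),
                    ]
                )
                + "\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into half-open 0-based intervals, order preserved."""
    intervals: list[GenomicInterval] = []
    for lineno, fields in _iter_tab_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs at least 3 columns")
        start = _int(fields[1], path, lineno)
        end = _int(fields[2], path, lineno)
        try:
            intervals.append(GenomicInterval(fields[0], start, end))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _iter_tab_lines(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _int(token: str, path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: malformed integer {token!r}") from None


# ---------------------------------------------------------------------------
# FASTA (promoter sequences)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{record id: uppercase sequence}``."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise FormatError(f"duplicate FASTA record {record.id!r}")
        out[record.id] = str(record.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Sample annotation / TSS / localization / tissue tables
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def read_sample_annotation(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample annotation TSV with columns sample_id, mycn_status."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample_id", "mycn_status"], path)
    return [
        SampleAnnotation(sample_id=row.sample_id, mycn_status=row.mycn_status)
        for row in df.itertuples()
    ]


def write_sample_annotation(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "mycn_status": [a.mycn_status for a in annotations],
            "group_label": [a.group_label or "" for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_tss_table(path: str | Path) -> list[GeneAnnotationRecord]:
    """Read a TSS table TSV with columns gene_id, chrom, tss, strand (0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    _require_columns(df, ["gene_id", "chrom", "tss", "strand"], path)
    records = []
    for row in df.itertuples():
        pos = int(row.tss)
        records.append(
            GeneAnnotationRecord(
                gene_id=row.gene_id,
                tss=GenomicInterval(row.chrom, pos, pos + 1, row.strand),
                strand=row.strand,
            )
        )
    _check_unique([r.gene_id for r in records], "gene")
    return records


def write_tss_table(records: Sequence[GeneAnnotationRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "chrom": [r.tss.chrom for r in records],
            "tss": [r.tss.start for r in records],
            "strand": [r.strand for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_localization_tsv(path: str | Path) -> list[LocalizationRecord]:
    """Read a long-format localization TSV: gene_id, category, score, secreted."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "category": str})
    _require_columns(df, ["gene_id", "category", "score", "secreted"], path)
    records = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        secreted_vals = set(sub["secreted"].astype(int))
        if len(secreted_vals) != 1:
            raise FormatError(f"inconsistent secreted flag for gene {gene_id!r}")
        records.append(
            LocalizationRecord(
                gene_id=str(gene_id),
                scores={str(r.category): int(r.score) for r in sub.itertuples()},
                secreted=bool(secreted_vals.pop()),
            )
        )
    return records


def write_localization_tsv(records: Sequence[LocalizationRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for category, score in rec.scores.items():
            rows.append((rec.gene_id, category, score, int(rec.secreted)))
    pd.DataFrame(rows, columns=["gene_id", "category", "score", "secreted"]).to_csv(
        path, sep="\t", index=False
    )


def read_tissue_tsv(path: str | Path, cns_tissues: Iterable[str]) -> list[TissueExpressionProfile]:
    """Read a wide gene-by-tissue TSV; ``cns_tissues`` declares the CNS subset."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cns = frozenset(str(t) for t in cns_tissues)
    profiles = []
    for gene_id, row in df.iterrows():
        profiles.append(
            TissueExpressionProfile(
                gene_id=str(gene_id),
                tissue_values={str(t): float(v) for t, v in row.items()},
                cns_tissues=cns & frozenset(str(t) for t in df.columns),
            )
        )
    return profiles


def write_tissue_tsv(profiles: Sequence[TissueExpressionProfile], path: str | Path) -> None:
    if not profiles:
        raise DataError("no tissue profiles to write")
    tissues = list(profiles[0].tissue_values)
    df = pd.DataFrame(
        [[p.tissue_values[t] for t in tissues] for p in profiles],
        index=[p.gene_id for p in profiles],
        columns=tissues,
    )
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")
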