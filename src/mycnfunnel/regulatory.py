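"""Promoter E-box detection and MYCN occupancy from ChIP-seq peak sets.

A gene's promoter window spans ``[tss - upstream, tss + downstream)`` in
strand-oriented coordinates (default 1 kb each side). Promoter sequences
are stored 5'->3' along the gene's strand with the TSS base at index
``upstream``, so a motif starting at sequence index ``i`` sits at offset
``i - upstream`` from the TSS (negative = upstream).

The canonical E-box CACGTG is its own reverse complement, so exact
scanning along one strand finds every occurrence on either; non-canonical
E-boxes (e.g. CATGTG) can be added to the motif set, in which case both
the motif and its reverse complement are scanned.

Occupancy is decided by interval intersection of filtered peaks (q <=
threshold, blacklist removed) with promoter windows (bound near TSS) and
with motif hit intervals (E-box occupied); any >= 1 bp overlap counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .diffexpr import benjamini_hochberg
from .io_formats import (
    ConfigError,
    DataError,
    GeneAnnotationRecord,
    GenomicInterval,
    Peak,
)

__all__ = [
    "MotifHit",
    "PromoterWindow",
    "OccupancyCall",
    "CANONICAL_EBOX",
    "promoter_window",
    "promoter_sequence_from_genome",
    "scan_eboxes",
    "scan_promoters",
    "overlaps",
    "filter_peaks",
    "call_occupancy",
    "consensus_calls",
    "toy_local_poisson_caller",
]

CANONICAL_EBOX = "CACGTG"
DEFAULT_WINDOW_UP = 1000
DEFAULT_WINDOW_DOWN = 1000

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC_OK = frozenset("ACGTN")


@dataclass(frozen=True)
class MotifHit:
    """One E-box occurrence: genomic interval plus strand-oriented TSS offset."""

    gene_id: str
    position: GenomicInterval
    offset_from_tss: int
    motif: str = CANONICAL_EBOX


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-oriented TSS-proximal window, clipped at chromosome start."""

    gene_id: str
    interval: GenomicInterval
    upstream_bp: int
    downstream_bp: int


@dataclass(frozen=True)
class OccupancyCall:
    """Per gene and cell line: is a filtered peak on the promoter / an E-box?"""

    gene_id: str
    cell_line: str
    mycn_bound_near_tss: bool
    ebox_occupied: bool
    supporting_peaks: tuple[Peak, ...] = ()

    def __post_init__(self) -> None:
        if self.ebox_occupied and not self.mycn_bound_near_tss:
            raise DataError(
                f"{self.gene_id}/{self.cell_line}: E-box occupancy implies "
                "binding near the TSS"
            )


# ---------------------------------------------------------------------------
# Promoter windows and motif scanning
# ---------------------------------------------------------------------------


def promoter_window(
    record: GeneAnnotationRecord,
    upstream_bp: int = DEFAULT_WINDOW_UP,
    downstream_bp: int = DEFAULT_WINDOW_DOWN,
) -> PromoterWindow:
    """Build the strand-oriented promoter window around a gene's TSS.

    For a + strand gene the window is ``[tss - up, tss + down)``; for a -
    strand gene it is mirrored so that ``up`` bases still lie upstream along
    the direction of transcription. The TSS base itself counts as the first
    downstream position, and the window is clipped at chromosome start.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ConfigError("window extents must be >= 0")
    t = record.tss.start
    if record.strand == "+":
        start, end = t - upstream_bp, t + downstream_bp
    else:
        start, end = t - downstream_bp + 1, t + upstream_bp + 1
    start = max(0, start)
    if end <= start:
        raise ConfigError(f"empty promoter window for {record.gene_id}")
    return PromoterWindow(
        gene_id=record.gene_id,
        interval=GenomicInterval(record.tss.chrom, start, end, record.strand),
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
    )


def promoter_sequence_from_genome(
    genome_seq: str, window: PromoterWindow
) -> str:
    """Extract the promoter sequence 5'->3' along the gene's strand."""
    seq = genome_seq[window.interval.start : window.interval.end].upper()
    if window.interval.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def scan_eboxes(
    sequence: str,
    window: PromoterWindow,
    motifs: Sequence[str] = (CANONICAL_EBOX,),
) -> list[MotifHit]:
    """Report every occurrence of the configured E-box motifs in a promoter.

    The sequence is read 5'->3' along the gene strand with the TSS at index
    ``window.upstream_bp``. Overlapping occurrences are all reported. Each
    non-palindromic motif is also scanned as its reverse complement.
    """
    if not motifs:
        raise ConfigError("motif set must be non-empty")
    seq = sequence.upper()
    bad = set(seq) - _IUPAC_OK
    if bad:
        raise DataError(f"non-IUPAC characters in promoter sequence: {sorted(bad)}")

    scan_set: list[tuple[str, str]] = []  # (pattern, canonical label)
    for m in motifs:
        m = m.upper()
        rc = m.translate(_COMPLEMENT)[::-1]
        scan_set.append((m, m))
        if rc != m:
            scan_set.append((rc, m))

    iv = window.interval
    hits: list[MotifHit] = []
    for i in range(len(seq)):
        for pattern, label in scan_set:
            if seq.startswith(pattern, i):
                k = len(pattern)
                if iv.strand == "-":
                    g_end = iv.end - i
                    g_start = g_end - k
                else:
                    g_start = iv.start + i
                    g_end = g_start + k
                hits.append(
                    MotifHit(
                        gene_id=window.gene_id,
                        position=GenomicInterval(iv.chrom, g_start, g_end, iv.strand),
                        offset_from_tss=i - window.upstream_bp,
                        motif=label,
                    )
                )
    return hits


def scan_promoters(
    promoters: Mapping[str, str],
    windows: Mapping[str, PromoterWindow],
    motifs: Sequence[str] = (CANONICAL_EBOX,),
) -> dict[str, list[MotifHit]]:
    """Scan every promoter sequence; genes absent from ``windows`` are an error."""
    out: dict[str, list[MotifHit]] = {}
    for gene_id, seq in promoters.items():
        if gene_id not in windows:
            raise DataError(f"no promoter window for gene {gene_id!r}")
        out[gene_id] = scan_eboxes(seq, windows[gene_id], motifs)
    return out


# ---------------------------------------------------------------------------
# Peak filtering and interval overlap
# ---------------------------------------------------------------------------


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 bp on the same chrom."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def filter_peaks(
    peaks: Iterable[Peak],
    q_threshold: float = 0.05,
    blacklist: Sequence[GenomicInterval] = (),
) -> list[Peak]:
    """Keep peaks with ``q <= threshold`` and no overlap with any blacklist region.

    The q comparison is inclusive at the boundary; any >= 1 bp overlap with a
    blacklisted interval removes the peak. Idempotent by construction.
    """
    if not (0.0 < q_threshold < 1.0):
        raise ConfigError(f"q threshold {q_threshold} outside (0, 1)")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in blacklist:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept = []
    for p in peaks:
        if p.q_value > q_threshold:
            continue
        if any(overlaps(p.interval, iv) for iv in by_chrom.get(p.interval.chrom, ())):
            continue
        kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# Occupancy calls
# ---------------------------------------------------------------------------


def call_occupancy(
    peaks_by_line: Mapping[str, Sequence[Peak]],
    windows: Mapping[str, PromoterWindow],
    hits: Mapping[str, Sequence[MotifHit]],
    min_lines: int = 1,
) -> tuple[list[OccupancyCall], dict[str, tuple[bool, bool]]]:
    """Decide per-gene, per-cell-line promoter binding and E-box occupancy.

    ``mycn_bound_near_tss`` holds when some (already filtered) peak overlaps
    the gene's promoter window; ``ebox_occupied`` when some peak overlaps one
    of the gene's motif-hit intervals. The per-gene consensus requires each
    flag in at least ``min_lines`` cell lines (default: any single line).

    Genes appearing in ``hits`` must have a promoter window; the returned
    consensus maps every windowed gene to ``(bound, occupied)``.
    """
    if min_lines < 1:
        raise ConfigError("min_lines must be >= 1")
    for gene_id in hits:
        if gene_id not in windows:
            raise DataError(f"gene {gene_id!r} has motif hits but no promoter window")

    calls: list[OccupancyCall] = []
    bound_count: dict[str, int] = {g: 0 for g in windows}
    occupied_count: dict[str, int] = {g: 0 for g in windows}
    for cell_line, peaks in peaks_by_line.items():
        for gene_id, window in windows.items():
            support = tuple(
                p for p in peaks if overlaps(p.interval, window.interval)
            )
            bound = bool(support)
            occupied = any(
                overlaps(p.interval, h.position)
                for p in peaks
                for h in hits.get(gene_id, ())
            )
            # a peak on a motif inside the window necessarily touches the window
            calls.append(
                OccupancyCall(
                    gene_id=gene_id,
                    cell_line=cell_line,
                    mycn_bound_near_tss=bound or occupied,
                    ebox_occupied=occupied,
                    supporting_peaks=support,
                )
            )
            bound_count[gene_id] += int(bound or occupied)
            occupied_count[gene_id] += int(occupied)

    consensus = {
        g: (bound_count[g] >= min_lines, occupied_count[g] >= min_lines)
        for g in windows
    }
    return calls, consensus


# ---------------------------------------------------------------------------
# Toy local-Poisson peak caller (fixture generator)
# ---------------------------------------------------------------------------


def toy_local_poisson_caller(
    coverage: Sequence[int],
    control: Sequence[int],
    window_sizes: Sequence[int] = (1000, 10000),
    alpha: float = 0.05,
    chrom: str = "chrSim",
    merge_gap: int = 0,
) -> list[Peak]:
    """Desk-scale local-Poisson peak caller used to fabricate peak fixtures.

    Per position, the coverage count is tested against a Poisson upper tail
    with rate ``lambda = max(local control means over the window sizes,
    global control mean)``; p-values are BH-adjusted over positions and
    maximal runs of adjusted ``p <= alpha`` become peaks, with ``q`` = the
    minimum adjusted p in the run and signal = the run's mean coverage per
    million summed coverage. This is a fixture generator, not a peak caller
    for real data.
    """
    cov = np.asarray(coverage, dtype=float)
    ctl = np.asarray(control, dtype=float)
    if cov.shape != ctl.shape:
        raise DataError(
            f"coverage length {cov.size} != control length {ctl.size}"
        )
    if np.any(cov < 0) or np.any(ctl < 0):
        raise DataError("coverage vectors must be non-negative")
    n = cov.size
    if n == 0:
        return []

    lam = np.full(n, ctl.mean())
    csum = np.concatenate([[0.0], np.cumsum(ctl)])
    for w in window_sizes:
        half = max(1, w // 2)
        lo = np.maximum(0, np.arange(n) - half)
        hi = np.minimum(n, np.arange(n) + half + 1)
        local = (csum[hi] - csum[lo]) / (hi - lo)
        lam = np.maximum(lam, local)
    lam = np.maximum(lam, 1e-9)

    p = stats.poisson.sf(cov - 1.0, lam)  # P(X >= cov)
    adj = benjamini_hochberg(p)
    sig = adj <= alpha

    # close gaps of <= merge_gap non-significant positions between runs
    if merge_gap > 0:
        idx = np.flatnonzero(sig)
        for a, b in zip(idx[:-1], idx[1:]):
            if 1 < b - a <= merge_gap + 1:
                sig[a:b] = True

    peaks: list[Peak] = []
    total = cov.sum()
    scale = 1e6 / total if total > 0 else 0.0
    i = 0
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1]:
            j += 1
        run = slice(i, j + 1)
        q = float(adj[run].min())
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, i, j + 1),
                signal=float(cov[run].mean() * scale),
                q_value=max(q, np.finfo(float).tiny),
                summit_offset=int(np.argmax(cov[run])),
            )
        )
        i = j + 1
    return peaks
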