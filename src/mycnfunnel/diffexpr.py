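"""Stratified differential-expression screen with moderated statistics.

The screen mirrors the standard count-data workflow for two-group tumor
comparisons:

1. counts are transformed to log2 counts-per-million (log-CPM) with the
   conventional half-count offset;
2. a mean-variance trend is fitted to per-gene residual standard deviations
   and inverted into per-observation precision weights (the voom idea);
3. a weighted two-group linear model is fitted per gene and the residual
   variances are shrunk toward a common prior by empirical Bayes, giving a
   moderated t-statistic with augmented degrees of freedom;
4. p-values are adjusted by Benjamini-Hochberg and genes passing
   ``log_fc > min_log_fc`` and ``adj_p < max_adj_p`` (both strict) survive.

Two stratification modes are supported: by MYCN amplification status
(RNA-seq cohorts) and by top/bottom quantile of the driver gene's own
expression (array cohorts, default 15%). The log-FC sign convention is
fixed as high-group minus low-group throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    GROUP_EXCLUDED,
    GROUP_HIGH,
    GROUP_LOW,
    MYCN_AMPLIFIED,
    MYCN_NON_AMPLIFIED,
    MYCN_UNKNOWN,
    NORMALIZED_INTENSITY,
    RAW_COUNTS,
    ConfigError,
    DataError,
    ExpressionMatrix,
    SampleAnnotation,
)

__all__ = [
    "DEResult",
    "StratificationConfig",
    "ScreenThresholds",
    "log_cpm",
    "fit_voom_weights",
    "moderated_t_test",
    "benjamini_hochberg",
    "stratify",
    "differential_screen",
    "run_screen",
    "de_table_to_frame",
]

#: Floor applied to per-gene residual standard deviations before trend
#: fitting, so zero-variance genes cannot produce infinite weights.
RESIDUAL_SD_FLOOR = 1e-8

#: Span of the locally weighted (lowess) mean-variance trend fit.
LOWESS_SPAN = 0.5


@dataclass
class DEResult:
    """Per-gene differential-expression statistics (high minus low group)."""

    gene_id: str
    log_fc: float
    raw_p: float
    adj_p: float = math.nan
    moderated_t: float = math.nan
    mean_expression: float = math.nan


@dataclass
class StratificationConfig:
    """How samples are split into high/low driver-expression groups.

    ``by_status`` maps amplified -> high, non_amplified -> low.  ``by_quantile``
    takes the ``quantile_fraction`` of samples with the highest (resp. lowest)
    expression of ``driver_gene_id`` as the high (resp. low) group and marks
    the remainder excluded.
    """

    mode: str = "by_status"
    driver_gene_id: str | None = None
    quantile_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.mode not in ("by_status", "by_quantile"):
            raise ConfigError(f"unknown stratification mode {self.mode!r}")
        if not (0.0 < self.quantile_fraction <= 0.5):
            raise ConfigError("quantile_fraction must be in (0, 0.5]")
        if self.mode == "by_quantile" and not self.driver_gene_id:
            raise ConfigError("by_quantile stratification needs a driver gene id")


@dataclass
class ScreenThresholds:
    """Survival thresholds for the screen; both comparisons are strict."""

    min_log_fc: float = 1.0
    max_adj_p: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.max_adj_p < 1.0):
            raise ConfigError("max_adj_p must be in (0, 1)")


# ---------------------------------------------------------------------------
# log-CPM
# ---------------------------------------------------------------------------


def log_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Transform raw counts to log2 counts-per-million.

    ``value(g, s) = log2((count + 0.5) / (library_size + 1) * 1e6)`` where the
    library size is the column sum. The result carries the library sizes so
    the precision-weight fit can convert fitted log-CPM back to log-counts.
    """
    matrix.require_unit(RAW_COUNTS)
    lib = matrix.values.sum(axis=0)
    zero = np.flatnonzero(lib <= 0)
    if zero.size:
        raise DataError(
            f"sample {matrix.sample_ids[zero[0]]!r} has zero library size"
        )
    values = np.log2((matrix.values + 0.5) / (lib + 1.0) * 1e6)
    return ExpressionMatrix(
        list(matrix.gene_ids),
        list(matrix.sample_ids),
        values,
        NORMALIZED_INTENSITY,
        library_sizes=lib,
    )


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------


def stratify(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    config: StratificationConfig,
) -> list[SampleAnnotation]:
    """Assign high/low/excluded group labels to every sample.

    Quantile mode takes ``floor(fraction * n)`` samples (minimum 2) from each
    extreme of the driver gene's expression; ties at the boundary are broken
    by ascending sample id so the assignment is order-independent.
    """
    ann_by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in ann_by_id if s not in matrix.sample_ids]
    if missing:
        raise DataError(f"annotated samples absent from matrix: {missing[:3]}")

    labels: dict[str, str] = {}
    if config.mode == "by_status":
        for sid in matrix.sample_ids:
            ann = ann_by_id.get(sid)
            status = ann.mycn_status if ann else MYCN_UNKNOWN
            if status == MYCN_AMPLIFIED:
                labels[sid] = GROUP_HIGH
            elif status == MYCN_NON_AMPLIFIED:
                labels[sid] = GROUP_LOW
            else:
                labels[sid] = GROUP_EXCLUDED
        n_high = sum(1 for v in labels.values() if v == GROUP_HIGH)
        n_low = sum(1 for v in labels.values() if v == GROUP_LOW)
        if n_high == 0 or n_low == 0:
            raise ConfigError(
                f"status stratification left an empty group "
                f"(high={n_high}, low={n_low})"
            )
    else:
        driver = matrix.row(config.driver_gene_id)
        n = len(matrix.sample_ids)
        k = max(2, int(math.floor(config.quantile_fraction * n)))
        if 2 * k > n:
            raise ConfigError(
                f"quantile groups of size {k} overlap with only {n} samples"
            )
        # sort by (expression, sample_id): deterministic under input permutation
        order = sorted(range(n), key=lambda i: (driver[i], matrix.sample_ids[i]))
        low_ids = {matrix.sample_ids[i] for i in order[:k]}
        high_ids = {matrix.sample_ids[i] for i in order[-k:]}
        for sid in matrix.sample_ids:
            if sid in high_ids:
                labels[sid] = GROUP_HIGH
            elif sid in low_ids:
                labels[sid] = GROUP_LOW
            else:
                labels[sid] = GROUP_EXCLUDED

    return [
        SampleAnnotation(
            sample_id=sid,
            mycn_status=(
                ann_by_id[sid].mycn_status if sid in ann_by_id else MYCN_UNKNOWN
            ),
            group_label=labels[sid],
        )
        for sid in matrix.sample_ids
    ]


def group_vector(
    matrix: ExpressionMatrix, annotations: Sequence[SampleAnnotation]
) -> np.ndarray:
    """Map stratified annotations onto matrix columns: 1=high, 0=low, -1=excluded."""
    label_by_id = {a.sample_id: a.group_label for a in annotations}
    out = np.full(len(matrix.sample_ids), -1, dtype=int)
    for j, sid in enumerate(matrix.sample_ids):
        lab = label_by_id.get(sid)
        if lab == GROUP_HIGH:
            out[j] = 1
        elif lab == GROUP_LOW:
            out[j] = 0
    return out


def _check_two_groups(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hi = np.flatnonzero(groups == 1)
    lo = np.flatnonzero(groups == 0)
    if hi.size < 2 or lo.size < 2:
        raise ConfigError(
            f"need >= 2 samples per group, got high={hi.size}, low={lo.size}"
        )
    return hi, lo


# ---------------------------------------------------------------------------
# Precision weights (voom)
# ---------------------------------------------------------------------------


def fit_voom_weights(logcpm: ExpressionMatrix, groups: np.ndarray) -> np.ndarray:
    """Fit the mean-variance trend and return per-observation precision weights.

    Per-gene residual standard deviations from group-mean fits (floored at
    ``RESIDUAL_SD_FLOOR``) are square-rooted and regressed on average
    log2-count by lowess. The trend, evaluated at each observation's fitted
    log-count, is raised to the fourth power and inverted:
    ``w = trend(fitted)**-4``, the quarter-power standard-deviation
    convention. When the matrix carries library sizes the x-axis is on the
    log2-count scale; otherwise the log-CPM values are used directly.

    Parameters
    ----------
    logcpm
        A ``normalized_intensity`` matrix, usually from :func:`log_cpm`.
    groups
        Integer vector over columns: 1=high, 0=low (others excluded).
    """
    logcpm.require_unit(NORMALIZED_INTENSITY)
    hi, lo = _check_two_groups(groups)
    used = np.concatenate([lo, hi])
    y = logcpm.values[:, used]
    g = groups[used]

    mean_hi = y[:, g == 1].mean(axis=1)
    mean_lo = y[:, g == 0].mean(axis=1)
    fitted = np.where(g == 1, mean_hi[:, None], mean_lo[:, None])
    resid = y - fitted
    df_resid = used.size - 2
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)
    sigma = np.maximum(sigma, RESIDUAL_SD_FLOOR)

    if logcpm.library_sizes is not None:
        lib = logcpm.library_sizes[used]
        # average log2-count per gene, and fitted log2-counts per observation
        sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
        fx = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    else:
        sx = y.mean(axis=1)
        fx = fitted
    sy = np.sqrt(sigma)

    trend = lowess(sy, sx, frac=LOWESS_SPAN, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    ty = np.maximum(ty, math.sqrt(RESIDUAL_SD_FLOOR))
    pred = np.interp(fx, tx, ty)  # constant extrapolation beyond the range

    weights_used = pred**-4
    weights = np.zeros_like(logcpm.values)
    weights[:, used] = weights_used
    # excluded columns get the gene's mean weight; they never enter the fit
    if used.size < weights.shape[1]:
        fill = weights_used.mean(axis=1)
        for j in range(weights.shape[1]):
            if j not in set(used.tolist()):
                weights[:, j] = fill
    return weights


# ---------------------------------------------------------------------------
# Moderated t-test
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def estimate_variance_prior(
    variances: np.ndarray, df: float
) -> tuple[float, float]:
    """Moment-match a scaled-F prior to per-gene sample variances.

    Works on the log scale: for ``z = log(s^2)``,
    ``E z = log(s0^2) + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)``
    and ``Var z = trigamma(df/2) + trigamma(d0/2)``; the excess of the
    empirical variance of ``z`` over ``trigamma(df/2)`` is inverted through
    the trigamma function to give the prior degrees of freedom ``d0``.
    Returns ``(d0, s0_sq)``; ``d0 = inf`` when the empirical spread is no
    larger than expected under a single common variance.
    """
    v = np.asarray(variances, dtype=float)
    v = v[v > 0]
    if v.size < 2:
        return math.inf, float(v.mean()) if v.size else 1.0
    z = np.log(v)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return math.inf, float(math.exp(emean))
    d0 = float(2.0 * _trigamma_inverse(np.array([excess]))[0])
    s0_sq = float(
        math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    )
    return d0, s0_sq


def moderated_t_test(
    logcpm: ExpressionMatrix,
    weights: np.ndarray | None,
    groups: np.ndarray,
    prior_df_override: float | None = None,
) -> list[DEResult]:
    """Weighted two-group fit per gene with empirical-Bayes variance shrinkage.

    Each gene gets a weighted linear fit with intercept + group indicator;
    the residual variances across genes are shrunk toward the moment-matched
    prior, ``s2_post = (d0*s0^2 + d*s^2) / (d0 + d)``, and the moderated t is
    the coefficient over its standard error using the shrunken variance, with
    ``d + d0`` degrees of freedom.

    ``prior_df_override`` forces ``d0`` (0 recovers the ordinary weighted t;
    ``inf`` recovers the common-variance z-like statistic); it exists for
    validation against closed-form small cases.

    Returns results with ``raw_p``, ``log_fc``, ``moderated_t`` and
    ``mean_expression`` filled; ``adj_p`` is left to
    :func:`benjamini_hochberg`.
    """
    logcpm.require_unit(NORMALIZED_INTENSITY)
    hi, lo = _check_two_groups(groups)
    used = np.concatenate([lo, hi])
    y = logcpm.values[:, used]
    g = (groups[used] == 1).astype(float)
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)[:, used]
        if np.any(w <= 0):
            raise DataError("precision weights must be positive")

    w_hi = (w * g).sum(axis=1)
    w_lo = (w * (1.0 - g)).sum(axis=1)
    mean_hi = (w * y * g).sum(axis=1) / w_hi
    mean_lo = (w * y * (1.0 - g)).sum(axis=1) / w_lo
    log_fc = mean_hi - mean_lo

    fitted = np.outer(mean_hi, g) + np.outer(mean_lo, 1.0 - g)
    resid = y - fitted
    df = used.size - 2
    s2 = (w * resid**2).sum(axis=1) / df
    unscaled_se = np.sqrt(1.0 / w_hi + 1.0 / w_lo)

    if prior_df_override is None:
        d0, s0_sq = estimate_variance_prior(s2, df)
    else:
        # validation hook: 0 -> ordinary weighted t; inf -> z-like statistic
        # with the pooled common variance
        d0 = float(prior_df_override)
        s0_sq = float(s2.mean()) if math.isinf(d0) else 0.0

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    s2_post = np.maximum(s2_post, RESIDUAL_SD_FLOOR**2)

    t = log_fc / (np.sqrt(s2_post) * unscaled_se)
    if math.isinf(df_total):
        raw_p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        raw_p = 2.0 * stats.t.sf(np.abs(t), df_total)

    mean_expr = y.mean(axis=1)
    return [
        DEResult(
            gene_id=gid,
            log_fc=float(log_fc[i]),
            raw_p=float(raw_p[i]),
            moderated_t=float(t[i]),
            mean_expression=float(mean_expr[i]),
        )
        for i, gid in enumerate(logcpm.gene_ids)
    ]


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def benjamini_hochberg(raw_p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------


def differential_screen(
    matrix: ExpressionMatrix,
    groups: np.ndarray,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> tuple[set[str], list[DEResult]]:
    """Run the full two-group screen and return survivors plus the full table.

    Raw-count matrices go through log-CPM and precision weighting; matrices
    already on a log-intensity scale are tested with unit weights. Survivors
    satisfy ``log_fc > min_log_fc`` and ``adj_p < max_adj_p``, both strict.
    """
    if matrix.unit == RAW_COUNTS:
        lc = log_cpm(matrix)
        weights = fit_voom_weights(lc, groups)
    elif matrix.unit == NORMALIZED_INTENSITY:
        lc, weights = matrix, None
    else:
        raise DataError(
            f"screen expects raw_counts or normalized_intensity, got {matrix.unit!r}"
        )
    results = moderated_t_test(lc, weights, groups)
    adj = benjamini_hochberg([r.raw_p for r in results])
    for r, a in zip(results, adj):
        r.adj_p = float(a)
    survivors = screen_survivors(results, thresholds)
    return survivors, results


def screen_survivors(
    results: Sequence[DEResult], thresholds: ScreenThresholds = ScreenThresholds()
) -> set[str]:
    """Genes passing both strict thresholds of the screen."""
    return {
        r.gene_id
        for r in results
        if r.log_fc > thresholds.min_log_fc and r.adj_p < thresholds.max_adj_p
    }


def run_screen(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    strat_config: StratificationConfig = StratificationConfig(),
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> tuple[set[str], list[DEResult], list[SampleAnnotation]]:
    """Stratify then screen; convenience wrapper used by the CLI and funnel."""
    stratified = stratify(matrix, annotations, strat_config)
    groups = group_vector(matrix, stratified)
    survivors, results = differential_screen(matrix, groups, thresholds)
    return survivors, results, stratified


def de_table_to_frame(
    results: Sequence[DEResult], thresholds: ScreenThresholds | None = None
) -> pd.DataFrame:
    """DEResult list as a DataFrame, with a pass flag when thresholds given."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "log_fc": [r.log_fc for r in results],
            "raw_p": [r.raw_p for r in results],
            "adj_p": [r.adj_p for r in results],
            "moderated_t": [r.moderated_t for r in results],
            "mean_expression": [r.mean_expression for r in results],
        }
    )
    if thresholds is not None:
        df["passes"] = (df.log_fc > thresholds.min_log_fc) & (
            df.adj_p < thresholds.max_adj_p
        )
    return df
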