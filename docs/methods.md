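# Methods

## The screening model

The differential-expression screen treats a two-group comparison of tumor
expression (high vs low driver activity) gene by gene, with information
shared across genes in two places: the mean–variance trend and the
variance prior.

**Log-CPM.** Raw counts are transformed to
`log2((count + 0.5)/(libsize + 1) · 1e6)`, with the library size taken as
the column sum. The half-count offset keeps zeros finite; the `+1` on the
library size keeps the transform defined for any positive library. The
transform refuses matrices not tagged as raw counts, so FPKM or array
intensities cannot be run through it by accident.

**Precision weights.** Counts are heteroscedastic on the log scale, with
variance falling as expression rises. Per-gene residual standard
deviations from group-mean fits (floored at 1e-8 so zero-variance genes
cannot produce infinite weights) are square-root transformed and
regressed on average log2-count with lowess (span 0.5, a conventional
smoother default exposed in `diffexpr.LOWESS_SPAN`). The fitted trend,
evaluated at each observation's fitted log-count and raised to the fourth
power, is inverted into a per-observation weight. Outside the fitted
range the trend is extended as a constant. On matrices without library
sizes (already-normalized intensities) the same machinery runs directly
on the log-intensity scale; array screens simply use unit weights.

**Moderated t.** Each gene gets a weighted two-group fit. For the
two-group design the weighted least-squares solution has the closed form
used in the code: weighted group means, log-FC = high − low, residual
variance `s² = Σw·r²/(n−2)`, unscaled standard error
`sqrt(1/Σw_high + 1/Σw_low)`. The per-gene variances are then shrunk
toward a common prior: treating `s²` as scaled-F distributed, the prior
degrees of freedom `d0` and prior variance `s0²` are estimated by moment
matching on the log scale (mean and variance of `log s²`, with the
trigamma function inverted by Newton iteration); the posterior variance
is `(d0·s0² + d·s²)/(d0 + d)` and the moderated t is referred to a t
distribution with `d + d0` degrees of freedom. When the empirical spread
of `log s²` is no larger than sampling noise the prior df is infinite and
the statistic degenerates to a common-variance z. A `prior_df_override`
hook exposes the two limits (0 = ordinary weighted t, ∞ = pooled z) for
validation; a test also cross-checks the whole chain against the
R limma/voom implementation on a simulated cohort, where log-FCs agree to
~1e-4 and t statistics to ~1e-4 relative.

**Thresholds.** Survivors satisfy `log_fc > 1` and BH-adjusted
`p < 0.05`, both strict. The fold-change threshold is printed as strict
in the source material; the adjusted-p boundary is unspecified there and
strict was chosen for symmetry. A candidate-matrix row whose array
fold change is missing (NaN) passes the array side on its adjusted p
alone — the published matrix retains one such gene (NME1), and the
assembly honors that convention.

**Stratification.** `by_status` maps amplified → high and non-amplified →
low, erroring if either group is empty. `by_quantile` takes
`floor(fraction·n)` samples (minimum 2) from each extreme of the driver
gene's own expression, default fraction 0.15, the rest excluded; boundary
ties are broken by ascending sample id so the assignment is invariant
under column permutation. Both modes are provided because the published
analyses describe stratification "by driver expression" for both
platforms while coloring tumors by amplification status; nothing in this
package depends on which of the two produced the published matrix.

## Regulatory evidence

Promoter windows are strand-oriented `[tss − up, tss + down)` with ±1 kb
defaults. "TSS-proximal" has no published numeric definition, so the
window is configuration, chosen at the scale conventional for promoter
analyses and exposed as `--window-up/--window-down`. Promoter sequences
are stored 5'→3' along the gene's strand with the TSS at index `up`, so
motif offsets read directly as signed distances from the TSS.

The motif set defaults to the canonical E-box `CACGTG` only. It is its
own reverse complement, so exact scanning along the stored strand is
strand-agnostic; non-canonical E-boxes (e.g. `CATGTG`) can be added, in
which case each motif and its reverse complement are both scanned.
Overlapping occurrences are all reported.

Peaks are filtered at `q ≤ 0.05` (inclusive, matching common
peak-calling usage) after decoding narrowPeak column 9 from −log10;
any ≥ 1 bp overlap with a blacklist interval removes a peak. A gene is
"bound near TSS" when a filtered peak overlaps its window and its E-box
is "occupied" when a filtered peak overlaps a motif interval — summit
position is deliberately not used, since the published occupancy calls
state no summit rule. Consensus across cell lines defaults to "any line"
(`min_lines=1`) because the published analysis aggregates discovery
lines without stating a quorum; occupied ⇒ bound is enforced as a type
invariant.

The local-Poisson caller included here is a fixture generator for tests,
not a peak caller for real data: per-position Poisson upper tails against
the max of local control means (1 kb and 10 kb windows) and the global
control mean, BH over positions, significant runs merged into peaks.

## Annotation filters

Membrane designation: max compartment score attained by "Plasma
membrane" or "Cell surface" (case-insensitive, configurable synonym
list) and ≥ 3; a tie with a non-membrane category passes because the
rule constrains only which labels attain the max. Normal-tissue
restriction: expression ≤ 1.0 (TPM-like units, configurable — no numeric
cutoff is published) in every tissue outside a configurable CNS panel.
Secretion: a recorded Boolean. All three are pure predicates, so the
funnel's stage order cannot change its final set — asserted as a
property test.

## The funnel and ranking

Stages run in the fixed order: matrix membership (dual-platform DE +
membrane), E-box near TSS, bound, occupied, CNS-restricted, not
secreted. Survivor sets are nested by construction and the per-stage
counts equal brute-force conjunction counts (oracle-tested).

Ranking the final survivors is genuinely ambiguous on the packaged
matrix: the published nominee (CAMKV) has the larger RNA-seq log-FC
(1.73 vs 1.00) but the *larger* adjusted p (2.02e-6 vs 1.17e-6), so
"most significant" and "largest effect" disagree. The default ranks by
descending RNA-seq log-FC with adjusted p as tiebreak, which reproduces
the published nomination; `key="adj_p"` gives the significance-first
order, and whenever the two leaders differ the report carries an explicit
note instead of resolving the tension silently. The published narrative
also invokes protein-localization literature for the final
CAMKV-over-NME1 judgment; that qualitative step is not modeled. (The
source material is also internally inconsistent about the occupied-E-box
count — its discussion says 4 where its results table supports 8; the
packaged fixture follows the table.)

Array statistics are reported but never ranked on; the published
head-to-head comparison quotes RNA-seq values.

## Synthetic data

`simulate_cohort` draws NB counts with `var = μ + φμ²` (φ = 0.1 by
default, a typical bulk-tumor dispersion scale), per-gene baselines
log-normal around 100 so the mean–variance trend is non-trivial, a
default cohort of 60 samples with 40% amplified (the published discovery
cohorts are larger — 150 and 250 tumors — but the generator's default is
sized for routine testing while keeping ≥ 20 samples per group), 50
planted targets at log2FC 1.5 (straddling the screen's >1 threshold the
way real hits must) and the driver itself at log2FC 3 so status and
quantile stratification agree. `simulate_genome` spaces TSSs so promoter
windows never overlap, which makes zero-decoy occupancy equal the
planted truth exactly — chance background E-boxes exist (and are
scanned) but never receive peaks. `simulate_chip` emits peak-level
objects directly (±75 bp around each planted motif, q as configured);
read-level simulation is out of scope. `simulate_annotations` plants
independent Bernoulli membrane/CNS/secretion flags and builds score and
tissue tables that decode back to exactly those flags.

What the simulators do **not** emulate: library-size variation beyond
sampling noise, batch effects, correlated genes, GC or mappability bias,
fragment-level ChIP noise, and the fuzzy boundaries of real compartment
and tissue annotations. Passing recovery tests therefore demonstrates
the pipeline's logic and calibration, not robustness to those real-data
pathologies.

## Validation experiments and problem sizes

The suite sizes its simulations to run on a single CPU in a few minutes:
null calibration uses 10 cohorts of 2000 genes × (30+30) samples, where
the moderated test's raw-p-below-0.05 fraction averages 0.05 ± 0.01 and
BH at 0.05 yields no survivors; end-to-end recovery uses 10–20 seeds of
the default cohort with q = 0.001 peaks and zero decoys, scored by
pooled sensitivity (≥ 0.9) and pooled false-discovery proportion
(≤ 0.1) against the planted all-criteria truth (pooling across seeds is
used because each seed's joint truth set — DE ∧ E-box ∧ membrane ∧ CNS ∧
non-secreted — is small, a realistic feature of a funnel whose stages
are individually uncommon). The published cohort-level numbers (CAMKV
log-FC 1.73 at adjusted p 2.02e-6; driver–nominee correlation R ≈ 0.6
over 150 tumors) cannot be recomputed without the external cohorts; they
enter only through the packaged matrix fixture, and the correlation
estimator is validated on a bivariate-normal surrogate at the same ρ
and n.

## Known limitations

- Two-group designs only; no covariates, batch correction or
  multi-factor models.
- Exact-match motif scanning; no PWM scoring or degenerate-motif
  statistics beyond an explicit motif list.
- The toy Poisson caller ignores duplicate reads, fragment-size
  modeling and local biases; it exists to fabricate test fixtures.
- Annotation filters consume schema-compatible tables; they do not query
  live compartment or tissue-expression databases.
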