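# Methods

This note documents the models behind `sipracs`, the defaults and why they
were chosen, the numerical details that affect results, and the limits of
what the synthetic-data tests demonstrate.

## Single-cell Raman classification

**Spectral model.** A cell's spectrum over 500–2000 cm⁻¹ (1 cm⁻¹ grid, the
standard acquisition window for 532-nm single-cell work) is modeled as a sum
of Gaussian bands, a smooth polynomial background standing in for
fluorescence, and i.i.d. Gaussian noise. The default band set is
phenylalanine ring breathing (1003 cm⁻¹), Amide III (1105 cm⁻¹), CH₂
deformation (1450 cm⁻¹) and Amide I (1660 cm⁻¹); amplitudes 0.6/1.0/0.8/0.9,
widths 6–10 cm⁻¹. Only Amide III carries the labeling signal — the others
exist so preprocessing and localization are exercised on a realistic,
multi-band profile. A Lorentzian lineshape is available behind a flag; the
choice does not matter for shift localization, which is why Gaussian is the
default. ¹³C labeling translates the Amide III component by −23 cm⁻¹
(to 1082 cm⁻¹); partial labeling is modeled as a mixture of shifted and
unshifted components weighted by the labeling fraction. The default noise
level is 2% of the Amide III amplitude.

**Baseline correction** uses asymmetric penalized least squares (AsLS):
iteratively fit a curve z minimizing Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)², with weights
`asymmetry` above the current fit and `1 − asymmetry` below, so the fit hugs
the lower envelope and leaves peaks intact. Defaults: λ = 1e5, asymmetry
0.01, 10 iterations — the de-facto standard for fluorescence background
removal, and all three are exposed. On a known quadratic background the
corrected spectrum matches the generating peak to within 2% of its amplitude
both off-peak and at the apex.

**Vector normalization** divides by the Euclidean norm, making every
downstream quantity invariant to acquisition intensity. The canonical
preprocessing order is baseline correction, then normalization.

**Band localization.** The Amide III position is the maximum inside a
1040–1140 cm⁻¹ window, refined to sub-grid resolution by a least-squares
parabola fitted over grid points within ±5 cm⁻¹ of the three-point-refined
apex. The two-stage refinement matters: a plain three-point parabola has
~1 cm⁻¹ jitter at 5% noise, while the windowed fit brings the mean absolute
error of the planted −23 cm⁻¹ shift down to ~0.4 cm⁻¹; centering the fit
window on the refined (not the discrete) apex removes the bias that
otherwise appears when a band apex falls between grid points. A window with
no interior local maximum (monotone ramp, constant segment, maximum on a
window edge) is reported as a distinct "no band" condition rather than a
position; such cells are classified *indeterminate* and excluded from
labeled counts.

**Decision rule.** A cell is called labeled when its band position lies
below the midpoint of the two printed positions, 1093.5 cm⁻¹. The midpoint
gives symmetric error against both band positions and is exposed as a
parameter; a band within 1e-9 cm⁻¹ of the boundary counts as unlabeled (tie
rule, guarded against float round-off). Cells are classified individually —
no cross-cell averaging — and classification is invariant to rescaling the
input spectrum because normalization precedes it.

**Group contrast.** Band intensities (normalized value at the grid point
nearest 1105 and 1082 cm⁻¹) are compared between labeled and unlabeled
groups by one-way ANOVA; with two groups F equals the squared
pooled-variance t statistic, which the tests verify numerically.

## SIP fraction tables and the REF screen

**Partition model (generator).** Each ASV's DNA mass splits between heavy
and light gradient fractions. Unlabeled DNA has heavy share 0.1 (a 1:9
heavy:light partition — fractionation is imperfect, some unlabeled DNA
always reaches the heavy window). Fully labeled DNA has the mirrored share
0.9, and the labeling strength s interpolates linearly between the two.
Only active ASVs in the ¹³C treatment deviate from baseline. The expected
relative abundance of ASV i in a fraction-class sample is its mass over the
class total, so planting a strongly labeled taxon *depresses* everyone
else's heavy-fraction share in the ¹³C gradient — the compositional closure
effect the REF statistic must tolerate (inactive taxa then sit slightly
below REF = 1; under a null design every taxon sits near 1).

**Replicate noise** is Dirichlet: each sample composition is drawn as
Dirichlet(dispersion × expected composition) with dispersion 500, which
preserves the sum-to-one constraint exactly. Buoyant densities are drawn
uniformly inside the corresponding window (heavy 1.7342–1.7411, light
1.7042–1.7089 g/ml); 6 replicates per treatment × class matches the
microcosm design.

**Default community.** 20 ASVs with mild geometric unevenness (ratio 0.98
per rank). This is deliberately flatter than a typical soil community: at
dispersion 500 a taxon's effective Dirichlet count is 500 × abundance, and
rare taxa (counts below ~10) would have REF sampling noise large enough to
defeat any fixed screening threshold. The defaults are chosen so the screen
is *testable* — the false-positive control below holds — not to mimic a
long-tailed field community; with real long-tailed data the same code
applies but rare-taxon REF values should be treated as unstable (the
bootstrap intervals are there for exactly this).

**REF computation.** Replicate samples are averaged within each
(treatment, fraction class) *before* forming ratios, yielding one REF per
ASV. Any ASV with a zero among its four terms has a pseudocount — half the
smallest nonzero term in the combined table, or a fixed value — added to
**all four** of its terms, which bounds the ratio symmetrically without
discarding taxa; the stored term fields remain un-adjusted. The screen
applies strict inequalities on both gates (mean of the four fraction-class
means > 0.5%; REF > 1.5); whether the abundance gate should instead use
whole-community abundance is genuinely ambiguous, so the gate's basis (the
four-term mean) is a deliberate, configurable choice. Densities outside
both windows are excluded rather than nearest-assigned. An optional
seeded bootstrap (resampling replicate columns within strata) provides
percentile intervals for REF; it is off by default.

**Calibration, measured by the test suite.** Under the null design
(strength 0, 200 simulations) the per-ASV mean REF stays inside
[0.95, 1.05] and under 0.6% of screened taxa are falsely flagged (the
false-active control is assessed per screened taxon). A fully labeled taxon
at ~6% abundance is flagged active and attains the top REF in ≥95% of 200
simulations. The closed-form expected REF under the partition algebra is
matched by simulation means; at default dispersion the simulated mean REF of
a strongly enriched taxon carries a small (~5%) upward Jensen bias, which is
a property of ratio estimators, not of the implementation — the oracle test
therefore also checks a high-dispersion condition where the bias vanishes.

## Kinetics and enzyme statistics

**Removal percent** is 100·(C₀−C_t)/C₀, returned at full precision;
reporting rounds half-up to one decimal via a separate formatter. Negative
values (C_t > C₀) are returned but flagged with a warning. The canonical
worked example: C₀ = 5 mg/kg falling to 2.01 mg/kg by day 7 gives 59.8%.

**First-order fit.** ln C = ln C₀ − k·t by log-linear least squares over
all replicate points, excluding (and counting) zeros. Because measurement
noise is additive on the concentration scale, its log-scale variance grows
as 1/C²; the default fit therefore applies two IRLS passes weighting each
point by its squared fitted concentration. This keeps the 95% CI on k
honest late in the time course — plain OLS covers the true rate in only
~80–88 of 100 simulated experiments at 5% noise, the weighted fit in ~92
(the suite requires ≥90) — while leaving noiseless recovery exact to ten
significant digits and preserving invariance to rescaling all
concentrations. `weighting="uniform"` restores plain OLS. Half-life is
ln 2 / k for k > 0 and undefined otherwise; slopes within float round-off
of zero are snapped to exactly zero so constant series report k = 0.

**Correlations and group tests.** Enzyme activity vs removal uses Pearson
correlation (r, R² = r², two-sided p; ≥3 pairs, zero-variance input
rejected). Treatment comparisons default to the Welch unequal-variance
t-test — the safer default when variances are unknown — with pooled t and
one-way ANOVA available; the enzyme generator plants activity =
slope·removal + intercept + noise, clipped at zero.

**Decay defaults.** C₀ = 5 mg/kg, k = ln(5/2.01)/7 ≈ 0.130 d⁻¹ (the rate
implied by the day-7 removal), sampling at days 0/7/14, six replicates,
noise 0.25 mg/kg (5% of C₀, a realistic GC–MS-scale scatter), truncated at
zero.

## Pipeline and I/O

The replay pipeline derives one independent child seed per stochastic stage
from the top-level seed (all below 2³¹), executes simulate → classify →
SIP → REF screen → kinetics, writes every intermediate table, and emits a
manifest with the SHA-256 of each artifact; identical configurations are
byte-identical. Numeric TSV fields use the shortest decimal representation
that round-trips the float exactly, so read(write(x)) == x bit-for-bit (12
significant digits would leave ~1e-12 relative residue, right at the
round-trip tolerance). Stage failures abort with a stage-named error and
exit code 3 from the CLI; configuration errors exit 2 before any stage
runs. Simulation sizes in the default configuration (150 cells, 20 ASVs ×
24 samples, 200-repetition calibration loops in the tests) keep the entire
suite in the tens of seconds on one CPU.

## What the synthetic data do not show

The generators emulate the *statistical structure* the analysis assumes,
not the messiness of real data: no cosmic-ray spikes, wavenumber
miscalibration, or cell-to-cell band-intensity variation in the spectra; no
sequencing error, chimeras, compositional zeros from undersampling, or
GC-content density confounds in the fraction tables; no matrix effects in
the chemistry. Passing tests therefore demonstrate that the statistics are
implemented correctly and are well calibrated under their own assumptions —
they do not certify performance on field data, where the indeterminate-cell
path, the pseudocount policy, and the bootstrap intervals are expected to
matter much more.
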