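# Methods

## The measurement model

Plant sterols are C27–C31 triterpenoids sharing a four-ring skeleton.
Under atmospheric-pressure chemical ionisation they are detected as the
dehydrated protonated ion [M−H2O+H]+, so the measurable quantity for a
sterol class `ST(c:d)` — `c` carbons, `d` double-bond equivalents beyond
the rings — is

    m/z = 12·c + (2c − 6 − 2d − k)·m_H + k·m_D + m_O − m_H2O + m_proton

with `k` deuterium substitutions (k = 7 for the internal standard).  Two
conventions matter and are fixed throughout:

- the charge carrier is the **proton** (1.007276 Da), not atomic
  hydrogen; this is the only choice that reproduces the reference grid
  and the d7-cholesterol ion at the printed 3-decimal precision;
- `d` counts **all** unsaturations beyond the four canonical rings, so
  the cyclopropane ring of the cycloartenol family is part of `d`
  (cycloartenol C30H50O is `ST(30:2)`); this is the only convention that
  reproduces the C30/C31 reference masses.

The packaged registry holds the 14 classes whose dehydrated ions appear
on the reference grid and 21 named sterols.  Four additional printed
masses (399.362, 413.378, 427.394, 441.409) form a CH2 homolog series
that matches the plain protonated [M+H]+ ions of `ST(28:2)`–`ST(31:2)`
to within ~1 mDa; no `ST(c:d)` dehydrated ion reproduces them, so they
are stored as unassigned auxiliary masses and never matched during
annotation.  A few grid entries are printed truncated rather than
rounded (e.g. 381.351 vs the theoretical 381.3516), so mass fidelity is
asserted at the printed precision (1 mDa) rather than as exact 3-d.p.
rounding.

Reference retention times in the registry are synthetic placeholders —
the published standards appendix is not distributed — except the
internal standard's 5.6 min.  They are spaced ≥ 0.15 min within isomer
groups so that level-1 assignment at the 0.1-min window is always
unambiguous; users with measured standards should supply their own
registry TSV.

## Annotation pipeline

Peaks are filtered to RT 3–11 min, m/z 360–442 and area ≥ 5·10⁵ (closed
intervals; the threshold value itself is retained).  Cross-sample signal
identities combine the m/z rounded to 3 d.p. with single-linkage RT
clusters: a gap larger than 0.1 min opens a new cluster.  This
reproduces a fixed RT window without imposing a grid phase, and makes
binning a partition of the retained peaks (total area is conserved;
within-sample co-elutions are summed).

The blank rule compares, per signal, the mean area over all non-blank
samples with the mean over all blanks (solvent and extraction pooled;
absent areas count as zero in both means).  A signal passes only if the
sample mean is strictly greater than 3× the blank mean.  Passing signals
with a grid mass (±5 ppm; ~2 mDa at m/z 400, subsuming the 3-d.p.
printed precision) become level 2; a reference RT within 0.1 min
additionally promotes to level 1.  Ambiguity is resolved by smallest
mass error, then nearest reference RT.

One deliberate exception: the deuterated internal standard is spiked
into the extraction blanks by design, so the blank rule would always
reject it.  The spike is therefore identified by its own deuterated mass
and RT regardless of the blank flag, and is excluded from every
composition denominator.  All other blank-failing signals stay level 3
no matter what their mass matches.

## Compositions

Relative abundance is per mille of the sample's retained signal:
`1000 · areaᵢ / Σ areas`.  The default denominator is every
blank-passing signal (annotated or not, spike excluded), matching how a
total-signal correction is applied in practice; `annotated_only=True`
restricts the denominator to the annotated sterols, in which case rows
sum to exactly 1000.  Carbon-family summaries (C27–C31) are a linear,
total-conserving regrouping; the dominant family of a sample is the one
exceeding 60% of total signal, if any.

Total sterol per kg pollen uses the d7-cholesterol spike (20 µL ×
0.1 mg/mL = 2 µg ≈ 5.084 nmol; the reference protocol prints the same
numeral with a µmol unit, which is dimensionally inconsistent with the
stated volume and concentration, so the nanomole reading is used) and a
single-point response factor of 1.  It is a labelled approximation — no
calibration curve exists — and is reported but never used by the
statistics.

## Distance-based inference

Bray-Curtis dissimilarities feed a one-factor PERMANOVA: with `n`
samples in `a` groups,

    SS_total = Σ_{i<j} d²ij / n,     SS_within = Σ_g Σ_{i<j∈g} d²ij / n_g,
    pseudo-F = (SS_between/(a−1)) / (SS_within/(n−a)).

The p-value is the add-one permutation estimate
`(1 + #{F_perm ≥ F_obs}) / (1 + N_perm)` — never zero, and exactly
`1/(N+1)` when no permutation reaches the observed statistic.  A random
effect (species, in the paired leaf/pollen design) is handled by
restricting permutations to move labels only within strata, the
standard distance-based analogue of a nested design; a factor constant
within every stratum is reported as an error, since no admissible
permutation changes the grouping.  Pairwise post hoc tests run the same
machinery per level pair with Holm correction (a step-down control that
needs no independence assumptions).

SIMPER decomposes each cross-pair Bray-Curtis distance additively over
sterols, `|x_ai − x_bi| / Σ_k (x_ak + x_bk)`, and averages over pairs;
contributions therefore sum *exactly* to the mean between-group
dissimilarity, which is asserted to 1e-9.  PCA is an
eigen-decomposition of the column-centred covariance — unscaled, since
all variables share the per-mille unit — with each component signed so
its largest-magnitude loading is positive, making results reproducible
across BLAS implementations.

## Ancestral state reconstruction

A sterol proportion evolving by Brownian motion with rate σ² implies tip
values `x ~ N(root·1, σ²C)` with `C[i,j]` the root-to-MRCA path length.
The package uses the ML estimators: GLS root `(1'C⁻¹x)/(1'C⁻¹1)` and
rate `(x−root)'C⁻¹(x−root)/n`.  The divisor `n` (ML, not REML) matches
the maximum-likelihood framing of the analysis; its known downward bias
of order 1/n is visible in the recovery checks (≈ −3% at 31 tips,
within the documented 10% band) and is deliberate.

Each internal node's state is the GLS mean computed after re-rooting the
tree at that node.  These re-rooted estimates equal the multivariate
normal conditional expectations
`root + c_v'C⁻¹(x − root·1)` (with `c_v[i]` the depth of MRCA(v, tip i)),
which serves as the independent oracle in the tests.  Note that the
*maximised likelihood itself* is not invariant under physically
re-rooting the BM model (the log|C| term changes); what is invariant is
the fitted model — estimating states at any set of nodes leaves σ², the
root and the log-likelihood untouched, and that is the property the
tests assert.  Reported node variances are `σ̂²/(1'C_v⁻¹1)` in each
node's own rooting.

Characters are per-mille proportions reconstructed directly, mirroring
how proportions are reconstructed in practice; a logit option is
available (states are back-transformed) but off by default.  Polytomies
are resolved to binary nodes with 1e-8-length branches, with a warning;
zero or missing branch lengths are errors because they make C singular.
Leaf and pollen characters of the same sterol are reconstructed
independently.

## The synthetic generator

`generate_study` emulates the data structure of a 40-species leaf/pollen
sterol survey: 31 species with both tissues (the set used for ASR), 6
leaf-only, 3 pollen-only, 7 solvent blanks, 3 extraction blanks and
triplicate QCs at 2.5/5/10 mg pollen loadings.  Species-level variation
is Brownian motion on a Yule tree (depth scaled to 1) applied to latent
log-abundances with σ² = 0.15, i.e. ≈ ±40% abundance variation per tree
depth — enough phylogenetic signal for related species to resemble each
other without destroying C29 dominance.  Tissue and pollination effects
are additive on the latent log scale and then closed to the simplex, so
compositions stay valid by construction.  The default baseline is
C29-dominant (73% of signal), with the tissue shifts placed where the
field expects them: isofucosterol up in pollen (+0.9 log units),
β-sitosterol up in leaves (−0.45), smaller shifts on cycloartenol,
24-methylenecholesterol, desmosterol and campesterol.

Rendering to peaks uses a total area of 10⁸ per sample, lognormal
multiplicative noise with CV 10% (typical LCMS area repeatability),
uniform mass jitter ≤ 2 ppm (the instrument class holds < 1 ppm on the
spike; 2 ppm is conservative) and RT jitter ≤ 0.03 min.  Decoy signals
are drawn off-grid (> 10 mDa from every registry mass, > 0.2 min from
every reference RT); half are contaminants present in blanks at a level
that makes them fail the 3× rule.  The internal standard is added to
every pollen sample, every QC and the extraction blanks.

Presets: `paperlike` (the defaults), `null` (no planted effects, for
type-I calibration), `noiseless` (no noise/jitter/decoys, area scale
10⁹ so every planted signal clears the threshold — the pipeline then
returns the planted compositions exactly), and `large-effect` (±1.5
log-unit tissue shifts for power checks).

What the generator does **not** emulate: chromatographic peak shapes and
co-elution tails, isotope envelopes, ionisation suppression, batch and
RT drift, missingness mechanisms other than the area threshold, and
real phylogenetic branch lengths.  Passing round trips therefore show
that the pipeline's bookkeeping and statistics are correct under the
stated noise model, not that the thresholds are optimal for any given
instrument.

One quantified consequence of the area threshold: trace sterols
(baseline ≲ 5‰ ≈ 5·10⁵ area) are censored in part or all samples, which
removes them from the denominator and inflates the recovered shares of
retained sterols by ~1–2%.  Measured over 500 samples at default noise,
mean recovered compositions track truth within 3% relative for every
sterol at ≥ 20‰ — the frozen round-trip fidelity of the default
conditions.  Real acquisitions share this censoring effect.

## Numerical and design choices

- Area threshold boundary inclusive (≥ 5·10⁵); blank ratio strict (> 3×).
- Signal identity uses the area-weighted mean RT as representative.
- Default normalization denominator includes unannotated level-3
  signals (with a switch), because the total-signal correction is
  defined over all retained signals.
- Permutation streams are seeded `numpy` generators; every result object
  records its seed, permutation count and degrees of freedom.
- PERMANOVA uses `F_perm ≥ F_obs − 1e-12` when counting, so exact ties
  (label permutations that reproduce the same partition) count toward p,
  keeping the test valid rather than anti-conservative.
- Problem sizes in the checks — 1000 null simulations at 199
  permutations, 500 rate-recovery replicates at 31 tips, 200 oracle
  trees at ≤ 12 tips, 500-sample round trips — were chosen as the
  smallest sizes at which the binomial or Monte-Carlo error is clearly
  below the asserted tolerances.

## Known limitations

- Annotation is mass+RT only: no isotope-pattern scoring, no adducts
  beyond [M−H2O+H]+, no structure elucidation.  Isomers without a
  separable RT cannot be told apart.
- The blank rule is a per-signal grand-mean comparison; a per-batch or
  per-run blank model is out of scope.
- PERMANOVA is one factor at a time (with strata); no interaction terms,
  dispersion tests (PERMDISP) or dbRDA.
- Total sterol assumes equimolar response — a labelled approximation.
- BM only for ASR: no Ornstein-Uhlenbeck, rate shifts or measurement
  error in tips; proportions are reconstructed on the raw scale by
  default and can leave [0, 1000] on extreme trees (use the logit
  option when that matters).
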