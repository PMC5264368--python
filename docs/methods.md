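# Methods

This note records the models, conventions and numerical choices behind the
package, and what its validation does and does not establish.

## Connected-speech coding

Transcripts of a single-picture description are parsed from a minimal
CHAT-like dialect (one speaker line per row; `[/]` repetition, `[//]`
retrace, `&+` false-start fragment, `xxx` unintelligible, `[and]`
clause-joining conjunction; `.?!` complete terminators, `+...`/`+/.`
incomplete).  Utterance segmentation allows one clause-joining "and" per
sentence; a second one starts a new utterance, with the split falling before
that "and" (a carried-over leading "and" does not join two clauses in its
own utterance and so does not count against the rule there).  Only complete
utterances containing at least one countable token are coded; tokens flagged
as repetitions, retraces, false starts or unintelligible are dropped from
every count.

Measures: T = kept tokens; types = distinct lower-cased surface forms (no
lemmatisation — TTR is defined on word types); TTR = types/T (0 when T = 0);
MLU = morphemes per kept utterance; WPM = 60·T/duration, using the total
sample duration (whether the original coding used recording time or speaking
time is not documented; total sample time is the reproducible choice).
Morphemes are counted by rule: one per free word plus one per recognised
inflectional suffix (-s plural/possessive/3rd person, -ed, -ing, -er/-est,
contracted auxiliaries), with a bundled exception list (pseudo-suffixed
words such as *is*, *water*, *thing*) and an irregular lexicon with explicit
counts (irregular pasts are not decomposed; *gonna*-type contractions count
2).  The rule set is a documented approximation to hand coding conventions
and is versioned with the package; unknown words count one morpheme.

Percent conversion divides each measure by its cohort maximum (so the best
participant scores 100), or by a supplied test maximum.  Conversion is
linear per column, so it leaves every between-measure Pearson correlation —
and hence the PCA — unchanged.

## Rotated PCA

PCA is computed on the Pearson correlation matrix of the percent scores.
Retention uses the Kaiser criterion with a strict threshold (λ > 1.0).
Unrotated loadings are eigenvector·√λ.  Varimax rotation uses Kaiser
row-normalisation (the SPSS default), an SVD-based update, convergence
tolerance 1e-6 on the criterion with at most 1000 iterations, and raises on
non-convergence.  Factor scores use the regression (Thomson) method
`W = R⁻¹L`; under PCA extraction and an orthogonal rotation these have
exactly zero mean, unit variance and identity cross-correlation, which the
simultaneous VBCM design relies on.

Determinism conventions: rotated factors are ordered by descending sum of
squared loadings (the SPSS display convention) and each factor's sign is
flipped so its largest-|loading| measure loads positively.  Eigen-tie and
eigenvector-sign ambiguity across linear-algebra backends is thereby
resolved; alignment is idempotent.

On the packaged 31 × 21 cohort this reproduces the published solutions to
well within the printed precision: speech-only solution (2 components,
84.65 % total variance, per-component 59.28/25.35 %), omnibus solution
(4 components, 54.8/11.6/8.3/6.3 % unrotated variance), maximum elementwise
loading difference < 0.001, and factor-score correlations of 1.000 with the
published columns.  A sensitivity refit with ±0.005 uniform jitter (the
2-dp rounding half-width of the input tables) moves no loading by more than
0.01.

One published pair of numbers is *not* recoverable from the published
tables: the correlations between the speech factors and the earlier
battery factors are reported as .404 and .452, but Pearson correlation of
the corresponding published score columns gives .454 and .475 (and .454 at
n = 31 has p = .0103, matching the "p = .01" printed alongside the first).
The package computes and reports the values implied by the tables; the
corresponding acceptance checks fail by construction and are documented
rather than loosened.  The executive-factor/lesion-volume correlation
(−.373) reproduces exactly using the omnibus executive column.

## VBCM

Dependent variable: smoothed continuous tissue intensity (8 mm FWHM
separable Gaussian, σ_axis = fwhm/(voxel·2√(2 ln 2)), reflecting
boundaries; no global intensity normalisation is applied).  Design: all
factor scores entered simultaneously, intercept, and optionally the lesion
volume (raw voxel count, mean-centred so it decouples from the intercept
without changing interest t values).  Per voxel, OLS with
`t_j = β_j/se(β_j)`, df = n − p.  The vectorised fit uses fixed-order
(unoptimised einsum) accumulation so it is bit-identical to a per-voxel
loop.  Voxels whose intensity is constant across patients get t = 0.

Inference: one-tailed positive by default (damage lowers intensity and
scores together; two-tailed available), voxel threshold p < .005 strict,
clusters by 26-connectivity (6/18 available; 18 matches SPM's surface
convention, 26 FSL's).  Cluster-level FWE uses the Freedman–Lane scheme:
data are residualised on the nuisance columns, residual rows permuted, the
full model refit, and the maximum suprathreshold cluster extent recorded;
corrected p = (1 + #{max ≥ observed})/(1 + n_perm), which honours the
1/(1 + n_perm) floor and is monotone in extent.  Permutation was chosen over
random-field theory because it is assumption-free and testable by
simulation at desk scale.  Note the floor means cluster-level thresholds
below 1/(1+n_perm) (for example a corrected p ≤ .001 at n_perm = 200) are
unreachable; the default α is .05 with n_perm configurable.

Default analysis mask: voxels lesioned in at least one patient, within the
brain mask (both the minimum count and the mask source are configurable).
Coordinates are reported in world mm via the affine; voxel indices are
0-based internally.

Empirical type-I error of the full pipeline on pure-noise cohorts
(n = 31, 14³ voxel lattice, 6 mm smoothing, 200 permutations) is computed by
`pcavbcm.validation.type_i_error`; at 200 datasets it lands inside the
binomial 95 % band around the nominal .05.  Pilot runs showed mild
liberality (≈.07) at very small cohorts (n = 16, df = 13), a known
small-sample behaviour of residual-permutation schemes; at the cohort sizes
used here the rate is nominal.

## Synthetic cohorts

The generator produces the structure the analysis assumes, with ground
truth, at desk scale (48×56×48 lattice of 2 mm voxels ≈ one quarter linear
scale of a normalised brain):

* latents: n × k independent standard normals (defaults n = 31, k = 4);
* behaviour: `raw = Λz + ε`, Λ a fixed block pattern over 21 measures
  (blocks of 11/3/3/4 with primary loadings .75 and a few fixed
  cross-loadings, echoing the published omnibus structure), unique noise
  sd 0.45 — chosen so Kaiser retention recovers k = 4 in ≥ 90 % of cohorts
  at n = 31 — then affinely mapped to [0, 100] with clipping (clipped
  fraction logged, < 5 % under defaults);
* template: unit-intensity ellipsoidal brain (≈38 000 voxels); four
  disjoint ellipsoidal target regions (≈471 voxels each) in the left
  hemisphere, one per factor, whose intensity drops by
  0.65·max(0, −z_f) with a radial taper (deeper at the core), so lesion
  extent grows continuously with deficit;
* a common infarct core (141 voxels, constant damage 0.8) lesioned in every
  patient — the overlap-map maximum;
* a left-hemisphere severity belt (outer shell, ≈6 500 voxels) whose damage
  is `severity · depth(voxel)`, with severity bounded in [0.55, 1] (normal
  CDF of a driver correlated .85 with the mean deficit) and an
  inverse-square radial depth profile.  The bounds and profile are chosen so
  both belt intensity and the lesioned-belt voxel count are linear in
  severity: lesion volume is then a linear proxy for the global severity
  confound, which is exactly the condition under which a linear
  lesion-volume covariate can absorb it.  Pilot experiments with a lognormal
  severity and saturating (clipped) intensities showed the covariate cannot
  remove a confound whose intensity–volume relation is nonlinear — even
  adjusting on the true severity failed — which is worth bearing in mind
  when interpreting volume-corrected analyses of real data;
* lesion masks: voxels whose damaged (pre-smoothing) intensity falls below
  0.5 of the template; volumes: damaged intensity plus in-brain Gaussian
  noise (sd 0.06), smoothed 8 mm.  Generated lesion volumes span roughly
  600–4 900 voxels (right-skewed), the published cohort's range at this
  lattice scale.

Everything is deterministic given (spec, seed).

What passing the synthetic validation shows: the permutation FWE control is
calibrated, planted factor-specific regions are recovered (top
FWE-significant cluster per factor has Dice > 0.5 with its region, with the
volume covariate in the model, in ≥ 80 % of cohorts), and the severity belt
appears as a spurious factor correlate without the volume covariate and
disappears with it.  What it does not show: robustness to registration
error, anatomically realistic lesion shapes or vascular-territory
correlation structure, non-Gaussian intensity noise, or behaviour whose
severity coupling is nonlinear — real-data conclusions still depend on
those.

Parameter-recovery checks compare fitted rotated loadings to their
*estimand* — varimax applied to the population correlation implied by
(Λ, noise) — because with cross-loadings the varimax optimum itself deviates
from Λ by up to ≈0.05, so ±0.1 elementwise against raw Λ would conflate
estimator error with the rotation criterion's own bias.

## Pipeline conventions

Runs are configured by YAML; outputs are TSV tables, NIfTI maps and a JSON
report carrying the package version, seed, the applied defaults and a
config hash.  Wall-times go to a separate log so reruns with unchanged
inputs and seed produce byte-identical reports.  The median split for case
placement assigns the median patient (odd n) to the lower half
(configurable); ties at the median are reported, not resolved silently.

## Known limitations

* The morpheme rule set approximates hand coding; exotic vocabulary outside
  the exception/irregular lexicons counts one morpheme per suffix match.
* The permutation floor limits how small corrected p values can be;
  reaching stricter cluster α requires more permutations (cost is linear).
* The synthetic severity belt is a single global confound; real severity is
  multi-dimensional.
* Spatial normalisation, lesion delineation from real MRI, anatomical
  labelling and tract-overlap analyses are out of scope.
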