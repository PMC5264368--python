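# pcavbcm

Decomposition of aphasia assessment batteries by rotated principal component
analysis, and mapping of each component's unique neural correlate by
voxel-based correlational methodology (VBCM), for cohorts of chronic
post-stroke aphasia.

## The problem and the method

Scores on aphasia batteries are strongly inter-correlated: lesion size drives
overall severity, and no task is a pure measure of one ability.  Correlating
raw test scores with voxel status therefore smears every behavioural measure
over the same middle-cerebral-artery territory.  This package implements the
two-part remedy used in individual-differences lesion-mapping studies:

1. **Rotated PCA of the battery.**  The patients × measures percent-score
   matrix is standardised and the correlation matrix `R` eigendecomposed.
   Components with eigenvalue λ > 1 are retained (Kaiser criterion), varimax
   rotation (with Kaiser row-normalisation) yields interpretable simple
   structure `L`, and each patient receives regression (Thomson) factor
   scores `S = Z R⁻¹ L`.  Under PCA extraction these scores have exactly unit
   variance and zero cross-correlation — orthogonal behavioural regressors.
2. **Mass-univariate VBCM.**  At every voxel inside the analysis mask,
   smoothed continuous tissue intensity is regressed on all factor scores
   simultaneously plus nuisance covariates (intercept, mean-centred lesion
   volume), giving a t map per factor (`t_j = β_j / se(β_j)`, df = n − p).
   Voxels at one-tailed p < .005 form clusters (26-connectivity), whose
   family-wise error is controlled by a Freedman–Lane max-cluster-extent
   permutation null: corrected
   `p = (1 + #{permutation max extent ≥ observed}) / (1 + n_perm)`.

The package also computes the connected-speech fluency measures that feed the
battery — tokens (T), types, type–token ratio (TTR), morphemes, mean length
of utterance in morphemes (MLU) and words per minute (WPM) — from
picture-description transcripts in a CHAT-like dialect, with coded
repetitions/retraces/false starts excluded and a one-"and"-per-sentence
utterance segmentation rule.

A 31-patient cohort (demographics with lesion volumes, the 31 × 21 behaviour
matrix, and the published reference loadings and factor scores) is packaged
as TSV fixtures.  Because no imaging data can be shipped, a synthetic-cohort
generator produces lesion images with the structure the analysis assumes —
latent abilities, block-structured behaviour, disjoint target regions whose
intensity tracks each ability, and an outer "severity belt" eroded by a
global severity that also drives lesion volume — providing ground truth for
the imaging machinery (see `docs/methods.md`).

## Worked example

```python
>>> from pcavbcm import load_cohort, fit_pca
>>> records, scores = load_cohort()
>>> speech = fit_pca(scores[["wpm", "ttr", "mlu", "tokens"]])
>>> speech.n_components_, round(100 * speech.total_variance_fraction_, 2)
(2, 84.65)
>>> speech.loadings_frame().round(3)
           F1     F2
wpm     0.800  0.258
ttr     0.082  0.973
mlu     0.803  0.488
tokens  0.904 -0.157
```

Two components: F1 loads on the *quantity* of speech (tokens .904, MLU .803,
WPM .800) — "speech quanta" — while F2 is dominated by TTR (.973), the
lexical *variety* of speech.  Together they carry 84.65 % of the variance in
the four measures.  The omnibus decomposition of all 21 measures retains four
components (phonology, semantics, executive, speech quanta):

```python
>>> omnibus = fit_pca(scores)
>>> omnibus.n_components_
4
>>> (100 * omnibus.variance_fraction_).round(1)
array([54.8, 11.6,  8.3,  6.3])
```

Per-patient placement (median split on the executive factor, extremes on
speech quanta):

```sh
$ pcavbcm report --patient EB
{
  "patient_id": "EB",
  ...
  "group": "high_executive",
  "is_group_max_quanta": true
}
```

The imaging stage runs end-to-end on a synthetic cohort:

```sh
$ pcavbcm simulate --seed 1 --out cohort1
$ pcavbcm run --config examples/synthetic.yaml
```

writing per-factor t maps (NIfTI), FWE-corrected cluster tables (TSV) and a
deterministic JSON run report.

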