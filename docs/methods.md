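# Methods

This note documents the models, algorithms and numerical choices behind
`desilipid`, and what the synthetic cohort does and does not establish
about real tissue data.

## Unit of analysis

The pipeline classifies **patients**, not pixels. For each patient the
tissue-labeled pixels of one DESI-MSI image are pooled, their peaks
matched, and the matched features averaged over the labeled pixel count
(a peak absent from a pixel contributes zero). The per-patient averaged
spectra are then matched across patients into one peak matrix. Averaging
before normalization reflects the design in which each tissue section
contributes a single profile; pixel-level classification is out of scope.

## Peak matching

All peaks from all input spectra are pooled, restricted to the *m/z*
600–1000 window, and sorted. A single-linkage-style sweep closes a
feature when the gap between the next peak and the running
intensity-weighted consensus exceeds the maximum shift (default 8 ppm).
A refinement pass enforces that each spectrum contributes at most one
peak per feature: the nearest-ppm peak stays, ties break toward the
higher intensity (then the lower *m/z*), and each displaced peak opens a
feature of its own. Consensus *m/z* is the intensity-weighted mean of the
members. The procedure is deterministic and invariant to the order of
input spectra because it operates on the pooled sorted peak list.

## PQN normalization

Global per-sample intensity scale (spray efficiency, section thickness)
is removed by probabilistic quotient normalization. The reference is the
element-wise mean of the **total-normalized** sample spectra, rescaled to
the mean total; quotients are sample/reference over features with a
positive reference, and the per-sample factor is the median of the
quotients (the mean-quotient variant is a switch, `--pqn-quotient mean`).
Building the reference from total-normalized spectra makes the reference
shape immune to any one sample's global scale: rescaling a sample changes
no sample's normalized profile (outputs change only by one cohort-wide
scalar through the mean-total rescale). A single-sample matrix gets
factor exactly 1. Zeros are excluded from quotient computation because a
quotient at reference zero is undefined.

## RMMC-LDA

The maximum margin criterion seeks unit directions **w** maximizing
tr(**w**ᵀ(S_b − S_w)**w**) with S_b, S_w the between-/within-class scatter
matrices of the mean-centered (and by default unit-variance standardized)
data. Unlike Fisher LDA it requires no inversion of S_w, which matters
when features outnumber patients. Components are extracted recursively:
the leading eigenvector of the symmetrized S_b − S_w is taken, the data
are deflated onto its orthogonal complement, the scatters recomputed, and
the next component solved strictly within the complement subspace (this
avoids re-selecting a deflated direction whose eigenvalue, zero, can
exceed the remaining spectrum). Default k = 1 for two classes. Sign is
fixed by making the largest-magnitude loading positive.

**Prediction** assigns the nearest class mean in score space, ties toward
the first declared label. The class means are, by default, estimated from
*leave-one-out* scores within the training data (each sample scored by a
projection refit without its patient). On peak matrices with ~200
features and ~60 training patients, in-sample score means are
optimistically displaced away from the boundary — roughly in inverse
proportion to class size, so a 14-patient benign class is displaced ~4×
more than a 50-patient cancer class — which places the midpoint boundary
inside the held-out benign score distribution and collapses specificity.
The leave-one-out means estimate where unseen profiles of each class
actually score; `calibrate="none"` restores the classical in-sample rule.
Classes with fewer than three samples fall back to in-sample means.

**LOPO cross-validation** excludes all rows of the held-out patient from
fitting (including the inner calibration), predicts them with the refit
model, and makes the patient-level call by majority (ties toward the
positive class). A training fold that loses a class entirely is an error;
a one-sample class in a fold is fitted (its within-class scatter is zero).

## Univariate statistics

Feature discrimination uses one-way ANOVA on normalized intensities (for
two groups this equals the squared pooled-variance t statistic; log10 is
used only for display). Multiple testing is controlled by
Benjamini–Hochberg step-up q-values; features are selected at q < 0.05
and ranked by q. Fold change is the ratio of group means of normalized
intensities, direction assigned from its position relative to 1; a zero
denominator yields a flagged NaN rather than an error. Demographic 2×2
tables use the two-sided Fisher exact test under the point-probability
rule (which reproduces standard published values; doubling the one-tail
does not), and continuous variables use the Welch t test (pooled variant
switchable).

## Lipid annotation

Observed *m/z* values are matched against a reference of deprotonated
([M−H]⁻) glycerophospholipids. For each record and isotopologue count
k ≤ max_isotope, the matched mass is mono + k·1.0033548 Da (the ¹³C−¹²C
difference, fixed to 7 d.p.) and the error is
(observed − theoretical)/theoretical × 10⁶ ppm, reported to 4 d.p. Hits
within tolerance (default 10 ppm, covering the largest error the bundled
table itself requires, 9.88 ppm) are ranked by |ppm error|, ties toward
lower isotope count then name. The bundled table stores monoisotopic
masses; for species only observed as ¹³C isotopologues the monoisotopic
mass is the isotopologue mass minus one ¹³C shift. Theoretical masses are
stored, never computed from formulas, and MS/MS notes are opaque
pass-through metadata.

## Protein statistics

Each antibody is related to tissue status by a univariate logistic
regression (binomial link, IRLS, tolerance 1e-8, ≤100 iterations). The
odds ratio is exp(β) per unit of expression (per-SD is a switch) with
Wald 95% interval exp(β ± 1.96·se). Separation is detected (|β|·sd > 15,
or se ≫ |β|, or non-finite) and flagged with an infinite-OR marker rather
than reported as a finite estimate; flagged fits are excluded from the
FDR denominator and counted. Group summaries are arithmetic means and
n−1 SDs with direction Increased/Decreased in cancer.

## Integration

Lipid rows are divided by each patient's total lipid intensity; protein
columns by each antibody's maximum (each antibody lands on (0, 1]). Each
species is then the vector of its values across the shared patients, and
every pair gets cosine distance 1 − u·v/(‖u‖‖v‖) — the full matrix over
lipids and proteins together, feeding average-linkage (default; complete
and centroid available) agglomerative clustering with deterministic leaf
order and Newick export. A classical two-block canonical correlation
analysis is deliberately not implemented; the pairwise cosine matrix is
the computation the heatmap displays. Note that on positive-valued
normalized data all cosine similarities are high (vectors share the
mean component); the *ranking* of pairs carries the signal.

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions:

| parameter | default | meaning |
|---|---|---|
| n_cancer / n_benign | 50 / 14 | cohort sizes |
| image_shape | 20×20 px | circular tissue ROI (~156 px), background outside |
| planted_features | 7 peaks | *m/z* 688.49–915.59, folds 1.23–1.28, base 80–150 au, pixel CV 0.25 |
| phenotype_features | 4 peaks | benign-cohort high-risk folds 3.1–11.0, mean-preserving |
| n_background_peaks | 200 | uniform in 600–1000, ≥50 ppm apart |
| ppm_jitter_sd | 2 ppm | per pixel per peak, Gaussian truncated at 3σ |
| tic_scale_range | 0.5–2.0 | per-pixel uniform whole-spectrum factor |
| patient_cv | 0.10 | between-patient log-normal CV per feature |
| n_proteins / differential | 282 / 104 | effect 1.5 SD, higher in cancer |

Pixel intensities are log-normal, parameterized by arithmetic mean and
CV; each patient carries an independent log-normal effect per feature.
All randomness flows from one seeded generator in a fixed order, so a
config reproduces its cohort bit for bit.

Three generator choices deserve explanation:

- **patient_cv = 0.10.** The between-patient dispersion is not directly
  observable from a published table of summary statistics, but the
  published per-feature q-values (10⁻⁷–10⁻⁵ for folds of 1.23–1.28 at
  50 vs 14 patients) imply per-feature t statistics of roughly 5–7,
  i.e. a residual dispersion near 0.10–0.11 after normalization. The
  default is set once from that constraint.
- **Mean-preserving phenotype modulation.** Phenotype peaks multiply
  high-risk patients by the configured fold and rescale the whole cohort
  so its mean is unchanged. This plants the high/low-risk contrast at
  the published ratio without leaking a spurious signal into the
  cancer-vs-benign contrast — necessary because several phenotype peaks
  are shared with, or sit alongside, the main discriminatory set.
  The within-cancer modulation (ratios 1.84/1.63/1.69 on shared peaks)
  is a separate preset: it inflates within-cancer variance at those
  peaks by design, which is exactly what the subgroup analysis studies
  and what the main contrast's pooled ANOVA should not be confounded by
  by default.
- **Truncated jitter.** The per-pixel mass jitter is clipped at 3σ
  (6 ppm at the default) so that a feature's within-cohort spread stays
  inside the 8-ppm matching window; untruncated Gaussian tails over
  ~10⁴ pixel-peaks per cohort would occasionally split one true peak
  into two features and make the feature count nondeterministic in
  distribution.

**What passing tests show — and don't.** The generator produces
independent log-normal features with planted mean shifts; real DESI
spectra have correlated lipid co-regulation, chemical noise, spatial
autocorrelation within sections, isotope envelopes and batch structure,
none of which are modeled. Recovery of planted effects therefore
validates the pipeline's statistical machinery and its implementation,
not the clinical performance of the assay; the published diagnostic
figures come from real tissue and are emulated, not reproduced, here.

## Numerical conventions

- Pixel coordinates 0-based, x = column, y = row, origin top-left
  (shifted to the 1-based imzML convention on disk); *m/z* stored as
  float64, intensities as float32 in the binary container.
- Eigen-solver: symmetric `eigh` on the symmetrized scatter difference;
  orthogonality tolerance 1e-8.
- ANOVA with zero total variance returns p = 1 by convention; zero
  within-group variance with distinct means returns p = 0.
- Annotation, matching and clustering tie-breaks are all deterministic
  (documented above), so every stage is reproducible byte for byte
  under a fixed seed.

## Problem sizes

The test suite exercises desk-scale cohorts (6–14 patients, 8×8–10×10
images) for unit behavior and the full default cohort (64 patients,
20×20 images, 211 features) for the end-to-end recovery checks; the
acceptance script runs the full default cohort. Monte-Carlo checks of
generator calibration use 150 patients per class on small images.

## Known limitations

- Only two-class contrasts; no molecular-subtype multiclass mode.
- Processed-mode imzML is assumed centroided; no profile-mode binning,
  baseline correction or lock-mass recalibration.
- The LOO calibration of score-space class means costs one refit per
  training patient per fold (~4k small eigendecompositions for the
  default cohort, tens of seconds); it can be disabled where the
  feature-to-sample ratio is small.
- Logistic odds ratios are per unit of expression by default; with
  arbitrary-unit antibodies the per-SD switch is usually the
  interpretable choice.
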