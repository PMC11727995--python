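# Methods

This note documents the models and procedures implemented in
`woundscreen`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic validation does and
does not demonstrate.

## Fuzzy gray-scale morphology

Gray images are functions f : Z² → [0,1]; a structuring element B is a
fuzzy set on a small window with a designated origin. For a t-norm C and
its residual implication I,

    erosion   (f ⊖ B)(x) = inf_y I(B(y − x), f(y))
    dilation  (f ⊕ B)(x) = sup_y C(B(x − y), f(y))
    opening   f ∘ B = (f ⊖ B) ⊕ B
    top-hat   f − f ∘ B

The default logic is the **minimum t-norm with Gödel implication**
(I(a,b) = 1 if a ≤ b, else b). This choice makes the operators reduce
exactly to classical flat gray-scale morphology on crisp elements — which
gives an independent oracle (`scipy.ndimage` flat operators) and preserves
every lattice property we rely on: (⊖, ⊕) form an adjunction, so
dilate(erode(f)) ≤ f ≤ erode(dilate(f)) and the opening is idempotent.
The Łukasiewicz pair is available behind the same interface for graded
elements. Boundaries are padded with the neutral value of each operator
(1 for erosion, 0 for dilation) so the image border never generates
spurious top-hat residues — i.e. no phantom staples at the frame edge.

## Staple detection

Staples are modelled as the brightest thin, elongated, *achromatic*
structures. Detection runs on a "metallic sheen" channel V·(1−S) (bright
and desaturated), which suppresses erythema (saturated) and shadows
(dark). A white top-hat with a flat 7×7 element removes everything wide
enough to contain the element, leaving the ~3 px-wide staple bars; the
response is thresholded at 0.15 and connected components are kept when
their area lies in [20 px, 1% of the image] and their principal-axis
elongation is ≥ 2.5. These defaults describe a staple (bar of roughly
3×20 px at the 500-px photo scale) rather than any particular dataset.
Components are ordered row-major by centroid; everything downstream is
deterministic.

**Wound axis.** Staples straddle the incision, so the axis is the
total-least-squares line through the staple centroids: the principal
eigenvector of the centroid scatter, sign-normalised (first nonzero
component positive). With fewer than two staples the axis is undefined and
the pipeline falls back to a whole-image ROI, flagging "axis
undeterminable" rather than failing — real uploads can defeat detection.

**Region of interest.** Peri-wound erythema is what the symptom
"redness around the wound" refers to, so redness is scored over a band of
half-width 2 × (median staple length) around the axis, clipped to the
image. Scoring the whole photograph instead would dilute the signal with
background skin; whole-image mode is retained as the fallback and as a
configuration option.

## Staple inpainting

Before colour scoring, staple pixels are reconstructed by a diffusion
fill: masked pixels are repeatedly replaced by their 4-neighbour mean
(unmasked pixels fixed as boundary data) until the maximum change falls
below 1e−5 or 500 iterations — the discrete Laplace equation, whose
solution depends only on the surrounding intact skin. Diffusion was chosen
because it is deterministic, parameter-light and oracle-testable
(constant surroundings must reproduce the constant to within tolerance).
The alternative of simply excluding staple pixels from the ROI is exposed
as `scoring_order="mask"`; inpaint-first is the default because it keeps
the ROI denominator geometry-independent of the detector.

## Redness proportion and cutoff

"Close to red" is a trapezoidal membership on circular hue distance d
from 0°: 1 for d ≤ 10°, 0 for d ≥ 30°, linear between, and 0 whenever
saturation < 0.25 or value < 0.2. The gates separate erythema from
desaturated skin tones and dark shadows. The image score is the
**crisp** proportion of ROI pixels with membership ≥ 0.5 (a count, the
default) or the **weighted** mean membership (continuous; used for
sensitivity analyses such as the monotonicity-in-erythema check, where a
count is flat below the membership knee).

The default positivity cutoff is **0.63**, the ROC-selected operating
point of the original clinical calibration. It is treated as a
configuration constant, not a universal one: it was fitted to one cohort's
photographs, and `woundscreen calibrate` re-derives a cutoff for any
scored cohort. Ties at the cutoff are positive — the screen is
sensitivity-first, so borderline wounds go to review.

## Questionnaire and triage

The questionnaire is a pain VAS (integers 0–10) plus six binary items
(redness, burning, opening, swelling, secretion, fever). Fever is
temperature-defined: 1 iff strictly above 37.7 °C; a binary answer is
accepted, but when a raw temperature is also supplied and disagrees, the
temperature wins and a warning is logged. Validation is a hard gate —
any missing answer rejects the record; nothing is imputed.

Fusion is disjunctive: review is needed if the image call is positive,
**or** any hard flag (opening, secretion, fever) is present, **or** the
symptom count ≥ 3, **or** VAS ≥ 7. An OR rule is the natural reading of a
screen designed for high sensitivity: each channel can independently
escalate, and adding symptoms can never rescind a referral (monotonicity,
enforced by test). The symptom-count and VAS cutoffs are package
calibration constants with no clinical validation behind them; they are
surfaced in `TriagePolicy` for exactly that reason, together with
image-only and questionnaire-only modes.

## Evaluation statistics

- Sensitivity tp/(tp+fn) and specificity tn/(tn+fp) with **exact
  Clopper–Pearson 95% CIs** — chosen over Wald/Wilson for validity at the
  small positive counts typical of SSI cohorts (five infections).
- **Cohen's κ** = (p₀ − p̂ₑ)/(1 − p̂ₑ) with chance agreement from marginal
  products; undefined (raised) when both raters are constant.
- **ROC**: the decision rule is score ≥ t; the sweep runs over the unique
  scores plus a predict-none sentinel; AUC by trapezoid (equal to the
  normalised Mann–Whitney U, verified in tests). The optimal cutoff
  maximises Youden's J = tpr − fpr, ties broken toward the lower threshold
  (higher sensitivity), and is reported as the midpoint between the lowest
  included and the highest excluded score — so a perfectly separated
  cohort yields the midpoint between the two clusters.
- Unit of analysis is the **image**; patient-level aggregation (positive
  if any image positive) is a documented manifest-level operation, since
  published per-cohort counts (5 + 14 + 69 = 88) are image-level.

## Synthetic scene generator

Each scene is a pure function of its parameter record (seed included):
skin base colour (default (0.75, 0.62, 0.50), hue ≈ 29°) with Gaussian
texture (σ = 0.02); a dark incision line (length 300 px, width 3 px at the
512×512 default); staples as bright (0.92) achromatic bars of 22×3 px
perpendicular to the incision at 40 px spacing with ±1.5 px jitter;
peri-incisional erythema as a blend toward an inflamed red
(0.82, 0.26, 0.26) with amplitude e^γ·exp(−v²/2σ_e²) (intensity e ∈ [0,1],
γ = 2, cross-axis scale σ_e = 30 px, soft falloff past the incision ends).

The **square-law amplitude** (γ = 2) encodes that mild erythema is
visually faint: with the membership defaults above, the blend fraction at
which peri-wound hue crosses the crisp membership knee is ≈ 0.16, so
intensities below ≈ 0.4 stay sub-threshold everywhere while intensities
above ≈ 0.65 redden most of the band. This places the generative
infection label (e > 0.5) on the natural boundary between the two colour
regimes instead of making the label invisible (γ = 1 would redden even
e ≈ 0.1 wounds at the axis).

Confounders mirror what defeats redness reading in practice: antiseptic
stains are orange-brown blobs *clustered on the incision* (antiseptic is
painted along the wound), which inflate the redness score of uninfected
wounds; a dressing edge is a bright achromatic strip at a border (large
and non-elongated, so the staple filters reject it).

Cohorts assign each patient an infection state (Bernoulli, default
prevalence 0.122 — a typical abdominal-surgery SSI rate), an erythema
intensity uniform on [0.65, 0.95] (infected) or [0.05, 0.35] (not), two
visits (days 3 and 10) with small intensity jitter clipped to the regime,
and questionnaires from per-item Bernoulli models (e.g. infected: redness
0.85, secretion 0.55, fever 0.50, VAS 3+Bin(7, 0.5); clean: items
0.03–0.08, VAS Bin(4, 0.3)). All parameters sit in `EffectParams` in one
block.

**What the generator does not emulate:** photorealistic skin (pores,
hair, specular highlights), skin-tone diversity beyond the configurable
base colour, 3-D lighting and perspective, motion blur, sutures instead of
staples, or multi-wound images. Passing the recovery and recalibration
suites therefore shows the pipeline is *internally* correct and
well-calibrated under the stated generative model — not that the 0.63
cutoff or the detector thresholds transfer to any particular camera or
population; the scripts exist precisely so users can recalibrate.

## Numerical and scale choices

- All operators preserve [0,1] exactly (clipped after floating-point
  subtraction in the top-hat).
- Erosion skips zero-membership offsets (I(0,·) = 1 cannot lower an
  infimum), dilation skips them too (C(0,·) = 0 cannot raise a supremum);
  this is an optimisation with no numerical effect.
- Component labelling uses 8-connectivity; ties everywhere are broken by
  row-major order for determinism.
- Inpainting diffuses only within a margin-padded bounding box of each
  mask component, which leaves results unchanged (the fill depends only on
  local boundary data) and keeps large images fast.
- Property tests run on 256×256 scenes with the default geometry scaled
  by ~0.5 (incision 140 px, staples 14 px, σ_e = 18 px); full-scale
  (512×512) runs are reserved for the recovery and recalibration suites
  (50 and 200 images). These sizes were chosen as the smallest at which
  the band/staple geometry is unambiguous.
- Intake images below 500×500 px (the minimum phone-camera resolution the
  screening protocol assumes) are analysed with a warning rather than
  rejected: the limit is an acquisition-protocol rule, not an algorithmic
  requirement.

## Known limitations

- No illumination or white-balance normalisation: redness proportions are
  not comparable across cameras without recalibration.
- Heavily stained wounds are indistinguishable from erythema by design of
  the colour model — the stain confounder exists to quantify exactly this
  specificity loss.
- The inter-rater agreement statistic is pairwise Cohen's κ only; no
  weighted or multi-rater generalisations.
- Suture (thread) closures produce no staple signal; the pipeline then
  degrades to whole-image scoring with a flag.
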