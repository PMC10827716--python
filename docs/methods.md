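# Methods

This note documents the models, conventions and numerical choices behind
`strokequant`, what the synthetic-data generator does and does not emulate,
and the limitations a user should keep in mind.

## Coordinate and image conventions

All section positions are in mm from bregma along the anterior–posterior
(AP) axis, positive rostral; this matches the stereotaxic convention of the
coordinates the defaults encode (illumination field centered AP +1.5 / ML
3.5, electrode center AP −0.5 / ML 3.5). Images are single-channel
grayscale, 8-bit on disk, with isotropic pixel pitch (default 10 µm/px) and
a vertical midline at a known pixel column. The default section frame is
600×1200 px (6×12 mm), the smallest round size that contains the default
lesion (radius 2.5 mm centered 3.5 mm lateral) without clipping; all of
this is per-section metadata, not an assumption of the analysis. A lesion
disc that would extend past the frame is clipped with a warning and the
clipping recorded in the ground truth.

The lesioned-hemisphere side is metadata (`left`/`right`); the default is
left, following the stereotaxic coordinates the generator encodes.

## Lesion model and volumetry

The synthetic lesion is a sphere of the illumination radius: a section at
AP offset d from the lesion center shows a disc of radius √(r²−d²), and the
ground-truth volume is the analytic 4/3·π·r³. This is the simplest shape
with a circular per-section profile and a closed-form volume, which makes
recovery testable to arbitrary precision. A real photothrombotic infarct is
a cortical cap rather than a full sphere, has ragged borders and partial
depth; the generator makes no attempt at that realism, so volumetry tests
validate the *measurement chain* (segmentation → area → frustum
integration), not biological shape assumptions.

Segmentation defaults to Otsu's threshold on the degeneration channel with
removal of components smaller than 0.01 mm². Because Otsu always splits a
histogram — including pure background — the split is accepted only when the
foreground-class mean lies 8 robust SDs (median absolute deviation × 1.4826)
above the image median; lesion-free sections therefore yield empty masks.
A provided-mask path bypasses segmentation entirely and preserves a manual
delineation workflow.

Volumes integrate the per-section areas with the conical-frustum rule,
V = Σ h/3·(A₁+A₂+√(A₁A₂)). Terminal sections with nonzero area are closed
with a cone whose height defaults to the local section spacing; this
end-cap convention is explicit and configurable because different frustum
implementations differ exactly here. On a 2-mm sphere sampled every 0.1 mm
the rule is accurate to ~0.24 %; the tests accept 2 % against the analytic
volume and 0.5 % against a fine-grid numerical integration. Sections are analyzed every 0.3 mm by default — the cutting
thickness of the emulated protocol is 30 µm, but which sections enter
volumetry is a user choice, so the spacing is a parameter and is always
reported in the output table.

The caudal lesion border is the smallest AP position whose area exceeds a
configurable minimum (default 0), with an explicit "no lesion" sentinel.

## Tile-based reactivity scoring

The 200-µm tile grid is anchored at the midline and at the top image row
and grown outward in whole tiles; incomplete border tiles are dropped and
the lateral extent is limited by the narrower hemisphere, so mirror pairing
is an exact involution by construction. The high-reactivity threshold is
the contralesional tile-mean + 1.5 × sample SD (n−1), computed per section
from that section's non-excluded contralesional tiles; computing it per
section (rather than pooled over sections) makes the score robust to
section-to-section staining intensity variation. On Gaussian data the
contralesional side itself exceeds its own threshold with probability
P(Z > 1.5) ≈ 0.0668, so an injected activated-tile fraction f yields an
expected ipsi−contra ratio difference of f·(1−0.0668); both are verified by
the calibration tests (50 null sections, 30 recovery seeds).

Exclusion (stroke core, artifacts) is a pixel mask; a tile with ≥ 20 % of
its pixels excluded is dropped from its hemisphere's tally. Mirror partners
of excluded tiles are *not* auto-excluded, because the ratios are computed
per hemisphere rather than per pair — this maximizes analyzed area. Tiles
are attributed to closed AP windows D (−2.0..−1.7), E (−0.1..+0.2) and
F (+3.8..+4.5); the per-animal summary is the mean ratio difference per
region (one value per animal-region) plus the mean over regions.

## Behavioral scoring

The mNSS items and ranges are: placing 0–1, proprioception 0–1, beam
balance 0–6, walking 0–3, tail-raise forelimb/hindlimb flexion and head
turn 1 each, absent corneal/pinna/startle reflexes 1 each, seizure-like
behavior 1 — ceiling 18. The beam-balance entry is the mean of three
integer repetitions and is carried at full precision (multiples of 1/3)
into the total; the total is rounded half-up only for reporting. Relative
change from post-stroke to post-stimulation is (s₁−s₂)/s₁ and is reported
missing (not zero) when the post-stroke score is 0.

Pasta sessions present at most five pieces and stop after the fourth valid
trial; invalid trials ("no performance", "pasta break") carry their reason,
and an animal without a valid trial is excluded from that timepoint rather
than averaged as zero. Grasp laterality is defined relative to the stroke
hemisphere (contralateral = affected limb). Atypical behaviors are nine
binary categories (six core behaviors plus the three failure-to-contact
subcategories), so a trial scores 0–9. The atypical-count change score is
computed baseline → day 2.

## Stratified assignment

Animals are assigned on arrival to the arm minimizing, lexicographically:
(1) the post-assignment range of arm sizes, (2) the range of arm mean
scores over non-empty arms, with a seeded uniform tie-break. Size leads the
key deliberately: a mean-spread-first greedy is degenerate early on (while
only one arm holds animals its spread is zero, so every arrival would stack
into the same arm). With sizes held within one, each round over the arms
places the arrival where arm means stay closest — the behavior a
"stratified step-by-step randomization" is meant to have. The cohort
generator uses the same objective under fixed per-arm capacities.

## Group statistics

Independent-group outcomes are gated per group by Shapiro–Wilk at α = 0.05
with an "all groups must pass" rule (the aggregation rule and α are
package choices; the gate itself is standard). Parametric data go to
one-way ANOVA with Tukey's HSD; non-normal data to Wilcoxon rank-sum (two
groups) or Kruskal–Wallis with Dunn's post-hoc (rank-sum z with mid-rank
tie correction, Bonferroni-adjusted over all pairs — implemented in-package
since no installed library provides it). Groups with n < 3 cannot be
gate-tested and fall to the nonparametric branch with a warning; all-equal
data take a documented degenerate path (p = 1, no evidence of difference).

Repeated-measures outcomes are gated by a single Shapiro–Wilk on the
cell-mean residuals rather than per-cell tests: with ~8 cells of n ≈ 5, per
-cell gating trips on roughly a third of perfectly normal datasets and
needlessly diverts parametric analyses to rank fallbacks. Parametric
repeated measures use a two-way mixed ANOVA (between = arm, within =
timepoint, Type II sums of squares via pingouin; stated in every report
header because the convention matters with unequal group sizes), with
Tukey post-hoc on per-subject means. The nonparametric branch uses the
Friedman test over timepoints (Wilcoxon signed-rank when there are only
two), which addresses the time effect; the group question then goes to a
rank test on per-subject means, and the report says so. Subjects missing a
timepoint are removed listwise and logged.

The full gate-then-test procedure holds its type-I error: on normal null
data (4 groups × n = 7) the measured rejection rate over 2000 replicates is
≈ 0.053 at nominal α = 0.05.

## What the generator emulates, and what it does not

Defaults are the study conditions of the modelled experiment: four arms at
0.0/0.8/31.8/47.8 A/m² with 6/5/8/7 animals, a 2.5-mm lesion radius with
0.1-mm between-animal SD (the radius scatter implied by the printed volume
dispersion, SD_vol ≈ 9 mm³ → SD_r = SD_vol/(4πr²) ≈ 0.1 mm), behavioral
group means/SDs equal to the printed group trajectories (SD = SEM·√n), and
per-arm activated-tile fractions chosen so f·(1−0.0668) reproduces the
printed per-arm reactivity differences (0.150/0.118/0.086/0.364 — only the
highest intensity adds to the stroke's own activation). Image structure is
deliberately minimal: Gaussian noise, hard-edged discs, no point-spread
function, no vignetting, no staining-chemistry or anesthesia effects.

Two consequences deserve emphasis. First, passing recovery tests shows the
measurement chain is correct under these idealized conditions; it does not
certify performance on real micrographs with uneven illumination or
antibody variability. Second, because the behavioral defaults are the
printed per-arm means, *small real differences exist in every behavioral
outcome* (e.g. day-2 time per pasta 52.0 vs 67.9 s across arms). At n ≈ 5–8
these flag only sporadically, while the two injected dose effects
(reactivity, strongly; atypical counts, at the borderline strength of the
printed group effect) flag systematically — which is exactly how the
end-to-end pattern test is phrased (a seven-seed panel: reactivity always,
atypicals in the majority, structural/neurological outcomes never, other
pasta outcomes at most a minority). In the cohort flow the post-stroke
severity is drawn from the pooled distribution *before* arm assignment (as
stratified randomization requires), so per-arm post-stroke means equal the
pooled mean by construction and relative mNSS change per arm follows
1 − μ_post-stim/μ_pooled rather than the printed per-animal ratios.

Determinism: one master seed drives everything through independent
spawn-keyed streams (severity draws, assignment tie-breaks, one stream per
animal index), so a cohort is bit-reproducible and growing it never
changes the draws of existing animal indices; arm labels can shift only
near capacity exhaustion, where the sequential balancer legitimately sees
different remaining capacities.

## Problem sizes used in tests

The default pipeline (26 animals, 29 sections × 2 channels at 600×1200 px)
runs in about 90 s on one core. Calibration tests use 400×800-px sections
(50 null seeds, 30 recovery seeds); the end-to-end panel runs the default
cohort at 20 µm/px (300×600 px), which leaves every group comparison
unchanged while keeping a seven-seed panel near two minutes; the type-I
simulation uses 2000 replicates. These sizes are choices documented here so
they can be scaled up when more precision is wanted.

## Known limitations

- The frustum rule is exact for conical interpolation between measured
  sections; for non-convex or patchy lesions it inherits whatever error
  the per-section areas carry.
- Otsu segmentation assumes a bright lesion on a darker background with a
  clear bimodal histogram; faint or low-contrast staining should use the
  provided-mask path.
- The mirrored grid assumes the midline column is correct; it performs no
  registration, atlas alignment or tilt correction.
- Friedman addresses only the within factor; the group flag on
  nonparametric repeated measures comes from subject means and is less
  powerful than the mixed ANOVA it replaces.
- Dunn's adjustment is Bonferroni over all pairs, which is conservative
  relative to stepwise procedures.
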