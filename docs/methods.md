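# Methods

## Model and assumptions

The segmentation model assumes that, within one short-axis slice, myocardial
T2-weighted intensities are a two-component Gaussian mixture: normal
myocardium N(μ_n, σ_n²) and edematous myocardium at risk N(μ_MaR, σ_MaR²)
with μ_MaR > μ_n. Because signal intensity drifts between slices
(coil sensitivity, slice-dependent gain), every slice is fitted
independently; fits are never pooled across slices.

Anatomy enters through two priors per culprit artery on a 9-ring × 24-sector
extended AHA bulls-eye: a *normal* extent (the typical territory) and a
*maximal* extent (everything the artery could possibly supply). MaR is
assumed transmural and confined to a single connected region inside the
maximal extent — the physiology of a single occluded vessel.

### Sector coordinates

Sectors are numbered counterclockwise (in standard short-axis display) from
the inferior RV insertion angle, each spanning 2π/24; the per-slice origin is
the centre of mass of the myocardial mask. A stack of n slices maps slice i
to ring ⌊9·i/n⌋, so 9-slice stacks hit rings 0–8 identically and other stack
lengths are assigned proportionally; the ring index is non-decreasing from
base to apex.

### Extent models

The shipped territory models (`src/segmentmar/data/extent_models.json`) are
a parametric consensus-style encoding — per ring, one contiguous circular
arc `[start_sector, arc_length]` — of typical LAD/LCx/RCA territories, with
the LM model the element-wise union of the three. They are deliberately
replaceable by user JSON files (either arc-parametric or explicit 9×24
matrices) because published territory drawings differ between centres;
validation enforces normal ⊆ maximal and per-ring arc contiguity for single
arteries. The default LAD maximal arcs span 13–16 sectors in basal/mid rings
and the full apical ring, wide enough that wedges up to half the
circumference remain inside the territory.

## Estimation

**Initialisation.** The MaR component starts from the sample mean/SD of
intensities inside the *normal* extent, the normal component from those
outside the *maximal* extent; the mixture weight starts at the myocardial
fraction of the normal-extent region. If either region has fewer than two
pixels (e.g. an apical ring fully inside the territory), initialisation
falls back to the upper/lower intensity quartiles with a logged warning.

**EM.** Standard two-component Gaussian-mixture EM (responsibilities use the
mixture weights, as any correct EM must), run until the relative
log-likelihood change is below 10⁻⁶ or 200 iterations — values chosen to
make fits reproducible to ≥ 6 digits across platforms. Component labels are
fixed by the initialisation; if a fit ends with μ_MaR < μ_n the components
are relabelled so MaR is the brighter one (logged). A sigma floor of 10⁻³ ×
slice intensity range prevents singular components; a clamped fit is flagged
non-converged. Slices with fewer than 10 myocardial pixels are left
unmodeled and excluded.

**Probability.** The MaR probability is the *weight-free* density ratio
p(x) = G_MaR(x) / (G_MaR(x) + G_n(x)), computed from log-densities
(`expit(log G_MaR − log G_n)`) so it is exact in [0, 1] arbitrarily far into
the tails. Mixture weights are estimated inside EM but deliberately excluded
from this ratio: the reported probability compares intensity evidence only,
and the same intensity then maps to the same probability regardless of how
large the MaR region is.

## Region logic

Sector probabilities are plain arithmetic means of pixel probabilities.
Candidate regions are connected components of supra-0.5 sectors under the
4-neighbourhood on the (slice, sector) cylinder with wrap-around at
23 ↔ 0 — the only coherent adjacency on a circular anatomy. On slices
flagged as containing the outflow tract, only sectors on the anterior side
of the supplied angular interval are admissible for LAD/LM, only the
complement for RCA/LCx. The region score is Σ_inside p + Σ_outside (1 − p)
over myocardial pixels of modelled slices; ties in the argmax are broken by
larger member count, then lowest (slice, sector) member, making selection
deterministic.

### Boundary interpolation

The selected region is represented per slice by the two angular edges of its
minimal covering arc, unwrapped across slices so trajectories are continuous.
Each edge trajectory is smoothed by normalized averaging — a Gaussian kernel
(SD 1.5 slices, truncated at ±3 slices; the width is fixed by the method,
the Gaussian shape is our choice) weighted by a per-edge certainty that is
the *product* of three terms:

- **c_a** — linear from 1 at the normal-extent arc edge to 0 at the
  maximal-extent arc edge (edges pressed against the territory limit are
  distrusted);
- **c_b** — Gaussian (SD 2 sectors) of the deviation of the observed
  inter-slice edge step from the expected territory drift: arc width growing
  2 sectors/slice towards the apex for LAD/LM, shrinking 1 sector/slice for
  RCA/LCx. The width drift is split evenly across the two edges (∓m/2 per
  edge), an interpretation the method statement leaves open;
- **c_c** — the sector probability just inside the edge.

The product rule and per-edge attachment are design choices where the method
lists the three reductions without a combination rule. The smoothing is
computed on deviations from the centre sample, so constant trajectories pass
through bit-exactly. Smoothed edges are clipped to the maximal-extent arc,
rounded to the nearest sector boundary, re-intersected with the admissible
cells, and the largest connected component is kept, so the final region
always satisfies the regional criteria (asserted post-hoc on every run).
Single-slice regions are returned unchanged. Rasterization labels every
pixel of each member sector — transmural by construction, which is also what
keeps hypo-intense MVO cores inside the segmentation.

## Comparators

2SD and FWHM use the remote region = myocardium outside the maximal extent,
per slice; Otsu needs none. Thresholds are inclusive (≥, unstated in the
method descriptions). Otsu runs on a 256-bin histogram over the slice's
myocardial range; the split minimises within-class variance with the lower
class [0, k) and threshold at bin edge k. It is implemented in-package so
the bin/edge convention is pinned for exact oracle comparison;
`skimage.filters.threshold_otsu` serves as an independent cross-check in the
test suite.

## Phantom

The phantom generates what the model assumes: a rotationally uniform annulus
(endo 22 mm, epi 32 mm, 128² pixels at 1.5 mm, 9 slices of 8 mm + 2 mm gap),
a transmural wedge at N(120, 10²) against normal myocardium at N(60, 8²) —
a cleanly separable ~6 SD contrast — per-slice multiplicative gain uniform
in [0.85, 1.15], optional focal disc artifacts at mid-wall, and an optional
MVO core (default N(25, 5²), central 40% of the wedge arc, middle 50% of the
wall). Noise is Gaussian, matching the model assumption rather than Rician
MR physics. The default wedge (6 of 24 sectors, LAD) is aligned to sector
boundaries, so its ground truth is exactly reproducible by transmural sector
labelling and covers 25% of LVM analytically. Cohorts draw wedge fractions
uniform on [15, 50]% of LVM (centred at sector 16 so all widths fit the LAD
maximal territory).

What the phantom does **not** emulate: partial-volume border zones, spatial
noise correlation, papillary/trabecular structure, through-plane motion,
surface-coil shading within a slice, or realistic territory shapes. Passing
phantom tests therefore demonstrates correctness of the algorithmic
machinery under its own assumptions, not clinical accuracy.

## Numerical and interface choices

- Angles: display-counterclockwise radians, `atan2(−Δrow, Δcol)`; recorded
  in the JSON sidecar.
- Degenerate slices (≤ 1 myocardial pixel) are flagged empty and skipped
  with a warning; an all-empty stack is an error. An empty final MaR region
  is a reported result, not an error.
- Dice of two empty masks is defined as 1 (agreement that there is no MaR)
  and logged; bias is always method − reference.
- LV mass uses slice spacing = thickness + gap (contiguous-coverage
  convention); the geometry cancels in the MaR% ratio.
- The pipeline is deterministic: identical inputs give bit-identical
  segmentations; randomness exists only in the phantom generator, controlled
  by explicit seeds.
- Problem sizes in the test-suite experiments (20-seed end-to-end runs,
  10-seed ablations, 3-seed × 5-level noise sweeps, 47-subject cohorts at
  128² × 9 slices) were chosen as the smallest sizes at which the sampling
  variability of each check is comfortably below its decision margin.

## Known limitations

- A sufficiently bright artifact *inside* the EM initialisation regions can
  corrupt a slice's fit and split the candidate region, after which only the
  best fragment is kept (underestimation). This failure mode is inherent to
  single-region selection.
- The boundary representation assumes each slice's region is a single arc;
  genuinely non-convex per-slice regions are replaced by their minimal
  covering arc during interpolation.
- Territory models are stylised defaults, not patient-specific anatomy, and
  should be replaced when centre-specific consensus models exist.
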