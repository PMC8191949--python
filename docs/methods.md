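# Methods

This note documents the models behind `phagenuc`, the parameters that
matter, the numerical conventions that make results exactly reproducible,
and what the synthetic validation does and does not demonstrate.

## The measurement model

A fluorescent reporter in a phage-infected rod-shaped bacterium is
characterised by where its signal sits relative to the phage nucleus, the
DNA-filled compartment positioned at midcell. The pipeline reduces each
infected cell to a one-dimensional readout in three steps.

**Axial profile.** The GFP channel is sampled by bilinear interpolation
at `n_points` (default 101) evenly spaced positions along the cell's long
axis, optionally averaging `line_width` parallel reads spaced 1 px apart
perpendicular to the axis. Fixed resampling makes the position coordinate
a fraction of cell length, so cells of different lengths are directly
comparable and positionwise averaging over a population is well defined.

**End anchoring.** The raw profile is divided by its *anchor*, the mean
over the first `anchor_frac` (default 5%) of positions — the initial
measured end of the cell. Division (not subtraction) is used: on the
resulting ratio scale 1.0 means "same as the cytoplasm at the cell end",
a mixed population averages to a flat baseline at 1, and the readout is
invariant to any multiplicative gain of the imaging system. A window
rather than the single first sample makes the anchor robust to shot
noise. The mean of the normalized profile over the anchor window is 1 by
construction (an exact identity, tested as such).

**Classification.** The score of a cell is the mean of the normalized
profile over a central window (`center_frac`, default 20% of the length)
divided by the pooled mean over both end windows (`end_frac`, default 10%
each). Pooling both ends makes the score exactly invariant to profile
reversal, so the arbitrary choice of "initial" end cannot change a call.
Calls: *imported* if score ≥ `t_hi` (default 1.2), *excluded* if
score ≤ `t_lo` (default 0.8), else *mixed-ambiguous*. The thresholds are
deliberately undemanding: the phenotypes of interest produce scores far
outside the [0.8, 1.2] band (≈0.3 and ≈2.7 for the default synthetic
contrasts), so the fractions reported for such populations are
insensitive to the exact threshold values.

**Pole margin.** Under PSF blur the spherocylinder's pole caps dim the
axial profile near its extreme ends for purely geometric reasons — the
cell simply ends there — which would contaminate an end-measured anchor.
By default the pipeline therefore insets the sampled span by half the
cell width (the cap radius) from each pole, so the end windows measure
cytoplasm on the cylindrical body. `extract_profile` itself defaults to
`pole_margin_px = 0` (strict pole-to-pole sampling); the inset is a
pipeline-level default (`pole_margin: "auto"`) and can be set to any
pixel value or disabled. With the inset, a uniformly fluorescent cell
scores ≈1.0 even under blur; without it, the geometric end-dip alone
inflates the score of every cell by ~25–30% at the default optics.

## Nucleus DAPI quantification

Within each infected cell's mask (the cell is cropped first), the DAPI
pixels are Otsu-thresholded and the largest above-threshold 8-connected
component is the nucleus mask. Reported are the mean **raw** DAPI
intensity inside the mask and over the in-cell complement (background);
no offset or background subtraction is applied to the headline number, so
adding a constant to the image moves both quantities by exactly that
constant (tested as an identity). A background-subtracted column is
emitted alongside in all tables. Group comparison bins both groups'
per-cell means on a shared equal-width grid (default 20 bins) over the
pooled range and reports the percent difference of group means relative
to the reference group. No significance test is attached.

## Otsu's method — fixed conventions

The threshold search must be bit-reproducible, so the conventions are
part of the contract: pixel values are binned into `n_bins` (default 256)
equal-width bins over [min, max]; for every split *t* (class 0 = bins
0..*t*) the between-class variance ω₀ω₁(µ₀−µ₁)² is evaluated; the
returned threshold is the **upper edge** of the argmax bin; among tied
maxima (which occur whenever the histogram has an empty gap between
modes) the floor of the mean argmax index is taken, i.e. the middle of
the plateau. The implementation is cumulative-sum based and is tested
against an O(n²) from-scratch recomputation on 1000+ random histograms,
and against scikit-image's `threshold_otsu` on histograms whose maximum
is unique (the libraries differ only in plateau tie-breaks).

## Cell detection and infection flagging

Segmentation thresholds a smoothed (σ = 1 px) composite of the interior
channels (GFP + DAPI). Two refinements proved necessary for accurate
footprints: the composite is log-compressed before Otsu, because an
infected cell's bright nucleus makes the histogram trimodal and the raw
split can land between cytoplasm and nucleus instead of between
background and cell; and the final binarisation level is the midpoint of
the two class *medians* in linear intensity, which pins the mask contour
to the half-intensity edge of the blurred cell boundary regardless of
histogram weights (medians keep bright nuclei from dragging the
foreground level up). The membrane channel is not summed into the
composite: its blurred ridge straddles the true boundary and biases an
intensity threshold outward by most of a pixel. A membrane-only image can
still be segmented directly. Components are hole-filled, 8-connected,
area-filtered (defaults 200–6000 px²), border-touching components are
discarded with a log entry, and ids are assigned in raster order of the
centroid. Pre-drawn masks (a label-image TIFF, e.g. exported from ImageJ
ROIs) can be supplied instead of automatic segmentation.

The long axis is the principal eigenvector of the mask's second central
moments; endpoints are found by marching from the centroid along that
direction to the mask boundary (0.25 px steps, nearest-pixel
membership). Masks with eigenvalue ratio < 1.05 are rejected as
axis-ambiguous and skipped with a logged reason. The "initial measured
end" is not biologically meaningful, so it is fixed deterministically as
the lexicographically smaller (row, col) endpoint; an optional
orientation pass can instead flip profiles so the brighter half comes
first.

A cell is flagged infected when the largest bright DAPI component inside
it looks like a phage nucleus: mean intensity ≥ 2× the rest of the cell,
area ≤ 60% of the cell (in an uninfected cell the "bright" Otsu class
degenerates to the whole interior), circularity 4πA/P² ≥ 0.7, and
centroid projecting into the central third of the cell axis. All four
cutoffs are configuration parameters; they are heuristics standing in for
a by-eye judgement and are validated only against the synthetic ground
truth (sensitivity and specificity ≥ 0.95 at default SNR).

## The synthetic scene generator

Each cell is a 2-D spherocylinder (rectangle of length − width plus two
semicircular caps) of emitter density; an infected cell carries a disk
nucleus of radius `nucleus_radius_frac` (default 0.8) × half-width at
`nucleus_axial_pos` (default 0.5, midcell). Channels: GFP (cytoplasm
level with in-nucleus density = `gfp_contrast` × cytoplasm), DAPI (dim
cytoplasmic DNA, bright nucleus), membrane (one-pixel outline). The
imported phenotype renders GFP in both compartments with contrast > 1
rather than nucleus-only, matching the diffuse-plus-focus appearance of
imported reporters. Optics: isotropic Gaussian PSF, then expected counts
= density × `photon_scale`, Poisson shot noise, camera offset, Gaussian
read noise, clipping at 0 and rounding to 16-bit. With `noise=False` the
expected counts (offset included) are returned unrounded — the
infinite-photon limit used by the exactness tests.

Defaults (all configurable): pixel size 65 nm and PSF σ 130 nm (typical
100× widefield sampling); photon_scale 200, GFP cytoplasm density 5
(≈1000-count cytoplasm), camera offset 100, read noise 10 — a
mid-exposure sCMOS regime; default contrasts 3 (imported), 0.2
(excluded), 1 (uniform), strong phenotypes like those of fully penetrant
reporter variants; DAPI nucleus density 48 and background 5, chosen so
the Otsu-masked in-nucleus mean of a default infected cell sits near the
7,500-count scale reported for real infected cells (no exposure or gain
being available to emulate, only this scale is meaningful). Populations
place cells by rejection sampling (≤ 100 repositions per cell, then an
error) against an occupancy map dilated by `margin_px` (default 6), with
uniform random orientations, relative Gaussian jitter (default 10%) on
length and width, and phenotype counts allocated by largest remainder so
the realized mix matches the requested fractions as closely as integers
allow. Identical scene specifications (including the seed) render
bit-identical images.

What the generator does *not* emulate: 3-D structure and z-stacks,
deconvolution, photobleaching and time-lapse correlation, cell-to-cell
background variation, touching or dividing cells, irregular nucleus
shapes, and out-of-focus light. Passing the synthetic acceptance
experiments therefore demonstrates that the measurement chain is correct
and unbiased under the stated imaging model — not that the
classification thresholds or infection heuristics are optimal for any
particular real microscope.

## Acceptance experiments and problem sizes

Four presets reproduce the study's quantitative claims on
phenotype-matched populations at the published sample sizes: 177
excluded-phenotype cells → 100% classified excluded; 111
imported-phenotype cells → 100% classified imported; a 116-cell 50/50
mixture at matched |log contrast| whose ensemble mean central value lies
within 5% of 1.0; and two 150-cell groups generated at in-nucleus DAPI
ratio 0.8 recovered as a ≈20% intensity difference. The fraction-recovery
property runs 100-cell populations at import fractions {0, 0.25, 0.5,
0.75, 1} over 20 replicate seeds each; these sizes keep the whole suite
within a few minutes on one core while leaving the binomial acceptance
regions meaningful.

For the mixed-baseline preset the contrast pair is (1.25, 1/1.25). On a
ratio scale the population mean of a log-symmetric pair (c, 1/c) is
(c + 1/c)/2 ≥ 1, which stays within 5% of baseline only for mild
contrast (c ≲ 1.37); the preset therefore represents the mixed mutant as
a mixture of *partial* phenotypes, which is also what its broad
per-cell score distribution looks like. Strong symmetric contrasts would
push the arithmetic mean of the normalized profiles above baseline — a
property of ratio normalization worth remembering when interpreting
averaged profiles.

## Known limitations

* Intensity thresholding locates the cell boundary only to ~½ px;
  bright nuclei bleed into the composite and locally dilate infected-cell
  masks (mask Jaccard vs truth ≈ 0.93 at default optics, ≈ 0.86 in the
  noiseless worst case with a nucleus halo, ≥ 0.9 for nucleus-free
  cells).
* Ground-truth emitter contrast is recovered from rendered images only
  away from mask edges: a hard-edged disk under Gaussian blur mixes the
  classes in a ring of width ~2σ, so full-mask mean ratios are biased
  toward 1 (interior means recover the contrast to <5% at σ = 1 px).
* Touching cells are not split; crowded fields should use pre-drawn
  masks.
* The classifier is a single centre-versus-ends ratio; it cannot
  distinguish polar foci, multiple puncta or filaments from the
  nuclear/cytoplasmic axis readout.
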