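# Methods

## The measurement

An AFM topograph of a partially deposited supported lipid bilayer is, after
artifact removal, approximately a two-level surface: a substrate plane and a
lipid terrace one bilayer thickness above it (≈ 4.5 nm for DMPC below its
chain-melting temperature).  Coverage is the fraction of pixels on the upper
level.  Because AFM heights carry an arbitrary origin, every step in this
package operates on height *differences*; no stage assumes an absolute zero,
and the dominant terrace is never forced to zero.

## Flattening

Raw rasters carry three instrument artifacts: a global tilt (sample/scanner
plane mismatch), low-order bow (piezo arc), and per-scan-line DC offsets
(feedback drift).  `plane_fit` removes a least-squares 2-D polynomial of
order 0–3; `line_flatten` removes per-row medians or per-row polynomial
fits.  Both accept an inclusion mask so surface features are not treated as
background.

The subtle failure mode is that the features being measured bias the
background estimate: an unmasked per-row median references each row to
whichever phase holds its median, so at ~50% coverage adjacent rows can be
referenced to different phases and the height distribution splinters.
`masked_flatten` therefore iterates:

1. plane-fit only (row corrections deferred — they are the bistable step);
2. locate up to two height modes (substrate and terrace) in the
   Gaussian-smoothed histogram;
3. compute each pixel's residual to its *nearest* mode; pixels further than
   `terrace_band_nm` (default 2.0 nm) from every mode — defect walls,
   multilayer islands, vesicle caps — are excluded;
4. fit the global polynomial plus per-row offsets to those residuals and
   subtract; repeat until the update's RMS (modulo a constant, since heights
   are relative) is below `convergence_tol` (default 0.01 nm, max 3
   iterations; non-convergence is recorded in provenance, not raised).

Referencing rows to their nearest mode rather than to a single "terrace"
phase means fully covered, fully bare and evenly mixed rows are all tied to
a common frame.  Defaults: plane order 1, median line offsets — the minimal
treatment for the artifacts simulated, and the conventional first-line
treatment for real scans.

## Thresholding and coverage

The default threshold is the minimum of the Gaussian-smoothed height
histogram (bin width 0.05 nm, smoothing σ = 2 bins) between the two tallest
peaks separated by ≥ 1 nm.  This is a deterministic stand-in for the manual
practice of reading a threshold off height profiles; Otsu (plateau-midpoint
tie-break: the between-class variance is constant across an empty inter-mode
gap, so the maximiser of h and of −h are averaged), peak midpoint, and
manual values are available, and the method used is recorded in provenance.

A pixel is covered iff its height is *strictly* above the threshold (ties
uncovered).  Coverage is computed with exact rational arithmetic
(`Fraction`) before float conversion, so coverage(mask) +
coverage(complement) = 100 identically.

Unimodal histograms — fully covered or bare, indistinguishable from
topography alone — are never silently assigned.  `analyze_image` flags them
and decides by elevation: if the single mode sits 3.5–5.5 nm (the expected
bilayer window) above the robust scene floor (0.5th percentile), the image
is called fully covered, else bare.  On a genuinely complete bilayer with no
defects the floor equals the mode and the rule reports 0% with the
`unimodal` flag — the correct behaviour for topography alone, which cannot
distinguish a perfect bilayer from clean substrate; the flag tells the
operator that complementary evidence (e.g. chemical mapping) is needed.

## Defect depths

Defects are 8-connected components of the uncovered phase (diagonal bridges
are common after thresholding noisy boundaries); components under `min_area`
(default 4 pixels) are threshold noise.  Depth of an interior defect is

    median height of the annular ring of covered pixels within
    `ring_width` (3 px) of the boundary
  − floor statistic of the defect interior,

clamped at ≥ 0.  The default floor statistic is the interior **median**:
under symmetric roughness it is an unbiased estimate of the floor level, so
recovered depths match construction to well within ±0.2 nm at σ = 0.3 nm
roughness.  A 10th-percentile floor (`floor_stat="p10"`) is offered for
real scans where the tip may only intermittently reach the substrate — it
approaches the deepest credible floor while resisting single-pixel spikes —
but it reads ≈ 1.28 σ deeper than the median under Gaussian roughness, a
bias a user should accept knowingly, so it is not the default.
Border-touching defects have no complete background ring and contribute to
coverage but never to depth statistics.

Two mutually exclusive rules process a depth list: the **outlier rule**
discards depths > 7 nm as multilayer pits before averaging, and the
**population split** partitions at 6 nm into thin/thick populations with
nothing discarded (used where a condition genuinely shows two defect
classes).  Aggregation reports mean ± sample SD (n − 1) of per-image
coverages per condition, warns below the 10-image / 2-sample protocol, and
pools depths per condition before classification.

## Synthetic topographs

The generator emulates the morphologies the pipeline must handle: terrace at
`bilayer_thickness` over substrate 0; non-overlapping circular defects with
lognormal diameters punched until the covered fraction is within ±0.5
points of target (the **achieved** fraction is the ground truth, never the
requested one); optional multilayer islands raising covered pixels to
8–15 nm total; optional spherical-cap vesicle features (cap height below
half the cap diameter, emulating partially fused vesicles of 100–150 nm
suspension diameter); then tilt, per-row offsets and pixel noise.  Ground
truth is captured before the artifact stage.  Default conditions: 512×512 px
at 10 nm/px, noise σ 0.3 nm, tilt 0.05 nm/px per axis, line offsets σ
0.5 nm.

Circular, non-overlapping defects make diameter and count ground truth
exact.  Random sequential placement of disjoint discs jams near ~45–50%
punched area, so uncovered fractions ≳ 45% are unreachable in that mode;
the opt-in `allow_overlap` mode (used for the half-covered condition, whose
real counterpart is a coalescing-island morphology anyway) punches
overlapping circles and book-keeps coverage by mask counting.  One seed
drives independent sub-streams per construction stage, so toggling noise
does not move defects, and a scene is a bit-exact function of its spec.

What the generator does **not** emulate: irregular defect outlines, tip
convolution (defect walls are vertical), height-correlated noise, scars,
and thermal drift.  Passing recovery tests therefore demonstrates the
correctness of the *algorithms* under controlled artifacts, not performance
on every pathology of real scans.

## Isotherm analysis

Monolayer π–A isotherms are analysed with finite differences on the raw
sequence (no smoothing by default).  The "steeper portion" used for
limiting-area extrapolation is operationalised as the 5-point sliding
window maximising mean |dπ/dA|, extended while the local slope stays ≥ 80%
of that maximum; the least-squares line through it is extrapolated to π = 0.
The fit is rejected when |slope| < 3 × its standard error.  Collapse is the
first point after the condensed region where the segment slope changes sign
or drops below 20% of the condensed slope.  A transition plateau is ≥ 3
consecutive points with slope magnitude below 0.3 × the median slope of the
flanking segments, required to be interior (a terminal plateau is collapse,
not a phase transition); absence returns `None`, as for cholesterol-rich
films or films above the chain-melting temperature.

## Validation problem sizes

Coverage recovery runs 5 levels × 10 seeds at 512×512 px; depth recovery
pools ~50 defects per construction depth from two 256×256 scenes; geometry
recovery uses one 512×512 scene per diameter.  These sizes give sub-0.1-pp
coverage errors and sub-0.01-nm depth errors against ground truth while
keeping the whole validation suite around ten seconds.

## Known limitations

* The valley threshold needs the minority phase to contribute a detectable
  histogram peak; below ~0.5% minority area the image is treated as
  unimodal and resolved by the elevation rule.
* Depth statistics exclude border-touching defects, which slightly biases
  sampling toward small defects on sparse images.
* The unimodal full/bare decision depends on the robust-floor percentile;
  an image that is fully covered *and* has a few deep scratches could be
  misread as partially covered substrate.
* Isotherm detectors assume compression-ordered, low-noise data; opt-in
  smoothing is the remedy for noisy traces, at the cost of plateau-edge
  localisation.
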