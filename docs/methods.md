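# Methods

This note documents the models implemented in `lithotex`, the conventions
and defaults that matter, what the synthetic data generator does and does
not emulate, and the numerical choices a maintainer would want to know.

## Surface pre-treatment

All texture parameters are computed on a regular height grid `z(x, y)`
(mm) after the standard metrology chain, applied **per sub-area**:

1. **Levelling** — ordinary least-squares plane subtraction over unmasked
   cells; residuals are orthogonal to {1, x, y} and the operator is
   idempotent to 1e-9 mm.
2. **Form removal** — least-squares polynomial of *total* degree ≤ 3
   (10 monomials), the conventional F-operator. The alternative
   (degree 3 per axis) can be obtained by changing `degree`; the choice is
   recorded in the map's provenance.
3. **Tiling** — a centred 3 × 3 layout of 10 × 10 mm sub-areas by default;
   tiles can be flagged worked/unworked from a mask so unworked tiles are
   excluded from statistics.

Coordinates: x rightwards, y upwards, z up; angles in degrees
counter-clockwise from +x; texture directions are axial, reported on
[0°, 180°).

## Areal parameters

Definitions follow the ISO 25178 vocabulary with documented choices where
the standard leaves freedom:

* **Smc** inverts the areal material-ratio curve at p = 10% (quantile with
  linear interpolation); **Vvv** integrates the void below the p = 80%
  material-ratio height. Both ratios are config keys — commercial software
  does not publish its defaults, so absolute values are comparable only
  within a fixed configuration.
* **Sal/Str** use the FFT (zero-padded, aperiodic) normalized
  autocorrelation with decay threshold s = 0.2, scanned radially at 180
  angles with sub-cell interpolation. Directions whose ACF never reaches
  s within the half-window are censored at the half-window, which drives
  Str toward 0 for periodic or striated textures. The FFT ACF is verified
  against the direct O(n²) sum on small grids (1e-9).
* **Sdr** triangulates each cell into two triangles on its corner heights.
* **Feature parameters** use watershed segmentation of the surface
  (dales) and its negation (hills), with h-extrema pruning at 5% of Sz
  (Wolf-style merging of insignificant features). A feature's pour level
  is the highest point of its region border (map edges are not saddles).
  Spc is the arithmetic mean principal curvature −(z_xx + z_yy)/2 from a
  3 × 3 quadratic fit at each retained peak. Hill/dale roundness is the
  isoperimetric ratio 4πA/P² of the half-prominence contour around each
  retained extremum; the commercial definition being proprietary, this
  variant is fixed by its own unit tests (a circular bump scores 1.0) and
  is never compared numerically to external software.

## Scale-sensitive fractal analysis

Relative area is estimated by triangulating the surface subsampled every
k cells (nominal triangle area (k·spacing)²/2), averaged over up to four
lattice offsets; the default ladder is 16 log-spaced steps from one cell
to a quarter of the grid side. From the log–log curve:
Asfc = −1000 × the steepest negative slope, Smfc the geometric midpoint of
that segment, Das = 2 − 2 × (slope over the finest third), Y-max the
maximum relative area. HAsfc and MedianAsfc are the MAD/median and median
of Asfc over a 3 × 3 partition. epLsar samples profiles at 36 orientations
(5° bins) with 40 µm chords and takes the axial (angle-doubled) mean
vector length of the normalized rose; NewEplsar is the same statistic on
log-transformed relative lengths — the published formulation of that
variant is not fully specified, so only orderings of NewEplsar are ever
asserted, never values.

## Furrows and texture direction

Furrows are watercourse lines. A cell is a furrow vertex when it is a
strict transverse minimum along one of the four grid directions **and**
the surface rises by at least 8 µm on *both* sides within 0.15 mm. The
two-sided rim makes this a true valley test (points on open slopes, e.g.
crater walls, are rejected); the 8 µm floor is a few times the noise
amplitude of a structured-light scanner, below which valleys are
indistinguishable from measurement noise. Candidates are thinned to a
one-cell skeleton; length uses the half-sum of neighbour distances (exact
for straight chains), density is reported in cm/cm², and vertex depths
are re-measured against rims within 0.5 mm so grooves wider than the
detection window report their full depth. An earlier design used
watershed-dale skeletons; it degenerates on dense crossing striation
fields (merged dales become area-covering basins whose skeletons lose the
individual lines) and was replaced by the directional detector, which
passes the same constructed-geometry oracles.

Texture direction resamples the Hann-windowed 2-D FFT power onto a polar
grid and integrates over radial frequency per 1° angular bin; the
interpolation spreads the sparsely sampled low frequencies over
neighbouring bins instead of concentrating them by pixel-grid accident.
Reported angles are the direction texture ridges run along. Isotropy is
100 × mean/max of the (3°-smoothed) bin powers — flat spectrum 100%, a
single orientation near 0%; the three strongest local maxima at least 10°
apart give the first/second/third directions.

## Engraving profiles and EFA

Landmarks: apex = global minimum (flat-bottom ties resolve to the plateau
midpoint); shoulders = nearest reference-level crossings on each side
(trace ends, flagged, if absent); depth-convergent wall points at 90% of
D. Measurements: D, WIS, θ (angle at the apex between the shoulder
vectors; an alternative fitted-wall-angle definition would be easy to add)
and the reflection asymmetry A = mean over 20 evenly spaced depth
fractions of the horizontal distance between the left wall mirrored about
the apex vertical and the right wall. A is reported in mm but treated as
an arbitrary-unit score in comparisons, since published values of this
statistic do not state units or aggregation. A trace with a secondary
trough deeper than D/2 (behind a ridge rising at least D/2) is rejected.

Outlines are closed by the straight shoulder-to-shoulder segment and
resampled to 256 equally spaced points, counter-clockwise from the left
shoulder. EFA uses the classical polyline formulation with chord-length
parametrization (a `uniform` option exists, under which an ellipse
sampled uniformly in its own parameter is exactly one harmonic — the
closed-form oracle). Normalization standardizes starting point, rotation
and size via the first harmonic; the π/2 (major-vs-minor axis) and π
(traversal start) ambiguities of the half-angle formula are resolved by
maximizing the first-harmonic semi-axis and by a deterministic sign rule
on the higher harmonics, giving start-point invariance to machine
precision. Shape variables are the 4h − 3 remaining coefficients
(a₁ = 1, b₁ = c₁ = 0 after normalization). "Total power" for harmonic
truncation uses a 20-harmonic reference.

## Statistical layer

The study-wide significance threshold is α = 0.003 everywhere, including
the Shapiro–Wilk normality gate that routes linear variables to ANOVA
(all groups Gaussian) or Kruskal–Wallis. Circular tests: Rayleigh with
the small-sample exponent correction; generalized Watson–Williams with
the 1 + 3/(8κ̂) correction (a pooled κ̂ < 1 is recorded as an assumption
warning); Mardia–Watson–Wheeler uniform scores with a seeded permutation
fallback when more than 10% of the sample is tied; Fisher's
nonparametric common-median-direction test (the specific "Fisher
nonparametric test" variant is not published for this workflow; the
common-median test is implemented and labelled). Circular–circular
correlation is Jammalamadaka–Sarma, linear–circular is
Johnson–Wehrly–Mardia; permutation p-values use the add-one rule
(p is never 0).

Variable selection keeps variables significant at α, then greedily drops,
from each pair with R² ≥ 0.7 (largest R² first), the member with the
larger univariate p (alphabetical on ties); every drop logs its retained
partner. PCA standardizes variables (z-scores — the defensible default
for mixed-unit tables; a toggle exists) and retains the smallest k with
cumulative explained variance > 0.95. The LDA protocol is a stratified
80/20 split, 10-fold cross-validation on the training portion, refit and
held-out evaluation; accuracy gets an exact Clopper–Pearson 95% CI and a
one-sided exact binomial test against the no-information rate (largest
class share of the evaluated set). CVA axes solve W⁻¹B (ridge-regularized
and logged if W is singular); per-observation scores are jack-knifed with
axis signs aligned to the full-sample axes. The permutation MANOVA uses
Wilks' Λ on the first two score columns with n = 999 permutations.

## Synthetic data generator

The generator emulates the study conditions of a carving experiment on
coarse bioclastic limestone: 19 modalities (4 pecking, 2 scraping, 3
multi-stroke engraving, 3 polishing, 7 sequential combinations) × 5
participants (2 novices, 2 intermediates, 1 expert) = 95 trials; each
technique step has a five-minute budget mapped to event counts by
documented rates (pecking 6 impacts, scraping 9 strokes, polishing 80
striations per cm² per minute — physical rates are not published for this
kind of experiment, so these are calibration choices fixed here).
Polishing modalities include a scraping preparation pass, as polishing was
applied to freshly scraped squares in the protocol.

The substrate is a self-affine spectral-synthesis field (Hurst 0.8, RMS
8 µm over 10 × 10 mm) with spherical-cap pore depressions (2/mm², radius
0.12 mm, depth 20 µm) and a 2 µm Gaussian noise floor. Technique
operators only remove material (pointwise non-increasing heights):

* **sawing** subtracts parallel sinusoidal grooves (control surfaces);
* **pecking** subtracts ellipsoidal-cap craters organized in directional
  sweep rows; orientations are von Mises around the gesture direction,
  sizes/depths scatter log-normally with the skill CV, and low skill adds
  intra-crater fracture chatter and glancing secondary nicks;
* **scraping** cuts long parabolic striations with angular jitter, a
  crossed-stroke fraction and stick-slip depth modulation, with periodic
  peak truncation against a smoothed tool envelope;
* **polishing** iterates multi-scale peak truncation and overlays fine
  multi-directional abrasion tracks whose depth follows the medium
  (cobble > wet sand > skin);
* **engraving** cuts a V channel along a path; multiple strokes superpose
  laterally jittered cuts, widening the groove and evening its asymmetry.

Striation and engraving stamps use *cut-to-envelope* semantics — material
is removed down to (smoothed reference − profile), so overlapping strokes
re-cut a groove instead of stacking, as a real tool edge does.

Skill presets (novice κ = 2, intermediate κ = 8, expert κ = 32 von Mises
concentration; coverage uniformity 0.5/0.7/0.9; spacing CV 0.6/0.35/0.15)
are calibration knobs; only their *ordering* is contractual. At the
documented defaults the generator reproduces, by design, the gradients the
analysis is meant to recover: Sal, Spc and MedianAsfc decrease and Str and
furrow density increase from pecking through scraping to polishing;
expert pecking is less isotropic and less complex than novice pecking;
superimposed techniques converge toward polishing-like values. Passing
these tests therefore demonstrates that the *pipeline* recovers contrasts
that are present — it does not demonstrate that real limestone surfaces
carry contrasts of this size. Features of real data the generator does not
attempt: petrographic heterogeneity (fossils, cementation), tool wear and
participant fatigue, fracture mechanics of spall formation, scanner
artefacts other than isotropic noise.

Synthetic engraving sets A–I mirror the experimental design: three
superficial multi-stroke tools (burin/flake/blade at depths 0.98/0.80/
0.64 mm), four engrave-polish sequence variants (single-stroke sets
shallow, ~0.3 mm, and more asymmetric), and two deep U-shaped
pecked-then-incised sets (~2 mm deep), with log-normal scatter (CV 0.18)
and noise at 2% of depth. Opening angles follow from the depth/width
geometry: superficial multi-stroke ≈ 120–140°, shallow single-stroke
≈ 145–150°, deep sets ≈ 85–95°.

## Problem sizes used in the validation suites

The test suites run on one CPU with deliberately scaled problems: the
technique-recovery suite uses 3 classes × 30 sub-areas of 10 × 10 mm at
25 µm (the documented default grid), Monte-Carlo calibrations use 500
null replicates per test with n = 999 permutations where applicable, and
the acceptance script uses 50 profiles. Full 10 × 10 cm squares at
scanner resolution are supported but generated only on demand.

## Known limitations

* Absolute parameter values depend on documented choices (Smc/Vvv ratios,
  pruning level, isotropy definition, furrow depth floor) and are not
  bit-compatible with proprietary metrology software; cross-software
  comparisons should use orderings, not values.
* The rasterizer assumes a height field; undercuts and vertical walls are
  out of scope, and mesh gap filling is limited to 3 cells.
* Engraving section lines are inputs; the package does not auto-detect
  engraving paths on a map.
* Participant is not modelled as a random effect in the statistics; the
  per-technique expertise analysis treats sub-areas as exchangeable.
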