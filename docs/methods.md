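# Methods

`nanoxtal` recovers crystallographic intensities *and phases* from
(simulated) cryo-electron tomograms of protein nanocrystals. Unlike
diffraction, imaging retains the phase of each structure factor, so the 3D
Fourier transform of a tomogram of a crystal carries a full, if incomplete
and noisy, set of phased reflections. The package implements the whole
chain — synthetic data generation, preprocessing, indexing, Bragg-peak
extraction, multi-crystal merging, crystallographic-origin location,
radiation-damage simulation and the tilt-spread diagnostic — and this note
records the models, conventions and design choices behind each stage.

## Conventions

* Phases are degrees on (−180, 180]; a symmetry operation acts on
  fractional coordinates as x → Rx + t, reflections transform as row
  vectors h′ = hR, and phases obey φ(hR) = φ(h) − 360·(h·t) together with
  Friedel symmetry φ(−h) = −φ(h).
* Shifting the phase origin by the fractional vector u changes every phase
  by φ′(h) = φ(h) − 360·(h·u) (translation theorem); intensities are
  unaffected.
* Real-space volumes place voxel (0,0,0) at the grid corner; discrete
  transforms put the phase origin at the central voxel N//2 per axis
  (the volume is cyclically rolled before the FFT), and the zero frequency
  of a `FourierVolume` also sits at N//2.
* The tilt axis is x, the beam axis z; the tilt scheme is dose-symmetric
  (0, −δ, +δ, −2δ, …) spanning ±60° at 3° steps or ±40° at 2° steps
  (41 images either way).

## Synthetic crystals (`sim_crystal`)

Pseudo-structures are Gaussian scatterers: positions uniform in the cell
(the asymmetric-unit content), expanded by the space-group operators, with
per-atom widths σ ∈ [0.7, 1.2] Å and integrated scattering weights
∈ [6, 16] (roughly C…S electron counts). Structure factors follow by
direct summation, F(h) = Σ w exp(−2π²σ²q²) e^{2πi h·x}, q = 1/d;
systematically absent reflections are excluded (they are exactly zero with
ill-defined phases). A dual-route test pins this against the FFT of the
real-space cell density.

Finite crystals place every atom of an N×N×N block of cells at its
absolute position on a common voxel grid, band-limit at the working
resolution with a soft spherical low-pass, and embed the block in a cube
at least 1.4× the crystal diagonal so rotations never clip density.
Because the cell lengths are generally not integer multiples of the voxel,
the sampled crystal is imperfectly periodic — deliberately, since the
preprocessing stage exists to handle exactly that. Default test scale is
3–5 cells per axis at 1 Å voxels (grids ≲ 100³), far below the 10-cell
crystals of a full-scale study; this keeps a complete
simulate-to-reflections run at a few seconds without changing any
algorithmic behavior.

Tilt series are line integrals of the volume rotated about x (trilinear
interpolation); the detector axis points along (cos α, sin α) so the
Fourier-slice theorem holds against the central slice in that direction
(tested at correlation > 0.99). Reconstruction is weighted back-projection
with an r-weighted ramp filter (small DC retention 0.25/N avoids a hollow
reconstruction); the dense-sampling limit (1° steps over ±89°) restores a
smooth phantom at correlation > 0.95, and a ±60° series shows the expected
beam-axis elongation.

Real-space radiation damage follows a local-blurring model: each "hit"
replaces a 5 Å cube at a random site inside the crystal bounding box
(sites whose box crosses the volume edge are clipped) with its
Gaussian-filtered copy, σ = 1 Å per axis. Hits accumulate on a single
evolving volume in dose-symmetric acquisition order, so the image acquired
n-th carries n × hits_per_image cumulative events — a linear dose ramp.
The bounding box is taken at 2% of the density maximum because
band-limiting leaves low-amplitude ripples across the padded volume.

## Preprocessing (`preprocess`)

Imperfectly periodic crystals truncated by the transform window produce
*phase splitting*: the window-filling signal has a Dirichlet-kernel
envelope whose sign alternates between adjacent frequency bins, so around
a Bragg peak that falls between voxels the phase jumps by 180° between
adjacent octants. Two operations remove it: a separable Tukey window
(taper fraction 0.5) suppresses the circular discontinuity at the window
boundary, and the auto-convolution function f∗f — whose peak sits at twice
the density center regardless of the density's symmetry — locates the
translation (rounded to whole voxels; the sub-voxel remainder is a benign
phase ramp absorbed later by the origin search) that moves the crystal
center onto the transform origin. The cyclic two-fold ambiguity of the
auto-convolution peak (p/2 vs p/2 + N/2 per axis) is broken with the
density's center of mass.

`phase_splitting_metric` quantifies the effect at one peak: among the
3×3×3 neighborhood pixels whose intensity is within 3× of the local
maximum, it averages |Δφ| over neighbor pairs at odd-parity offsets
(even-parity offsets cross octant boundaries twice and carry no net
signature). Sharp single-pixel peaks give 0 by construction, which is the
correct answer for an ideal crystal.

## Spot finding and indexing (`indexing`)

Spots are found per x-slice (parallel to the tilt axis) with a local
mean/variance dispersion test (window 7, default 4σ, gain-scaled),
merged across slices at 26-connectivity, and filtered by resolution window
and pixel count. The indexer uses the 1D-FFT directions method: ~4000
Fibonacci-distributed hemisphere directions; spot centroids are projected
onto each; a 512-bin FFT of each projection scores periodicity. Candidate
real-space lattice vectors are the scored direction × refined frequency,
with two refinements that matter in practice: a zoom step (the coarse FFT
bin quantizes vector lengths by several percent, too coarse for Miller
rounding) and a fundamental-frequency check (the strongest bin is
sometimes the 2nd/3rd harmonic). Because tomogram transforms contain
artifact spots (shape-transform sidelobes, wedge streaks), only the ~150
strongest spots are used and candidate triples are ranked by the fraction
of spots they index jointly, not by first success; the top triples are
refit and re-scored at tight tolerance, since non-lattice vector
combinations can look consistent at loose tolerance over a small index
range but cannot sharpen under refit. Two further safeguards: a
near-coplanar candidate pool is extended with out-of-plane vectors, and
because *any* integer combination of true basis vectors indexes every
spot, a solution whose Miller assignments occupy only a sublattice of Z³
(detected by congruence voting robust to artifact spots, then collapsed
via a Hermite-normal-form basis) is rewritten as primitive. The accepted
basis is refined by intensity-weighted least squares against rounded
Miller assignments with a tightening tolerance schedule. On 5-cell test
crystals this recovers the generating cell within 2% for 9/10 random
tomogram orientations.

The provisional P1 cell is then projected onto the known space group's
constraints (orthorhombic: angles 90°; tetragonal: a=b averaged; …) and
the basis rotated onto the constrained cell by orthogonal Procrustes;
deviations beyond 5% raise an error (wrong space group). Laue-class
determination from intensities is not attempted — the space group is an
input. When the conventional cell is known, `rebase_to_cell` finds the
unimodular change of basis matching it, so Miller indices become
comparable with reference data.

## Peak extraction (`peak_extraction`)

Reflection positions are predicted from the indexing matrix to the
resolution limit; predictions in the missing wedge (angular coordinate
beyond the tilt range) are discarded. Extraction per reflection, inside a
spherical subvolume of radius 7 reciprocal voxels:

1. assign pixels above mean + 4σ of the subvolume; keep the contiguous
   set nearest the prediction;
2. reject if the observed centroid is more than 2 voxels from the
   prediction ("partial" — such peaks are frequently off by 180° in
   phase);
3. mask the peak plus contiguous pixels above mean + 2σ and estimate the
   background under the mask from the nearest unmasked voxel along each
   of the six axis directions (inverse-distance weighted; subvolume-mean
   fallback) — the background is anisotropic because the data lie on skew
   slices;
4. iteratively drop the pixel with the largest intensity-weighted wrapped
   deviation (ties: the weaker pixel) until the intensity-weighted
   circular phase spread is ≤ 15°; fewer than 2 surviving pixels after
   dropping ⇒ "phase_incoherent" (a clean single-pixel assignment is
   accepted as is);
5. intensity = Σ background-subtracted retained pixels, phase = their
   intensity-weighted circular mean.

The phase spread is circular: deviations are wrapped about the circular
mean before the weighted RMS. Because the 4σ rule captures a
threshold-truncated sum, broad peaks are systematically underestimated in
absolute terms; relative intensities are consistent and the inter-dataset
scaling model absorbs the scale. Tests therefore inject compact peaks
(Gaussian truncated to the 7-voxel cross) whose discrete mass is the
oracle value.

Each observation records the tilt angle of the nearest sampled central
slice (assignment tolerance: half the increment).

## Merging (`merging`)

Origin alignment searches every node of a fractional grid (≈0.2 Å spacing
per cell axis) for the shift minimizing the intensity-weighted wrapped
residual between reference and shifted phases over shared reflections.
Choices:

* weights: geometric mean of the two observed intensities (arithmetic
  mean available);
* residual: root-mean-square wrapped difference by default. The
  mean-absolute form is available, but under heavy phase noise the L2
  minimizer localizes the true shift measurably better (Monte-Carlo
  success 0.80 vs 0.69 on hard damaged-pair conditions), and the
  companion intensity-scaling objective is explicitly least-squares;
* search: a resultant score C(u) = Σ w cos(Δφ − 360 h·u), evaluated on the
  whole grid at once by a zoom DFT over the occupied Miller box, shortlists
  1024 candidates; the exact residual is evaluated there. Exhaustive
  evaluation is kept as the reference oracle and is verified to agree.
* ties: smallest minimal-image ‖u‖, then lexicographic.

Intensities are scaled onto the reference with
ln I₂ − ln I₁ = b + m·q − q²σ²/2 by linear least squares over shared
positive pairs (log residuals for stability); the fitted model is divided
out, recovering an injected Debye–Waller width within 5%. Merging is
greedy: the unmerged set sharing the most reflections with the growing
reference is aligned, scaled and pooled; the final phase per reflection is
the intensity-weighted circular mean of its observations, the intensity
the plain mean, the multiplicity the count. Everything is treated as P1
during merging. The merge error is the minimal-image Euclidean distance
between fractional shifts; a merge is "successful" below 0.03.

## Crystallographic origin (`origin_search`)

On an arbitrary common origin the phases do not reflect the space-group
symmetry; the crystallographic origin is found by scoring every node of
the same fractional grid with three metrics: the intensity-weighted
residual of symmetry-equivalent phase estimates about their circular mean;
the intensity-weighted distance of centric phases (hR = −h) from their two
allowed values θ_h = 180·(h·t) mod 180 (omitted without centrics); and the
negative skew of a symmetry-averaged density map synthesized from
(√I, shifted phases) on a grid of ≈d/3 spacing — protein maps are
positively skewed, wrongly phased maps Gaussian. A plain P1 synthesis is
translation-invariant in its value histogram, so the skew only
discriminates origins after symmetry averaging
F_sym(g) = (1/N) Σ_s F_u(gR_s) e^{2πi g·t_s}.

Metrics are z-score normalized across evaluated candidates and summed with
equal weight. The search is hierarchical for speed: resultant scores of
the two phase metrics rank all grid nodes (zoom DFT), the exact phase
metrics run on the top 1024, the skew on the best 256 of those; this is an
optimization of the same objective, and removing any single metric still
recovers the origin on clean data. Success is judged against the space
group's permissible-origin set (the shifts o with (R−I)o ≡ 0 mod 1 for all
ops — 8 discrete choices in P2₁2₁2₁, a continuous polar axis in P2₁),
since no metric can distinguish equivalent origins.

ASU reduction maps every reflection to a canonical representative
(lexicographically largest among all hR_s and Friedel mates), transports
phases through the symmetry relations, and combines observations by
intensity-weighted circular mean phase, mean intensity and summed
multiplicity. On perfect data the reduce/expand round trip is lossless.

## Reciprocal-space damage simulator and JS diagnostic (`recip_damage`)

To decouple completeness, phase error and angular spread, damage is
simulated directly on reflections. For a random orientation, each
reflection's angular coordinate ψ = atan2(s_z, s_y) (folded to (−90, 90])
selects the nearest central slice; |ψ| beyond the tilt range is the
missing wedge. Intensities decay as I = I₀ exp(−(n·B_rel)·q²/4) with n the
dose-symmetric image number of that slice and B_rel a relative B factor in
Å² per image. The brightest reflections are kept to hit the target P1
completeness exactly (full Friedel-unique denominator); the phase origin
receives a uniform random fractional shift, and Gaussian phase noise with
σ = mean_error·√(π/2) realizes a specified mean |error|. Damage therefore
moves the retained set toward low tilt angles — the dose-dependent spread
the diagnostic measures.

The Jensen–Shannon distance bins each reflection's *continuous* ψ at 1°
over ±60° and takes the square root of the JS divergence (base-2 logs,
0·log 0 = 0) against the uniform distribution: 0 only for an even spread
over the full range; narrower ranges are penalized even when internally
uniform. Binning the quantized slice angle instead would produce an
artificial comb (41 occupied bins of 120) and a JS floor of ≈0.7, masking
the signal. Note a finite-sample floor remains: n uniform samples over 120
bins score ≈0.46/0.26/0.13 at n = 130/400/1300, so the small scaled-down
data sets here rarely reach the JS < 0.18 regime that large cells attain;
the low-JS behavior is exercised with a mid-sized cell (30×40×50 Å,
~3500 reflections).

The merging-success study sweeps target completeness {0.1, 0.2, 0.3, 0.4},
mean phase error {0, 10, 20, 30, 40}° and B_rel {0, 1, 3, 10} Å²/image for
the orthorhombic 16.2×29.1×47.7 Å P2₁2₁2₁ system (B values chosen to span
JS ≈ 0.15–0.65), generating pairs of data sets in independent random
orientations with independent true shifts, and compares (a) pairwise
common-origin alignment, (b) per-set crystallographic-origin location and
(c) origin location on the merged pair, all at 0.2 Å sampling with the
0.03 fractional-error success criterion. Defaults run 3 pairs per
condition (240 pairs, ≈11 min on one CPU) — far below the 25 920 data sets
of a full-scale study, so the reported success-rate differences carry
Monte-Carlo scatter of a few percentage points.

## Evaluation metrics (`metrics`)

R_ref,φ is the intensity-weighted mean |wrapped phase difference| against
reference phases over shared reflections, minimized over the space group's
permissible origin shifts (and polar-axis positions) — without that
minimization the metric would depend on which equivalent origin the
pipeline happened to select. CC(I) is the Pearson correlation of log
intensities; CC(map) correlates a Fourier synthesis
(ρ = Σ √I e^{iφ} e^{−2πi h·x}, symmetry-expanded, Friedel-completed) with
a reference map on the same grid. Completeness counts observed unique
reflections against the Friedel-unique set to the resolution limit
(systematic absences excluded; missing-wedge reflections *not* excluded
from the denominator), either in P1 or after ASU reduction.

## Known limitations

* No CTF, detector noise, beam-induced motion or multiple scattering —
  the simulators isolate sampling, damage and phase-noise effects only,
  so passing tests bound algorithmic behavior, not microscope reality.
* Real-space gridding assumes orthogonal cells; reciprocal-space
  simulation is fully general.
* Absolute extracted intensities are threshold-truncated sums (see peak
  extraction); only relative scales are meaningful.
* The scaled-down study sizes (small pseudo-structures, few unit cells,
  hundreds of Monte-Carlo pairs) reproduce orderings and regime boundaries
  rather than per-cell tabulated values.
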