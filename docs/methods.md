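# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic generator does and does not emulate, and
the known limitations.

## Units and coordinate conventions

All lengths are ångström internally; GRO/XTC files (nm) are converted ×10 on
read and write. Boxes are orthorhombic. Before any lateral analysis,
coordinates are wrapped into the primary box in x and y only: the membrane
is continuous through the lateral periodic boundaries, whereas wrapping z
would split leaflets. The membrane normal is the box +z axis throughout.

## Leaflet assignment

A residue counts as a lipid if it carries at least one of the configured
head or tail bead names. Each lipid is labelled by the sign of the z
component of its head-centroid minus tail-centroid vector: positive = upper
leaflet. This per-lipid orientation criterion, rather than a global z-median
plane, is deliberate: the membranes of interest are strongly deformed
(local thinning and bending around a protein docking site), and a global
plane misclassifies lipids on steep slopes. Lipids missing either bead set
are labelled unassigned with a warning, never an error. The choice of which
beads define leaflet membership is configurable because conventions differ
between analyses that use phosphodiester beads (visualization) and glycerol
beads (surface definition).

## Grid maps

The lateral grid divides the box into an integer number of cells per axis:
the requested cell size is rounded to the nearest divisor and the effective
per-axis size re-derived. Cells are half-open `[x0, x0 + Δ)`, so a bead
exactly on a boundary deterministically belongs to the cell starting there.

**Default spacing is 8 Å.** For the reference system size — ~325 lipids per
leaflet in a 15 × 15 nm box, i.e. ~69 Ų per lipid — an 8 Å cell holds about
one lipid per leaflet, which is the coarsest sampling that still resolves
deformations on the 30 Å scale while keeping most cells occupied every
frame. Substantially finer grids leave the majority of cells empty in any
single frame and fall foul of the occupancy mask below. The spacing is a
parameter (`--grid-spacing`) everywhere.

**Thickness.** Per frame and cell, thickness is the upper-leaflet mean z of
the surface beads (glycerol beads by default) minus the lower-leaflet mean
z, computed only where both leaflets occupy the cell; the map is the average
over the frames in which the cell was defined. Cells defined in fewer than
50% of frames (configurable) are masked — this is what blanks the footprint
of a protein inclusion. Averaging per-frame thickness values, rather than
taking the thickness of time-averaged surfaces, keeps intermittently
occupied cells near the protein from biasing the map.

**Curvature.** The midplane height h = (z⁺ + z⁻)/2 feeds the Monge-patch
mean curvature

    H = ± [h_xx (1 + h_y²) − 2 h_x h_y h_xy + h_yy (1 + h_x²)]
        / [2 (1 + h_x² + h_y²)^{3/2}]

with derivatives by central finite differences (periodic wrap on periodic
grids; second-order one-sided differences at the edges otherwise, which
keeps affine fields exactly curvature-free on non-periodic grids). The sign
is chosen so that **H > 0 where the surface bulges toward +z** (the
extracellular side in the usual setup); a membrane dimple around a docking
site therefore reads as negative curvature. Note that the textbook
upward-normal Monge form yields the opposite sign (−1/R at the apex of a
dome); we negate it to keep "bulge up = positive". The height grid is
optionally pre-smoothed with a Gaussian (default σ = 1 cell) using
normalized convolution, so masked cells carry zero weight instead of
bleeding zeros into their neighbourhood; curvature is reported only where
the full 3×3 finite-difference stencil is unmasked. Whether the quoted
negative curvature of a given system refers to the midplane or a single
leaflet is a modelling decision left to the caller — any `GridField` (a
leaflet surface or the midplane) can be fed to the estimator.

**Radial profiles.** Azimuthal averages around a point use periodic
minimum-image distances with the centre wrapped into the box, so any
periodic image of the centre gives the same table. Empty bins are omitted.

## Helix tilt

The helix axis is the first principal component (SVD) of the backbone bead
positions, with the sign fixed to point from the N-half centroid to the
C-half centroid. The tilt is the angle between this axis and +z folded into
[0°, 90°], so an axis and its negation are equivalent. Reporting the angle
from the membrane *normal* (not from the membrane plane) is deliberate: the
headline values in the literature for the toppled S-component (~50° stable,
~40° after the ATPase closes) are quoted against the normal; the in-plane
complement is 90° minus the reported value. Summary statistics include a
block-averaged standard error (5 equal blocks by default), the standard
estimator for time-correlated series.

## Superposition and displacements

Kabsch superposition via SVD of the covariance of the centred paired sets,
with the determinant correction enforcing a proper rotation. Pairing between
two models is the sorted intersection of (chain, residue id, atom/bead name)
keys; unmatched atoms are dropped, since deposited models differ in resolved
residues. Nearly collinear point sets (second singular value < 1e-8 of the
first) are flagged degenerate rather than rejected — the rmsd is still
well-defined, only the rotation about the line is arbitrary. Displacement
metrics superpose the second conformation onto the first over an alignment
selection, then report the probe-region centroid displacement, its z
component, the mean per-residue displacement, and (given two probes) the
change in inter-centroid separation, positive when the probes approach.
Which selections correspond to published displacement values is
intentionally a parameter: the operations expose selections rather than
hard-coding structural regions.

## Density maps

MRC/CCP4 I/O goes through gemmi; maps with permuted axis-order headers are
normalized to x, y, z on read, and only orthogonal cells are accepted.
The lowpass filter is a Fourier-space Gaussian with amplitude exactly 0.5 at
the cutoff frequency 1/resolution (so "filtered to 6 Å" halves the 6 Å
component); the DC term — the map mean — is untouched, and the resolution
must exceed the Nyquist limit of 2× the largest voxel spacing. A Gaussian
was chosen over a cosine-edge filter for its composition property (two
passes equal one pass at cutoff/√2), which the tests exploit as an identity
check. Contour levels are n × the standard deviation over all voxels (the
common visualization convention); a solvent-region σ can be supplied via a
mask. The default order is filter first, then take σ of the filtered map,
matching how filtered maps are contoured interactively; the caller can
compute the level on the unfiltered map instead by calling `sigma_level`
before `lowpass_filter`. Slab thickness is measured on a trilinearly
interpolated line probe (step = voxel/4 by default, never more than half the
smallest voxel spacing): the contiguous ≥level run containing the
above-level sample nearest the anchor is taken and its edges refined by
linear interpolation of the level crossing, giving sub-step accuracy.
Contiguity is decided on samples, not voxels, so a probe anchored inside a
thin slab reports that slab even when a thicker one lies further along the
line. Probe anchors for real maps are user-supplied (several anchors can be
measured in one run), since published thickness arrows are figure
annotations without machine-readable coordinates.

## Synthetic generator

The generator reproduces the *geometry and statistics* of a coarse-grained
bacterial-membrane system, not its physics. Defaults mirror the reference
conditions: a 150 × 150 Å lateral box, 325 lipids per leaflet, three species
(POPE/POPG/cardiolipin analogues) at 70:25:5 mol% apportioned by
largest-remainder rounding (deterministic and exactly total-preserving:
325 → 228/81/16), base thickness t₀ = 38 Å. Each lipid is four beads on a
vertical stack — head (PO4) 4.5 Å above the glycerol bead (GL1), two tail
beads (C1A, C2A) at 4.5 and 9 Å toward the midplane — so head-to-tail
orientation encodes the leaflet by construction. Upper-leaflet glycerol
beads sit at z = h(x,y) + t(x,y)/2, lower at h − t/2, where h and t − t₀ are
prescribed deformation fields (flat, sinusoid, or radial Gaussian with
minimum-image wrapping; the radial Gaussian is A·exp(−r²/2σ²) with σ the
`width` parameter). Lateral positions come from a jittered hexagonal
lattice — overlap-free without running dynamics — with rejection of sites
inside the inclusion cylinder. Per frame, every lipid bead receives
independent isotropic Gaussian noise (default 1.5 Å for recovery studies,
the magnitude of glycerol-bead vertical fluctuations in coarse-grained
bilayers); the noise is white in time. The optional inclusion is a rigid
straight run of 29 backbone beads (residues 106–134, chain S) at a
prescribed tilt, with optional per-frame Gaussian jitter on the tilt angle
only. A fixed seed makes the output bitwise reproducible.

Deliberately **not** emulated: lateral lipid diffusion (sites are static,
so grid cells between sites stay empty rather than filling over time),
membrane undulation spectra, lipid internal conformations, species-dependent
geometry, and any protein–lipid energetics. Consequently, passing recovery
tests demonstrate that the estimators are unbiased and correctly normalized
under known deformations and noise — they do not validate force-field
physics, and masked-cell patterns on generator data are blockier than on
real trajectories.

Density slabs are unit-density z-slabs on a 1 Å voxel grid (voxel centres at
origin + i·spacing), optionally Gaussian-smoothed and noise-corrupted — a
controllable stand-in for a nanodisc membrane band in a reconstruction. The
synthetic benchmark widths 23/36/50 Å correspond to the three nanodisc
regimes of interest (thinned at an S-component face, and around a docking
site with closed vs open ATPases).

## Problem sizes in the test and benchmark runs

Recovery checks run at the full reference system size: 325 lipids/leaflet
with 200 frames for thickness (≈10 s), 500 frames per condition for tilt,
100 random-motion trials for superposition, and ~10⁵-voxel maps for the slab
protocol. These sizes put the statistical error of each estimate an order
of magnitude below its pass tolerance (e.g. tilt SEM ≈ 2°/√500 ≈ 0.09°
against a 0.5° band).

## Known limitations

- Trajectories are held in memory; systems beyond ~10⁶ bead-frames should
  be processed in chunks by the caller.
- Leaflet assignment assumes a single bilayer normal to z; vesicles and
  multilamellar stacks are out of scope.
- The selection grammar covers conjunctions of name/residue/chain
  predicates only; no boolean OR between predicates of different kinds.
- Curvature on periodic grids assumes the height field is itself periodic;
  a tilted-on-average membrane should be de-trended first or analysed with
  `periodic=False`.
- No Gaussian curvature, area-per-lipid, or continuum elastic fits.
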