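# memdeform

Membrane-morphology and conformational-geometry analysis for coarse-grained
bilayer simulations and cryo-EM density maps.

Membrane-embedded molecular machines — the motivating case is an
energy-coupling factor (ECF) transporter, whose substrate-binding S-component
topples within the bilayer during transport — reshape the membrane around
them: the bilayer thins or thickens locally, bends around docking sites, and
the protein itself tilts against the membrane normal. `memdeform` quantifies
these effects from coarse-grained bead trajectories and from cryo-EM
reconstructions of nanodisc-embedded complexes, and ships a synthetic-data
generator that provides exact ground truth for every stage, so the whole
pipeline is testable as a parameter-recovery problem without downloading any
deposited data.

## What it computes

- **Leaflet surfaces and thickness maps.** Lipid glycerol beads of each
  leaflet are binned onto a lateral xy grid; the per-cell mean z defines the
  leaflet surface and the local thickness is the z-distance between the
  corresponding upper- and lower-leaflet cells, t(x,y) = ⟨z⁺(x,y)⟩ −
  ⟨z⁻(x,y)⟩, averaged per frame and then over frames. Lipids are assigned to
  leaflets by their head→tail orientation, which stays correct in strongly
  deformed membranes.
- **Midplane mean curvature.** H(x,y) from the Monge-patch formula applied
  to the midplane height field h = (z⁺ + z⁻)/2 with central finite
  differences and periodic wrapping; H > 0 where the surface bulges toward
  +z.
- **Helix tilt statistics.** The helix axis is the first principal component
  of its backbone beads (N→C oriented); the tilt is the angle between that
  axis and the box z-axis (the membrane normal), folded into [0°, 90°], with
  mean, standard deviation and block-averaged standard error per trajectory.
- **Superposition and displacement metrics.** Closed-form Kabsch
  least-squares rotation (proper rotation enforced) with rmsd over pairs
  matched by (chain, residue, atom name); displacement of a probe region
  between two conformations after aligning on a common rigid selection.
- **Density-map slab thickness.** MRC/CCP4 maps are lowpass filtered
  (Gaussian falloff, half amplitude at the cutoff frequency), contoured at a
  multiple of the voxel standard deviation (n·σ), and the membrane slab
  thickness is read off a trilinearly interpolated line probe.
- **Synthetic ground truth.** A generator emulating a two-leaflet bead
  bilayer (three lipid species at 70:25:5 mol%, ~325 lipids per leaflet in a
  15 × 15 nm box) with prescribed midplane-height and thickness fields,
  per-frame Gaussian noise, and an optional rigid tilted helix that excludes
  lipids — plus density slabs of known width for the map protocol.

## Worked example

Generate a bilayer carrying a Gaussian thickness bump and a 50°-tilted
helix, then recover both:

```python
import numpy as np
from memdeform.synthetic import (BilayerSpec, InclusionSpec,
                                 generate_trajectory, make_deformation_field)
from memdeform.membrane import thickness_map
from memdeform.geometry import HelixSelectionSpec, tilt_series

well = make_deformation_field("radial_gaussian", amplitude=12.0,
                              width=30.0, center=(75.0, 75.0))
spec = BilayerSpec(base_thickness_t0=38.0, thickness_field=well,
                   noise_sigma=1.5, n_frames=200)
inc = InclusionSpec(prescribed_tilt=50.0, tilt_jitter_sigma=2.0)
traj, truth = generate_trajectory(spec, inc, seed=11)

tmap = thickness_map(traj)
grid = tmap.field.spec
X, Y = np.meshgrid(grid.x_centers(), grid.y_centers(), indexing="ij")
err = np.abs(tmap.field.values - truth.thickness_at(X, Y))[tmap.field.mask]
print(f"thickness range {np.nanmin(tmap.field.values):.1f}"
      f"-{np.nanmax(tmap.field.values):.1f} A, recovery MAE {err.mean():.2f} A")

series = tilt_series(traj, HelixSelectionSpec((106, 134), "BB"))
print(f"tilt {series.mean:.1f} +/- {series.block_sem:.2f} deg")
```

```
thickness range 37.9-48.3 A, recovery MAE 0.15 A
tilt 50.1 +/- 0.04 deg
```

The map spans the base thickness 38 Å up to ~50 Å at the bump centre
(cells under the helix footprint are masked), recovered cellwise to
0.15 Å despite 1.5 Å bead noise, and the prescribed 50° tilt is recovered
to a tenth of a degree.

The same stages run from the shell:

```sh
memdeform simulate --config cfg.yaml --out run/
memdeform thickness run/system.gro run/trajectory.xtc --out run/ --png
memdeform tilt run/system.gro run/trajectory.xtc --resid 106-134 --out run/
memdeform mapthick map.mrc --lowpass 6 --sigma 6.5 --anchor 60 60 75
```

or as one configured pipeline, `memdeform run --config cfg.yaml`, which
writes parameter-stamped TSVs and a run manifest.

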