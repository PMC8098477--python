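# nanoxtal

Crystallographic structure determination from cryo-electron tomograms of
protein nanocrystals — in simulation. Tomographic imaging of a nanocrystal
retains what diffraction destroys: the *phases* of the structure factors.
`nanoxtal` implements the full data-processing chain that turns a (simulated)
tomogram of a crystal into a phased reflection data set, merges data sets
from crystals in different orientations onto a common phase origin, places
the result on a crystallographic origin consistent with the space group, and
quantifies — via radiation-damage simulators and a Jensen–Shannon
tilt-spread diagnostic — which data-collection strategies make that merging
succeed.

It is aimed at methods developers in electron cryo-microscopy and
crystallography who want a self-contained, testable simulation workbench for the
phase-recovery workflow: every stage runs on synthetic nanocrystals built
from pseudo-atomic models, with no external data.

## The core model

For a crystal with unit cell (a, b, c) and space group G, the tomogram's 3D
Fourier transform samples the structure factors F(**h**) = |F| e^{iφ} on the
reciprocal lattice, minus a *missing wedge* (|ψ| > 60° about the tilt axis)
and minus reflections lost between tilt increments. Key relations used
throughout:

* translation theorem: shifting the phase origin by fractional **u** maps
  φ(**h**) → φ(**h**) − 360·(**h**·**u**);
* symmetry: φ(**h**R_s) = φ(**h**) − 360·(**h**·**t**_s) for each operation
  (R_s, **t**_s) of G; centric reflections (**h**R = −**h**) have phases
  restricted to 180·(**h**·**t**) mod 180;
* common-origin search: the shift between two data sets minimizes the
  intensity-weighted wrapped phase residual over shared reflections,
  searched on a ~0.2 Å fractional grid;
* damage: I(**h**) = I₀·exp(−(n·B_rel)·q²/4), with n the dose-symmetric
  image number and q = 1/d;
* tilt spread: JS distance between the 1°-binned tilt histogram of the
  recorded reflections and the uniform distribution over ±60°.

See `docs/methods.md` for the full account.

## Worked example

Simulate two damaged, incomplete reflection data sets of an orthorhombic
peptide crystal (cell 16.2 × 29.1 × 47.7 Å, P2₁2₁2₁), align them onto a
common origin, and locate the crystallographic origin of the merged data:

```python
import numpy as np
from nanoxtal.symmetry import UnitCell
from nanoxtal.sim_crystal import generate_pseudo_structure, structure_factors
from nanoxtal.recip_damage import (RecipDamageConfig,
                                   simulate_damaged_dataset, js_distance)
from nanoxtal.merging import origin_alignment, merge_datasets, merge_error
from nanoxtal.origin_search import find_crystallographic_origin

cell = UnitCell(16.2, 29.1, 47.7)
model = generate_pseudo_structure(7, 6, cell, "P212121")
reference = structure_factors(model, d_min=3.3)        # 1287 reflections
                                                       # (absences excluded)

rng = np.random.default_rng(1)
cfg = RecipDamageConfig(b_rel=3.0, target_completeness=0.3,
                        phase_error_mean=20.0)
ds1, truth1 = simulate_damaged_dataset(reference, cfg, rng)
ds2, truth2 = simulate_damaged_dataset(reference, cfg, rng)
print(len(ds1), "reflections, JS =", round(js_distance(ds1.tilt), 3))

u, residual = origin_alignment(ds1, ds2, interval=0.2)
err = merge_error(u, (truth2["u_true"] - truth1["u_true"]) % 1.0)
print("common-origin shift", np.round(u, 3), "merge error", round(err, 4))

merged, _ = merge_datasets([ds1, ds2], interval=0.2)
result = find_crystallographic_origin(merged, interval=0.2)
print("crystallographic origin shift", np.round(result.shift, 3))
```

Output:

```
386 reflections, JS = 0.297
common-origin shift [0.963 0.288 0.391] merge error 0.0043
crystallographic origin shift [0.679 0.575 0.672]
```

The 386 retained reflections are 30% of the Friedel-unique set to 3.3 Å;
JS = 0.30 says they are moderately concentrated at low tilt. The estimated
pairwise shift lands within 0.005 (fractional) of the true one — well below
the 0.03 success threshold — and the origin search returns the shift that
puts the merged phases on one of the eight permissible P2₁2₁2₁ origins.

A real-space pipeline (crystal density → tilt series → weighted
back-projection → taper/centering → spot finding → 1D-FFT indexing → peak
extraction) is available through `nanoxtal.pipeline.run_pipeline` and the
`nanoxtal` command-line tool (`simulate`, `process`, `merge`, `origin`,
`simulate-recip`, `sweep`, `metrics`).

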