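# sugarstack

Carbohydrate–aromatic CH−π stacking analysis for structural biologists and
molecular modellers: geometric detection of stacking interactions in
protein–carbohydrate complexes, dataset-level prevalence and enrichment
statistics, and reconstruction/analysis of well-tempered metadynamics
(WT-MetaD) free-energy landscapes over the stacking-orientation collective
variables — validated end to end by a built-in toy Langevin/WT-MetaD
simulator.

## The science

Glycan-binding proteins frequently recognize sugars by stacking the apolar
face of a pyranose ring onto an aromatic side chain (Trp, Tyr, Phe, His).
For a galactose carbon Cn and an aromatic ring with centroid Ctr, two
features describe the contact geometry:

* d(Cn–Ctr) — the carbon-to-centroid distance (Å);
* θ(Proj–Cn–Ctr) — the angle at Cn between the direction to its orthogonal
  projection onto the ring plane and the direction to Ctr (0° directly
  above the centroid, 90° in the plane).

A C–H group forms a **CH−π interaction** when d < 4.6 Å and θ < 50° (strict
inequalities), and a **CH−π stacking interaction** is three or more such
contacts between one sugar residue and one aromatic side chain (both Trp
rings pooled). The orientation of a stack is summarized by two collective
variables,

    CV1 = d(C1–Ctr) + d(C2–Ctr)        CV2 = d(C4–Ctr) + d(C6–Ctr)

so that low CV2 marks stacking through the 3,4,5,6 face of galactose and
low CV1 through the 1,3,5 face. WT-MetaD simulations biased along
(CV1, CV2) log their Gaussian hills to a HILLS file; summing the hills
gives the accumulated bias V(s) and the free energy follows as
F(s) = −γ/(γ−1)·V(s) for bias factor γ.

## Worked example

```python
import numpy as np
from sugarstack import (PoseSpec, make_pose, scan_structure,
                        ToyPotential, MetaDParams, SimParams, run_replicas,
                        bias_potential, fes_from_bias, average_replicas,
                        minimax_path_barrier)
from sugarstack.fes_analysis import make_axis

# 1. detect a stacking interaction in a synthetic galactose/Trp pose
model, _ = make_pose(PoseSpec(ring_type="TRP6", face="axial-3456", offset=3.6))
report = scan_structure(model)
s = report.stackings[0]
print(s.face_label, s.n_contacts, round(s.cv1, 2), round(s.cv2, 2))
# -> 3456 4 10.47 7.74

# 2. recover a known 5 kcal/mol barrier from three toy WT-MetaD replicas
pot = ToyPotential.double_well(h=5.0)
runs = run_replicas(pot, MetaDParams(pace=250, w0=0.5, sigma=(0.15, 0.15)),
                    None, SimParams(n_steps=200_000, seed=1), n_replicas=3)
ax = make_axis(-2.6, 2.6, 0.05)
fes = average_replicas([
    fes_from_bias(bias_potential(r.hills, ax, ax), 20.0, ax, ax,
                  energy_unit="kcal/mol") for r in runs])
half = len(ax) // 2
left = np.unravel_index(np.argmin(fes.values[:half]), (half, len(ax)))
r_ = np.unravel_index(np.argmin(fes.values[half:]), (len(ax) - half, len(ax)))
right = (r_[0] + half, r_[1])
barrier = minimax_path_barrier(fes, left, right) - fes.values[left]
print(round(float(ax[left[0]]), 2), round(float(ax[right[0]]), 2),
      round(float(barrier), 2))
# -> -1.0 1.0 5.01
```

The first block reports the stacking face (carbons 3,4,5,6), the number of
passing contacts, and the orientation CVs of the pose. The second block
runs three seeded Langevin/WT-MetaD replicas on an analytic double well
whose true barrier is 5 kcal/mol, rebuilds the free-energy surface from the
HILLS the runs wrote, and recovers the minima at CV1 = ±1 and the barrier
to ~0.01 kcal/mol of the analytic value.

A `sugarstack` command exposes the same pipelines from the shell:
`sugarstack scan <structure.pdb>`, `sugarstack dataset <metadata.tsv>`,
`sugarstack fes <HILLS...>`, `sugarstack toysim`, and
`sugarstack fixtures <dir>` to regenerate the synthetic fixture set.

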