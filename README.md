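# memborient

Trajectory analytics for membrane-bound proteins whose extracellular domain
reorients on the bilayer surface — the situation of voltage-gated sodium
(Na_v) channel β subunits, whose immunoglobulin-like (Ig) extracellular
domain is tethered to a single transmembrane (TM) helix and can lie flat on
the membrane, stand upright, or anything in between, and whose copies
oligomerise into higher-order clusters in crowded coarse-grained membranes.

The package provides, as a library and a CLI:

* **Rigid-body domain orientation.** Per frame, the mass-weighted moment of
  inertia tensor of a selected domain,

  *I* = Σᵢ mᵢ [(**r**ᵢ·**r**ᵢ) 𝟙 − **r**ᵢ ⊗ **r**ᵢ],  **r**ᵢ relative to the COM,

  is diagonalised, Λ = Uᵀ I U with U = (**p**₁, **p**₂, **p**₃) the principal
  axes (ascending moments, so **p**₁ is the long axis). The direction-cosine
  matrix between the axes and a reference basis is decomposed into intrinsic
  Z-Y′-X″ Tait-Bryan angles (yaw, pitch, roll). Pitch 0° means the domain
  long axis lies in the membrane plane; ±90° means it points along the
  membrane normal. Eigenvector signs are made continuous frame-to-frame.
* **TM-helix tilt**: arccos(|axis·n̂|) ∈ [0°, 90°] against the membrane
  normal (default +z), with a bias-free helix-axis estimator.
* **Contacts**: residue-resolved protein–lipid occupancy (side-chain COM
  within 5 Å of a headgroup phosphorus; coarse-grained first-side-chain-bead
  within 6.5 Å of typed headgroup beads) and inter-copy protein–protein
  contact probability with a strict > 2.5 % reporting mask.
* **Oligomer clustering**: per-frame single-linkage components of the
  copy-contact graph, cluster-size evolution, and down/intermediate/up
  classification of the Ig domain by pitch.
* **Lipid RDFs** around the protein with ideal-gas normalisation (analytic
  shells for a COM reference, seeded Monte-Carlo accessible-volume
  estimation for a protein-surface reference).
* **Synthetic ground-truth scenes** (rigid bodies on programmed angle
  schedules, ideal tilted helices, bilayer surrogates, planted oligomer
  scenes) so every stage is testable end-to-end without simulation data.

Internally everything is nm / ps / amu / degrees; PDB ångströms and
Å-tagged config cutoffs are converted once at the I/O boundary.

## Worked example

Generate a 100-frame synthetic rigid body whose pitch ramps 0→60°, then
recover the schedule with the orientation analysis:

```sh
memborient simulate --scene rigid-body --n-frames 100 --seed 42 --out-prefix body
memborient orient --topology body.gro --trajectory body.xtc \
    --selection "resname BOD" --out-prefix orient_out
head -4 orient_out_angles.csv
```

```
time_ps,yaw_deg,pitch_deg,roll_deg,gimbal_lock,run
0.0,0.15918261631117664,-0.022298712932219824,-0.083008165725336,False,0
100.0,0.1591722653636622,0.5835491342272995,-0.08000555217672424,False,0
200.0,0.1589407615125462,1.1896421770306276,-0.07999852677170669,False,0
```

The programmed schedule steps pitch by 60/99 ≈ 0.606° per frame; the
recovered pitch column tracks it to well under 0.1° (the residual comes
from the 10⁻³ nm XTC coordinate precision). `orient_out_hist.csv` holds the
pooled probability-normalised histogram (each of the 100 frames carries
mass 0.01 at the default 1° binning):

```
 bin_left_deg  bin_right_deg  bin_center_deg  probability
         -1.0            0.0            -0.5         0.01
          0.0            1.0             0.5         0.01
          1.0            2.0             1.5         0.02
```

`orient_out_heatmap.csv` is the machine-readable run × time pitch grid, and
every stage writes a JSON provenance record (inputs, parameters, seed,
version, wall time).

The same workflow runs from a single declarative config over replicas:

```sh
memborient run --config pipeline.yaml
```

with stages `orient`, `tilt`, `rmsd`, `dihedrals`, `mindist`,
`lipid_contacts`, `protein_contacts`, `cluster`, `rdf`; all cutoffs carry
explicit unit tags (`"5 A"`, `"0.65 nm"`).

### Selection mini-language

`select(topology, expr)` supports `segment A`, `resid 153-189`,
`resname POPC GM3`, `name P N`, `index 0-99`, `all`, combined with
`and` / `or` (`and` binds tighter) and a leading `not`. The strings used
by the bundled analyses look like `"segment A and resid 153-189"` (the TM
helix of one chain) or `"name P"` (headgroup phosphorus markers).

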