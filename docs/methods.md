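# Methods

## Domain orientation from the inertia tensor

The orientation of a quasi-rigid protein domain is tracked through the
mass-weighted moment-of-inertia tensor of a fixed atom selection,

I = Σᵢ mᵢ [(rᵢ·rᵢ) 𝟙 − rᵢ ⊗ rᵢ],

with rᵢ taken relative to the mass-weighted centre of the selection at
that frame. The selection should be the domain's secondary-structure core
(β-sheets and 3₁₀ helices for an Ig fold): flexible loops add orientation
noise without carrying orientation information. Selections are supplied as
explicit residue ranges in the config; there is no per-frame secondary
structure assignment, because the domains analysed here have a fixed
structural annotation.

Diagonalisation Λ = Uᵀ I U (NumPy `eigh`) yields the principal axes as the
columns of U. Moments are ordered **ascending**, so p₁ — the axis about
which the mass is most elongated — is the domain long axis. The tensor
fixes eigenvectors only up to sign, so axes are signed by:

1. first frame: pₖ·eₖ ≥ 0 against the reference basis, ties broken toward
   +e_z, then handedness det(U) = +1 enforced by flipping p₃;
2. subsequent frames: pₖ·pₖ(t−1) ≥ 0; if that leaves det(U) = −1 the axis
   with the weakest continuity signal (smallest |dot|) is flipped.

Without this, pitch time series show spurious ±180° jumps. Near-degenerate
moment pairs (relative gap < 1e−6, configurable) are flagged with a
warning — axes are still returned but are ill-conditioned (a spherical
body has no preferred axes).

The direction-cosine matrix R_jk = e_j·pₖ against the reference basis is
decomposed as intrinsic Z-Y′-X″ Tait-Bryan angles: R = Rz(yaw)·Ry(pitch)·Rx(roll),
with pitch = −asin(R₃₁) ∈ [−90°, 90°] and yaw, roll ∈ (−180°, 180°]. At
|pitch| = 90° yaw and roll degenerate into one in-plane rotation; by
convention roll ≔ 0, yaw absorbs the remainder, and the output is flagged
`gimbal_lock`. Any convention consistent with the composition contract
would do — pitch, the physically reported angle, is unaffected.

Two reference modes exist because both are legitimate: `standard_basis`
measures absolute lab-frame angles (membrane normal = +z), `first_frame`
measures reorientation relative to the starting pose (frame 0 is (0,0,0)
by construction). Neither is privileged; histograms keep the signed pitch
by default with an optional |pitch| fold, since folding discards the
up/down distinction and should be a conscious choice.

Replica pooling: the default histogram concatenates frames (every frame
equal weight); a per-replica mode averages per-run histograms instead. The
two coincide exactly when replicas have equal frame counts and can differ
otherwise — both are exposed so either convention can be matched.

## Helix tilt

Tilt is arccos(|axis·n̂|) folded into [0°, 90°]; the membrane normal
defaults to +z (all systems here are planar bilayer patches; no local
normal estimation). The helix axis is the principal component of the
backbone trace after a boxcar smoothing pass spanning 18 Cα steps — one
full cycle of the ~100°/residue α-helical twist. Raw PCA of helix
coordinates carries a finite-length bias of order (radius/length): the
helical circle does not average out over a non-integer number of turns,
displacing the principal component by a few tenths of a degree at
transmembrane-helix lengths (measured: 0.3–0.5° at 30–40 residues). The
one-period boxcar cancels the circular component exactly — on an ideal
helix of ≥ 19 residues the estimator is exact to machine precision — while
also averaging coordinate noise. Below 19 backbone atoms raw PCA is used
and accuracy degrades; 8 atoms (two turns) is the hard minimum.

## RMSD and dihedrals

Cα RMSD uses the Kabsch SVD superposition restricted to proper rotations,
against a chosen reference frame; per-subset series (whole protein / TM
residues / extracellular domain) are plain selections, and replica
averaging reports mean ± one standard deviation per frame. Backbone φ/ψ
follow the IUPAC sign convention via the atan2 formulation; terminal or
incomplete residues yield NaN entries flagged `undefined` rather than
errors, and collinear bond geometries (dihedral undefined) give NaN.

## Contacts

Atomistic protein–lipid criterion: a residue touches the membrane in a
frame when the heavy-atom mass-weighted COM of its side chain is within
0.5 nm of a lipid headgroup phosphorus. Hydrogens are excluded (the
heavy-atom COM is the stable convention); glycine, which has no side-chain
heavy atoms, is probed at Cα and flagged. Coarse-grained criterion: first
side-chain bead within 0.65 nm of the typed headgroup bead, one occupancy
series per lipid type (POPC/POPE/Sph/GM3/CHOL/POPS/PIP2).

All contact comparisons are **strict** (`distance < cutoff`) and all
distances use the minimum image in x, y, z. Neighbour searches run on a
periodic k-d tree (`scipy.spatial.cKDTree`); because `query_ball` is
inclusive at the radius, candidates are re-filtered with the strict
comparison, and the whole path is validated against a dense all-pairs
oracle in the tests. Protein–protein contact probability marks a residue
in contact when any of its particles is within the cutoff of any particle
of a *different* copy; the reporting mask keeps residues strictly above
2.5 % of total time, computed over pooled frames of all replicas (pooling
equals the per-replica mean for equal-length replicas). The
protein–protein cutoff default of 0.65 nm reuses the CG headgroup cutoff —
an assumption, exposed as a parameter.

## Clustering

Per frame, copies form a graph with an edge when any particle pair of two
copies is within the cutoff (minimum image); clusters are the connected
components (single linkage). Single linkage over full particle sets rather
than COM–COM distance is deliberate: fibril-like end-on chains
(tip-to-base contacts between elongated copies) are exactly the geometry a
COM criterion misses. Cluster ids are deterministic (lowest member index)
so time-series outputs diff cleanly. Optional temporal smoothing applies a
centred majority vote (the boolean median) over a window to each pair's
adjacency series before components are re-derived; a partition itself has
no median, so smoothing the adjacency is the well-defined counterpart that
suppresses single-frame touch events. Window 1 (default) disables it.

Ig-domain states classify |pitch| as down (< 20°), intermediate
(20–60°, inclusive at both bounds), or up (> 60°). The thresholds are
package defaults — representative poses, not literature-derived values —
and are configurable.

## Radial distribution functions

g(r) counts lipid reference beads in distance shells around the protein,
normalised so a uniform ideal gas gives 1. With a COM reference the shell
volumes are analytic (4πr²dr) and r_max is capped at half the smallest box
edge, where the minimum-image shell is still spherical. With the default
protein-surface reference (distance to the nearest protein particle —
appropriate because a 36-copy protein assembly is not a point) analytic
shell volumes are wrong; accessible shell volumes are instead estimated by
seeded Monte-Carlo sampling of the box, binning uniform samples by their
own surface distance. The estimator satisfies a counts-closure identity
(Σ g·ideal-counts = total counted neighbours) that the tests verify to
better than 1 %. Statistical accuracy of g(r) in a bin is set by its
expected count; the narrow default bins (0.02 nm) are for resolving contact
structure, while uniformity checks use coarser bins so each holds
thousands of counts.

## Synthetic scenes

The generator writes standard GRO/XTC files that the package's own readers
accept unchanged, plus ground-truth CSV sidecars sufficient to score every
analysis without re-deriving truth. All randomness flows from one seed;
output is byte-identical across runs.

* **Rigid body**: a Gaussian cloud with distinct spreads (default
  3.0/1.5/0.8 nm, 500 particles, masses U[10,16] amu), pre-rotated into
  its own principal frame so the per-frame rotation schedule
  Rz(yaw)·Ry(pitch)·Rx(roll) *is* the ground truth the orientation
  analysis must recover. An isotropic body with a non-zero schedule is
  rejected — its angles are unobservable.
* **Ideal helices**: Cα traces with 0.15 nm rise and 100°/residue twist;
  a full N/Cα/C backbone variant is built atom-by-atom from canonical bond
  lengths/angles and requested (φ, ψ, ω), making recovered dihedrals exact
  by construction. Tilt requests outside [0°, 90°] are rejected (tilt is
  unsigned by definition).
* **Bilayer surrogate**: two jittered planar lattices of typed headgroup
  markers at ±2 nm from the box mid-plane, default composition
  POPC(40):POPE(10):Sph(15):GM3(10):CHOL(25) upper /
  POPC(10):POPE(40):POPS(15):PIP2(10):CHOL(25) lower — a generalised
  mammalian plasma-membrane mixture. Phosphate-bearing types carry a "P"
  site; POPC additionally a choline-like "N" site 0.1 nm outward.
* **Multi-copy scenes**: 4-bead rods with distinguishable base/tip, chained
  end-on within planted clusters (tip↔base gap 0.4 nm < cutoff) and
  separated between clusters and across periodic images by ≥ 2× cutoff.
  Static mode freezes the planted partition as truth at every frame; drift
  mode adds independent per-copy random walks with truth guaranteed only
  at frame 0.

What the generators do **not** emulate: physical dynamics (no force field,
no autocorrelated motion — noise is i.i.d. isotropic Gaussian per particle
per frame), lipid diffusion, membrane undulation or local bending, and
conformational flexibility within a copy. Passing tests therefore
demonstrate estimator correctness and convention consistency on known
ground truth, not the biological conclusions one would draw from real
trajectories. Scene scales default to desk size (≤ 5,000 particles,
≤ 500 frames; the statistical checks use up to 10⁴ beads × 100 frames) so
the full suite runs in seconds.

## Numerical choices

* Internal units nm/ps/amu/degrees; conversions only at I/O and config
  parse (`"5 A"` → 0.5 nm).
* Orthorhombic boxes only; triclinic input raises an explicit error.
* Inertia tensors are symmetrised after accumulation to remove float
  noise; degenerate point sets (collinear clouds) are rejected.
* Gimbal-lock threshold: |sin(pitch)| ≥ 1 − 1e−9.
* Contact boundary: strict `<`; threshold mask: strict `>`. Fixtures avoid
  exact-boundary values, which are float-representation-sensitive.
* Heat-map tables resample replicas to the first run's time grid by
  nearest frame.
* CG beads without usable masses fall back to 1 amu with a warning (GRO
  files carry no masses; bead names are not element symbols).

## Known limitations

* No triclinic periodicity, velocities, bond topology, or on-the-fly
  trajectory alignment.
* Helix-axis accuracy degrades below 19 backbone atoms (one full discrete
  twist cycle).
* The surface-mode RDF normalisation is Monte-Carlo and carries sampling
  noise set by `mc_samples`; the seed is recorded in provenance.
* Contact kinetics (on/off rates, residence times) and depletion–
  enrichment indices are out of scope.
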