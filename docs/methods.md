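# Methods

This note records the modeling and numerical choices behind `scalasim`, and
the known limits of the default coarse configuration.

## Physical model

Stimulation currents in the inner ear are small and slow enough that the
quasi-static approximation holds: the potential satisfies the volume-conduction
equation ∇·(σ∇V) = 0 with piecewise-constant isotropic conductivities. A
contact injects a fixed current (34 µA by default) and the outer boundary of
the bone block is the ground (V = 0). The electrode-to-ground impedance of a
contact is Z = V_contact / I.

Default conductivities (S/m): scala tympani (perilymph) 1.43, cochlea wall
0.3, basilar membrane 0.0125, spiral ligament 1.67, stria vascularis 0.0053,
spiral ganglion 0.33, artery 0.32, bone 0.0156, silicone carrier 1e-7.

The stria vascularis is a ~30 µm, poorly conducting sheet. Meshing it as a
solid would force sliver elements, so it is treated as a thin-layer
(contact-impedance) interface: mesh nodes are duplicated across the surface
and the potential jump satisfies σ_layer/t · [V] = j_n. Scaling σ_stria or
the thickness therefore acts on the solution without remeshing.

## Geometry

The cochlea is a parametric conical-helix duct (2.5 turns by default): an
elliptical scala tympani cross-section that tapers toward the apex, wrapped by
a cochlea-wall shell, a basilar-membrane sector on top, a spiral-ligament +
stria sector on the lateral side, all embedded in a bone block whose outer
surface is the ground. The electrode array is a silicone carrier swept along
an offset of the duct centerline, with 16 rectangular contacts (E1 apical …
E16 basal) facing the +x direction of the local cross-section frame — the
direction of the modiolar wall. In-plane carrier placements are parameterized
on a 12 × 12 grid with equal spacing d along both axes; candidates whose
carrier would touch or cross a bounding layer are flagged invalid and are
never solved. The grid is anchored so that the mid-scala placement (0, 0) is
a member, and its deep extreme along +x lies on the side the contacts face,
so the "toward the wall" ray is sampled up to ~9 µm clearance.

## Discretization and solver

The mesher is a structured swept-tet generator: each cross-section is an
annular ring stack on a shared angular grid, stations are marched along the
arc length with curvature-limited spacing, and each hexahedral cell is split
into tetrahedra with globally consistent diagonals, which makes the mesh
deterministic (bit-identical across runs) and conforming. Radial bands can be
geometrically graded inward or outward; the disk-contact validation relies on
inward grading to resolve the contact-edge singularity.

Elements are linear (P1) only; accuracy is obtained by h-refinement.
Contacts are driven as floating equipotential surfaces carrying a prescribed
net current, implemented by a master–slave reduction (each contact collapses
to one degree of freedom), which keeps the system symmetric positive
definite. A uniform-current-density contact model is also available; on this
geometry it yields impedances ~10–19% above the equipotential model, the
expected ordering since the equipotential (complete-electrode-style) contact
is the energy-minimizing current distribution. The default linear solver is a
sparse LU factorization reused across right-hand sides; conjugate gradients
with an ILU preconditioner is available and agrees with the direct solve to
the requested tolerance.

Current conservation is checked with the Galerkin-consistent reaction flux
(the stiffness residual restricted to a labeled surface), which balances the
injected current to solver tolerance; raw element-gradient fluxes converge
only with refinement and are reported separately.

## Validation

There is no anatomical (µCT) reference model here, so validation replaces
anatomical comparison with closed-form oracles, each exercised as a
convergence study with Richardson extrapolation and an observed order:

- 1-D bar (uniform axial field): exact for P1 up to round-off; tolerance 1%.
- Concentric spheres on cubed-sphere shell meshes: ~0.5% at the default
  resolution, observed order ≈ 2; tolerance 2%.
- Disk contact on a half-space (spreading resistance 1/(4σa)): the edge
  singularity limits uniform meshes, so the study uses edge-graded bands and
  clustered axial stations; ~4% at the finest default mesh, observed order
  ≈ 1; tolerance 5%.

Current-driven FEM underestimates impedance on under-resolved meshes (the
trial space constrains the current paths), which is visible in all three
studies' approach from below.

## Known limits of the coarse default

- Near-wall rise: moving the carrier from mid-scala toward the wall raises
  the basal-contact impedance monotonically, but the rise at the last valid
  sample is ≈1.4× at the coarse preset and ≈1.4–1.5× under θ/axial/radial
  refinement — below the 2× acceptance threshold asserted in
  `tests/test_acceptance.py::test_qualitative_trends`, which is therefore an
  expected failure. Root causes, in order of weight: (1) the last valid grid
  sample still leaves ~9 µm of perilymph plus a conductive spiral-ligament
  path behind the wall, so the constriction resistance saturates; (2) the
  carrier cross-section is small relative to the duct, so even at the
  extreme offset most of the contact face sees open perilymph; (3) the
  equipotential contact redistributes current away from the constricted
  side. The threshold was not relaxed to fit the model.
- At the coarsest preset the apical contact E1 shows a small non-monotone
  dip at the extreme offset that vanishes under refinement; the acceptance
  assertion uses E16, where the profile is monotone at all tested
  resolutions.
- Meshes beyond ~4×10⁵ elements are possible but approach the memory budget
  of a small (8 GiB) machine with the direct solver; use `method: cg` there.
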