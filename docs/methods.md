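# Methods

This note records the models, conventions, and design choices behind
`waxpore`, in the spirit of the methods documentation that simulation
analysis packages ship alongside their code.

## The wax model

The epicuticular wax is represented as a crystalline slab of all-trans
alkane chains on an orthorhombic lattice. Real epicuticular waxes are
mixtures (alkanes, esters, fatty alcohols and acids), but ≥97% of their
carbon inventory is CH₂/CH₃, so a pure-alkane crystal captures the
geometry and hydrophobicity of the barrier. The subcell is the
polyethylene-type orthorhombic cell — a = 0.742 nm, b = 0.496 nm, two
chains per subcell in a herringbone arrangement with setting angles
±45° — standard crystalline-alkane values consistent with the X-ray-derived
structures the model is based on.

Chains are united-atom: one site per carbon, CH₃ at both ends, CH₂ in
between. Because the wax is frozen in the simulations this package
supports, only geometry, labels, and formal charges matter; an all-atom
representation would add nothing the analyses read. The all-trans backbone
uses a C–C bond of 0.154 nm and a C–C–C angle of 114°, giving a per-carbon
axial rise of 0.154·sin(57°) = 0.129 nm and a C30 backbone extent of
29 × 0.129 ≈ 3.75 nm.

**Layer pitch.** The literature quotes a layer thickness of "about 4 nm"
for 30-carbon chains and a pore depth of 15 nm spanning four layers; those
two statements are mutually inconsistent (4 × 4 = 16). The default layer
pitch is therefore set to 3.75 nm = 15/4, which simultaneously (i) spans
the 15 nm pore depth with exactly four layers and (ii) accommodates the
3.75 nm C30 backbone. It remains "approximately 4 nm" within the precision
of the quoted value.

**Coordinates.** The exposed methyl surface defines z = 0; wax occupies
z < 0 and solution z > 0. Penetration depths are negative, more negative
meaning deeper. Lateral (x, y) directions are periodic; z is not, because
the slab breaks z periodicity.

## Pore carving

A cylindrical pore is carved by whole-chain deletion, never by moving
atoms. Two conventions are offered because a radius and a chain count
cannot generally both be satisfied exactly on a discrete lattice:

* `by_count` (default, authoritative): remove exactly `n_remove` chains
  nearest the pore axis in every layer spanned by the depth, distance ties
  broken by ascending chain id. The default of 14 chains corresponds to an
  accessible radius of roughly 0.75–0.8 nm on this lattice.
* `by_radius`: remove every chain whose axis lies within
  `accessible_radius + methyl_radius` of the pore axis, where the methyl
  van-der-Waals radius is 0.20 nm — i.e. the accessible radius is the
  chain-axis cut radius minus the methyl radius.

The pore depth must be a whole number of layer pitches (±5%); the removal
count is monotone in the cut radius, and carving with `n_remove = 0`
returns the slab unchanged.

## Surface functionalization

Plant cuticles are negatively charged at ambient pH (isoelectric point
≈ 3) because carboxyl groups deprotonate. The builder replaces terminal
CH₃ groups on a chosen face (top, bottom, or pore wall) by COO⁻ (formal
charge −1) or COOH (neutral). The replacement fraction is quoted relative
to **all** CH₃/CH₂ carbon groups in the slab — the convention under which
about 2% replacement matches the experimentally measured bound-Ca²⁺
density — but replacements are realized only at terminal CH₃ sites of the
chosen face. The measured Ca²⁺ surface density itself (2.73 nmol/cm²) is
not converted to a fraction by the builder; the fraction is a direct
input. Note the face-site budget: at 1.5% a single-layer 6 × 6 nm slab
needs 86 sites of the 192 available, while a four-layer slab would need
320 — more than one face exposes — so the charged-surface studies use the
single-layer slab. Selection among sites is uniform-random under a
required seed. Pore-wall sites include the terminal carbons of chains
within one subcell diagonal of the carved pore boundary, including the
pore-wall carbons themselves.

All count conversions round half away from zero.

## Solution composition

Surfactant monolayers are placed at each requested interface with the
molecule count `round(Γ · area · N_A)`; the realized surface excess is
recomputed from that integer, so it differs from the request by at most
one molecule per interface area. Surfactants are coarse bead chains (12
tail beads, 6–11 head beads depending on species, 0.13 nm pitch) oriented
tails-to-wax at the bottom interface and tails-to-air at the top: enough
structure for counting, density, and charge analyses, which is all the
package performs. Full force-field topologies are out of scope.

The AI count follows the molar ratio applied to the surfactant total over
**both** interfaces (8:3 for C₁₂E₆, 1:1 for C₁₂G₁, 5:2 for C₁₂G₂).
Concentrations are interpreted as moles per litre of water with water at
55.5 mol/L, so the water count targeting c_AI = 2.2 mol/L is
`round(n_AI · 55.5 / 2.2)`. When no AI is present the water count is
either given explicitly or chosen to fill the solution region at bulk
density (33.37 nm⁻³). The target c_AI is approximate by construction; the
composition report always carries the value realized by the integer
counts.

Salts (NaCl, CaCl₂, KCl, MgCl₂) dissociate fully; ionic strength is
I = ½ Σ cᵢzᵢ². Counterions (Ca²⁺ by default, appropriate for hard-water
studies; Na⁺ selectable) are added so the total formal charge is exactly
zero. If a divalent counterion cannot neutralize an odd wax charge, one
COO⁻ is protonated to COOH and a warning is logged. H⁺ is never modelled
explicitly: where protons would dominate (NaCl systems), carboxyls are
built as COOH from the start.

Point molecules (water, AI, ions) are inserted on a jittered cubic lattice
whose pitch guarantees the 0.25 nm minimum inter-molecular heavy-atom
separation, shuffled under the composition seed; identical seeds give
bit-identical systems, different seeds change positions but never counts.
Water is a geometry-only 3-site model (O–H 0.09572 nm, H–O–H 104.52°).

## Synthetic trajectories

The generator produces depth kinetics directly from the saturation law
z(t) = −(M₀/B)(1 − e^(−At)) rather than simulating physics: the package
validates analysis and fitting machinery, not force fields. Noise is
i.i.d. Gaussian on depth (no noise model is prescribed by the underlying
experiments). Default conditions mirror the study design: 200 ns spans,
A = 0.02 ns⁻¹, depth scale 3 nm, noise 0.05 nm where noise is wanted.
Times are ns and rates ns⁻¹ throughout; experimental uptake assays run for
hours, and the h⁻¹ conversion (1 ns⁻¹ = 3.6 × 10¹² h⁻¹) is provided but
never applied implicitly.

Pore systems are built from a declarative layout: water clusters as
compact random walks with 0.28 nm O–O steps (below the 0.35 nm clustering
cutoff, so each cluster is one connected component by construction),
distinct clusters kept ≥ 0.6 nm apart (above the cutoff), an optional
bulk slab above the surface, and per-region ion counts. A bulk-connected
cluster is realized by a vertical ladder of waters reaching just above
z = 0. Layouts that cannot keep clusters distinct are rejected rather
than silently merged.

What the generator does **not** emulate: force-field dynamics, thermal
motion of the wax, surfactant conformational behaviour, hydrogen-bond
networks, or the slow approach to steady state. Passing tests therefore
demonstrate that the analysis stack measures what it claims on data with
known ground truth — not that any particular physical system behaves this
way.

## Trajectory metrics

"Inside the pore" means the molecule's centre of mass lies within the
pore cylinder (lateral minimum-image distance to the axis ≤ radius); the
underlying study does not state a lateral gate, and the COM-in-cylinder
rule is the simplest defensible one. Centres of mass are mass-weighted
over all sites; for the 3-site water this is near the oxygen. The deepest-
water depth is the per-frame minimum COM z among waters laterally inside
the pore, averaged over analysed frames; a `discard` fraction (default 0)
allows dropping an equilibration window, since the averaging window is
not specified by the source material. Water clustering uses the O–O
contact graph at a 0.35 nm cutoff — the first-hydration-shell O–O
distance — and a cluster is bulk-connected when it reaches the region
above the surface. Density scans are plain 2-D occupancy histograms over
frames (top view x–y or side view x–z) with conservation of the total
count; per-species pore occupancy counts are read at the final frame by
default, matching the "uptaken in 200 ns" convention.

## Kinetics fitting

The fit minimizes ordinary least squares of |z₀ − z(t)| against
`prefactor · (1 − e^(−At))` (no weighting is prescribed by the source
experiments), with initial guesses prefactor = maximum excursion and
A = 1/(time to half of it), and non-negativity bounds. M₀ and B are not
separately identifiable from a depth trace, so only the lumped prefactor
M₀/B is reported. Flat traces raise a dedicated degenerate-trace error;
non-convergence reports the starting point and sample count. Uptake
fractions ≥ 1 passed to R(t) are an error, never clipped, because the
statistic diverges at complete uptake.

## Free-energy post-processing

Profiles are kT-valued on a strictly monotonic ξ grid; evaluation between
grid points is linear (no rule is stated by the source; linear is the
least-assuming choice). Before every RMSD comparison the global minimum is
shifted to 0 kT, so constant offsets never register. N in the RMSD
formulas is the number of grid points summed over. The penetration
barrier is reported as a magnitude with caller-specified anchors: the
source material's sign and anchor conventions are internally inconsistent
(the printed difference would be negative for an uphill barrier), so the
package does not guess an orientation. Converged adaptive-bias profiles
of this kind carry an uncertainty of roughly ±1.5 kT, and no report
implies precision beyond that.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from a single global seed by hashing, each below 2³¹. The
test and acceptance workloads run at desk scale by design: 6 × 6 nm slabs
(192 chains/layer), hundreds to thousands of solution molecules,
100-replicate Monte-Carlo recovery studies with 2000-sample traces, and
randomized metric-oracle instances of up to 500 molecules over 100 seeds —
sizes at which exhaustive O(n²) oracles remain exact and fast.

## Known limitations

* The builder emits geometry and bookkeeping, not force-field topologies;
  its outputs are starting structures and analysis fixtures, not runnable
  MD inputs.
* Only the (001) methyl surface is built; (100)/(010) orientations,
  mixed-composition waxes, and micrometre-scale roughness are out of
  scope.
* Surface/interfacial tension, solvation free energies, viscosity,
  aggregation, and the free-energy *calculation* methods themselves
  (adaptive biasing, umbrella sampling) are out of scope; the package
  post-processes their converged outputs.
* z-periodicity is never applied; systems are slabs by assumption.
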