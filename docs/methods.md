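# Methods

This note documents the models and numerical choices behind each
analysis, what the synthetic fixtures do and do not establish, and the
places where a design was genuinely open.

## Units and conventions

Å, ns, amu, kJ/mol and elementary charges internally; Lennard-Jones
sigma is kept in nm (force-field convention) and distances are converted
to nm only inside the Coulomb/LJ sums. XTC (nm, ps) and GRO (nm) are
converted at the I/O boundary. Frame and atom indices are 0-based;
author residue numbering is preserved for reporting. Formats without
time stamps (multi-model PDB) get the frame index as time; DCD time
metadata is taken from the reader's notion of the timestep and is
approximate. Waters are recognised by residue name
(HOH/SOL/WAT/TIP3/TIP3P/..., configurable); hydrogens by the element
field with a name-based fallback (leading H after digit stripping).

## Superposition and fluctuation metrics

Kabsch superposition via SVD with reflection correction; collinear
configurations are rejected (the rotation about the line is undefined).
Fits are uniform-weight by default — the common default when fitting on
a plain atom selection — with mass weighting available. RMSD series fit
on one selection and measure on another; RMSF is computed about the
ensemble mean after per-frame fitting to the first frame (or a supplied
reference). No periodic-boundary unwrapping is done anywhere: inputs
are assumed whole.

A caveat the tests respect: a rigid fit removes ~6 degrees of freedom,
so for an M-atom ensemble of pure isotropic jitter the post-fit RMSF is
biased low by roughly 6/(3M) in variance. The √3·σ closed form
therefore describes the *unfitted* ensemble, and the closed-form checks
run with fitting disabled; fitting-specific behaviour is covered by the
rigid-motion invariants instead.

## Essential-dynamics PCA

Frames are superposed on the analysis selection, displacements from the
ensemble mean are scaled per coordinate by √mass (when mass-weighted),
and the population covariance (divide by n_frames, matching the usual
MD tools) is eigendecomposed — directly for coordinate dimension
≤ 5000, otherwise through the frame-space Gram dual with an identical
nonzero spectrum. Eigenvector signs are fixed by orienting the
largest-magnitude component positive, so runs are reproducible;
`flip_pc_sign` recovers presentation parity with plots that negate a
PC. Projections are √w-weighted displacements dotted with eigenvectors;
reconstruction un-applies the weights, so interpolated extreme motions
come out in Cartesian Å. External structures are superposed to the
model's fit reference on the same selection before projecting; no
energy minimisation is applied to them (out of scope, so projections of
un-minimised structures carry their strain).

State clustering runs K-means (k-means++, 10 restarts, fixed seed,
tolerance 1e-6) over the first three PCs for k = 1..k_max and picks the
smallest k whose SSR/SST improvement to k+1 falls below the 2.5%
threshold (SSR = within-cluster sum of squares, SST = total). This
consecutive-drop reading of the elbow rule is pinned by tests. It
cannot return k = 1 for a featureless single Gaussian — the k = 1→2
drop of an isotropic Gaussian is ≈ 0.21 in any dimension ≥ 1 — which is
an inherent property of the rule, not of this implementation; on
genuinely multi-state data it lands on the planted state count.

## Reciprocal-distance pose clustering

Featurization: per frame, the minimum distance between each residue's
heavy atoms (heavy is the default because ligand contacts are mostly
side-chain mediated; main-chain is available) and each ligand
fragment's atoms, reciprocated as 1/max(d, 0.5 Å). The floor bounds the
features at contact and costs nothing in practice — real complexes
never reach 0.5 Å. Features are internal coordinates: rotating or
translating a frame changes nothing, so no superposition (and no mass
weighting) enters the feature PCA. Distances are computed exactly
(squared differences summed then rooted, bit-equal to the naive pair
loop); nothing frames × frames is ever allocated.

Fragments default to a distance-based heuristic: bonds below
1.85 Å (2.1 Å to S/Cl/Br/P), rings found as non-bridge edges, and
acyclic bonds between two non-terminal atoms cut when a side holds a
ring or ≥ 3 atoms. This is a stand-in — published work on specific
inhibitors would use curated fragment lists, which can be passed in
directly as a `FragmentScheme`.

Model selection: K-means over the first three feature PCs for each
candidate k; Silhouette (subsampled at a fixed seed above 5000 frames;
Davies–Bouldin always on full data) recorded per k; chosen k maximises
the Silhouette subject to a Davies–Bouldin rank of 1 or 2, ties to the
smaller k. The rank constraint codifies the published practice of
accepting only clusterings whose DB index is lowest or second lowest;
the visual-inspection component of that practice cannot be automated,
so the rule is deterministic here. If no candidate is admissible (only
possible with degenerate metrics) the result carries status
`no_admissible_k` and no labels, never a silent choice.

Representatives: the cluster's central frame (nearest the centroid in
3-PC space, ties to the lower frame index) plus up to 1000 members
ascending by feature-space distance.

## Gorge radius profiling

The reference structure is rotated so the supplied gorge axis is
parallel to Y; frames are Cα-fitted to it. The axis range (default
2.5–20 Å) is divided into 0.5 Å slices; per slice the largest sphere
centred in the slice plane that avoids all atoms' van der Waals spheres
is sought: pore radius r(c) = min over atoms of (|c − a| − vdW), a
simulated-annealing random walk (Gaussian steps of 0.1 Å, accept on
improvement, step halved after 50 consecutive rejections, 2000 steps),
marching outward from the slice containing the seed point and starting
each slice at its neighbour's optimum. A Nelder-Mead polish of the best
point (default on, `polish=False` restores the raw MC estimate) removes
the residual stochastic error; since every candidate is an exact
pore-function evaluation, reported radii never exceed the true optimum.
Waters and ligand are excluded from the blocking set by default. vdW
radii: explicit per-atom table if present, else Bondi (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20 Å) — slightly different from HOLE's
AMBER-derived defaults, so exact numeric parity with HOLE is not
claimed; the analytic fixtures pin the behaviour instead.

Geometry note: because the sphere is three-dimensional, in a sloped
channel it touches the narrower wall below the slice plane; for a
linear funnel of wall slope b the recovered radius slope is b/√(1+b²),
not b. The channel generator therefore exposes the exact
inscribed-sphere oracle (pore function on the symmetry axis) and the
tests compare against that, not against the in-plane wall radius.

A residue "lines the gorge surface" at a slice when any heavy atom lies
within (radius + vdW + 1.0 Å margin) of the optimal sphere centre; its
axial position distribution is the histogram of those slice heights.

## Water occupancy

One count per water molecule, located by its oxygen (the only heavy
atom of three-site models), strictly below the cutoff (the thresholds
are stated as "< 3.5/3.0 Å", so boundary cases are excluded). The
KD-tree path only preselects candidates; the strict test uses exact
distances, keeping it bit-equal to the brute-force loop. No
periodic-image search by default: gorge sites sit far from box edges;
a minimum-image mode is not needed for the fixture systems and real
wrapped boxes should be made whole upstream. Percent change between
tables is (other − reference)/reference × 100 with a flagged-undefined
result (not an exception) at zero reference.

## Per-residue MM energetics

Vacuum Coulomb with f = 138.935458 kJ·mol⁻¹·nm·e⁻², dielectric 1, and
Lennard-Jones with Lorentz–Berthelot combination, summed over all
intermolecular pairs with no cutoff — the complexes are compact and the
finite sums are exact. Pairs closer than 0.05 nm are treated as clashes
(an error, since such geometries are unphysical inputs). Per cluster,
frames are the members nearest the central structure thinned to
pairwise trajectory-index separation ≥ 20, up to 20 frames ("evenly
spaced by 20 frames" codified as this greedy rule; the phrasing is
ambiguous and the rule is test-pinned). The Poisson–Boltzmann and
surface-area terms of a full MM-PBSA treatment need an external solver
and are deliberately absent; outputs are labelled "MM term" so they are
not read as binding free energies, and charged residues (Asp, Glu, Lys,
Arg, declared protonated His) are reported separately from the
noncharged ≤ −4 kJ/mol contributors because their bare Coulomb terms
are meaningless without solvation screening. Bands: ≤ −10 strong,
≤ −5 favorable, ≤ −4 weak.

## Synthetic fixtures — what a green test establishes

The generators are bit-reproducible from (spec, seed) via explicitly
keyed numpy Generators and return machine-readable truth.

* **Planted poses** (default: 3 poses, equal occupancy, 3000 frames,
  noise σ = 0.2 Å, 50-frame dwell blocks, exact block quotas): a ring
  "protein" of 12 six-atom residues (radius 26 Å) and a three-ring rod
  ligand whose rings the default fragmenter provably recovers. Each
  pose contacts two adjacent residues (< 4 Å) and stays > 8 Å from all
  others. This validates featurization, model selection, label
  recovery, populations and the energetics protocol — not force-field
  realism, solvent effects, or gradual pose exchange.
* **Channels**: atom rings of radius R(y)+vdW at ≤ 0.8 Å spacing, so
  the inscribed radius is R(y) up to ~0.02 Å discretisation; optional
  sinusoidal breathing. Validates the slice search against exact
  oracles; says nothing about rugged, asymmetric protein gorges beyond
  the monotonicity and lower-bound properties, which hold universally.
* **Water boxes**: waters placed in shells with a 0.2 Å guard band
  around every cutoff, per an exact per-frame schedule; occupancies are
  reproduced exactly, so the tests check counting semantics, not water
  dynamics.
* **Harmonic ensembles**: isotropic per-atom jitter about a helix with
  optional planted collective modes orthogonalised against rigid-body
  motions (expected RMSF = √(3σ² + A²|u_i|²)). Validates RMSF and PCA
  recovery; real anharmonic, correlated protein motion is outside the
  model.

## Determinism and provenance

Every stochastic stage takes an explicit seed (K-means restarts,
Silhouette subsampling, MC substreams per frame, generators). The CLI
writes a RunRecord per run whose digest covers command, parameters,
input content hashes, seeds and version — not paths or timestamps — and
stamps it into tabular outputs, so identical runs yield byte-identical
data files.

## Known limitations

No periodic-image handling; no mmCIF; no bond topology beyond the
distance heuristic; external structures are not energy-minimised before
projection; DCD time stamps are nominal; the sequence utility's
alignment convention (Needleman–Wunsch, BLOSUM62, gap 10/0.5, identity
and similarity over all alignment columns, integer rounding) is a
documented choice — the percentages depend on it.
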