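# Methods

This note records the models, conventions, numerical choices and known
limitations behind each stage of the pipeline, in the order the analysis
runs.

## Structure model and selections

Structures are parsed with gemmi and converted to a small hierarchical model
(Atom/Residue/Chain/StructureModel). Author residue numbering is preserved
verbatim — literature residue labels (Cys149, His176, Arg231 …) must match
file numbering, so no renumbering ever happens. Alternate conformations are
reduced to the highest-occupancy conformer at read time (ties resolve to
altloc 'A'); this matters for doubly modelled surface cysteines, where a
single-conformer model keeps all downstream geometry single-valued. Elements
come from PDB columns 77–78 when present and are otherwise inferred from the
atom name. Hydrogens are kept if present in the file but excluded by default
from surface-area and contact analyses, since crystal structures generally
lack them.

The selection language is a small recursive-descent grammar (`chain`, `resn`,
`resi` with ranges, `name`, `element`, `hetero`, `water`, `protein`,
`hydrogen`, boolean operators, parentheses, and `within D of (expr)` backed by
a k-d tree). Malformed expressions raise an error carrying the character
position.

Sequence properties use average residue masses plus one water; the 280 nm
molar extinction coefficient uses the standard chromophore coefficients
(Trp 5500, Tyr 1490, cystine 125 M⁻¹cm⁻¹). Because the cystine convention is
a genuine ambiguity for any cysteine-containing protein, both the free-thiol
and all-cystine values are always reported and the convention used for the
headline value is recorded in the output (default: free thiols, appropriate
for a reduced enzyme).

## Contact geometry

A "polar contact" is any N/O/S atom pair within a cutoff, 3.5 Å by default —
the customary crystallographic reading of hydrogen bonds plus electrostatic
interactions when no hydrogens are available. No donor/acceptor chemistry or
angle scoring is attempted (a deliberate non-goal). Catalytic dyads are
reported for every Cys SG within 4.0 Å of a His imidazole nitrogen; the
default brackets the canonical 3.3–3.4 Å crystallographic range with margin.
The thiol microenvironment lists N/O atoms within 4.5 Å of a given SG,
annotated backbone vs side chain; anion-site mapping lists polar atoms within
3.5 Å of any oxygen of a bound anion (sulfate/phosphate mimics). Neighbor
searches use scipy k-d trees and are validated against brute-force O(n²)
scans in the tests.

## Accessible surface area

Shrake–Rupley with a deterministic golden-spiral lattice — no random points,
so a given (structure, parameters) pair always yields identical numbers.
Defaults: probe 1.4 Å, 960 lattice points per atom, Chothia-style radii
(aliphatic C 1.87 Å, carbonyl/aromatic C 1.76, N 1.65, O 1.40, S 1.85,
P 1.90). The radii table is an explicit, swappable parameter because
published ASA values differ by a few Å² across tools purely through the radii
convention; comparisons to literature values should carry that caveat.
"Thiol ASA" is the ASA of the SG atom alone — the only unambiguous reading
for heavy-atom models. Hetero entities (cofactors, anions) are included by
default and waters excluded, matching the bound-state convention; a `strip`
selection recomputes after removing named entities (e.g. the cofactor) to
quantify how binding shields a thiol. Accessibility classes for the SG:
buried < 1 Å², low < 10 Å², exposed otherwise.

Quadrature error at 960 points is below 0.5% on an isolated sphere and below
~1 Å² per atom against a doubled lattice; because the lattice is space-fixed,
rigid motions perturb individual atom values by up to ~2 Å² on crowded
models. Tests pin all three bounds.

## Superposition

Kabsch via SVD with the determinant correction, so reflections are never
returned; weighted variant available (uniform weights reproduce the
unweighted fit exactly). Collinear point sets warn with the covariance rank.
Residue correspondence uses Biopython's global pairwise alignment of the
modeled sequences and keeps identically typed aligned positions with the
required atoms present in both chains (modes: `ca`, `backbone`, `heavy`); no
outlier trimming by default, since whole-common-set fits are what published
aligned-atom counts refer to. Assembly superposition applies one rigid
transform to the pooled correspondence; `"auto"` chain mapping tries all
sequence-compatible bijections and keeps the minimal rmsd. Crystallographic
symmetry operators are user-supplied inputs to `apply_transform`, never
derived from file headers.

## Binding decomposition (MM/GBSA-style)

Single-trajectory end-point scheme: each frame of the complex ensemble is
evaluated as complex, receptor-alone and ligand-alone *at the complex
geometry*, and ΔE = E(complex) − E(receptor) − E(ligand) per term:

* Coulomb: k_e q_i q_j / (ε_in r_ij), k_e = 332.0636 kcal·Å·mol⁻¹·e⁻², no
  cutoff, ε_in = 1 by default.
* Lennard-Jones 12-6 with Lorentz–Berthelot combination.
* Generalized Born: Hawkins–Cramer–Truhlar pairwise descreening integrals
  with OBC tanh rescaling (α = 1.0, β = 0.8, γ = 4.85, radius offset 0.09 Å —
  the "OBC-II"-style constants, all exposed in `EnergeticsParameters`) and
  the canonical smooth interpolation
  f_GB = sqrt(r² + R_iR_j·exp(−r²/4R_iR_j)), self terms included,
  ε_solv = 78.5. The descreening integral is verified against direct
  numerical quadrature in the tests, the Born single-ion limit is exact, and
  Coulomb + GB of a far-separated pair reproduces the 1/ε_solv screened
  interaction to <1%.
* Nonpolar γ·ΔSASA (γ = 0.0072 kcal/mol/Å²) is available but off by default:
  the per-residue motif is electrostatics-dominated, and the term adds
  quadrature noise to every row.

Attribution: Coulomb/LJ cross pairs go to the receptor residue involved. GB
energies are split per atom (half of each pair term to each partner), and
each atom contributes the *difference* of its per-atom energy between complex
and its separated state; ligand atoms accumulate into an explicit ligand row,
hetero entities into entity rows. This makes the table sum to the exact frame
total (residual < 1e-6 kcal/mol, asserted per frame). Entropy terms are out
of scope. Charges/LJ/GB radii are inputs via a TSV charge topology — no
parameter assignment or charge fitting happens here.

## Barrier fingerprint

The reacting subsystem (QM region) is given twice — reactant and transition
state — each with its own geometry and point charges (total charge must be
conserved across states; this is validated). For every environment residue
with any atom within 5 Å of any QM atom in either geometry (whole residues
included; cofactors appear as their own rows), the vacuum Coulomb interaction
with the QM charges is evaluated in both states; ΔΔE = E_TS − E_reactant,
negative = stabilizes the transition state = lowers the barrier. ε_in = 1,
matching a QM-charge perturbation analysis; neutral band ±0.1 kcal/mol for
the stabilizing/destabilizing call. Environment atoms coinciding with QM
atoms (< 1e-3 Å) are excluded to avoid double counting. Both state-specific
geometries (default) and a fixed-geometry charge-swap mode are provided,
since either protocol is defensible; the default evaluates each state in its
own geometry. Fingerprint additivity over disjoint environments, cutoff
monotonicity, and agreement of the full-environment row sum with the direct
double sum are all asserted.

## Ensemble mobility

Frames are Kabsch-fitted on a protein heavy-atom selection (reference: the
running mean after one bootstrap fit to frame 1; option: first frame). A
moiety's mobility is the RMS fluctuation about the per-atom mean position,
pooled over the moiety's atoms; the whole-ligand value is therefore exactly
the atom-count-weighted quadratic mean of the per-moiety values. No mass
weighting. For iid isotropic Gaussian displacements of amplitude σ per
coordinate the statistic converges to √3·σ (up to the (1−1/F) mean-removal
factor), which is what the recovery tests exploit.

## Synthetic data

The toy site is a set of minimal idealized residue fragments — not rotamers,
and deliberately not force-field-realistic — placed so that every designed
interaction distance is exact: Cys149 thiolate (SG at the origin, net −1),
protonated His176 (NE2 at 3.30 Å, net +1), Thr150 backbone N at 3.25 Å, a
Ser148 hydroxyl dipole with its proton 2.20 Å from the SG, a glutathione-like
γGlu–Cys(NO)–Gly tripeptide (net −1) whose sulfur sits 5.0 Å from the
thiolate along the NO-transfer axis, its γ-glutamyl carboxylate anchored to
His ND1 (2.85 Å) and to a bifurcated Arg231 guanidinium, a second arginine
near the S···S axis slightly closer to the ligand sulfur, and an optional
di-anionic phosphate-like cofactor mimic. The 5.0 Å S···S separation is a
representative pre-reaction near-attack distance and lets the reaction-state
NO interpolate to the exact S···S midpoint without steric collapse. A clash
check (no inter-residue pair < 1.8 Å, covalent tripeptide links exempt) runs
at generation time. Reaction states put the full −1 on the protein sulfur
(reactant), mirror it (product) and interpolate charges linearly at λ
(default 0.5), conserving total charge; TS geometry moves the NO along the
transfer axis, reaching the midpoint at λ = 0.5.

Ensembles add iid isotropic Gaussian displacements per moiety (selection
expression → σ) plus optional global rigid-body jitter that the fitting stage
must remove; identical spec + seed reproduces artifacts byte for byte (one
`numpy` Generator per artifact, seed recorded in the PDB header remark).

What the generator does *not* emulate — and hence what passing tests do not
show about real data: force-field-quality charges and geometries, anisotropic
and correlated thermal motion, conformational transitions, solvent structure,
and real MD snapshot statistics. The tests demonstrate that the analysis
machinery is correct, not that real trajectories would yield these numbers.

## Problem sizes

The synthetic site has 58 atoms; decomposition runs use 25-frame ensembles
and mobility runs 1000 frames with 100 seeded replicates for the ordering
statistic — sizes chosen so the entire suite plus the acceptance script
completes in well under a minute while keeping all sampling-based assertions
(5% on √3·σ, two-SEM stride checks) comfortably powered.

## Known limitations

* Accession-based analyses (deposited crystal structures) exercise the same
  code paths but are not part of the test suite, which is fully synthetic.
* Contact categorization ("salt-bridge-candidate") recognizes standard
  residue names only; nonstandard ligands fall back to "polar".
* GB is a single fixed variant (OBC-style); ion screening, variable internal
  dielectrics and PB cross-checks are out of scope.
* The SASA lattice is space-fixed, so values carry a small orientation
  dependence (bounded in the tests); no Gly-X-Gly relative normalization.
* The fingerprint treats the environment as fixed point charges of a single
  frame; polarization and geometric relaxation of the environment between
  states are not modelled.
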