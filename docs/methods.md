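# Methods

This note records the models and procedures ptpkit implements, the
assumptions behind them, the defaults that matter, what the synthetic
generators do and do not emulate, and the numerical choices made where
the design was genuinely open.

## Containers and conventions

Coordinates are Ångström throughout. Residue numbering is the author
(PDB) numbering, 1-based, never renumbered. Trajectories are exchanged
as multi-model PDB only; binary formats (DCD/XTC) are a documented
extension point, not supported. Water residues are recognised by name
(`HOH`, `WAT`, `SOL`, `TIP3`), and the water probe atom is the oxygen
(atom name starting with `O`). All distance-cutoff comparisons are
inclusive (≤). Every CLI run writes a provenance record (inputs,
parameters, seed, package version) next to its outputs.

## Chimeric shuffling

A chimera is sampled column-by-column from an equal-length alignment:
a single-state column contributes its residue deterministically; a
multi-state column contributes one state drawn **uniformly over the
distinct states**, not weighted by occurrence. The uniform-over-states
reading is the package default because "unweighted" selection most
naturally means each observed residue type is equally likely; an
occurrence-weighted mode (`weighting="occurrence"`) is provided for
sensitivity comparisons, since the column profile can also be read as an
empirical posterior over sequences. Gap handling is likewise a policy
parameter: by default a gap is a selectable state (`selectable`); under
`excluded` gaps are removed from the state set before drawing and an
all-gap column emits a gap. Both modes are tested. The emitted sequence
strips gaps; per-column choices retain them so identity and substitution
accounting stay in alignment coordinates.

Percent identity is computed on the *given* alignment (matches over
columns where both sequences are non-gap); the package never re-aligns,
so identities derived from external alignment heuristics are reproduced
in kind, not bit-exactly.

## Dihedral-space loop analysis

φ and ψ follow the standard definitions
(φᵢ = dihedral(Cᵢ₋₁, Nᵢ, CAᵢ, Cᵢ), ψᵢ = dihedral(Nᵢ, CAᵢ, Cᵢ, Nᵢ₊₁));
terminal residues lacking a neighbour are dropped with a warning.

The loop-conformation similarity between a frame and a reference is

    angleRMSD = (1/N) Σᵢ sqrt(Δφᵢ² + Δψᵢ²)

with every angle difference wrapped into (−180°, 180°] **before**
squaring — mandatory for a periodic quantity, otherwise a 1° physical
change across the branch cut would register as ~359°. The aggregation is
genuinely ambiguous between "mean of per-residue norms" and "root mean
square over all angles"; the default is mean-of-norms (it reads most
directly as a per-residue average), and the RMS variant is selectable
via `method="rms"`. Both are tested against independent brute-force
oracles; the metric is a pseudometric (symmetric, zero on identical
frames, invariant to adding full turns) with range [0, 180·√2].

Frames are classified by nearest reference; exact ties go to the
first-listed reference and are flagged. Loop residue ranges are config
inputs — no residue enumeration is hard-coded, because loop definitions
vary between structures and studies.

RMSF is computed about the time-mean position, optionally after a
Kabsch fit of every frame's Cα set to the first frame (the default
superposition target; configurable). Backbone RMSD (N, CA, C, O) is
computed after optimal least-squares superposition on a fit selection
that defaults to the analysis selection; the Kabsch implementation is
validated against an independent quaternion-method oracle.

`reference_crosscheck` reports pairwise angleRMSD and superposed
backbone RMSD matrices for a set of reference structures. With
user-supplied deposited crystal structures this reproduces the kind of
loop-state comparison reported for archaeal PTP P-loops (backbone RMSD
≈ 0.4 Å between active and inactive states; angleRMSD of intermediates
to the end states of order 70–100°); those printed values depend on the
exact residue set and aggregation chosen and are therefore approximate
cross-checks, not gated tests. The test suite exercises the same code
path on synthetic reference backbones.

## Hydration and grid integration

Hydration is the per-frame count of water oxygens within a probe sphere
(default radius 5 Å) centred on a named atom — typically the
nucleophilic cysteine Sγ — summarised as a histogram and tail
probabilities P(count ≥ k). The bridging-water criterion asks whether
any water oxygen lies within a cutoff (default 3.5 Å) of **both** a
carboxylate oxygen of a candidate acid and the phosphorus of the
phosphoenzyme intermediate; occupancy is the % of frames with at least
one such water, and is bounded above by each single-distance occupancy.

Scalar solvation free-energy grids are consumed (plain-text x/y/z/value
table plus a JSON sidecar with origin, spacing, dims), never produced.
Sphere integration sums values over voxels whose **centres** lie inside
the sphere — the simplest defensible membership rule; partial-volume
weighting is deliberately not attempted because upstream integration
conventions vary and are rarely stated. The implementation is tested
for exact equality with a triple-loop voxel scan. The voxel count and
sphere-coverage fraction are reported alongside the integral so
truncation at grid edges is visible.

## Interaction census

The census substitutes documented geometric criteria for external
interaction-network software whose detection rules are not published;
results are comparable in kind, not bit-compatible. Criteria (all
cutoffs config-exposed): hydrophobic contact — side-chain carbon pair
≤ 4.5 Å between residues of {A,V,L,I,M,F,W,P} with sequence separation
≥ 2 (excludes trivial neighbours); salt bridge — basic side-chain N
(Arg NH1/NH2/NE, Lys NZ, His ND1/NE2) ≤ 4.0 Å from acidic carboxylate O
(Asp/Glu); His is treated as potentially cationic regardless of
protonation and this is flagged in the documentation because structures
rarely resolve protonation; side-chain hydrogen bond — side-chain N/O
donor–acceptor ≤ 3.5 Å, with a D–H···A ≥ 120° requirement when the donor
carries an explicit hydrogen (in a residue with explicit hydrogens, a
heavy atom with none attached is acceptor-only; the distance-only
fallback serves hydrogen-free crystal structures), salt-bridge pairs
excluded so the two censuses stay disjoint; cation-π — cationic-group
centroid ≤ 6.0 Å from an aromatic ring centroid.

Helix content uses a dihedral window (φ ∈ [−100°, −30°],
ψ ∈ [−80°, −5°]) plus a ≥ 4-consecutive-residue run rule, over residues
with defined dihedrals; runs break across chains and numbering gaps.
Hydrogen-bond-pattern secondary-structure assignment (DSSP-style) is a
non-goal — the dihedral rule is cheap, deterministic and sufficient for
relative helix-content comparisons.

"% residues engaged" is 100 × (distinct residues in ≥ 1 detected pair) /
(total protein residues), which normalises away protein size when
comparing systems.

## Sequence descriptors

Composition, hydrophobic fraction, GRAVY, aliphatic index and
instability index operate on the 20 standard residues; anything else is
a hard error listing the offending positions (silent skipping would
shift every fraction). "Hydrophobic content on the Kyte–Doolittle
scale" is operationalised as the % of residues with strictly positive
hydropathy (A, C, F, I, L, M, V); the threshold is configurable because
the phrase has no single standard definition, and the chosen
operationalisation is documented rather than asserted as anyone else's.
The constant tables (Kyte–Doolittle 1982 hydropathies; Ikai 1980
aliphatic coefficients 2.9/3.9; Guruprasad 1990 dipeptide instability
weights with the <40 = stable rule) ship as versioned in-package assets
with literature provenance, and the descriptor implementations are
tested against an independent reference implementation.

## Kinetics and thermodynamics

All fits are unweighted least squares on the stated transform — natural
log for exponential decay and Arrhenius, log10 for the bell profile —
since no weighting scheme is asserted by the data model.

* **Michaelis–Menten**: nonlinear least squares of v = Vmax·S/(K_M+S);
  kcat = Vmax/[E] when the enzyme concentration is given.
* **Bell profile**: kcat(pH) = kcat_lim/(1 + [H⁺]/K_E1 + K_E2/[H⁺]) with
  [H⁺] = 10^(−pH), fitted in (log10 kcat_lim, pK_E1, pK_E2) space. The
  curve peaks exactly at pH = (pK_E1+pK_E2)/2 with peak value
  kcat_lim/(1 + 2√(K_E2/K_E1)). Data monotone in pH (optimum at a design
  boundary) raises a `FitWarning` and falls back to a one-limb fit with
  the visible limb flagged — the situation that arises when one limb of
  a profile is experimentally inaccessible (e.g. variant precipitation
  at low pH).
* **Inactivation**: k_obs per peroxide concentration from the negated
  slope of ln(residual activity) vs time; k_inact from the slope of
  k_obs vs [H₂O₂] with a free intercept reported (spontaneous
  inactivation); forcing through the origin is a flag.
* **Arrhenius**: Ea = −slope·R from ln k vs 1/T; the regression R² is
  reported as the deviation-from-Arrhenius diagnostic (protein
  denaturation inside the studied range would bend the line).
* **TST**: ΔG‡ = R·T·ln(k_B·T/(h·k)) with transmission coefficient 1 and
  CODATA 2018 constants. At 298.15 K a turnover of 8.6 s⁻¹ maps to
  ≈ 16.18 kcal/mol; converting the same rate at a slightly different
  assumed temperature (or rounding convention) shifts this by a few
  tenths, which is why the temperature is an explicit argument rather
  than a baked-in constant.
* **Denaturation enthalpy**: ΔH(T) = mass_kDa · (h_ref + c_p·(T−T_ref))
  in kcal/mol, affine in T and linear in mass. The default coefficients
  (h_ref = 12.6412 cal·g⁻¹ at 100 °C, c_p = 0.13941 cal·g⁻¹·K⁻¹) are the
  least-squares calibration against a 17 kDa reference protein's anchor
  series 191/215/239/262 kcal/mol at 90/100/110/120 °C, which they
  reproduce at nearest-integer precision; they are frozen as package
  constants rather than transcribed from the original
  structure-energetics tabulation, which the package does not vendor.

Temperatures are kelvin internally; CLI entry points accept Celsius and
convert with 273.15.

## Synthetic-data generators

Every generator is a pure function of (spec, seed); internal streams are
derived deterministically (per-column substreams for alignments) so
growing a problem does not perturb earlier draws.

* **Alignments**: exactly round(conserved_fraction·length) single-state
  columns; every variable column realises exactly its drawn k-state set
  (which is why n_seqs ≥ k is required). Default generator conditions
  used in the end-to-end runs — 5 sequences, length 150, conserved
  fraction 0.85, 3 states per variable column — put progenitor mutual
  identities in the ~85–90 % band typical of closely related
  thermophilic archaeal PTP sets.
* **Loop trajectories**: a two-state Markov chain (stay probability per
  frame) whose states carry reference (φ, ψ) sets, plus independent
  wrapped-Gaussian noise per angle. This is a statistical stand-in for
  MD loop hopping: it reproduces the occupancy/classification structure
  the analyses assume, but has no kinetics, no correlated motions and no
  energetics — passing tests demonstrate the estimators, not MD realism.
  The companion backbone builder realises dihedrals as 3-D coordinates
  with ideal bond lengths (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å) and
  ideal tetrahedral/trigonal angles; coordinates are a carrier for φ/ψ
  round-trip tests, not physical models. One flanking glycine on each
  side gives every signal residue defined dihedrals.
* **Hydration frames**: per-frame in-sphere water counts are
  Poisson(λ), positions uniform in the sphere; the water set is padded
  to a fixed topology, with surplus and decoy waters placed in a shell
  strictly outside the sphere (≥ radius + 0.5 Å), so trajectory
  invariants hold and the construction guarantees the counting oracle.
* **Kinetic datasets**: response = model(predictor; truth) ×
  lognormal(mean 1, stated CV). Default recovery conditions follow the
  study's designs: 13 pH points in [3.5, 6.5] at 1 % noise for the bell
  profile; 8 substrate points bracketing K_M = 2.3 mM; inactivation time
  courses over the 0.1–0.8 mM peroxide range with k_inact = 64.8
  M⁻¹·s⁻¹; Arrhenius series over 295–363 K.
* **Toy active sites**: exact-geometry fixtures (sphere-intersection
  construction, realizability checked via the triangle inequality) for
  the distance criteria.

## Problem sizes and statistical tolerances

Statistical tests use ≥ 5000 samples and 3-standard-error bands, sized
so the suite is stable under seed changes; the two-state recovery runs
10 000 frames at stay probability 0.5 (frames then i.i.d., so the
binomial standard error applies exactly), noise 5° against references
≥ 60° apart. Distribution-free checks (chi-square uniformity over
10 000 chimera draws, p > 0.001) separate the unweighted-over-states
rule from occurrence weighting with large margin. The full suite and
the end-to-end script each complete in well under a minute.

## Known limitations

* No MD, EVB, electrostatics/pKa or solvation-thermodynamics
  computation: trajectories, grids and kinetic observations are inputs.
* The interaction census is not bit-compatible with any specific
  external tool; only the in-repo criteria define it.
* Identity percentages depend on the supplied alignment; no re-alignment.
* Multi-model PDB is the only trajectory format; mmCIF and binary
  formats are out of scope.
* The bell fit's one-limb fallback reports the hidden ionization as
  unresolved rather than extrapolating it.
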