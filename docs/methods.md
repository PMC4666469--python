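# Methods

`dnaenm` models the thermal dynamics of double-stranded B-DNA with two
harmonic elastic networks built on a sequence-dependent reference ("basic")
structure, and analyzes them by normal modes. This note records the models,
the numerical conventions, and the choices made where the design was open.

## Reference structure from helical parameters

A duplex is rebuilt for an arbitrary sequence from dinucleotide **base-step
parameters** (Shift, Slide, Rise / Tilt, Roll, Twist) and intra-pair
**base-pair parameters** (Shear, Stretch, Stagger / Buckle, Propeller,
Opening). Consecutive base-pair frames follow the mid-step-triad (CEHS)
composition used by the standard rebuild tools:

    Γ = √(Tilt² + Roll²),  φ = atan2(Tilt, Roll),  Ω = Twist
    R_{i+1} = R_i · Rz(Ω/2−φ) · Ry(Γ) · Rz(Ω/2+φ)
    o_{i+1} = o_i + R_i · Rz(Ω/2−φ) · Ry(Γ/2) · Rz(φ) · (Shift, Slide, Rise)

Frames are re-orthonormalized (polar decomposition) each step; drift stays
below 1e−12 over thousands of steps. Within a pair frame the six pair
parameters are split half-and-half between the two bases with opposite
sense (the same mid-frame construction), and the strand-2 template is first
rotated 180° about the frame's short axis — the flip that antiparallel
Watson–Crick geometry requires of standard-frame templates.

The bundled parameter table (set "i") is an experimental/crystallographic
compilation. As printed it does not satisfy reverse-complement step
symmetry exactly for every step (e.g. AC vs GT Roll); values are kept
verbatim, and `HelicalParameterSet.symmetrized()` provides an exactly
symmetric variant for symmetry-sensitive property checks. Parameter sets
"ii"/"iii" are recognized labels whose source tables are not distributed
with the package.

### Nucleotide templates (synthetic idealized geometry)

Heavy-atom nucleotide templates (base + deoxyribose + phosphate; C 19,
T 20, A 21, G 22 atoms; 5'-terminal residues lose P/OP1/OP2) are expressed
in the standard base reference frame with the glycosidic N at
(−1.289, 4.551, 0) and C1' at (−2.479, 5.346, 0). They are *synthetic*:
generated once by `scripts/make_templates.py` from MMFF-optimized planar
base geometries (Watson–Crick mirror resolved by an H-bond distance fit)
plus a single shared sugar–phosphate backbone whose ten torsions were
optimized for deoxyribose ring closure and O3'(i)–P(i+1) bond-distance
closure across all sixteen step types, with steric-clash penalties and weak
B-form torsion priors (the optimum lands at χ ≈ −117°, γ ≈ 62°, β ≈ 169°).
The frozen result reproduces fiber-B-DNA hallmarks: intra-pair C1'–C1'
10.49 ± 0.05 Å, C1' helical radius ≈ 5.9 Å, inter-residue O3'–P 1.7 ± 0.25 Å
over all steps, no non-bonded contacts under 2.2 Å. These templates stand
in for an external rebuild program; absolute atomic detail is idealized,
which matters little for elastic-network contact topology but means the
builder is not a crystallographic modelling tool.

## Elastic networks

Both networks use identical springs with natural lengths equal to the
reference distances, so the reference is the exact potential minimum and
the Hessian has the Tirion form (±C·ûûᵀ blocks).

**All-atom network (AAENM).** Nodes: every DNA heavy atom and, for
crystals, every water oxygen. Springs of stiffness `Ca` join atoms with
reference separation ≤ R_i + R_j + R_c (Bondi radii C 1.70, N 1.55, O 1.52,
P 1.80 Å; cutoff R_c = 2.0 Å, boundary inclusive). Isotropic restraints of
stiffness B_j·Ca anchor atoms of the first and last base pair (B_j = B_B)
and water oxygens (B_j = B_w) to their reference positions — a
phenomenological stand-in for crystal packing. A config option is *not*
provided for two pairs per end; the single terminal pair at each end is the
implemented reading.

**Coarse-grained network (CGENM).** One node per nucleotide at its C1'
atom. Node i connects to its partner i′, to i±1 and i′±1, to i±2 and i′±2,
and to i′±3 (existing indices), stiffness `Cg`, no restraints. Interior
degree is 11; the rule yields 11N − 18 springs for an N-bp duplex (the
terminal degree deficits are 5+3+1 per strand end).

**Units.** Lengths Å, energies kJ/mol, spring constants kJ/(Å²·mol);
thermal energy enters as R·T, so mean-square fluctuations are in Å². All
node masses are equal (1 g/mol), which cancels out of every fluctuation
formula; eigenfrequencies keep their meaning through ω² = λ/m. Because
fluctuations scale as T/C, all correlation-based outputs are independent of
the absolute temperature and stiffness; defaults are T = 300 K (screening),
Ca = 1.29, Cg = 7.7 kJ/(Å²·mol).

## Normal-mode statistics

Eigenvalues of the Hessian below 1e−8 × (largest eigenvalue) are classified
as rigid-body modes and excluded from every thermal sum ("ω_k ≠ 0"); free
networks have exactly 6 of them, fully restrained ones none. A negative
eigenvalue beyond that tolerance raises (reference not a minimum).
Cross-mode covariances vanish in thermal equilibrium of a harmonic system,
so every mean-square quantity is a single weighted mode sum with weights
RT/λ_k:

* AF_i (per-atom) and TF_i = (8/3)π²·AF_i (temperature factor);
* MATF: TF averaged over the atoms of each motif (phosphate = P, OP1, OP2,
  O5', O3'; sugar = C1'–C5', O4'; base = rest), ordered
  phosphate → sugar → base per nucleotide; empty motifs (5'-terminal
  phosphates) are skipped. O3'/O5' are assigned to the phosphate so the
  group stays contiguous; the radius table and motif map are plain module
  data and can be overridden per call via `build_aaenm(radii=...)`.
* NF_n: MSF of the unweighted atom-averaged displacement of nucleotide n
  (all-atom model); CF_n: MSF of the C1' node (coarse-grained model).
* Directional components project per-pair unit axes: b_i along
  C1'(strand 1) − C1'(strand 2); s_i the normalized forward difference of
  consecutive pair midpoints with the terminal rule s_N = s_{N−1}; t_i the
  normalized b×s. DF components use the projected *relative* displacement
  of the two paired nodes. b and s are not exactly perpendicular — with
  standard-frame C1' geometry the pair midpoints precess ≈2.5 Å off the
  helix axis, making the b–s angle 57–78°; `AxisFrames.orthonormalized()`
  gives exact triads when Parseval-type component sums are wanted.
  Because s is a forward difference, s/t components are only approximately
  strand-exchange symmetric (a few %); axis-free quantities and b
  components are exact.

## Shape descriptors

λ1 ≥ λ2 ≥ λ3 are the eigenvalues of the 3×3 position covariance (second
moment about the equal-mass centroid; population normalization) over all
atoms of the resolution in use (C1' nodes for coarse-grained structures).
Linearity σ1 = √(λ1/λ2) and line symmetry σ2 = √(λ3/λ2) are ratios of the
square roots of the principal components; the bare-eigenvalue-ratio reading
is available behind `root=False` for sensitivity checks.

## Profile correlations

Pearson correlation, with a one-pass outlier rule for experimental
comparisons: entries deviating from their own series mean by more than
s = 2.5 population standard deviations are excluded (union over both
series, keeping the profiles index-aligned; no iteration). Applied to both
series by default; crystal TF correlations use DNA atoms only (waters are
model nodes but not part of the reported profile) unless
`include_water=True`.

## Screening pipelines

* `profile_sequence` / `gc_sweep`: C1 build → CGENM modes → CF/DF
  components → shape descriptors; sweep averages are reported per GC
  content, and pooled correlations (σ1, ⟨CF⟩), (⟨DF^b⟩, σ1), (⟨DF^b⟩, σ2)
  are given with and without the outlier rule. "Average GC content" is
  realized per-position i.i.d. (G or C each with probability gc/2), the
  simplest reproducible reading of an average composition; within-class
  choice is uniform. A master seed spawns per-sequence streams
  (`SeedSequence`), so batch composition never changes a sequence's result.
  ⟨CF⟩ averages include both strands (2N nucleotides); ⟨DF⟩ averages the N
  pairs.
* `compare_aaenm_cgenm`: both models from the same frames; per-nucleotide
  NF vs CF (total and b/s/t) correlated per sequence across all 2N
  nucleotides. Random 50-bp sequences use gc = 0.5 (uniform base
  composition), the neutral choice where composition is unstated.
* `fit_crystal`: exhaustive grid over (Ca, B_B, B_w) maximizing the robust
  ρ(TF). ρ is invariant to the overall stiffness scale, so Ca only sets
  absolute TF units; the fit shape is controlled by the restraints.
  `synthetic_crystal` fabricates a model-generated pseudo-crystal (built
  duplex + hydration-shell water oxygens + the model's own TF in the
  B-factor field, optional lognormal noise) for parameter-recovery and
  round-trip tests.

## What the synthetic data does and does not establish

Random-sequence screening and synthetic crystals exercise every code path
with exactly known ground truth (parameter recovery, ρ = 1
self-consistency, symmetry and scaling laws). They do not establish
agreement with experimental B-factors: that requires real crystal
structures (e.g. PDB entries 1BNA, 122D), which cannot be downloaded in an
offline environment. The crystal-comparison acceptance test therefore fails
with an explanatory message unless the PDB files are placed under
`tests/data/crystals/`. Likewise, the idealized templates reproduce fiber
B-DNA statistics, not any specific crystal's fine structure.

## Known limitations

* Harmonic, solvent-free, uniform-stiffness models: absolute fluctuation
  magnitudes are meaningful only up to the overall T/C scale.
* The rebuild direction only (sequence → coordinates); extraction of
  helical parameters from coordinates is out of scope.
* No IUPAC ambiguity codes or RNA; no A-/Z-form parameter tables bundled.
* Eigendecompositions are dense; ~150 bp coarse-grained (900×900) costs
  ~0.2 s, a 50-bp all-atom duplex (~6,000×6,000) tens of seconds. Long
  all-atom duplexes are the coarse-grained model's reason to exist.
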