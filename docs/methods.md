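# Methods

This note records the models, conventions and numerical choices behind
`ligandqc`, and what the synthetic test data do and do not demonstrate.

## Ligand selection

Non-polymer residues are enumerated from the coordinate file (HETATM flag,
falling back to a standard-residue list covering water, the 20 amino acids
and the standard nucleotides, all configurable). Candidate residue *types*
are ordered by the number of non-hydrogen atoms in their restraint
dictionary entry — the dictionary count is authoritative, so missing or
extra hydrogens in the model do not affect the ordering. Ties between types
are broken lexicographically by comp-id, and between instances of a type by
(chain, sequence number); both tie-breaks are conventions chosen for
determinism. An instance is rejected, with a logged reason code, if its
comp-id is on the obsolete list, any of its atoms appears in a LINK /
struct_conn record, any atom carries an alternate-location indicator, or
the structure's data are flagged unavailable or twinned; the next candidate
is then tried. Data availability and twinning are consumed as caller-
supplied metadata flags — the package does not analyse reflection data to
detect twinning. The environment of a ligand is every non-ligand atom
within a cutoff (default 4.0 Å) of any ligand atom, in orthogonal Å space;
crystallographic symmetry mates are not generated.

## Density model

Maps are synthesized in real space: atom *i* contributes an isotropic
Gaussian

ρᵢ(r) = occᵢ · Zᵢ · (2π s²)^(−3/2) · exp(−|r−rᵢ|²/2s²),  s² = Bᵢ/8π² + w²

with Zᵢ the atomic number and w = 0.5 Å a fixed softening width that keeps
zero-B atoms finite on a 0.5 Å grid. Atoms are rendered out to 6s, beyond
which the truncated mass is ≪ 0.1%. This replaces the structure-factor /
FFT round trip of a crystallographic pipeline: the "observed" map is a
synthesis at the true occupancy (plus optional i.i.d. grid noise), the
direct (ligand-omit) map is observed minus the environment-only model, and
the difference map is observed minus the full model. The correlation
metrics are defined on these grids exactly as they would be on 2mFo−DFc /
mFo−DFc maps; what is *not* emulated is model bias, σA weighting, series
termination and solvent effects, so numerical agreement with values
computed from real diffraction data is not claimed — the synthetic route
preserves the metrics' definitions, signs and degeneracies, not
crystallographic noise structure.

Grid points entering a correlation are those within the masking radius
r₀(element) + c_b·√(B/8π²) of at least one ligand atom and outside the
(optionally inflated) radius of every environment atom. Defaults:
r₀ = 1.7/1.6/1.5/1.8/1.8 Å for C/N/O/S/P, c_b = 3.0, inflation 0.0 Å,
default r₀ 1.7 Å for unlisted elements (with a warning). These parameters
are configuration, not a reproduction of any specific program's table. An
empty masked set raises an error naming the pathology (ligand fully masked
by its environment).

Pearson correlation is computed by numpy over the masked values; zero
variance on either side raises `UndefinedCorrelationError`. For the
difference-map correlation specifically, a residual whose spread over the
masked points is below 10⁻⁹ of the ligand density's spread is treated as
identically zero (`ZeroResidualError`): this is the perfectly-modelled
limit, where the correlation is undefined rather than meaningful. The CLI
pipeline reports cc_diff = 0 in that case, which is the value the metric
approaches as noise vanishes around a correct model.

### Occupancy scan

Trial occupancies default to 0.0–1.0 in steps of 0.05 (21 points). Because
the Gaussian synthesis is linear in occupancy, the model map at trial
occupancy q is assembled as env_map + q·(unit-occupancy ligand map); a test
verifies this equals rebuilding each map from scratch. No re-refinement is
performed between trial occupancies, so on noise-free synthetic data the
cc_diff zero crossing recovers the rendering occupancy to within one grid
step; on real data, where refinement would redistribute error, the scan is
a diagnostic rather than an estimator. Undefined correlations at individual
points (q = 0, or q equal to the true occupancy on noise-free data) become
missing entries, not scan failures.

### Q–Q data and effective resolution

Difference-density Q–Q data standardize the masked Δρ values by their own
mean and standard deviation and pair empirical quantiles at plotting
positions (i−0.5)/n with standard-normal quantiles; constant input is an
error. The context is local — only the masked ligand-site points — so the
plot diagnoses the residual at the ligand, not the global error model. The
estimate of σ(Δρ) from the solvent region, and the Z-score of the ligand
residual derived from it, are not implemented.

Effective resolution uses N_eff = Σ_observed F²/(F²+σ(F)²) and
R_eff = d_min·(N_total/N_eff)^⅓: complete error-free data give R_eff =
d_min, and incompleteness or noise only ever increase it. The cube root
reflects the scaling of reflection count with resolution sphere volume.
This specific functional form is this package's own definition of the
quantity "nominal resolution corrected for missing data and amplitude
errors"; it is deliberately simple and is exposed behind its own function
so a different convention can replace it.

## Geometry scoring

Bond lengths are Euclidean distances, angles arccos of the normalized dot
product (clipped to [−1,1]), in degrees. Z = (observed − target)/max(σ,
floor) with floors 0.015 Å (bonds) and 1.0° (angles); flooring inflates σ
rather than discarding the feature, so it can only lower |Z| — restraints
with suspiciously tight σ cannot generate extreme claims. Restraints
involving hydrogen, or atoms absent from the model, are skipped with a
warning and counted. Z-worst is the maximum-|Z| feature; ties go to the
first feature in (bonds before angles, dictionary order). Torsions, planes
and chirality are out of scope. The slider classification is |Z| ≤ 1
"likely", |Z| ≥ 5 "unlikely", linear in between.

The dictionary is a monomer-library-style mmCIF (atom, bond and angle
categories with value/esd columns) parsed with gemmi; duplicate restraints
and restraints naming unknown atoms are integrity errors.

## Contacts

Contacts are computed on heavy atoms with united-atom vdW radii (C 1.90,
N 1.70, O 1.60, S 1.95, P 1.95 Å; configurable), not on an explicit-H dot
surface — so absolute counts differ from H-aware clash scores, while the
recorded quantity (an integer count of badly overlapping pairs) has the
same meaning. The gap is distance minus summed radii; categories: gap >
0.25 Å wide, 0 < gap ≤ 0.25 close, −0.4 ≤ gap ≤ 0 small overlap, gap <
−0.4 bad (the conventional clash threshold). N/O···N/O pairs get +0.2 Å of
relaxation before classification (default on) because such approaches are
typically hydrogen bonds. Pairs named in a covalent link record are
excluded, as are 1–3 pairs reachable through a link via one dictionary bond
on the ligand side; deeper environment-side topology is unknown to the tool
(no environment dictionary is consulted), a known limitation for heavily
cross-linked ligands.

## Ranking

Percentiles use the mid-rank convention 100·(n_worse + ½·n_equal)/N, which
maps an all-ties store to 50 and makes ranks monotone in the oriented
value. Orientations: cc_direct higher-better; cc_diff nearer-zero-better
(either sign of residual correlation indicates mismodelling; overridable to
higher-better); |Z-worst| and n_bad lower-better. The combined score is the
sum of squared ranks divided by 400 — the simplest unit-weight form that is
strictly increasing in each rank, maps (0,…,0)→0 and (100,…,100)→100, and
rewards top-heavy profiles over balanced ones with the same linear sum. It
is a single swappable strategy function. The overall percentile ranks S
against the S values of every stored record (each computed by ranking the
record against the whole store, vectorized via mid-ranks). Resolution is
deliberately not part of the scoring model; it is stored per record and
queryable (binned histograms) for exploratory analysis.

The store is a single-file SQLite database with a versioned schema and CSV
round-trip; rebuilding from CSV reproduces every percentile exactly.

## Synthetic data

The toy ligands are acyclic tree molecules defined as Z-matrices ("TL6", a
6-heavy-atom triol; "T11", an 11-heavy-atom branched C/N/O tree). They are
synthetic — no real chemical component has these topologies — and were
chosen acyclic so that every internal coordinate can be perturbed
independently and the Cartesian coordinates rebuilt exactly (a ring-closure
bond would not survive independent perturbation). Dictionary targets and σ
values come from the same Z-matrix, so a freshly built ligand scores
Z-worst = 0 by construction; σ values include entries below the floors to
exercise the floor arithmetic. Distortion perturbs bonds by N(0,(λσ)²) and
angles by N(0,(μσ)²), rebuilds, and superposes back onto the input frame
(Kabsch), making λ=μ=0 the identity to floating-point precision.

Pocket atoms are placed one per pseudo-residue by rejection sampling around
random ligand atoms so that every ligand–pocket vdW gap respects a
configurable floor (default +0.3 Å ⇒ zero bad contacts by construction;
negative floors create clashing complexes for contact tests). B-factors are
uniform in 15–35 Å², typical of well-ordered moderate-resolution
structures; grid spacing defaults to 0.5 Å as a desk-scale balance of
accuracy and speed.

The reference corpus draws cc_direct from a shifted Beta (median 0.85),
cc_diff from a Normal with median −0.073 and σ 0.15, |Z-worst| from a
log-Normal (median 1.6, shape 0.5) and n_bad from a Poisson whose rate is
solved from the requested integer median (λ ≈ 1.4 for median 1). The
cc_diff and n_bad medians are anchored to corpus-wide statistics reported
for deposited structures (a slightly negative difference-map correlation
median of −0.073, reflecting systematically over-estimated occupancies, and
a median of 1 bad contact); cc_direct and Z-worst medians are plausible
round values chosen once. The families match the qualitative shapes of the
corresponding empirical distributions but none of their higher moments, so
corpus tests demonstrate the ranking machinery, not population realism.

## Test and script problem sizes

The default test suite and the acceptance script use a ~15-atom complex on
a ≈ 45³ grid at 0.5 Å, 50-case brute-force oracles for masking and
contacts, 100 distorted ligands for the geometry oracle and a 10⁴-record
corpus; these sizes make every oracle exhaustively checkable while the
full suite runs in well under a minute.

## Known limitations

No structure factors, symmetry mates, twin handling, refinement, explicit
hydrogens, torsion/plane/chirality scoring, or resolution-dependent scoring
model. The effective-resolution formula and the masking-radius parameters
are declared conventions of this package, exposed in configuration.
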