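# Methods

## The model

The package treats flavonoid activity on the osteoblastic CaV channel as a
linear QSAR problem: the response pIC₅₀ = −log₁₀ IC₅₀(μM) is a linear
function of molecular descriptors, Y = β₀ + Σ βⱼXⱼ + ε. Because the
descriptor pools used in this field are small-sample and strongly
intercorrelated, the fit is done by principal-components regression:
standardize the descriptor matrix, decompose X = TPᵀ, regress Y on the
first p′ score columns, and fold the component-space coefficients back
through the loadings and scaling into a descriptor-space equation. With
p′ equal to the rank, PCR is exactly ordinary least squares; with smaller
p′ it trades a little bias for stability under collinearity.

Two fitted-model families are carried: an activation model (descriptors
k2alpha, Id, IdwAverage) and an inhibition model (Most+vePotential,
MomInertiaY, DeltaEpsilonC). Their published coefficient records ship at
printed precision; the package never pretends to recover the unpublished
full-precision fits, because the candidate descriptor pool and GA
configuration behind them were never published.

## Descriptors

**Hydrogen suppression.** All topological descriptors are computed on the
heavy-atom graph, the standard convention for Kier-type indices. An
explicit-hydrogen mode exists for sensitivity checks only.

**k2alpha.** The default variant is Kier's second-order form
(A+α−1)(A+α−2)²/(P+α)². A `literal_printed` variant evaluating
(A+α−1)³/(P+α)² is also provided because published tables are sometimes
typeset that way; the default is the standard form, and the literal
variant exists so such tables can be audited without silently correcting
them. P is the count of two-bond paths (the standard choice for the
second-order index). The α contributions come from Kier's covalent-radius
ratios (C sp3 = 0, C sp2/aromatic = −0.13, C sp = −0.22, O sp3 = −0.04,
O sp2 = −0.20, N/S/P/halogens likewise), stored as a versioned constant
table keyed by (element, hybridization).

**Id / IdwAverage.** Both distance modes are first-class: plain
topological shortest-path counts (default) and the reciprocal-square
weighting 1/d², which emphasizes near pairs and is the natural reading of
a "weighted" information index. Equality classes are formed after
sorting, exactly in topological mode and with relative tolerance 1e-9 in
reciprocal-square mode, so the grouping is deterministic. The identity
Id = K·IdwAverage (K = A(A−1)/2) is an algebraic consequence of the two
definitions and is enforced by property test in both modes.

**MomInertiaY.** Σ mᵢ(xᵢ² + zᵢ²) after translation to the center of mass,
in amu·Å². Coordinates are taken as-is from the input record — no
re-embedding — so 2D records give a planar value, flagged as 2D-derived
on the graph.

**Most+vePotential and DeltaEpsilonC** are quantum-chemical quantities
(maximum positive electrostatic potential on the van der Waals surface;
frontier-orbital energy gap) and are out of computational scope; they
enter only as supplied table columns with per-cell provenance, so the
inhibition model remains exercisable end-to-end.

## Component and subset selection

`p_prime="auto"` scans 1..rank and keeps the count maximizing adjusted
r², breaking ties toward fewer components. Descriptors are standardized
(centered, unit variance) before the decomposition: the descriptor scales
in this domain differ by orders of magnitude (Id ≈ 800 vs IdwAverage
≈ 7.7), and an unstandardized PCA would be dominated by the largest
column.

The genetic algorithm evolves fixed-length descriptor bitmasks:
population 50, 100 generations, tournament selection of size 3, uniform
crossover at rate 0.8, per-bit mutation at 0.02, elitism 1. These are
reproducible desk-scale defaults, not values from any published
configuration (none exists). All-zero masks are repaired by switching one
random bit on. Fitness is the adjusted r² (or optionally LOO q²) of a PCR
fit with auto component selection on the masked columns; evaluations are
memoized per mask. Seeds are explicit arguments everywhere — no global
random state is touched.

Note that adjusted r² is a weak parsimony penalty: on planted-model data
the GA reliably *includes* the active descriptors but often keeps a few
inactive ones whose coefficients are near zero. Identification is
therefore assessed as "active set selected and carrying the largest
coefficient magnitudes", not as exact subset match.

## Validation metrics

All metrics are pure functions of observed/predicted vectors (or a refit
callback for cross-validation) and are checked against independent
brute-force transliterations of their defining formulas to 1e-12.
Conventions that the literature leaves loose are explicit arguments:

- **Standard error of estimate** exposes both df = N−p−1 (default) and
  df = N−p, because published tables are inconsistent about which they
  used; the packaged activation-model value 0.0933 reproduces only with
  df = N−p, so the reproduction routine uses that convention and records
  it.
- **r0² / r0′²** in Roy's r_m² family follow Roy's definition: the
  determination coefficient of the least-squares regression through the
  origin (observed on predicted, and the converse), with the centered
  total sum of squares in the denominator. A consequence worth recording:
  under this definition the origin-constrained RSS can never beat the
  best affine fit, so r0² ≤ r² and the radicand r² − r0² is never
  negative. The clamp-to-zero branch (with a report flag) is purely
  defensive; anticorrelated predictions drive r_m² negative without
  tripping it.
- **q²** uses the full training-set mean in its denominator, not
  fold-local means.
- The scaled r_m² variant min-max scales both vectors by the observed
  range.

`kfold_external` accepts a "6x4" partition spec (six folds of exactly
four compounds, matching the 24-compound external scheme), a plain k, or
an explicit partition; with singleton folds its pooled squared errors
equal LOO PRESS, which is tested.

## Published-table fixtures and what is (not) reproducible

The packaged CSVs transcribe the published tables verbatim, guarded by
SHA-256 checksums. Loading validates cardinalities (activation: 20 train
+ 4 test; inhibition: 20 + 3 — the flavanone naringenin appears only in
the activation table). The residual convention is predicted − observed,
verified by audit across all 47 rows to within 0.0005 (3-decimal
rounding).

From the printed observed/predicted pairs the package reproduces, for the
activation model: training r² = 0.3183, external r²_pred = 0.958,
standard error 0.0933 (df = N−p), test RMSEP 0.0178. The published F
(3.9664) and q² (0.0693) for that model, and all inhibition-model summary
statistics, are **not** reproducible from the printed tables — the
package's independent recomputation of F from the same pairs gives 2.48 —
so they are stored with status `printed_unreproduced` and attached to
reports as reference metadata only; tests assert this package's
computations, never those values.

Two further published inconsistencies are recorded rather than patched:

- The printed descriptor-ranking table's Id values violate the algebraic
  identity Id = K·IdwAverage for any plausible atom count, so the
  generating software's conventions are unrecoverable; the table is a
  fixture, not an oracle, and two rows whose column boundaries are
  typographically ambiguous carry an `ambiguous_parse` flag (stored as
  the most internally consistent parse, Id ≈ 800).
- Pushing the printed descriptor triple of scutellarein through the
  printed activation equation gives ≈ 0.660, not the printed prediction
  0.534; `apply_printed_equation` quantifies this divergence per compound
  and flags it instead of raising.
- The published compound ranking (scutellarein first) follows from
  neither the printed predictions nor any stated formula;
  `rank_by_predicted` implements the reproducible criterion — descending
  predicted activity, ties alphabetical — and documents the difference.

## Synthetic data

The generator emulates the statistical shape of the study: default 24
compounds, 6 descriptors, compound-symmetric inter-descriptor correlation
ρ = 0.5 (a single ρ keeps the collinearity stress interpretable), half
the descriptors active with coefficients 1.0..0.5, Gaussian noise
σ = 0.05 on the pIC₅₀ scale, and a 20/24 training fraction. Molecule-like
graphs are random spanning trees plus optional ring closures, degree
capped at 4, C/O elements — chemically plausible but not valence-exact,
which is sufficient for descriptor testing.

What passing on synthetic data does *not* show: real descriptor
distributions are not Gaussian, real inter-descriptor correlation is not
compound-symmetric, and real responses are not exactly linear; the
synthetic results certify the machinery (recovery, cross-validation
identities, determinism), not field performance.

## Problem sizes and numerics

The planted-model recovery study uses 50 replicates at n = 40, 8
candidate descriptors, σ = 0.05; the exhaustive-search cross-check
enumerates all 255 subsets at the same size. PCA uses SVD with a
deterministic sign convention (largest-magnitude loading positive).
Degenerate inputs error early and name the offender: zero-variance
columns under standardization, missing descriptor columns, constant
observed vectors, empty distance triangles, non-positive degrees of
freedom. Noise-free fits return an infinity sentinel from the F
statistic rather than dividing by zero.

## Known limitations

- Aromaticity and hybridization come from the input's own flags/bond
  orders (RDKit perception on SMILES); no tautomer or protonation
  handling.
- Multi-fragment inputs (salts, solvates) are rejected, not stripped.
- The Kier α table covers C/N/O/S/P/halogens; exotic elements raise.
- No PLS or MLR model families, no Y-randomization or applicability-
  domain estimation.
- 3D descriptors from 2D records are planar projections, flagged but not
  corrected.
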