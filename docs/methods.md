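# Methods

## Model and scope

The package computes degree-based topological indices of hydrogen-suppressed
molecular graphs. A graph enters either as an explicit edge list (or SMILES /
MOL file via the optional rdkit readers) or directly as a degree-pair edge
partition — the map from unordered endpoint-degree pairs `(s, t)` to edge
counts. Every supported index depends on the graph only through this
partition, so the partition is the canonical intermediate object and the CSV
format `s,t,count` is the package's exchange format.

Two computation routes are implemented and kept deliberately independent:

1. **Direct edge sums** (`indices.direct_index`): Σ count·kernel(s,t) with
   the kernels listed in the README.
2. **Operator calculus** (`mpoly.index_from_operators`): build
   M(Γ; x, y) = Σ m_st x^s y^t as a sparse bivariate polynomial and apply
   the per-index operator chain (Dx, Dy, Sx, Sy, fractional powers, the
   exponent shift Q(α), and the diagonal substitution J), then evaluate at
   x = y = 1.

Their exact agreement on seeded random graphs is a standing test; it
exercises the calculus end to end, including the AZI chain
Sx³ Q(−2) J Dx³ Dy³ whose intermediate exponents go negative.

## Numerical conventions

- Coefficients and exponents are exact `fractions.Fraction` throughout;
  floats appear only for genuinely irrational quantities (Randić variants
  with fractional α) and at final presentation.
- The symbol conflict between the diagonal-substitution operator and the
  inverse-sum-indeg index is resolved by calling the operator **J** and the
  index **I**.
- **Randić convention.** The literature writes the general Randić index in
  two incompatible ways, Σ(d_u d_v)^α and Σ(1/(d_u d_v))^α. This package
  adopts R_α = Σ(st)^α and RR_α = Σ(st)^(−α), the convention realised by
  the operator chains (Dx^α Dy^α and Sx^α Sy^α) and by the closed forms of
  the polysaccharide families; α = −1/2 recovers the classic Randić index,
  and R_{−1} ≡ ᵐM₂.
- **AZI singularity.** On a (1,1) edge the AZI kernel divides by zero. The
  direct route raises `UndefinedIndexError`; the operator route reaches the
  same state as Sx applied to a zero x-exponent term (`UndefinedOperatorError`).
  Tabulations record such cells as NaN instead of aborting.
- **Rounding** is presentation-only: half-up to 4 decimals for index
  tables, 3 decimals for r/r²/F, with p below 5·10⁻⁵ displayed as 0.0000.
  All comparisons in tests use exact rationals or a 1e−9 float tolerance.

## Parametric families

Guar gum, HPG, CMG and CMHPG are modelled purely by their degree-pair edge
counts as linear functions of the repeat count n ≥ 1 (table in
`families.py`). The atom-level repeat-unit connectivity is not
reconstructed: the linear count formulas fully determine every in-scope
quantity, and re-deriving the skeleton from structure drawings would add
only uncertainty. HPG and CMG share a single partition (their substituents
differ chemically but not in heavy-atom degree structure) and are exposed
as two display names over one object.

Because each count is linear in n and each kernel is n-free, every index is
exactly linear in n; `closed_form` returns that line with rational slope
and intercept, e.g. M₁ = 160n + 2 for guar gum and
AZI = (16265/64)n + 27/8. Where published decimal renderings of these lines
are internally inconsistent with their own partitions, the package pins the
exact rational and documents the delta:

| family | index | published line | exact line |
|---|---|---|---|
| guar gum | SDD | 75.67n + 2.5 | (227/3)n + 11/3 |
| guar gum | AZI | 254.125n + 3.375 | (16265/64)n + 27/8 |
| HPG/CMG | M₁ | 192n + 1 | 192n + 2 |
| HPG/CMG | ᵐM₂ | 7.99n + 0.663 | 8n + 2/3 |
| HPG/CMG | AZI | 320.315n + 3.375 | (5125/16)n + 27/8 |
| CMHPG | SDD | 106.03n + 3.66 | 94n + 11/3 |
| CMHPG | AZI | 340.95n + 3.4 | (5455/16)n + 27/8 |

(Sub-0.01 differences such as 16.44 vs 493/30 are ordinary rounding and not
listed.)

## Packaged carbohydrate data and the audit

Eight small carbohydrates ship as data files: their edge partitions, their
physicochemical properties (density, boiling point, melting point,
molecular weight, water solubility), and the index table *as originally
published*. Recomputing every index from the partitions reproduces the
published table except for twelve audited cells (six of them in the
hydroxymethyl-furfural row, which matches its own partition only for H);
`datasets.audit_published_indices()` returns the list, and the test suite
pins both sides of every deviation. The package's canonical output is the
recomputed table; the published one is retained verbatim because it is what
the original regressions were fitted to.

The raffinose density is recorded as printed, 884.8 g/cm³ — implausible by
three orders of magnitude (presumably a unit slip). It is preserved rather
than corrected, and density regressions exclude it by default behind the
explicit `exclude_anomalous_density` flag.

## QSPR layer

Single-descriptor OLS in three forms (linear, quadratic, logarithmic with
natural log), one index at a time — no multivariate models, selection, or
cross-validation. The fit is delegated to statsmodels; reported statistics
are the nonnegative multiple R = √r², F = (r²/k)/((1−r²)/(n−k−1)) and its
upper F(k, n−k−1) tail p. R is reported nonnegative even for negative
slopes, matching the convention of mainstream statistics packages. By
default the batch report fits the as-published index values (what the
original models were fitted to); a flag switches to the recomputed table.

Of the original regression tables only the molecular-weight rows are
reproducible from the shipped property and index tables: the MW multiple-R
values for M₁/M₂/SDD/AZI come back at 0.999/0.999/0.998/0.993 to three
decimals. The boiling-point (and MP/WS/density) rows do not reproduce from
these inputs — direct OLS gives materially different slopes and r — so the
package reports its own fits for those properties and asserts only internal
statistical consistency (r = √r², p consistent with F, quadratic r² ≥
linear r² by nesting), never agreement with the unreproducible rows.

## Synthetic data

Two generators support testing:

- `graphs.random_chemical_graph(n, max_degree, seed)` grows a random tree by
  valence-respecting attachment and adds a few ring closures, emulating the
  degree profile of organic skeletons (degrees 1–4, sparse, connected). It
  does not emulate element identity, bond orders, or realistic ring
  statistics — irrelevant here, since every index sees only degrees.
- `qspr.synthetic_qspr_data(n, form, coefficients, noise_sd, seed)` draws x
  uniformly on a positive range and adds Gaussian noise around the chosen
  model form. It emulates the regression model's own assumptions
  (independent homoscedastic errors, correct form), so recovery tests
  validate the estimator, not the realism of any chemical dataset.

Defaults used by the test suite: 200 random graphs of 14 vertices for the
dual-route equivalence check; 500 replicates of n = 30 observations at
noise 2.0 for coefficient-recovery bias (bounds at 4 Monte-Carlo standard
errors); closed forms checked exactly at n = 1..10.

## Known limitations

- No distance-based indices (Wiener etc.) and no reverse-degree variants.
- Families are partition-level models; questions that need the actual
  repeat-unit adjacency (e.g. distance-based descriptors) are out of reach.
- `closed_form` requires a rational kernel, so fractional-α Randić closed
  forms are not emitted (they are irrational-coefficient lines).
- The QSPR layer fits 7–8 data points; its statistics are reported as-is
  and carry the usual caveats of tiny-n regression.
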