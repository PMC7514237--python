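# Methods

## Data model

An interval matrix 𝒳 assigns each case i and variable j a closed interval
[a_ij, b_ij] (a_ij ≤ b_ij, finite). A *realization* Z ∈ 𝒳 is any point
matrix with a_ij ≤ Z_ij ≤ b_ij; the center matrix X^c = (a+b)/2 is one.
The *vertex matrix* X^v stacks, per case, all 2^{m_i} corners of its
hyper-rectangle, where m_i counts the case's nondegenerate intervals —
degenerate columns contribute their single value and are not duplicated,
so N = Σ_i 2^{m_i}. Corner rows are ordered by binary counting over the
nondegenerate columns (leftmost slowest, lower bound → 0); the rule is a
package convention fixed so that the row→case map and tests are
deterministic. Vertex rows are unweighted: with all m_i equal (as in the
faces data) a per-case 1/2^{m_i} weighting would change nothing, and for
ragged m_i the unweighted form is what the stacked-matrix PCA implies.

## Standardization and PCA conventions

Only correlation PCA is offered: every standardization in the interval
machinery divides by the column standard deviation, so a covariance mode
would be internally inconsistent. Columns are standardized as

    x̃ = (x − mean_j) / (√n · σ_j),

with σ_j the population (divisor-n) standard deviation of the fitted
matrix. Under this scaling Z̃ᵗZ̃ *is* the correlation matrix, its trace is
m, and the case-side Gram matrix Z̃Z̃ᵗ shares its nonzero eigenvalues —
the duality relations u_ℓ = Z̃ᵗv_ℓ/√λ_ℓ and v_ℓ = Z̃u_ℓ/√λ_ℓ then hold
exactly. Reported scores (and score intervals) use the (x − mean)/σ
scale — √n times the internal one — under which the k-th score column
has population variance λ_k: the conventional display scale for
principal-component scores, and the one on which the faces example's
score intervals are quoted throughout the package.

Eigenvector signs are fixed by making each component's largest-|entry|
loading positive (first index wins ties), which is deterministic and
idempotent. Reports may additionally re-anchor a component's sign to a
named variable (`sign_anchors`): the component is flipped so that the
anchor's correlation with it is positive. The faces example tables use
PC1 anchored to X4 and PC2 to X3. Tied eigenvalues are ordered by
descending value and then by the eigensolver's column order; exact ties
essentially never occur off the degenerate fixtures.

## Interval scores and dual loadings

Projection onto a component is linear, so the min/max of a case's corner
projections is attained by pairing each negative loading with the
opposite bound; the package computes the closed form (split the loading
vector into nonnegative and negative parts, combine with the a/b bounds)
and keeps a brute-force corner-enumeration oracle (guarded at 10^6 rows)
purely for verification. A loading exactly 0 is assigned to the
nonnegative part; its coefficient is zero, so the bound is unaffected —
the assignment only makes the partition deterministic. The same
construction on the case-side eigenvectors bounds every variable's
correlation-circle coordinate over all realizations of the box.

## Variable–component correlations

The comparison table correlates each variable's *vertex-matrix column*
with the vertex rows' supplementary scores in the method's basis, so all
methods are judged against the same underlying point set. For the vertex
method this is simply the variable–score correlation of the fitted PCA;
for the center and Best Point methods it differs from the correlation on
the fitted matrix itself (on the faces data, X4/PC1 center: 0.88
vertex-based vs 0.91 on the midpoints). The vertex-based definition is
how the faces example's comparison table is defined, and the one that
makes the four methods directly comparable. The dual coordinates r_ij = Σ_k Z̃_ki v_kj (equal to the fitted
matrix's own variable–score correlations) remain available via
`dual_components`/`dual_scores`, and their interval bounds via
`dual_interval_loadings`.

## Best Point objectives and optimizer

φ(Z, s) fits PCA on Z, standardizes the full vertex matrix with respect
to Z (√n·σ scale, so the subspace passes through Z's standardized
origin), and sums squared residuals against span{w_1..w_s}; it equals
total minus explained inertia of the standardized vertices, is
non-increasing in s and vanishes at s = m. Λ(Z, s) is the sum of the
top-s correlation eigenvalues; 0 ≤ Λ ≤ m with Λ(Z, m) = m.

Both objectives are continuous but only piecewise smooth in Z
(eigenvalue crossings), so line-search robustness matters more than
gradient exactness. The search reparameterizes Z = a + t∘(b−a),
t ∈ [0,1]^{n·m} (uniform, scale-free bounds; entries with a = b are
fixed and excluded), and runs projected quasi-Newton (L-BFGS-B) with
central finite-difference gradients (step 1e-6 in t-space) from the
mandatory center start t = 1/2; a derivative-free cyclic
coordinate-descent/golden-section fallback is selectable. Convergence is
declared when the absolute objective change between iterations falls
below `tol` (default 1e-8) or after `max_iter` (default 500) iterations.
Iterates whose Z develops a constant column get a large finite penalty
(1e12), which the line search rejects. The returned matrix is the best
*evaluated* point, so the criterion at the result is never worse than at
the center start — the monotone-improvement guarantee is exact, not
asymptotic. With `n_starts > 1`, seeded random corner starts are added
and the best final objective wins, ties to the lowest start index;
identical configurations (including seed) give identical results. No
global-optimality claim is made; on the faces data the single center
start already lifts the retained first-component inertia from 46.5% to
79.0% of the total (s = 1). Where a component count is not specified, s defaults to 2, the
plotted principal plane.

The comparison table's φ column evaluates each method's fitted matrix
under its own basis; for the vertex method — whose fitted matrix is the
vertex stack itself, not a realization — φ is reported as the corner
residuals in the vertex-PCA basis measured on the center-matrix
standardization, making the column comparable across methods. Only the
ordering of this column (distance-optimal ≤ center) is asserted
anywhere: the absolute values depend on the s and scaling conventions
chosen, so only the ordering is meaningful across conventions.

## Synthetic generator

`synthesize_interval_matrix` emulates morphometric interval data:
midpoints follow a correlated Gaussian driven by two latent factors
(100 + 10·FLᵗ + N(0, 2²), so a genuine two-component structure exists at
realistic measurement scales), and half-widths are independent |N(0,1)|
— comparable to the faces data's typical interval widths relative to its
between-case spread. It does not emulate within-case bound correlation,
outliers, or heavy-tailed widths; tests passing on it demonstrate the
algebraic and optimization guarantees (which are distribution-free), not
robustness to those real-data features. Width 0 reproduces classical
point data exactly: all four methods then collapse to the same classical
PCA with zero-width score intervals, which is tested.

## Numerical choices and limitations

- Eigendecompositions use dense symmetric solvers (`numpy.linalg.eigh`);
  eigenvalues are clipped at 0 against round-off. No sparse or iterative
  solvers: m is small in this problem class while N = Σ 2^{m_i} grows
  only the supplementary row count, which stays linear in the work.
- Constant columns are rejected with the column identified; interval
  standardization preserves bound order because the scale is positive.
- Closed-form interval scores agree with corner enumeration to 1e-10 in
  the tests (they are algebraically exact; the tolerance absorbs
  summation-order round-off).
- CSV round-trips are lossless (shortest-round-trip float formatting) in
  both dialects (`"[a,b]"` cells, or paired `.lo`/`.hi` columns).
- The test-suite and example problem sizes (27×6 data, 1728 vertex rows,
  162 optimization parameters; random instances up to n=6, m=8) keep any
  single check in seconds on one CPU while exercising every code path.
- Vertex-row enumeration is exponential per case; `m_i` beyond ~20
  nondegenerate intervals is impractical for the vertex method and φ,
  though the closed-form interval scores remain cheap at any m.
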