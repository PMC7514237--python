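# intervalpca

Principal component analysis for **interval-valued (symbolic) data**.

When each observation aggregates a sequence of classical measurements — a
series of images of the same face, repeated morphometric measurements of
the same specimen — a variable's value for a case is not a number but a
closed interval `[a_ij, b_ij]` carrying the case's internal variation.
`intervalpca` fits principal components to an n×m matrix of such
intervals with four methods:

- **center** — classical correlation PCA on the midpoint matrix
  `X^c = (a + b)/2`, with every hyper-rectangle corner projected as a
  supplementary element;
- **vertex** — correlation PCA fitted directly on the stacked corner
  matrix `X^v` (N = Σ_i 2^{m_i} rows, `m_i` = a case's nondegenerate
  intervals);
- **Best Point Distance** — the PCA base matrix `Z` is *optimized* inside
  the interval box to minimize the vertex-to-subspace squared distance
  `φ(Z) = Σ_i ‖x̃_i^v − P_{β(Z)} x̃_i^v‖²`;
- **Best Point Variance** — `Z` is optimized to maximize the retained
  inertia `Λ(Z, s) = Σ_{k≤s} λ_k^Z`.

For any fitted basis, each case's score on component k is itself an
interval. Because projection is linear in the data, the extremes over the
`2^{m_i}` corners have a closed form: the lower score pairs every
negative loading with the upper bound (and vice versa),

```
y_ik^lo = Σ_{j: w_kj<0} (b_ij − Z̄_j) w_kj + Σ_{j: w_kj≥0} (a_ij − Z̄_j) w_kj,
```

and symmetrically for the upper score — no corner enumeration needed.
The same sign-split argument applied to the case-side (dual) eigenvectors
of `Z̃Z̃ᵗ` bounds each variable's correlation-circle coordinate over every
realization `Z′` of the box; the package carries the full duality
(`u_ℓ = Z̃ᵗv_ℓ/√λ_ℓ`, `v_ℓ = Z̃u_ℓ/√λ_ℓ`).

## Worked example

The packaged faces dataset holds 27 cases (nine subjects × three image
sequences) × 6 interval-valued facial distances, in pixels.

```python
import intervalpca as ip

faces = ip.load_faces()
result = ip.IntervalPCA(faces, method="center", n_components=2,
                        sign_anchors=("X4", "X3")).fit()
print(result.summary())
```

prints

```
Interval PCA results
==========================================================
Method:            Center
Cases / variables: 27 / 6
Components (s):    2
Vertex rows:       1728
phi (vertex dist): 131.6833
----------------------------------------------------------
component     eigenvalue     % var     cum %
PC1               2.7877     46.46     46.46
PC2               2.0442     34.07     80.53
PC3               0.5472      9.12     89.65
PC4               0.3242      5.40     95.06
PC5               0.2344      3.91     98.96
PC6               0.0623      1.04    100.00
----------------------------------------------------------
Correlation of variables with retained components:
     PC1   PC2
X1  0.61 -0.60
X2  0.47 -0.69
X3  0.83  0.15
X4  0.88 -0.12
X5 -0.52 -0.62
X6 -0.47 -0.73
```

The first two components of the midpoint PCA retain 80.5% of the
inertia; the eye-to-lip distances (X3, X4) load strongest on PC1, the
lip-to-mouth distances (X5, X6) oppose it. `result.scores` holds the
per-case score intervals (`result.scores_frame()` formats them;
FRA1's PC1 interval is `[-2.97, -1.75]`), and
`result.plot_principal_plane(path="plane.png")` draws every case as a
rectangle on the principal plane. Running the Best Point methods instead,

```python
results = ip.compare(faces, sign_anchors=("X4", "X3"))
print(ip.variance_table(results).round(2))
```

```
     Center  Vertex  Best Point Distance  Best Point Variance
PC1   46.46   42.66                45.94                58.61
PC2   80.53   72.64                80.93                97.15
PC3   89.65   83.34                91.24                99.17
PC4   95.06   91.27                95.83                99.60
PC5   98.96   96.86                99.23                99.87
PC6  100.00  100.00               100.00               100.00
```

the variance-optimal base matrix lifts the principal-plane inertia from
80.5% to 97.2%, and the distance-optimal one roughly halves φ
(131.7 → 67.6, see `ip.distance_table(results)`).

A CLI wraps the same pipelines:

```sh
ipca fit --input faces.csv --dialect bracket --method bp-variance --components 2 --out results/ --plot
ipca compare --input faces.csv --out report/
ipca synth --n 27 --m 6 --seed 1 --out synth.csv
```

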