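# inventropy

Scale-invariant differential entropy and mutual information, estimated
nonparametrically from k-nearest-neighbor distances.

## The problem

Differential entropy h(X) = −∫ μ(x) ln μ(x) dx is not an intrinsic
property of a distribution: under Y = aX it shifts by ln|a|, so the
value depends on whether you measured in meters or millimeters. The
same unit-dependence corrupts kNN mutual-information estimation when
variables live on disparate scales — with X ~ N(0, 0.1) and
Z ~ N(0, 10), the Z coordinate dominates the joint Euclidean metric and
the estimated MI(X;Z) of *independent* variables diverges to negative
values. Anyone running MI-based dependence screens on mixed-unit data
(gene expression panels, sensor arrays, heterogeneous clinical tables)
hits this failure mode.

## The method

The package estimates an **invariant measure** m(X) — an intrinsic
scale of the sample — as the median of nearest-neighbor distances:

    dᵢ = min_{j≠i} |xᵢ − xⱼ|,      m(X) = median(d)

m is positive, translation-invariant and scale-equivariant
(m(aX+b) = |a| m(X)), and robust to outliers. The **invariant entropy**
is the entropy of the rescaled variable,

    h_c(X) = h(X / m(X)) = h(X) − ln m(X),

estimated with the Kozachenko–Leonenko kNN estimator
ψ(N) − ψ(k) + ln c_d + (d/N) Σ ln εᵢ. Because the median 1-NN distance
shrinks like 1/N, the estimator subtracts ln N per normalized variable
block (equivalently: it normalizes by the stabilized scale N·m, which
converges to a constant), so h_c converges to an N-independent value in
nats that is *identical for every member of a location–scale family* —
a fingerprint of the family's shape. Joint entropy normalizes each
marginal by its own m, and

    MI_c(X;Y) = h_c(X) + h_c(Y) − h_c(X,Y)

is invariant under independent affine maps of the inputs; the ln N
corrections cancel identically in the difference.

## Worked example

The nine-point sample X = {2, 3, 5, 7, 11, 17, 19, 23, 29}:

```python
>>> import numpy as np, inventropy as iv
>>> x = np.array([2, 3, 5, 7, 11, 17, 19, 23, 29.])
>>> iv.knn_distances(x, 1).dists.tolist()
[1.0, 1.0, 2.0, 2.0, 4.0, 2.0, 2.0, 4.0, 6.0]
>>> iv.invariant_scale(x).m                  # median of d
2.0
>>> round(iv.invariant_scale(x, center="mean").m, 2)
2.67
```

Appending an outlier at 100 leaves the median scale at 2.0 but drags
the mean to 9.50 — why the median is the default.

Family fingerprints (mean ± sd of h_c over 100 replicates of
n = 10,000, k = 1):

```python
>>> rep = iv.run_table2(families=["uniform", "normal", "levy"],
...                     n=10_000, replicates=100, seed=0)
uniform  1.061 +/- 0.012
normal   1.150 +/- 0.014
levy     1.974 +/- 0.025
```

These constants hold for *any* location/scale parameters of each
family (the uniform's limit has the closed form
ln 2 − ln ln 2 ≈ 1.0597). The semi-analytic large-N oracle
`asymptotic_invariant_entropy` gives the limits by solving the median
equation E_f[exp(−t f(X))] = ½ for t* and returning
ln 2 + h(f) − ln t*.

## Command line

```
$ inventropy simulate --family normal --params 0,2 --n 10000 --seed 42 --out s.csv
$ inventropy entropy --input s.csv --col normal --report-scale
column  n      k  variant    entropy_nats        m
normal  10000  1  invariant  1.1537408611939792  0.00026827234849002846
```

The estimate sits at the normal family constant 1.150 even though this
sample has σ = 2. Also available: `mi`, `mi-matrix` (pairwise MI over
table columns), and `validate` (the built-in simulation designs
`table1`, `table2`, `fig1`, `fig2`).

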