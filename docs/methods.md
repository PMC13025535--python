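# Methods

## Model and estimator

For a continuous random variable X with density μ, differential
entropy h(X) = −∫ μ ln μ transforms as h(aX) = h(X) + ln|a|: it
measures uncertainty *relative to the measurement unit*. The package
removes the unit by comparing each sample to its own intrinsic scale.

**Invariant measure.** m(X) is the median of nearest-neighbor
distances d_i = min_{j≠i} |x_i − x_j| (1-NN by default; Euclidean
metric throughout, also in d dimensions). The median — rather than the
mean — makes m robust to outliers and, empirically, keeps the
resulting entropy non-negative for every family we ship; the mean of
1/f(X)-driven NN distances is unstable for unbounded supports and
drives the estimate negative (the package retains the mean variant,
clearly non-default, precisely to demonstrate this).

**Invariant entropy.** h_c(X) = h(X/m(X)) = h(X) − ln m(X), estimated
by the Kozachenko–Leonenko kNN form

    ĥ = ψ(N) − ψ(k) + ln c_d + (d/N) Σ_i ln ε_i,

with ε_i the k-th-NN distance and c_d = π^{d/2}/Γ(d/2+1) the unit-ball
volume (c_1 = 2, c_2 = π); natural logarithms, values in nats.

**ln N stabilization.** The median 1-NN distance shrinks like 1/N, so
the raw plug-in ĥ(X/m) grows like ln N. The package subtracts ln N per
normalized variable block:

    ĥ_c(X) = ĥ(X/m) − ln N  ≡  ĥ(X/(N·m)).

N·m converges to an intrinsic constant (see the oracle below), so ĥ_c
converges to an N-independent family fingerprint. This convention is a
deliberate reconstruction: it is the only form consistent with
N-stable published constants (uniform 1.060 ≈ ln2 − ln ln2, normal
1.150, exponential = Laplace 1.227, …), and it cancels identically in
mutual information, so no MI value depends on it.

**Joint entropy and MI.** For blocks X₁,…,X_B sharing N rows, each
block is divided by its own marginal m_j, the normalized blocks are
concatenated, and B·ln N is subtracted. Normalizing per marginal makes
joint Euclidean distances invariant under independent affine maps of
the blocks, which is exactly what standard kNN MI lacks when scales
differ. MI_c = h_c(X) + h_c(Y) − h_c(X,Y); the decomposition (not a
KSG-style shared-ε estimator) is used deliberately, because the
disparate-scale pathology and its remedy live in the decomposition —
a KSG estimator would mask the failure mode the baselines exist to
show.

## The large-N oracle

At a point with density f, the 1-NN distance in a sample of size N is
asymptotically exponential with rate 2Nf (length 2s interval in 1-D).
The median m therefore satisfies E_f[exp(−2Nm·f(X))] = ½; writing
t = 2Nm, the stabilized scale converges to t* solving

    g(t) = E_f[exp(−t·f(X))] − ½ = 0,

with g strictly decreasing from ½ to −½ (bracketed Brent root-find).
The stabilized estimate converges to

    h_c∞ = ln 2 + h(f) − ln t*.

Closed checks: uniform f ≡ 1/(b−a) gives t* = ln 2 and
h_c∞ = ln2 − ln ln2 ≈ 1.0597; Exp(1) reduces to (1−e^{−t})/t = ½
(t* ≈ 1.5936, h_c∞ ≈ 1.2269); the Laplace has t* twice the
exponential's and h larger by ln 2, hence the same h_c∞. The
expectation is integrated in the probability scale u = F(x)
(∫₀¹ e^{−t f(F⁻¹(u))} du), which maps heavy tails (Cauchy, Lévy) and
edge singularities (arcsine) to a bounded integrand on [0,1];
simulation at n = 10,000 agrees with the oracle within ~0.005 nats for
all 14 families. This oracle was verified against brute-force
simulation before being trusted in tests.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| k (entropy/MI) | 1 (entropy), 5 (CLI MI) | neighbor order of the KL estimator; estimates are flat in k ∈ [3,30] by design |
| k for m(X) | always 1 | the scale is always the median 1-NN distance, regardless of the estimator's k; coupling m to the estimator's k would make the fingerprint drift with k |
| center | median | mean variant retained only for the robustness comparison |
| jitter | off | duplicates raise by default; opt-in deterministic jitter of 1e-10 × per-column IQR (seeded) for real data with ties |
| bins (histogram MI) | — | equal-width per axis over [min, max]; the simplest rule that is exactly invariant under increasing affine maps |

## Synthetic data

The 14 families (arcsine, uniform, semicircle, triangular, raised
cosine, normal, Rayleigh, chi, Gumbel, logistic, exponential, Laplace,
Cauchy, Lévy) are backed by scipy.stats frozen distributions with the
conventional parameterizations; chi defaults to ν = 1 (half-normal),
which reproduces the published 1.149 fingerprint. Sampling is seeded
per replicate (replicate r of block i uses base + i·replicates + r),
so every experiment is bit-for-bit reproducible from its config echo.
The independence study draws X ~ N(0, 0.1), Y ~ N(0, 1), Z ~ N(0, 10).

What the generator does *not* emulate: real data's ties and
quantization (only the jitter path exercises ties), dependence
structures beyond bivariate Gaussian correlation, and mixed
discrete–continuous variables (out of scope). A green simulation test
establishes estimator correctness under smooth i.i.d. sampling, not
performance on quantized or heavily tied measurements.

## Numerical choices and degenerate inputs

- 1-D kNN distances use an O(N log N) sorted-window path (the k nearest
  lie among the k predecessors/successors in sorted order); d ≥ 2 uses
  a KD-tree. The two paths agree to machine precision.
- Even-N median = midpoint of the two middle order statistics.
- Exact duplicates (zero distances) are a hard error naming the
  offending indices — a zero ε breaks ln ε — with the jitter opt-in
  above. All-identical samples are rejected ("degenerate sample").
- Affine invariances hold to ~1e-9 under floating point (translation
  moves mantissa bits, so equality is relative, not bitwise).
- Oracle quadrature: adaptive on [0,1] in probability scale, absolute
  tolerance 1e-10; root-finding tolerance 1e-12.

## Known limitations

- **Near-independence bias of the decomposition.** The 2-D joint KL
  estimator carries a finite-sample bias (≈ −0.013 nats at n = 5,000,
  k = 10 for independent equal-scale normals, decaying with n), so
  MI estimates near independence have a small positive bias of
  ~0.005–0.02 nats that grows with k. It appears identically with and
  without invariant normalization — it is a property of the
  entropy-decomposition route, not of the invariant measure — and is
  three orders of magnitude smaller than the ~1-nat negative
  divergence it replaces. Statistically sharp zero tests over many
  replicates will resolve it.
- Single-block multidimensional invariant entropy is *not* additive
  over independent coordinates: the ball-geometry constant differs
  between R^d and a product of per-marginal normalizations (unit
  square: ln(π/ln2) ≈ 1.511 single-block vs 2(ln2 − ln ln2) ≈ 2.119
  per-block). Use `joint_invariant_entropy` when additivity across
  variables is the semantics you need.
- Non-negativity of h_c is an empirical regression across the shipped
  families, not a theorem.
- The mean-based variant's numeric values are N-dependent (heavy-tailed
  1/f moments); only their sign is meaningful.
- No bias correction, Rényi orders, mixed discrete–continuous support,
  or non-Euclidean metrics.
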