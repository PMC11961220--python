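# Methods

## The aggregation problem

A protein language model maps a sequence of length *n* to *n* per-residue
embedding vectors in R^d.  Protein-level prediction needs one fixed-length
vector per protein, so the variable-size set {x_1, …, x_n} must be
summarized by a permutation-invariant, size-invariant aggregation map
π: (R^d)^n → R^L.  The ubiquitous choice, average pooling
π_avg = (1/n) Σ_i x_i, weighs every residue equally; when the
label-relevant information sits in a few residues (active sites, binding
pockets), averaging attenuates it by the factor k/n, which grows worse
with sequence length.

## Sliced-Wasserstein embedding (SWE)

`swepool` treats the token set as an empirical distribution and embeds it
by optimal transport against a trainable reference distribution.  Because
high-dimensional Monge couplings have no closed form, the comparison is
*sliced*: L trainable directions ω_l ∈ R^d project both the input set and
the reference onto 1-D distributions, where the optimal coupling is
computed by sorting.

For slice l, write u_il = ω_l·x_i for the projected input values and
u⁰_il for the m reference values of that slice (the reference is
parameterized directly at the slicer outputs, not as raw points in R^d).
The coupling vector z_l ∈ R^m is:

* **equal sizes (n = m):** z_il = u_{ρ[ρ₀⁻¹[i]], l} − u⁰_il, where ρ sorts
  the projected input and ρ₀⁻¹[i] is the rank of reference element i —
  i.e. the difference of rank-matched sorted values;
* **unequal sizes (n ≠ m):** z_il = F_l⁻¹(ρ₀⁻¹[i]/m) − u⁰_il, with F_l⁻¹
  the interpolated inverse empirical CDF of the projected input.

Stacking the L couplings gives Z ∈ R^{L×m}; a learned combination
w ∈ R^m across reference elements yields the protein embedding
π(x_1,…,x_n) = Z w ∈ R^L.  The trainable parameters are
θ_π = ({u⁰_il}, {ω_l}, w): mL + dL + m in total, or only the m entries of
w in the SWE_Simple variant, where slicers and reference stay frozen at
their random initialization.  L defaults to d so the pooler is a drop-in
replacement for average pooling.

### Quantile convention

F⁻¹ is the piecewise-linear interpolation through (k/n ↦ k-th smallest
value), k = 1..n, with F⁻¹(p) = min value for p ≤ 1/n, evaluated at
positions q_i = ρ₀⁻¹[i]/m with 1-based ranks.  This is the unique simple
convention under which the unequal-size path reduces *exactly* to the
equal-size path at n = m; the reduction is asserted to 1e-12 per
coordinate in the tests.  The midpoint alternative (q = (i−½)/m) does not
have this property and was not used.  The position q·n is computed with
an exact integer numerator, n·(rank+1)/m, so the reduction holds to
floating-point exactness rather than merely approximately.  At m = 1 the
single evaluation position is q = 1, i.e. F⁻¹(1) = max input value; this
falls out of the convention and is not special-cased.

### Ties, permutations, determinism

Both sorts are stable (ties broken by original index), making ρ and ρ₀⁻¹
deterministic functions of the data, so pooling is bit-reproducible and
permutation invariance holds bit-exactly even with tied values.

### Differentiation

Given fixed sort permutations the map is piecewise linear in all of Ω,
U⁰ and w, so the backward pass implements the exact analytic gradient
with the permutation treated as constant — the almost-everywhere gradient
of the map.  Gradients are verified against central finite differences
(agreement to ~1e-8) and the number of coordinates receiving nonzero
gradient equals mL + dL + m exactly (m when frozen), which is the
trainability contract.

### Initialization

Slicer rows are i.i.d. N(0, 1/d) (unit-scale projections for unit-scale
tokens); reference slice values are i.i.d. N(0, 1); w starts at the
constant 1/m, so the initial output is a mean over reference-aligned
couplings.  Slicers are left unconstrained (no unit-norm or orthogonality
projection); normalizing them is a known alternative in the sliced-OT
literature but adds a coupling between parameters that plain gradient
descent handles poorly, and the unconstrained version trains well here.

### Batching

Variable-length batches are pooled by iterating over the valid rows of a
padded array; padded positions never enter the sort or the CDF, so
padding content cannot influence the result (a tested contract).

## Baseline poolers

Average, max, K-max (per-dimension mean of the K largest values, K
clamped to n; default K = max(1, ⌈0.05·n⌉)) and softmax pooling
(log-mean-exp per dimension, computed max-shifted).  All are
unparameterized, permutation invariant and size invariant.  Empty token
sets are rejected rather than mapped to zeros — a length-0 protein has no
meaning.

## Task heads and losses

* **Binary DTI:** drug fingerprint f ∈ R^c and pooled protein embedding
  are mapped by linear projections S ∈ R^{D×c}, V ∈ R^{D×d} followed by
  ReLU into the non-negative orthant of a shared co-embedding space
  (D = 1024 by default).  On that orthant the cosine of the two
  projections lies in [0, 1] and serves directly as the interaction
  probability, trained with binary cross-entropy on the cosine.
  Numerical guards: norms clamped at 1e-8, log arguments clipped to
  [1e-7, 1−1e-7]; the clipped region is treated as flat in the backward
  pass.
* **Affinity regression:** same projections; the inner product of the two
  co-embeddings predicts the affinity, trained with squared error.
* **10-class classification:** a single linear head U ∈ R^{10×d} with
  softmax cross-entropy (max-shifted).  Accuracy is top-1 with argmax
  ties resolved to the lowest class index.
* **Binary enzyme-activity classification:** a two-layer perceptron with
  a d-dimensional hidden layer and LeakyReLU (negative slope 0.01),
  softmax cross-entropy over two logits.  This head is also used for the
  synthetic binary benchmark.

## Metrics

AUROC follows the Mann-Whitney pairwise convention (half credit for
ties); AUPR is the step-wise average-precision convention with no
interpolation — stated explicitly because AUPR conventions differ;
Fmax is the maximum F1 over the threshold rule score ≥ t with t ranging
over the observed scores plus −∞ (which covers every achievable
confusion matrix); PCC is the ordinary Pearson correlation, undefined
(error) on zero-variance input.  Multi-seed results are reported as mean
and sample standard deviation (ddof = 1; a single seed reports std 0
with an explicit flag).

## Training and selection protocol

Empirical risk minimization by mini-batch Adam (learning rate 1e-3,
batch size 64, β = (0.9, 0.999)); the token embeddings are frozen inputs
— only θ_π and the head parameters receive gradients.  Per epoch the
validation metric (AUPR for DTI, PCC for affinity, accuracy for the
10-class task, Fmax for the binary enzyme task) is recorded, and the
parameters of the best validation epoch are kept.  Hyperparameter
selection trains every (m, freeze) configuration and picks the highest
validation value across configurations *and* epochs; ties break to
smaller m, then to frozen (fewer trainable parameters).  The selected
configuration is re-trained over several seeds (five by default) and the
test metric is reported as mean ± std.  Fixed seed implies bit-identical
histories and reports on one platform.

The full-scale reference grid is m ∈ {100, 200, …, 1000} × freeze ∈
{true, false}; the default grid for synthetic desk-scale runs is
m ∈ {8, 16, 32} × freeze, which the config file can override.

## Synthetic benchmark: what it emulates and what it does not

The generator plants localized signal: each protein is n i.i.d.
N(0, σ² I_d) background tokens (n uniform on [length_min, length_max]),
and k key tokens at random positions additionally carry a mean shift of
magnitude μ along a label-dependent unit direction — one direction for
binary positives, ten orthogonal directions for the 10-class task, a
label-scaled direction for regression, and a drug-specific direction
â = A f / ‖A f‖ (A a fixed latent d×c map) for DTI triplets, with
non-interacting pairs planted along an unrelated random direction.

The average-pooled class-mean gap is then exactly (k/n)·μ per protein of
length n — verified empirically to within 5% — so difficulty grows with
length by construction, reproducing the mechanism by which averaging
loses localized information.  The default benchmark conditions are
d = 32, 3000 proteins, lengths 50–1000, k = 5, μ = 3.0, σ = 1.0,
balanced classes, seed 1.

What the generator does **not** emulate: correlations between residue
embeddings along the chain, anisotropic or heavy-tailed embedding noise,
length-composition confounds, multiple signal motifs per protein, and
any actual sequence-to-embedding model.  Passing the benchmark therefore
shows that the pooler can recover localized signal that averaging
dilutes — the mechanism, not the magnitude, of gains to be expected on
real embeddings.

On these conditions (m = 16, trained slicers/reference, 20 epochs, 5
seeds), the trained SWE pooler reaches a markedly higher test AUPR than
average pooling and the per-length-quartile AUPR gain is largest in the
longest quartiles; the exact numbers are computed by the test suite and
by `scripts/acceptance.py`, not quoted here.

## Numerical and design notes

* The exact-OT oracle module shares no code with the pooler: equal-size
  W1 is a direct sorted-matching sum, the general case goes through the
  transportation LP (HiGHS) for small instances (guarded at n·m ≤ 10⁴)
  and through the closed-form empirical-CDF distance for large ones; the
  two are cross-checked against each other where both apply.
* Problem sizes in the test suite and acceptance script (grids of a few
  configurations, 10–20 epochs, hundreds to thousands of proteins) were
  chosen so a complete run finishes in minutes on a single CPU while
  still exercising every code path at the stated benchmark conditions.
* Indexing is 0-based internally; rank formulas stated 1-based above are
  translated mechanically.

## Known limitations

* Training is plain NumPy on one CPU; it is intended for the synthetic
  benchmark and for moderate precomputed-embedding datasets, not for
  full-scale grids over m up to 1000 on millions of pairs.
* The pooler's gradient ignores the measure-zero set where sort order
  changes; optimizers that rely on exact subgradients at ties are out of
  scope.
* The precomputed-embedding container is the only implemented adapter;
  running a language model to fill it is external to this package.
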