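# Methods

## The model

A cytosine locus in a diploid genome carries one of three epigenotypes —
u/u, m/u, m/m — coded 0, 0.5 and 1. Spontaneous epimutations switch a
single epiallele u→m with probability α and m→u with probability β per
pedigree time unit (a generation for mutation-accumulation lines, a year
for the somatic phylogeny of a tree). The locus then evolves as a
three-state Markov chain whose one-step kernel **G** depends on the
propagation system:

- **selfing** — gametes segregate, so an m/u parent produces u/u, m/u,
  m/m offspring in the Mendelian 1:2:1 ratio before epimutation acts;
- **clonal/somatic** — the two alleles simply switch independently, with
  no segregation.

Selection enters as a Hadamard weight matrix **W** on the transitions
into each epigenotype column: against u (`ABmm`, columns w, (w+1)/2, 1)
or against m (`ABuu`, columns 1, (w+1)/2, w), with w ∈ [0,1] and w = 1
neutral. Because weighting breaks row sums, the working kernel is the
row-normalized **G′** = diag(rowsums(G∘W))⁻¹ (G∘W). Four model forms are
distinguished: `ABneutral` (w = 1), `ABmm`, `ABuu`, and the
no-accumulation null `ABnull` (α = β = 0, w = 1), which degenerates to
an intercept-only regression and is solved in closed form.

The observable is the mean absolute divergence between two samples,
D = mean |s_i − s_j| over shared loci, regressed on the pedigree:

    D_q = c + D*_q(Θ) + ε_q,    ε_q ~ N(0, σ²)

with, for pair q with sample times t_i, t_j and most recent common
ancestor at t_ij (the founder sits at internal time 1),

    D*_q = Σ_n [π G′^(t_ij−1)]_n Σ_{l,m} I(l,m) (G′^(t_i−t_ij))_{n,l} (G′^(t_j−t_ij))_{n,m},

I(l,m) = |s_l − s_m|. The founder state vector π is built from the
observed u/u and m/m proportions (p1, p3) of the founder (or, absent a
founder sample, their across-sample means): π = (p1, r + γ·p3,
(1−γ)·p3), where r is any directly observed intermediate mass and
γ ∈ [0,1] is a free parameter splitting the observed methylated mass
into hidden epiheterozygotes — status callers typically emit only
binary U/M calls, which is why γ exists. The intercept c absorbs
divergence created by measurement error rather than by inheritance.

Estimation minimizes

    Σ_q (D_q − D*_q(Θ) − c)² + M (p̄1 − p1(t∞, Θ))²

where p̄1 is the across-sample mean u/u proportion and p1(t∞, Θ) the
model's equilibrium u/u proportion — in closed form for neutral selfing
and clonal kernels, numerically (dominant left eigenvector of G′) under
selection. The penalty anchors the otherwise weakly identified α:β
ratio and presumes the sampled methylomes are near equilibrium; the
`ABnull` fit omits it (its equilibrium is undefined).

## Numerics

- Matrix powers G′^τ, including non-integer τ for year-scaled trees,
  use the eigendecomposition; imaginary parts below 1e-9 are clamped
  and degenerate (non-diagonalizable) kernels fall back to exact
  integer powers or `scipy.linalg.fractional_matrix_power`.
- The optimizer is Nelder–Mead (the method's convergence on this
  objective is known to be temperamental) with seeded random restarts
  (default 50), a deterministic heuristic first start, and one polishing
  pass from the best run. α, β, γ, w are logit-transformed to the real
  line and c is fitted on log scale; the optimizer minimizes the *log*
  of the objective so the function tolerance acts relatively, which
  keeps the stopping rule meaningful whether the RSS is 1e-3 or 1e-22.
- The optimizer's hot loop uses a closed-form spectral decomposition:
  a row-stochastic 3×3 kernel has eigenvalue 1 with right eigenvector
  (1,1,1), and the other two eigenvalues solve a quadratic in
  trace and determinant. Repeated, complex, or otherwise degenerate
  spectra fall back to the general numpy/scipy path, which is also the
  reference implementation used for all reported results; agreement of
  the two paths is itself under test.
- Degrees of freedom: df = M − k with k = 4 free parameters for
  `ABneutral` (α, β, γ, c), 5 for `ABmm`/`ABuu` (+w), 1 for `ABnull`
  (c). The nested F test uses F = ((RSS_R − RSS_F)/(df_R − df_F)) /
  (RSS_F/df_F) with p-values from F(df_R − df_F, df_F). A full-model
  RSS above the reduced one flags optimizer failure and clamps F to 0.
- Confidence intervals are percentile intervals from a residual
  bootstrap (default B = 1000): the response is rebuilt as fitted +
  resampled residuals and refit, warm-started at the point estimate.
- Tree age dating profiles the minimized objective over a grid of
  candidate founder ages, rebuilding divergence times (pair divergences
  are age-independent and cached); ties break toward the smallest age.
  `ABnull`'s γ is fixed at 0, so its founder π carries only directly
  observed intermediate mass.

## The simulator and what a green test establishes

The forward simulator draws founder states i.i.d. from a supplied π
(defaulting, in the package's study designs, to the kernel's stationary
distribution — the same near-equilibrium premise the p̄1 penalty makes),
advances them along every pedigree edge, and corrupts each *emitted*
sample by flipping a locus to one of the two other states with a
symmetric misclassification probability. Two stepping modes exist: one
multinomial draw per integer time unit (the literal generative story;
non-integer durations are an error), or a single draw per edge from
G′^duration, which is distributionally identical by Chapman–Kolmogorov
and used where speed matters.

The simulator emulates: independent loci, a known pedigree, equilibrium
founders, homogeneous rates, and state-symmetric measurement error. It
does **not** emulate rate heterogeneity along the genome, linkage,
context mixtures, coverage-dependent call quality, or partial
methylation within tissues. A green recovery test therefore establishes
the estimator's correctness under the model's own assumptions, not
robustness to their violation.

Default synthetic worlds: mutation-accumulation designs use per-
generation rates α = 1e-3, β = 4e-3 with 50,000 loci and 0.2%
misclassification (CG-scale rates and a realistic high-confidence locus
count); the synthetic two-stem tree used for age profiling is 330 time
units old with branch points dated 40–250 units before present,
per-unit rates α = 1e-5, β = 3e-5, one million loci and 5e-4
misclassification — chosen by a design-time power analysis so that the
age-profile curvature exceeds locus-sampling noise with a comfortable
margin (the profile recovers the true age exactly on noise-free
expectations, so the machinery is unbiased).

## Known limitations

- **Measurement-error attenuation.** Symmetric misclassification at
  rate e both offsets the divergence (absorbed by c) and *attenuates*
  its slope by ≈ (1−2e)², and it perturbs the observed p̄1 entering the
  equilibrium penalty. Rate estimates are therefore biased low by
  roughly the attenuation factor (≈1.5% at e = 0.2% in dense selfing
  designs). Dense pedigrees with very many pairs produce bootstrap
  intervals narrower than this bias; interval coverage of the truth is
  then not guaranteed. No errors-in-variables correction is attempted.
- **Residual-bootstrap undercoverage on all-pairs divergence data.**
  Pair divergences sharing a sample have correlated errors (the shared
  sample's realized epimutations shift all its pairs coherently;
  correlation ≈ ½ for pairs of equal path length), so the estimator's
  true sampling variance carries a design effect that within-dataset
  residuals cannot express. In simulation, 95% percentile intervals for
  the gain rate cover the truth in roughly 65–75% of clonal
  mutation-accumulation datasets — at any locus count, since the
  correlation is scale-free — and the gap widens in few-stem somatic
  trees (two independent stems: estimates scatter several percent
  between tree realizations while intervals span ±1–2%, coverage
  30–50%). Selfing designs fare better because segregation noise adds
  pair-specific variance. Interval estimates, especially from trees,
  should be treated as optimistic; a sample-level (rather than
  pair-level) resampling scheme would be the principled remedy but is
  not part of the residual-bootstrap procedure implemented here.
- **Observed heterozygotes vs. binary calls.** The divergence coding
  assumes the observed states are true diploid epigenotypes. If
  heterozygous loci are force-called to M (binary callers), divergence
  involving heterozygotes is overstated and rates inflate well beyond
  the γ correction, which only adjusts the founder vector. Inputs with
  intermediate calls preserved are strongly preferable.
- **Selection is detectable only off equilibrium.** A population whose
  founder already sits at the stationary distribution of the *selected*
  kernel evolves stationarily, and a neutral kernel with adjusted rates
  reproduces its expected divergence to ~1e-4 — the nested F test then
  has essentially no power at any realistic locus count. Power against
  w < 1 comes from the transient created when selection acts on a
  previously-neutral methylome (founder at the neutral equilibrium of
  the rates), which is how the package's selection-power checks are set
  up. Selection tests on long-stationary natural systems should be
  interpreted accordingly.
- The closed-form equilibria hold only at w = 1; under selection the
  stationary distribution is computed numerically.
- Sibling-mating pedigrees have no implemented kernel; two-parent
  pedigree nodes are rejected.
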