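# Methods

## Model and estimators

A Markov state model over p discrete states at lag τ is estimated from state
sequences by sliding-window counting: every pair (s_t, s_{t+τ}) adds one to
C0t; C00 and Ctt are the diagonal row/column marginals. Estimation is
restricted to the largest strongly connected component of the count graph
(ties between equal-size components go to the one containing the lowest
state index). The nonreversible estimator is the row normalization
T_ij = c_ij / c_i. The reversible estimator maximizes the likelihood
Σ c_ij ln T_ij subject to detailed balance via the standard fixed point on
the symmetric flux matrix X:

    x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j),   T_ij = x_ij / x_i,

initialized from the symmetrized counts. The iteration ascends the
likelihood; convergence requires the relative log-likelihood change to drop
below `tol` (default 1e-10) **and** the transition matrix to settle
(max |ΔT| ≤ max(100·tol, 1e-13)). The second condition matters because the
likelihood is flat to second order at the optimum: a likelihood-only stop
can leave T wrong at ~sqrt(tol) while the likelihood has converged.
Default iteration cap 1e5; non-convergence raises with the final residual.

Spectral analysis of a reversible T uses the symmetric similarity transform
diag(π)^{1/2} T diag(π)^{-1/2} (guaranteed real spectrum); nonreversible
models use the generic solver sorted by modulus. Right eigenvectors ψ are
π-orthonormal (so ψ₁ ≡ 1), left ones are φ = π·ψ, and the first nonzero
entry of each ψ is made positive. Implied timescales t_i = −τ/ln λ_i are
reported only for λ_i ∈ (1e-12, 1); non-positive eigenvalues yield NaN, never
a number. MFPTs solve (I − T_free) m = τ·1 with m = 0 on the target set.

## Scores

GMRQ(k) = trace[(UᵀC00U)^{-1} UᵀC0tU] over the top-k eigenvectors.
VAMP-r(k) is the sum of the r-th powers of the top-k singular values of the
whitened matrix (UᵀC00U)^{-1/2} UᵀC0tV (VᵀCttV)^{-1/2}; inverse square roots
are symmetric with an eigenvalue floor of 1e-12 relative to the largest
eigenvalue, so rank-deficient projected metrics do not crash sweeps.
VAMP2_eq(k) = Σ_{i≤k} λ_i² of the reversible transition matrix; the constant
process is included in k, so VAMP2_eq(2) = 1 + λ₂².

For a reversible model scored against its own counts, two bases for the
whitened score are exposed: the default feeds the reversible eigenvectors
into U = V with the *raw* count matrices — the combination in which
score/timescale rank inversions arise, because the reversible π is not
consistent with the raw marginals — and a `nonreversible_svd` variant that
uses the singular functions of C00^{-1/2} C0t Ctt^{-1/2} itself. The
inversion is a second-order effect: the antisymmetric (non-equilibrium) part
of the count noise does not shift symmetric-matrix eigenvalues to first
order, so the discrepancy scales like 1/N while the replicate-to-replicate
spread of λ₂ scales like 1/√N. That is why the toy experiment shows
inversions at 20 steps and a rank correlation above 0.999 at 1e5 steps.

Within one replicate, t_i and VAMP2_eq(k) are computed from eigenvalues
rounded to 12 decimals. Both are exact monotone functions of the same λ₂;
without rounding, last-bit iterative-solver noise occasionally breaks ties
in one score but not the other and creates spurious rank differences. Twelve
decimals is far above solver noise (~1e-15) and far below any statistical
resolution. The package's Spearman wrapper additionally returns exactly ±1
when the two rank vectors are identical (or exactly reversed), which is the
mathematical value by definition.

## Bootstrap

Trajectories are cut into contiguous non-overlapping blocks of equal length
(trailing remainders dropped, so replicates are exchangeable equal-length
units); N_b = 100 resamples of n-of-n blocks with replacement; point
estimate and interval are the median and 2.5/97.5% quantiles of the valid
replicates. Replicate failures (disconnected counts, no resolvable slow
process, or a connected set losing more than half of the model's states) are
counted and reported as n_valid, never fatal. Summaries are invariant to
block ordering in distribution, not realization-by-realization: resampling
draws indices, so permuting the blocks permutes which replicate gets which
block while leaving the bootstrap distribution unchanged.

## Pipeline and synthetic data

The full pipeline is featurize → tICA → k-means → per-lag reversible MSM.
Features: sine/cosine of signed dihedral angles (convention (−π, π], trans
= π); pair distances with a minimum index separation (default 3); and the
logistic transform logit(d) = 1/(1 + exp(s(d − c))) with shared scalar c ∈
[3, 15] and s ∈ [0.01, 5] across all pairs. For synthetic point-mass systems
the closest-heavy-atom and α-carbon distance schemes degrade to a single
generic scheme; the scheme field is retained so search spaces keep their
shape. tICA symmetrizes C(τ), adds a shrinkage ridge 1e-10·trace/dim to
C(0), and optionally scales projections by their eigenvalues (kinetic map).
k-means uses k-means++ (scikit-learn) with max 500 iterations and relative
tolerance 1e-6, fitted on strided frames (default every 10th) but assigning
every frame; equidistant assignment ties go to the lowest center index.

The discrete generator samples chains by one vectorized pass over time
(identical seed ⇒ bit-identical output; initial states from π by default,
uniform by flag). The default three-state chain is

    T = [[0.90, 0.08, 0.02],
         [0.20, 0.60, 0.20],
         [0.02, 0.08, 0.90]],

two metastable states exchanging through a short-lived transition state,
reversible with π = (5/12, 1/6, 5/12) and exact eigenvalues (1, 0.88, 0.52)
by its mirror symmetry — t₂ = −1/ln 0.88 ≈ 7.82 steps. The continuous
generator integrates overdamped Langevin dynamics (explicit Euler–Maruyama,
k_BT = 1) in harmonic, symmetric double-well (V = h(x²−1)²) or flat
(reflecting box) potentials, with independent particles standing in for a
multi-dimensional system. The explicit scheme is stable only for
dt < 2/(D·max V″); simulation refuses larger steps. The reference slowest
timescale is computed by brute force: fine uniform discretization, nearest-
neighbour rates k(i→i±1) = (D/Δx²)·exp(−(V_{i±1}−V_i)/2) (detailed balance
w.r.t. exp(−V) by construction), and −1/λ₂ of the rate matrix. What this
data does **not** emulate: real MD has many coupled degrees of freedom,
anisotropic friction, and features whose slow content is entangled across
coordinates; passing tests here show the pipeline's statistical machinery is
correct, not that any particular protein analysis would be well-posed.
1-D particle data cannot produce dihedral angles, so dihedral trials on such
data are recorded as per-trial failures — the same bookkeeping path real
sweeps use for trials that fail to converge an MSM.

## Lag selection

Per bootstrap replicate the gradient |d ln t₂ / d ln τ| is evaluated on the
lag grid by central differences (one-sided at the ends); the per-lag median
over replicates is taken per trial; the selected lag τ* is the smallest grid
lag at which the maximum over trials is ≤ ε **and remains** ≤ ε for every
larger grid lag. No qualifying lag is a valid, flagged outcome (None).
ε defaults to 0.1 and is a config value. Raising ε can only move τ* earlier.

## TPE optimizer

Completed trials are split into good/bad at the γ = 0.25 quantile (ceiling;
ties by earlier trial index). Numeric parameters get a per-observation
truncated-Gaussian mixture with bandwidth max(nearest-neighbour distance,
(hi−lo)/min(100, N)) plus one uniform prior component, all weighted
1/(N+1); categoricals get probabilities ∝ counts + 1 pseudo-count. Proposals
draw 24 candidates from the good density (respecting the conditional tree:
children are sampled and scored only under the activating parent level) and
keep the candidate maximizing l/g, with g floored at 1e-12. Until 5
completed trials exist, proposals are uniform. Integer parameters are
sampled continuously and rounded half-up. The dual-objective mode fills the
good set by successive nondominated fronts (trimming the last front by the
first objective) — a deliberate simplification of exact
expected-hypervolume-improvement splitting; the acquisition stays the l/g
ratio, and the single-objective path is the fidelity-critical one. A fixed
trial budget replaces an open-ended convergence criterion.

## Problem sizes and numerical choices in the shipped experiments

The analysis drivers and the acceptance script run desk-scale analogues of
the full study design: sweeps of ~14 trials × 3 lags × 15–25 bootstraps on
~10⁴-frame double-well data (the accounting ledger is exercised at this
scale and verified against the closed-form product, which at the full design
— 100 × 140 × 10 × 60 — equals 8,400,000); the toy inversion experiment
uses 1000–2500 replicates of 20-step trajectories (the short-data regime
where the inversion lives)
with a 150-replicate 10⁵-step control; lag-selection behaviour is measured
over 30 seeds with 5 × 4000-step Markovian trajectories and 400-step
bootstrap blocks, enough data that gradient noise sits well below the
ε = 0.1 threshold and the selection reflects the criterion rather than
sampling noise; optimizer comparisons use 50 seeds × 60 (quadratic) or 40
(discretization) trials. The replicate count of the toy experiment is a
parameter throughout, since reasonable choices range from 10³ to 10⁴.

## Known limitations

- The reversible estimator returns a point MLE; no Bayesian transition-matrix
  posteriors, Chapman–Kolmogorov tests, PCCA+ coarse-graining, or
  transition-path theory.
- Cross-validated (data-split) score estimators are deliberately absent; the
  bootstrap is used everywhere, and the whitened-score inconsistency would
  only worsen under data splitting.
- The stationary vector of the reversible model is knowingly inconsistent
  with the raw marginals C00/Ctt; no reweighting is applied (that mismatch
  is the phenomenon under study).
- The Parzen densities are one-dimensional per parameter; no correlations
  between hyperparameters are modelled beyond the conditional tree.
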