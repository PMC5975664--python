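# Methods

`branchgp` models, per gene, expression along pseudotime as a mixture of
three latent Gaussian-process functions — a trunk `f` and two branches
`g`, `h` — constrained to intersect at a gene-specific branching time
`t_b`. This note records the model, the inference scheme, the numerical
choices, and what the synthetic benchmark does and does not establish.

## Model

All three latent functions share one squared-exponential kernel
`K(t, t') = sigma_f^2 exp(-(t - t')^2 / (2 lambda^2))` and are conditioned
on `f(t_b) = g(t_b) = h(t_b)`. On the augmented input of
(pseudotime, function-label) pairs the joint covariance has the base kernel
in same-label blocks and `K(T, t_b) K(t_b, T') / K(t_b, t_b)` across
labels; as `t_b` leaves the data the cross blocks vanish and the model
degenerates to an overlapping mixture of independent GPs. Gradients of the
latent functions are not constrained at `t_b`, so branch paths may leave
the trunk with a kink.

Each cell `n` reads one latent function, selected by a one-hot indicator
row with categorical prior `Pi_n`, and is observed with Gaussian noise
`sigma^2`. The prior encodes the upstream global branching structure: cells
before the candidate `t_b` are trunk-only; cells after both the candidate
and the global branching time put probability `c` (the prior confidence)
on their globally assigned branch; cells after the candidate but before
the global branching time are unlabelled and get an even 50/50 split over
the branches. Defaults: `c = 0.99` for real data, `c = 0.8` in the
simulation study, `c = 0.5` is the uninformative mode.

## Inference

A mean-field posterior `q(Z) = prod Phi_nm^{Z_nm}` over assignments is
combined with analytic integration of the latent functions, yielding the
collapsed bound

```
L2 = -N/2 log(2 pi s2) - Y'Y/(2 s2) - 1/2 log|K| - 1/2 log|A/s2 + K^-1|
     + 1/(2 s2^2) (Phi'Y)' (A/s2 + K^-1)^-1 (Phi'Y) - KL[q(Z)||p(Z)]
```

with `A = diag(vec Phi)` on the expanded 3N representation. Numerically
everything is routed through `B = I + (1/s2) A^{1/2} K A^{1/2}`: because
the rows of `Phi` sum to one, the data terms collapse to `-1/2 e'B^{-1}e`
with `e = (1/sigma) A^{1/2} ytil`, which is free of the catastrophic
cancellation the textbook form suffers at small noise variance. No
factorisation of `K` itself is ever needed.

Optimisation alternates two steps, each provably non-decreasing in the
(penalised) objective:

1. **Assignment sweep.** The mean-field optimum
   `log Phi_nm ∝ log Pi_nm - ((y_n - mu_nm)^2 + s_nm)/(2 s2)` given the
   current GP posterior moments. Because the collapsed bound is the
   structured bound maximised over `q(F)`, this coordinate update cannot
   decrease `L2`.
2. **Hyperparameter step.** L-BFGS-B over
   `(log sigma_f^2, log lambda, log s2)` with analytic gradients on the
   full bound (finite differences on the sparse path, where each
   evaluation is O(k^2 N)).

The hyperparameter objective carries a weak log-normal penalty centred on
the initialisation scales (sd 1.5 / 1.0 / 2.5 in log space for signal
variance, lengthscale, noise variance). This is a regularised type-II MAP:
at high noise the unpenalised profile likelihood can drive the signal
variance to zero, which flattens the evidence over candidate branching
times and makes the argmax meaningless; the penalty is orders of magnitude
too weak to move any informative fit. Initialisation:
`lambda = 0.3 x` pseudotime range, `sigma_f^2 = var(y)`,
`s2 = 0.25 var(y)`, `Phi = Pi`; the noise variance is floored at
`1e-6 var(y)`. Convergence is declared at a relative objective change
below 1e-6 or after a fixed number of alternations (default 4); the
result carries a `converged` flag either way.

### Sparse inference

With `k` inducing pseudotimes (quantiles of the data, replicated across
the three function labels, frozen during optimisation), `K` is replaced by
the Nystrom approximation `Q = K_xu K_uu^{-1} K_ux` inside the bound and
the assignment-weighted trace correction `(1/(2 s2)) sum_i w_i (K_ii -
Q_ii)` is subtracted, in the collapsed inducing-point style. The sparse
bound equals the full bound when the inducing set is the data (the
jittered square covariance is reused for both `K_uu` and `K_xu`, making
the identity exact to machine precision) and is never above it for proper
subsets. Default `k = 30`; the full path is used automatically whenever
`k >= N` or `k = 0` is requested.

### Per-gene evidence profile

For each gene, candidate branching times (default: 20 equally spaced
points over the central 90% of the pseudotime range) are scored by the
optimised bound, used as a log marginal likelihood surrogate. A first pass
optimises hyperparameters per candidate with warm starts; a second
"profile" pass freezes the hyperparameters at the best candidate's optimum
and re-evaluates every candidate with assignments re-optimised. The second
pass removes two artefacts of per-candidate fitting: optimiser noise
between candidates, and a systematic bias toward early candidates (which
expose more assignable cells and hence more per-candidate fitting
freedom). The posterior over `t_b` is the softmax of the profile
evidences; the no-branch evidence comes from the same machinery with a
trunk-only prior (a single-GP model); and the log Bayes factor is
`r_g = log[(1/N_b) sum_i p(Y|t_b = i)] - log p(Y|t_b -> inf)`.

Two point summaries are reported: the MAP candidate and the posterior-mean
branching time. The benchmark scores localisation with the posterior mean,
which integrates over the posterior — a diffuse posterior contributes its
centre of mass instead of an arbitrary grid argmax. The credible interval
is the smallest contiguous grid window holding the requested mass (ties
toward earlier times). Pseudotime is min-max rescaled to [0, 1]
internally; expression is mean-centred per gene; all reported times are in
the original units.

## Synthetic benchmark

The generator draws each branching gene jointly from the constrained prior
at its group's branching time (signal variance 2, lengthscale 1.2 on the
unit pseudotime interval), assigns post-branch cells by a fair coin shared
across genes (so a single global structure describes the dataset), adds
iid Gaussian noise, and rejects draws whose branch functions cross again
after the branching point (sign change on the cell grid; detection at
observed resolution only). Non-branching genes are single-GP draws.
The default design is N = 150 sorted-uniform pseudotimes with gene groups
10 x t_b = 0.2, 20 x t_b = 0.8, 10 x non-branching; noise variances
{0.001, 0.01, 0.03, 0.08, 0.1, 0.2}; the derived global assignment uses
the true memberships with the earliest true branching time (an oracle
global; `corrupt_global_labels` emulates imperfect upstream estimation).
Everything is reproducible from a single integer seed via numpy's
Generator (PCG64).

The harness scores detection (AUROC of `r_g` against the branching flags)
and localisation (RMSE of the posterior-mean time over branching genes),
per noise level, prior mode and replicate. Desk-scale runs shrink the gene
counts proportionally (scale 0.3 gives 3/6/3 = 12 genes); cell count, grid
size and inducing count are kept at the full-scale values.

What passing benchmarks show — and don't: the data are generated from the
model itself, with Gaussian noise, a correct global assignment and a
single branching point, so they validate inference, not robustness to
zero inflation, count noise, pseudotime error or multiple branchings.
At the highest noise level (variance 0.2) the within-gene signal is weak
by construction: with this kernel the centred latent variance is of the
same order as the noise variance, and the typical end-state separation of
a late-branching gene's two branches sits below the noise standard
deviation, so a fraction of late-branching genes are genuinely
unresolvable and detection/localisation degrade accordingly.

## Known limitations

- Gaussian likelihood only; log-scale expression is assumed.
- One branching point per gene; recombination and multiple branchings are
  out of scope.
- Pseudotime and the global branching structure are taken as given;
  their uncertainty is not propagated.
- Evidence values are lower bounds used as marginal-likelihood
  surrogates; Bayes factors inherit that approximation.
- Inducing-point locations are frozen at pseudotime quantiles; only their
  count is configurable.
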