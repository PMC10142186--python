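# Methods

## Diversity indices

Both indices operate on compositions renormalized internally to sum to one.
Shannon diversity is `H = −Σ p_i ln p_i` in nats (natural log throughout);
the Simpson variant is the Gini–Simpson index `D = 1 − Σ p_i²`, not the
inverse form `1/Σ p_i²`. Zero components are retained in profiles but
contribute nothing to either index (the `p ln p → 0` limit). Attainable
ranges are `[0, ln R]` and `[0, 1 − 1/R]` for `R` categories; both maxima are
attained exactly at the uniform composition, and merging categories can only
decrease either index.

For an index computed from multinomial counts, `index_sampling_variance`
provides the first-order (delta-method) variance of the plug-in estimator:
`(Σ p (ln p)² − H²)/N` for Shannon, `4(Σ p³ − (Σ p²)²)/N` for Gini–Simpson.
The empirical pipeline treats the pooled diet index as exact (see below), but
the variance is available wherever diet uncertainty should be propagated, and
the synthetic round-trip tests use it.

## Cleaning rules

Venomic records are kept when their published percent total lies in
`[min_total_percent, max_total_percent]`, default 90–110%. The upper cap
reflects the convention that totals slightly above 100% arise from rounding;
the symmetric lower bound is this package's own choice — a profile summing to
60% is as suspect as one summing to 140% — and is configurable, with removals
tagged `total_below_floor` vs `total_above_cap` so the two rules can be
audited separately. Survivors are renormalized to sum to one, which preserves
component ratios exactly. Diet tables are filtered per taxonomic level:
species with fewer than `min_items = 5` prey records are removed at that
level only, so the family-level and order-level datasets can differ in
species content. Both steps are idempotent.

Diet diversity is computed once per species from pooled prey records and
replicated across that species' venomic records; venom diversity is computed
per record, which is what feeds the within-species variance below.

## Phylogeny handling

Input trees are parsed (Newick or Nexus with translate blocks, via dendropy)
as rooted at their outermost node; the package never re-roots, because
rooting changes the covariance matrix. Taxon labels have underscores
converted to spaces and are matched case-sensitively; a user alias map
handles residual taxonomy mismatches. Ultrametricity is checked within a
relative tolerance of 1e−3 and violations warn rather than fail (published
dated trees routinely carry rounding error).

The MCC tree is the tree *in the sample* maximizing the sum over its
non-trivial clades (tip-label bitsets; single tips and the full tip set
excluded) of the log of that clade's sample frequency — equivalent to
maximizing the product of clade credibilities. Branch lengths are those of
the selected tree itself (no averaging across the sample), and ties break
toward the earliest tree in file order. A consequence of summing
log-credibilities is that a partially resolved tree can beat a resolved one
whose extra clade is poorly supported; this matches the cited tool's
behavior on mixed-resolution samples.

The Brownian covariance has `C_ij` = depth of the most recent common
ancestor of tips i and j, computed in one postorder sweep; pruning to a
taxon subset and computing C commute exactly.

## The measurement-error regression

The stacked vector `(x̄, ȳ)` of species-mean diet and venom diversity is
modeled as multivariate normal with mean `(a_x 1, a_y 1)` and covariance

    V = [ σ²_x C + D_x    σ_xy C       ]
        [ σ_xy C          σ²_y C + D_y ]

`D_y` is diagonal with entries `s²_w / m_i`, where `s²_w` is the
within-species variance of per-record venom diversity pooled across species
with ≥ 2 records (per-species variances from 1–4 records are too unstable to
use individually) and `m_i` the record count; species with a single record
receive the pooled value. `D_x = 0` by default: the species diet value comes
from one pooled set of records and is treated as exact, though the field is
configurable (`SpeciesSummary.sampling_var_x`) for propagating finite-record
uncertainty via the delta-method variance above.

Estimation is by maximum likelihood — required for a valid LRT between
models differing in `σ_xy` — over `(a_x, a_y, log σ²_x, log σ²_y,
atanh ρ)` with `σ_xy = ρ √(σ²_x σ²_y)`, which keeps the rate matrix PSD by
construction. Numerical details:

- Likelihood evaluation uses a Cholesky factorization of V; a non-PD V
  returns `−inf` rather than raising, so multi-start exploration continues.
  Log-rates are clipped at ±700 before exponentiation to avoid overflow on
  exploratory steps.
- Each restart starts from the empirical GLS means ± 1 trait SD, the log of
  the empirical GLS rates ± 1, and `atanh ρ ~ U(−1, 1)`; optimization is
  L-BFGS-B with finite-difference gradients (`ftol` 1e−10).
- The unconstrained fit adds one deterministic start taken from an internal
  `ρ = 0` pre-fit, because the full model nests the slope-free model and its
  reported optimum must not fall below the constrained one; the best point
  is then polished with a derivative-free Nelder–Mead pass. Without these
  two safeguards roughly 1 in 200 simulated null datasets produced a small
  nesting violation.

The slope is `b1 = σ_xy / σ²_x` (exactly 0 in the constrained fit) and the
intercept `b0 = a_y − b1 a_x`.

## Inference protocol

Each (index, diet level) analysis runs the full/null model pair `n_runs`
times (default 100) from independently seeded starts. Parameter estimates
are reported as means across converged runs; the log-likelihoods entering
the LRT are the per-model maxima across runs — the best optimum found —
since averaging log-likelihoods over restarts would mix converged and
near-converged values into the test statistic (a mean-log-likelihood variant
is available behind `use_mean_loglik` for sensitivity analysis). `LR =
2 Δ lnL` is compared to χ² with 1 df; LR values negative within 1e−6 are
clamped to zero with a warning, larger violations raise. No multiplicity
correction is applied across the four analyses. Seeds spawn deterministic
child streams (numpy `SeedSequence`), so any subset of runs reproduces
exactly.

The proteome-vs-transcriptome check is a plain two-sided Welch test with
Satterthwaite df on per-record venom diversity values, run per index.

## Synthetic worlds

Scenario defaults mirror the shape of the empirical dataset: 66 species
(1–4 venomic records each, matching a ~3 records/species maximum typical of
venomics collations), toxin panels of 15 families, 15 prey categories nested
two families per order, 20–100 prey records per species, a Yule tree with
unit birth rate, traits on the Gini–Simpson scale around mid-range
(`x_root = 0.55`, `b0 = 0.4`) with a true slope of 0.15 — the magnitude of
the empirical coefficients — and Brownian rates (`σ²_x = 0.005`,
`σ²_y,resid = 0.002`) chosen so cross-species trait SDs land near 0.1–0.15,
keeping simulated indices well inside their attainable ranges.

Traits are simulated exactly (Gaussian increments per branch, root-to-tip),
directly on the index scale, since the regression is run on indices. Venom
records are Dirichlet draws whose symmetric concentration is solved so the
*expected* index equals `y_true` plus `N(0, within_sd_y)` noise, using the
closed forms `E[D] = (1 − 1/K)·Kα/(Kα+1)` and `E[H] = ψ(Kα+1) − ψ(α+1)`;
within-species variance is therefore genuine compositional sampling rather
than additive noise on the index scale. Diet counts are one multinomial draw
over a geometric probability family `p_i ∝ r^i` with `r` solved so the index
equals `x_true`. Targets outside the attainable range are clipped and
counted.

What a green end-to-end test does **not** establish: the generator does not
mimic real toxin-family identities or their empirical abundance
distributions, correlations between proteome and transcriptome methods,
non-Brownian trait evolution, or taxonomic structure in diet sampling
effort. The plug-in diet index from finite prey records carries sampling
noise that the default pipeline (with `D_x = 0`) does not model; in
slope-recovery simulations this attenuates estimates by roughly 20% unless
the delta-method variance is propagated, which is why the round-trip tests
propagate it and why the option exists.

## Limitations

- The within-species variance treatment (pooled, plugged in, scaled by
  `1/m_i`) is one defensible reading of measurement-error pGLS; estimating
  within-species variances jointly with the evolutionary rates is a known
  alternative and may differ near variance boundaries.
- No Ornstein–Uhlenbeck or λ-transformed covariance alternatives; the
  Brownian model is assumed, not tested.
- Isoform-level diversity within toxin families is invisible at the
  toxin-family resolution this pipeline operates on.
- The LRT relies on the χ²₁ asymptotics; with few species (< ~20) a
  parametric bootstrap would be preferable and is not implemented.
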