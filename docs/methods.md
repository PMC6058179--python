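# Methods

This note documents the statistical models, numerical choices, and the
synthetic-data design behind `depcat`, and states what the shipped tests
do and do not establish.

## Response models

Five polytomous IRT models share one interface (`category_probs`,
`item_information`, `response_loglikelihood`).  All are on the pure
logistic metric — no 1.7 scaling constant.  The packaged bank's
parameters are consistent with that convention, and every internal
computation (scoring, information, simulation) applies it uniformly, so
no result in the package depends on the constant.

- **GRM** — cumulative two-parameter logistic curves
  `P*_k(θ) = logistic(a(θ − b_k))`, category probabilities by adjacent
  differences.  Invariants: `a > 0`, strictly increasing thresholds.
- **GPCM / PCM / RSM** — divide-by-total (adjacent-category) family,
  `P_k ∝ exp(Σ_{v≤k} a(θ − d_v))`.  PCM shares one estimated slope
  across items; RSM further decomposes `d_v = location + τ_v` with the
  category offsets τ shared across items (first offset held fixed for
  identification, absorbed by the item locations).
- **NRM** — multinomial logit `P_k ∝ exp(a_k θ + c_k)` with
  `a_1 = c_1 = 0` for identification.

Fisher information uses analytic derivatives in every model
(`dP*/dθ = a P*(1−P*)` for GRM; `P'_k = a P_k (k − E[k])` for the
divide-by-total family; `P'_k = P_k (a_k − ā)` for NRM).  A floor of
1e−10 protects the `P'²/P` ratio and all logs against vanishing
category probabilities in deep tails; the floor is far below every
quantity the package reports.

## Quadrature and scoring

The latent prior is standard normal, represented by 61 equally spaced
nodes on [−4.5, 4.5] with weights proportional to the normal density and
renormalized to sum to one.  At 61 nodes the EAP error against a
2001-node grid is below 1e−3 (tested), which is far below the 2-decimal
reporting precision of any downstream summary.  EAP accumulates
log-likelihoods and normalizes via log-sum-exp, so extreme response
patterns cannot underflow.  An all-missing pattern returns the prior
mean by construction.

## Calibration (Bock–Aitkin EM)

The E-step computes each respondent's posterior over the grid and
accumulates expected category counts per item and node.  The M-step
maximizes each item's expected complete-data log-likelihood by L-BFGS on
an unconstrained reparameterization (`log a`; first threshold plus log
gaps for the GRM, which enforces ordering by construction).  Models with
cross-item parameters use block-coordinate M-steps (per-item block, then
the shared slope/offsets), so every step increases the EM objective and
the marginal likelihood is monotone — asserted in the tests to a 1e−8
relative tolerance.  Convergence is declared when the largest absolute
parameter change drops below 1e−4 (default), with a 500-iteration cap;
non-convergence flags the result instead of raising.  Starting values
come from probit transforms of the marginal category proportions.

Free-parameter counts per J-item, K-category test: `J·K` (GRM, GPCM),
`J(K−1)+1` (PCM), `J+(K−1)` (RSM), `2J(K−1)` (NRM).  AIC and BIC follow
directly (`−2LL + 2p`, `−2LL + p ln N`), and model comparison ranks by
AIC with BIC as tiebreak.

Parameter recovery at J=20 items, N=1,000 respondents (20 seeded
replicates) gives median RMSE ≈ 0.12 for discriminations and ≈ 0.08 for
thresholds, comfortably inside the design bounds (0.2 / 0.25) asserted
by the tests.

## Item screening

The cascade applies, in order and iterated to a fixed point:
unidimensionality, local independence (Q3), item fit (S-χ²), a
discrimination floor, and DIF.  Thresholds (YAML-configurable):

| screen | statistic | default rule |
|---|---|---|
| unidimensionality | one-factor minres loading on polychorics | drop λ ≤ 0.3 or not significant at 5% |
| local independence | Yen's Q3 residual correlation | drop one of each pair with Q3 > 0.36 |
| item fit | S-χ² (Orlando–Thissen) | drop p < 0.01 |
| discrimination | GRM slope | drop a ≤ 0.8 |
| DIF | ordinal logistic ΔR² (McFadden) | drop ΔR² ≥ 0.02 |

Notes on each:

- **Unidimensionality** is a deliberately lightweight proxy for a full
  categorical-data confirmatory factor analysis: polychoric correlations
  by two-stage maximum likelihood (thresholds from marginal proportions,
  then a bounded 1-D likelihood search per pair, with eigenvalue-clipping
  repair if the assembled matrix is not positive definite), followed by
  one-factor minimum-residual loadings.  Loading significance uses a
  normal approximation on the Fisher-z scale and is documented as
  approximate; it exists to catch near-zero loadings, not to provide
  exact coverage.  The proxy does not produce CFI/TLI/RMSEA-style global
  fit indices.
- **S-χ²** conditions observed and model-expected category frequencies
  on rest-score groups, with the rest-score distribution from the
  Lord–Wingersky recursion evaluated on the quadrature grid.  Adjacent
  rest scores are grouped until a group holds at least K·(minimum
  expected) respondents, then adjacent category cells are merged until
  every expected count is at least 1 (default).  Degrees of freedom are
  the collapsed cell count minus one per group minus the number of item
  parameters — the convention for parameters estimated from the same
  data.  The type-I-error test therefore runs the matched parametric
  bootstrap (simulate from a fitted bank, refit, test): the observed
  rejection rate at α = 0.01 sits inside the binomial 95% band.  Using
  generating parameters without refitting inflates the rate (≈ 0.02)
  precisely because the df correction then over-corrects.
- **Q3** correlates residuals `x − E[x|θ̂]` with θ̂ from EAP.  Under
  local independence its off-diagonal mean is ≈ −1/(J−1) (tested).  When
  a pair is flagged, the member with the lower discrimination is dropped
  — a deterministic, order-invariant rule.
- **DIF** fits proportional-odds models `item ~ θ` and
  `item ~ θ + group + θ×group` (statsmodels `OrderedModel`) and flags
  items by the change in McFadden pseudo-R².  The matching variable is
  the EAP θ̂ from the current fit, in a single pass without iterative
  purification.  The default flagging threshold is ΔR² ≥ 0.02: injecting
  a uniform one-logit threshold shift produces ΔR² ≈ 0.03 at N=1,000,
  while coin-flip groups stay below 0.02 in ≥95% of replicates, so 0.02
  separates real from null effects at this sample size.  Thresholds of
  0.2 on this scale would be insensitive to shifts of practical size.

## CAT engine

Design choices, each configurable where noted:

- **SE definition**: the stopping SE is the information-based
  `1/√(Σ I_j(θ̂))` over administered items, not the EAP posterior SD
  (the two differ; posterior-SD stopping is available via
  `use_posterior_sd`, off by default).
- θ̂ is re-estimated after **every** administered item, and stopping is
  evaluated immediately after each update; there is no minimum test
  length beyond the first item.
- The final θ̂ is computed by re-summing log-likelihood contributions in
  canonical bank order, so a run with no stopping rule reproduces the
  one-shot full-bank EAP *exactly* (bit-for-bit), making the r = 1
  reference row a structural identity rather than an approximation.
- MFI ties break toward the lower bank index (deterministic).
- Missing responses in post-hoc mode make the item ineligible: the
  engine selects the next-best item and flags the trace.
- Reproducibility: each respondent's RNG stream is derived from the
  master seed plus a CRC of the respondent id, so batches equal looped
  single sessions and are invariant to row order.

## Synthetic data

The generator's defaults define the simulated study conditions:

- **Population**: a single standard normal θ component — the scale on
  which the reliability formula `1 − 1/I` is defined.  A "study-like"
  preset mixes 81% healthy and 19% patient components (patient mean 2 SD
  above healthy, then re-standardized to overall mean 0, SD 1) for
  experiments that need a diagnosable subgroup; the true component
  separation in any real clinical sample is unknown, so this preset is a
  structural stand-in, not an estimate.
- **Responses** are drawn item-by-item from the bank's own category
  probabilities — local independence holds exactly, there are no
  response styles, careless responding, or missingness mechanisms.
- **Criterion scores** are built as `ρ·z(θ) + √(1−ρ²)·noise`, mapped to
  an integer 0–60 scale (a conventional questionnaire range; the range
  is cosmetic).  Diagnosis labels come either from the mixture component
  or from thresholding the noisy latent.

Consequently, simulation-based results (e.g. ≈27.9 items and marginal
reliability ≈0.958 under SE ≤ 0.2 at N=1,000; ≈11.8 items and ≈0.915
under SE ≤ 0.3) demonstrate that the *machinery* reproduces the
quantities that the stopping rules force by construction — a CAT that
stops at SE ≤ s yields reliability just above 1 − s² for every
respondent it stops, shaded down by the low-severity tail where the bank
runs out of information.  They do not certify the behaviour of any real
clinical population, whose θ distribution, local dependence, and
response quirks the generator deliberately omits.

## The packaged bank

`cat_depression_68.csv` carries the published calibration of the
68-item bank.  One caveat: the source table for item 43 was not
recoverable in our extraction of it.  Its discrimination (a = 2.29) is
reconstructed exactly from the bank's published mean discrimination
(1.784 over 68 items) and the 67 printed values; its thresholds are the
midpoint of the neighbouring rows (−0.27, 1.26, 2.29) and its
symptom domain (cognition) follows the development ledger's ordering.
The row is marked `(reconstructed)` in its content field.  Every
bank-level quantity asserted in the tests (n, min/mean/max
discrimination, domain counts) is insensitive to the threshold choice;
simulation summaries shift by well under their reporting precision.

Item 17's third threshold is printed as "3" in the source and stored as
3.00.

## Known limitations

- The unidimensionality screen is a proxy, not a CFA; it has no global
  fit indices and approximate significance.
- S-χ² p-values rely on the χ² approximation after cell collapsing;
  with very sparse extreme rest-score groups the approximation is rough
  (mitigated by the grouping rule, quantified by the bootstrap test).
- DIF uses observed-score-free matching on θ̂ but no purification loop;
  with heavy DIF contamination the matching variable itself is biased.
- The CAT engine implements MFI selection only — no exposure control or
  content balancing.
- RSM/PCM fits report the conventional free-parameter counts; the RSM
  identification redundancy (one location/offset trade-off) means its
  effective dimension is one lower than the conventional count, which is
  immaterial for the AIC comparisons made here (likelihood differences
  dominate).
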