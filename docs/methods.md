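# Methods

## Model

`preresist` treats pre-treatment tumor growth as a supercritical
birth–death branching process with neutral mutation. Cells divide at rate
*l* and die at rate *d*; stem-like cells divide symmetrically
self-renewing, symmetrically differentiating (probability *a*) or
asymmetrically (probability *b*). Each division produces, with probability
*u*, one daughter carrying a resistance-conferring point mutation.
Resistant cells are assumed neutral before therapy (same *l*, *d*), there
is no back-mutation, and at most one daughter mutates per division.

The probability that a tumor whose self-renewing compartment has reached
size *M* already contains at least one resistant cell is

    P_R = 1 − exp(−u · M · F),

with the effective division factor

    F = (1 − a/2 − b)/(1 − a − b)
        · l(1 − a − b)/(d + l·b)
        · ln[ l(1 − a − b) / (l(1 − a − 2b) − d) ].

F counts the expected number of divisions per final cell: death and
asymmetric division force extra divisions to reach the same size, so F ≥ 1
(F = 2·ln 2 at d/l = 1/2; F → (1 − a/2 − b)/(1 − a − b) as d + l·b → 0, and
F = 1 when a = b = d = 0). The model requires supercriticality,
l(1 − a − 2b) > d, for the tumor to grow and the logarithm to be defined.
Results depend on rates only through their ratios, so the time unit of *l*
is arbitrary.

## Parameters and their provenance

| parameter | default | units | rationale |
|---|---|---|---|
| u | 1e-8 | per division | per-base somatic mutation rate 1e-9 (conservative end of 1e-9..1e-8) × 10 known imatinib-resistance positions (a lower bound); both factors configurable |
| cell density | 1e9 | cells/cm³ | literature estimate for solid tumoral mass |
| tumor purity | 0.5 | — | halves the cell count to discount stromal and other non-tumor cells (conservative) |
| stem fraction | 6.2e-3 | — | frequency of interstitial-cells-of-Cajal progenitors, the candidate self-renewing compartment in GIST |
| l, d, a, b | 1, 0, 0, 0 | rates/probabilities | "all other parameters zero": the most conservative (smallest-F) choice; d enters via its analytic limit |

A tumor of diameter D cm is a sphere: total cells = (π/6)·D³·density·purity;
the self-renewing count is that times the stem fraction. Multi-lesion
patients are scored per lesion and combined as 1 − Π(1 − Pᵢ), assuming
independent lesions.

With these defaults: P_R(2 cm) = 0.122 (prints 0.12), P_R(6 cm) = 0.970
(prints 0.97).

### The expected resistant fraction

The reported resistant-cell fraction is u·F (1 per 10⁸ cells at the
defaults). This is an interpretive construction: λ = u·M·F resistant
lineages are expected among M stem cells, and each resistant stem lineage is
credited its proportional share of non-stem progeny, so the stem-fraction
factors cancel. It is a per-lineage accounting, not the mean *cell* fraction
of the branching process — under pure birth the latter is the classical
fluctuation-analysis mean u·(H_M − 1) ≈ u·ln M, dominated by rare early
"jackpot" mutants (see the simulator tests, which check both quantities
against their own oracles). The u·F fraction is the right scale for asking
whether a sequencing assay could detect resistance at diagnosis.

### Double resistance (combination therapy)

For two drugs with mutation probabilities u and u₂, the probability that a
doubly resistant cell pre-exists is approximated to first order in the
sequential-mutation picture as 1 − exp(−u·u₂·F²·M): second-site mutations
arise within the expected divisions of first-site-resistant lineages. It is
bounded by the single-drug probability at min(u, u₂) and is ~1e-5 even for a
40 cm tumor at the defaults — the quantitative case for TKI combinations
(cross-resistance is out of scope).

## Stochastic oracle

The simulator is an exact event-driven realization of the embedded jump
chain: each event is a birth (probability l/(l+d)) or death of a uniformly
chosen cell; sensitive births mutate one daughter with probability u,
resistant births with probability u₂. Only the jump chain matters for
questions indexed by population size, so no event clock is simulated. Runs
start from one sensitive cell and stop at `target_size`; extinct lineages
are restarted and counted, i.e. estimates are conditioned on non-extinction
(the observed tumor did reach detection size). The core loop is
numba-compiled; each replicate gets an independent sub-stream seed spawned
from the root seed via `numpy.random.SeedSequence`, so results are
reproducible and independent of replicate order.

Monte-Carlo probabilities carry 95% Wilson score intervals
(statsmodels). Two oracle regimes are tested:

- **Pure birth (exact):** with d = 0, growth 1 → M takes exactly M − 1
  divisions and no mutant lineage dies, so P = 1 − (1 − u)^(M−1) exactly;
  the simulator agrees within 3 standard errors at 20 000 replicates.
- **With death (approximate):** the closed form idealizes mutant-lineage
  survival, so at d/l = 0.5 agreement is checked within a deliberately loose
  [0.8, 1.25]× band (measured ratio ≈ 0.98 at u = 1e-4, M = 1000).

Problem sizes (target 1000 cells, 20 000 replicates) were chosen so the
Monte-Carlo standard error (~0.003) resolves the [0.8, 1.25] band and the
pure-birth comparison decisively while a full validation run completes in
seconds.

## Synthetic cohorts

`generate_cohort` draws lesion diameters from a log-normal truncated to
[1, 40] cm with log-mean 2.351 and log-sd 0.6, placing ≈75% of tumors above
7 cm — emulating the size distribution reported for advanced-GIST trial
populations (tumors between 1 and >40 cm, 75% larger than 7 cm). The log-sd
is a shape default (the single published constraint fixes only one
quantile); both parameters are exposed. The generator emulates *sizes only*:
real cohorts correlate size with mitotic rate, site, and multifocality, and
real purity/stem-fraction vary per patient — passing cohort tests therefore
validates the scoring pipeline, not those clinical covariates. The cohort
summary reports the model-predicted fraction of patients free of
pre-existing resistance alongside (never fitted to) observed
progression-free fractions.

## Numerical choices

- P and λ* are computed with `expm1`/`log1p` to keep precision at small
  probabilities.
- F switches to its analytic limit when d + l·b < 1e-12·l (configurable):
  far below any biologically meaningful rate, avoiding 0/0 cancellation.
- The diameter-for-probability inverse solves by Brent bracketing (bracket
  from the closed-form inverse, relative tolerance 1e-9); the closed form
  D = [6λ*/(π·density·purity·f_s·u·F)]^(1/3), λ* = −ln(1 − p), is exposed as
  `method="closed_form"` and agrees to solver tolerance.
- Saturation: P = 1 − exp(−λ) rounds to exactly 1.0 in double precision for
  λ ≳ 36 (≈13 cm at the defaults). Probability-space round trips and strict
  monotonicity on P are therefore only float-decidable below ≈11 cm; tests
  assert strictness on λ (exact at every scale) beyond that. Users needing
  tail resolution should work with λ, not P.
- Probabilities in reproduction reports are rounded to two decimals and the
  resistant fraction to its order of magnitude, matching how the anchor
  values are conventionally quoted; full precision is kept everywhere else.
- Config files are strict: unknown keys are an error, because a silently
  ignored parameter is the worst failure mode of a one-formula model.

## Limitations

- The general (a, b, d)-dependent factor F is validated against limits and
  simulation, not against an external derivation; the a = b = d = 0 regime
  used for all headline numbers is exact against the pure-birth oracle.
- No spatial structure, no fitness differences among subclones, no
  cross-resistance, no therapy-phase dynamics: the question addressed is
  strictly pre-treatment.
- Clinical outcome quantities (progression-free fractions, resistance
  timing) are reported for qualitative comparison only; the package neither
  fits nor predicts them.
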