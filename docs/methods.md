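# Methods

## Model

`duplipath` implements a static input–output map from two environmental
factors to the probability `P` that a developmental or physiological outcome
occurs. The pathway has two tiers (an upstream and a downstream gene), each
carrying one or more copies.

For a copy with per-factor responses `f(e) = exp(−r (e − opt)²)` the
environmental weight is `w(e1, e2) = f₁(e1) f₂(e2)`. The chain is

    U_i = w_i(e1, e2)                      (upstream copies)
    x_j = Σ_{i ∈ wiring(j)} U_i            (downstream inputs)
    D_j = σ_δ(x_j) · w_j(e1, e2)           (downstream copies)
    P   = σ_γ(Σ_j D_j)                     (outcome)

with logistic links `σ(x) = 1 / (1 + exp(p₀ − p₁ x))`. All quantities are
probabilities in [0, 1] except the downstream inputs, which can exceed 1 when
several upstream copies are pooled.

Assumptions: activity is a deterministic function of the momentary
environment (no stochastic gene expression, no kinetics or time courses, no
feedback); exactly two environmental factors; the only inter-tier couplings
are the single δ and γ links. "Probability" refers to whether the outcome
occurs under given conditions, not to a rate per unit time.

### Functional-form choices

The response curve and link parameterizations were genuinely open design
points; the package fixes them as follows.

- **Response curve**: a Gaussian in the squared distance from the optimum,
  with independent decay rates below and above it. This gives activity 1 at
  the optimum, a smooth decline to zero on both sides, a monotone
  (photoperiod-style) response when one rate is zero, and a constant
  insensitive gene when both are. At the default rate 0.01 on the 1–20
  scale, activity falls to `e⁻¹ ≈ 0.37` ten units from the optimum, which
  produces surface breadths commensurate with the grid. The boundary cell
  `e == opt` uses `rate_above` (irrelevant for symmetric curves).
- **Link parameterization**: `σ(x) = expit(slope·x − intercept)`, i.e. the
  second printed parameter of a pair such as (1, 2) or (5, 7) is the gain
  and the first the offset, with inflection at `intercept/slope`. This is
  the only reading under which the printed pairs place the inflection inside
  the attainable input range (0.5 and ≈0.71 for inputs bounded by ~2) and
  under which (5, 7) is steeper than (1, 2) where they cross, as the panel
  contrasts require.
- **Floor**: `σ_γ(0) > 0`, so `P` never reaches 0. All breadth metrics
  subtract this structural baseline: the half-max level is
  `floor + (max − floor)/2`.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| `optimum` | environmental value of peak activity | env units (1–20) | — |
| `rate_below`, `rate_above` | response decay | per squared env unit | 0.01 when sensitive, 0 when flat |
| `intercept`, `slope` (δ link) | upstream→downstream logistic | dimensionless | (1, 2); steep variant (5, 7) |
| `intercept`, `slope` (γ link) | downstream→outcome logistic | dimensionless | (1, 2) |
| `wiring` | pooled / independent / explicit map | — | pooled |
| grid | integer lattice per factor | env units | 1..20, step 1 |
| `min_prominence` | required height above floor for a peak | probability | 0.05 |

The peak prominence default suppresses floor-level ripple while leaving
every secondary peak of the registered panels (all ≥ 0.39 above floor)
intact. Peaks are 8-connected local maxima; connected equal-value plateaus
merge into one peak reported at the lexicographically smallest cell, and
peak lists are sorted by descending height with lexicographic tie-breaks —
deterministic rules that match visual peak counting on a coarse grid.

## The figure registry

The sixteen registered panels reproduce the published figure architectures:
upstream-only vs downstream-only sensitivity (2A/2B), sensitivity split
across factors (2C) with a steeper upstream link (2E), identical sensitivity
in both tiers (2D), compensatory displacement of optima (3A–3C), copy
divergence in one or both tiers (4A–4D), and pooled vs independent
regulation with matched or mismatched copy pairings (5A–5D). Two registry
choices were open and are the package's own:

- **Copy count in the undiverged panels (2A–3C)**: duplicate copies that
  have not diverged are collapsed into a single effective copy per tier.
  With two identical copies pooled, the δ link is driven far above its
  inflection across the whole grid and the breadth contrasts between panels
  wash out; the single-copy rendering preserves them. Multi-copy identical
  tiers remain fully supported through the library.
- **Wiring of the divergence panels (4A–4D)**: independent. Under pooled
  wiring every downstream copy shares the summed upstream activity, whose
  maximum always sits at the centroid of the upstream optima, so upstream
  divergence can never split the outcome peak; only independent wiring
  produces the published bimodality of 4B/4D. A `--wiring` override (CLI)
  or argument (library) renders any panel under either mode.

Each panel also carries its published qualitative expectations (peak count,
argmax location) as machine checks; `run_figure` and the `figure` CLI
command evaluate them and report pass/fail (exit code 3 on failure).

## What the model does and does not emulate

All inputs are parameterized curves; no biological data are consumed. The
model emulates the *shape* of environmentally gated developmental switches —
unimodal sensor activity, saturating regulatory transfer, multiplicative
dependence on two factors — but not gene-expression noise, dynamics,
dosage effects, or selection. Passing tests therefore demonstrate internal
mathematical consistency and faithful reconstruction of the published
architecture contrasts, not fit to any organism's data.

## Numerical choices

- Evaluation is vectorized over the grid; a pointwise scalar chain is kept
  and tested bit-equal to the vectorized path at every cell.
- Peak detection uses a 3×3 maximum filter plus connected-component
  labelling; the test suite checks it against an exhaustive nested-loop
  definition on all sixteen panels.
- A numerically flat surface (max − min < 1e−12) has no meaningful half-max
  footprint; it is flagged and assigned the full grid.
- Logistic evaluation uses `expit`, safe for arbitrarily large arguments.
- Surface CSVs store full-precision floats and are parsed back with
  round-trip float conversion, so write→read reproduces `P`, `U`, `D`
  bit-identically. File writes are atomic (temp file, then rename).

## Known limitations

Four published ordinal claims do not hold under the canonical functional
forms chosen here, and the corresponding acceptance cases fail by design
rather than being silently adjusted:

1. **Exact compensation (3C)**: displacing the two tiers' optima
   symmetrically about a target cell does not return the surface peak
   exactly to that cell (observed argmax (8, 11) vs target (10, 12)).
   Because the downstream weight multiplies the *output* of the saturating
   δ link, upstream and downstream displacements are not interchangeable;
   the peak settles nearer the downstream optimum. Applying the δ link to
   the product `x · w_down` instead would make compensation exact but
   eliminates the bimodality of panel 4B and contradicts the zero-weight
   limit `D → 0`.
2. **Peaks nearer upstream optima (4B)**: with undiverged downstream copies
   the two peaks sit at (9, 11)/(11, 13) — nearer the downstream optimum
   pair than the upstream ones. The claim holds for 4A and 4C.
3. **Pooled regulation lowering total mass (5A vs 5B)**: summed pooling
   gives every downstream copy more input than its own partner would, so
   the pooled surface dominates pointwise (mass 235.9 vs 180.6). A
   mean-normalized pooling would reverse the ordering but conflicts with
   the summed-input definition of pooling used throughout.
4. **Slope-only sweeps**: raising a link's slope with its intercept fixed
   *lowers* the inflection point and broadens the half-max footprint
   (areas 270 → 313 → 373 for γ-slope 2 → 4 → 7 on panel 2C). Steepness
   comparisons that co-vary both parameters, as the panel pairs (1, 2) vs
   (5, 7) do, restrict the footprint as expected (2E area 169 < 2C 270).

Further limitations: no continuous (sub-grid) peak localization; total mass
is a plain cell sum on the evaluation grid, not an integral; fitness,
selection and evolutionary dynamics are out of scope.
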