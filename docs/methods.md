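# Methods

This note documents the modelling choices in `pncell`: the assumptions of
each component, the parameters that matter, what the shipped defaults
emulate, and the numerical decisions a user should know before trusting or
overriding them.

## Scope and assumptions

The model treats the NP cell as a black box: environmental stimuli
(glucose, pH, IL1β, TNF-α) map directly onto normalized mRNA expressions,
with no intracellular pathway representation.  Stimulus effects are
integrated multiplicatively through a normalized activation/inhibition
equation (below); there are no stimulus×stimulus interaction terms — each
edge acts independently and cross-effects are out of scope.  All outputs
are normalized, dimensionless activation levels, not transcript counts.

## Weighting-factor calibration (`sca_model`)

* **Input**: per-edge maximal x-fold change ε over the physiological
  stimulus range, a sign (activating/inhibiting) and a significance flag.
  These are shipped as CSV tables and can be replaced wholesale; every
  downstream number is parameter-table-driven.
* **Cellular effort** f(ε) = max(ε, 1/ε) places n-fold induction and
  n-fold suppression on the same semi-unbounded scale (f ≥ 1, f → ∞ in
  both directions).  The name is conventional and carries no mechanistic
  claim.
* **Scaling**: θ = f(ε)/ϑ with ϑ the *maximum* effort among significant
  PN-system edges, so exactly one PN edge reaches θ = 1 (pH→MMP3, ϑ =
  28.7 under the defaults).  Inflammation-submodel edges reuse the same ϑ
  and may exceed 1 (pH→IL1β: 81/28.7 = 2.8223).
* **Non-significant edges** keep their sign but are pinned at θ = 0.01
  regardless of any ε in the table; 0.01 approximates a linear coupling
  between x and ω.  Significance is an input, never recomputed.
* **Rounding**: θ is derived in full precision and rounded half-to-even at
  4 decimals on derivation and export, the resolution at which the tables
  are stated and consumed.  All shipped θ values reproduce under this
  rule.

## Dose–response curves (`dose_response`)

Curves are phenomenological normalizations, not kinetics.  Each edge's
x_S^CA is a 4-parameter logistic fitted to anchor points by deterministic
least squares (initial guess read off the anchor endpoints; no random
restarts), then rescaled so its infimum/supremum over the physiological
range are exactly 0 and 1.  Because of that mandated rescaling the floor
and ceiling parameters are absorbed; the effective shape freedom is the
midpoint and steepness.  Anchor sequences must be monotone after averaging
replicate concentrations, otherwise calibration fails loudly.  Evaluation
clamps out-of-range concentrations to the range endpoints (the network
equation requires x ∈ [0, 1]) and warns.

**Direction convention.**  x encodes the *strength of the edge's effect*:
glucose curves rise with glucose availability, pH curves rise with acidity
(the stressor).  Whether the effect helps or hurts the activity is carried
by the edge sign inside the network equation, never by the curve.

**Shipped defaults.**  The exact continuous sensitivity functions used by
the original study are not published in a recoverable form, so the package
ships its own anchor tables, generated from normalized logistic shapes
chosen per edge to embody the qualitative experimental record:

| edge (pH) | midpoint | steepness | rationale |
|---|---|---|---|
| pH→Agg, pH→IL1β-mRNA | 6.62 / 6.70 | 0.05 / 0.08 | respond mainly below pH ≈ 6.9 (acid stress on anabolism and cytokine induction is a late effect) |
| pH→Col-II | 7.15 | 0.10 | strong sensitivity already near physiological pH (bovine data show Col-II as the most acid-sensitive matrix gene) |
| pH→MMP3, pH→ADAMTS4 | 6.85 | 0.10 | protease induction grows steadily with acidification |
| pH→Col-I, pH→TNF-α-mRNA | 6.90 | 0.12 | mild, mid-range response (non-significant edges) |
| glucose (all) | 0.5 mM | 0.35 mM | glycolytic NP cells half-saturate below 1 mM; 5 mM is the well-fed control |

These choices were fixed once, before any downstream evaluation, and all
qualitative model behaviour documented below follows from them; users with
better experimental anchors should override them via
`RunConfig.anchor_table` and re-examine the orderings.

## The network equation (`pn_core`)

ω_CA,CS = A·(1−B) with

* A = ((1+Σθ_α)/Σθ_α) · (S_α/(1+S_α)), where S_α sums θ·x over the
  network's activating edges and Σθ_α sums the activating θ of the *whole*
  PN-system.  This global normalization is what makes activities
  comparable across the parallel networks: a weakly-activated gene keeps a
  small ω even at saturation.
* B = (Σθ_S,β/(Σθ_S,α+Σθ_S,β)) · ((1+Σθ_β^CA)/Σθ_β^CA) · (S_β/(1+S_β)),
  where Σθ_β^CA collects every inhibiting weight converging on the
  activity regardless of cell state.

**Σθ_α scope.**  The system sum counts each unique stimulus→activity edge
once (`global_sum_mode: unique_edges`, the default).  Repetition of the
same edge across cell-state levels is presentation, not extra weight; a
`per_state_repeats` switch exists for sensitivity analysis because the
alternative reading is defensible.

**Totality guards.**  A network with no activating edges returns ω = 0
with a warning; an activity with no inhibiting weight anywhere has B = 0.
Neither case arises with the shipped tables.

**Bounds and rounding.**  The product is clamped to [0, 1] (the form can
only marginally exceed bounds through the clamp-free inflammation variant)
and rounded to 4 decimals once, at profile emission.  Internally all sums
are full precision; the implementation agrees with an independent
transcription of the equation to 1e-12 on randomized networks.

Published point values for specific profiles depend on the original
study's unpublished sensitivity functions and are therefore treated as
qualitative anchors only.  The orderings that the package does commit to —
and tests — are: ADAMTS4 activation higher in TNF-α⁺ than non-inflamed
cells in every preset environment; Col-II ≤ Agg within every profile; and
across-state profile dispersion (max over activities of the max−min of ω
across the four states) larger with calibrated θ than with invariant
θ = 0.01 under optimal conditions.

## Inflammation submodel (`inflammation`)

* ω_IL1β and ω_TNF-α are global (not per-cell) activities computed with
  the submodel's own weight sums and clamped to [0, 1].
* Protein update per 1-h step: p ← p·2^(−dt/t½) + k_syn·ω, with t½ = 2 h
  (IL1β) and 1 h (TNF-α).  k_syn is not constrained by data; the default 1
  (normalized units) only sets the protein scale and cancels out of the
  normalized carrier below.  Steady state: k_syn·ω/(1−2^(−dt/t½)).
* **Cytokine carrier.**  The PN-system's cytokine edges consume the
  protein level normalized by its ω = 1 steady state (default 24 steps of
  burn-in, by which the carrier equals ω to <2·10⁻⁴ for IL1β).  A config
  switch (`cytokine_x_carrier: mRNA`) passes ω directly; the two coincide
  at steady state, so the choice matters only for transient scenarios.
* **Immunopositivity** is an affine map of ω onto the tissue-derived
  ranges 10–59 % (IL1β) and 9–36 % (TNF-α): ω = 0 hits the floor observed
  in non-degenerated tissue, ω = 1 the degenerated ceiling.  A
  proportional map through zero would allow 0 % immunopositivity, which
  the tissue data exclude.  The overall published range is used rather
  than per-degeneration-grade sub-ranges; a grade-conditional map would
  need assumptions the data do not pin down.
* The two cytokine submodels are independent (no mutual induction), a
  simplification that likely understates double-positive counts.

With the shipped tables both TNF-α edges are non-significant (θ = 0.01),
so ω_TNF-α barely responds to nutrients — the model's way of saying that
nutrient environments alone cannot predict TNF-α-driven inflammation.
This is asserted in tests as: the spread of ω_TNF-α across the three
nutrient presets is smaller than the spread of ω_IL1β.

## Agent-based model (`abm3d`)

* 4,000 agents of 10 µm diameter in a 1 mm³ cube (≈0.2 % volume fraction),
  uniform rejection sampling with center distance ≥ 10 µm; hard walls, no
  periodicity, static positions (no motility, division, death).
* 15 nucleation agents per cytokine drawn without replacement from a
  single 30-agent sample; cluster growth adds, one at a time, the
  non-inflamed agent with the globally minimal Euclidean distance to the
  cytokine's marked set (all 15 clusters grow as one marked set), until
  round(pct×n) agents are marked.  Ties break on the lowest agent id so
  runs are exactly reproducible.
* The two growth processes are independent; double-positivity is the set
  intersection.  Note that because both processes act on the *same* random
  geometry and greedy growth favours locally dense neighbourhoods, the
  double-positive fraction exceeds what independent random marking would
  give — a structural property of the growth rule, not a bug.
* Replicates: seeds base…base+n−1, descriptive mean, SD and Student-t 95 %
  CI per state class.  Per-cytokine totals are deterministic given the
  percentages; only the overlap varies across runs.

## Problem sizes and verification

The default test suite runs the placement/growth invariants at 400 agents
with 3 seeds per cytokine (all invariants are scale-free) and the
exhaustive O(n²) oracles — minimum-distance scan and brute-force
nearest-neighbour growth — at the same scale; conservation, determinism
and replicate statistics are additionally verified at the full 4,000-agent
scale with 10 replicates.  The network equation is cross-checked against
an independent transcription on 10,000 randomized systems.  Dose–response
fits are compared against a grid-search oracle over the normalized
logistic family.

## Known limitations

* No spatial cytokine diffusion; cluster growth is a phenomenological
  stand-in for paracrine spread.
* No temporal ECM accumulation or feedback from predicted activities onto
  the environment (intended future coupling to finite-element transport
  models).
* The shipped dose–response anchors are package defaults, not published
  measurements; quantitative ω values inherit that uncertainty, which is
  why the package's committed claims are orderings and calibration
  constants, not profile point values.
* Synthetic fixtures (`generate_fixtures`) emulate table structure and
  monotone anchors with known ground truth; they do not emulate biological
  noise in ε beyond a log-uniform spread, so passing recovery tests shows
  correctness of the calibration arithmetic, not robustness to assay
  variability.
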