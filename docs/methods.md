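# Methods

## Limiting-resource model

A cell enters a poor environment carrying a pool *Z*₀ of a limiting resource
(arbitrary units; biologically, the vacuolar zinc store). Division is
impossible once the pool falls below a critical level *Z*c > 0, and each
division consumes Δ*Z* ≥ 0. Under symmetric segregation the pool halves
each cycle: division stops after ⌊log₂(*Z*₀/*Z*c)⌋ cycles and population
growth is bounded by *N*ₛ = *Z*₀/*Z*c. Under full maternal retention the
progenitor supports *N*ₐₛ = (*Z*₀ − *Z*c)/Δ*Z* daughters, unbounded when
Δ*Z* = 0. `resource_model` exposes both the continuous values and the
floor-based discrete counts; the discrete counts are validated against
brute-force depletion loops. Strategy comparison uses the continuous forms
with relative tolerance 1e-9, so float noise near the crossing point
Δ*Z* = (*Z*₀ − *Z*c)·*Z*c/*Z*₀ cannot flip the answer.

**Division feasibility convention.** Throughout the package a cell commits
to a division only if the pool it retains afterwards stays at or above
*Z*c (`f·Z − ΔZ ≥ Zc`). This "completion" rule — rather than requiring
`Z ≥ Zc` before the cycle — is what makes the discrete counts equal
⌊(*Z*₀−*Z*c)/Δ*Z*⌋ and ⌊log₂(*Z*₀/*Z*c)⌋ exactly, without off-by-one
boundary cases, and the simulator uses the identical rule so the two layers
agree to machine precision.

## Population simulator

Each cell carries a resource pool, a size (volume proxy, arbitrary units)
and a lineage position. Cells do not interact; each lineage evolves
independently.

* **Cycle timing.** Durations are lognormal with mean `mean_cycle_time` and
  CV `cycle_cv` (default 0.15; lognormal guarantees positivity and the
  mean/CV parametrization is exact). The mean is scaled by
  `max(1, K/Z)^γ` where *Z* is the pool at cycle start: cells whose pool
  falls below the sufficiency scale *K* slow down. *K* defaults to *Z*c so
  the coupling is inert in regimes whose dividers stay above the critical
  level (their cycle time is observed to be constant); the *whi5* preset
  raises *K* to 6 resource units so progressive dilution under symmetric
  splitting lengthens every successive cycle.
* **Start rule.** A newborn must grow to `critical_size` before completing
  its first division. Growth is linear at a rate such that a half-critical
  newborn reaches the threshold in `growth_time_fraction` (default 0.6) of
  a mean cycle, and requires the pool to be at least *Z*c — a
  resource-starved daughter neither grows nor divides, so arrest is doubly
  enforced. Mothers stay at the critical size (buds are new growth).
* **Partition.** At a division at time *t* the mother keeps `f·Z − ΔZ`
  (clipped at 0) and the daughter receives `(1−f)·Z`; before `shift_time`
  the split is forced to 0.5 (rich-medium behaviour). Conservation
  (`mother + daughter + ΔZ = pool`) holds exactly and is asserted by
  `LineageTree.validate`. Daughter birth size is
  `daughter_size_fraction × mother size` (0.5 pre-shift).
* **Regeneration.** Between divisions the pool refills linearly at a
  pre-shift and a post-shift rate, capped at `storage_max`. Rich media use
  1 unit/min (pool is effectively always full); the direct-shift low-metal
  preset uses 0 after the shift (stores cannot be replenished).
* **Determinism.** Every cell's RNG stream is seeded by the master seed plus
  its lineage position (founder index, then the division index at each
  ancestor), so identical configurations give bit-identical trees and
  extending the horizon or adding founders never perturbs existing draws.

### Regime presets

All presets share *Z*₀ = 10, *Z*c = 1 (resource units) and a critical size
of 1 (size units) unless noted. The retention fraction *f* and Δ*Z* jointly
set how many divisions a founder completes: with *f* < 1 the mother also
sheds `(1−f)·Z` per division, so Δ*Z* is tuned to the observed division
count rather than to (*Z*₀−*Z*c)/count.

| preset | cycle (min) | f | regen/min | ΔZ | daughter size | notes |
|---|---|---|---|---|---|---|
| `rich` | 103 | 0.5 | 1.0 | 0.1 | 0.5 | exponential growth |
| `low_metal` | 120 | 0.98 | 0 | 0.95 | 0.65 | direct shift; founders divide exactly 8× |
| `low_metal_preadapted` | 150 | 0.98 | 0 | 1.9 | 0.65 | 4 divisions per founder |
| `whi5` | 120 | 0.5 | 0 | 0.1 | 0.5 | critical size ×0.7; K = 6 → lengthening cycles |
| `whi5_rich` | 103 | 0.5 | 1.0 | 0.1 | 0.5 | rich dynamics, critical size ×0.7 |
| `semi_low` | 130 | 0.5 | 0.15 | 0.1 | 0.5 | slower but exponential |
| `vac17_rich` | 103 | 1.0 | 1.0 | 0.1 | 0.5 | no bud transport; daughters regenerate vacuoles |
| `vac17_semi_low` | 180 | 1.0 | 0 | 1.125 | 0.65 | linear growth at intermediate zinc |
| `zrc1cot1` | 140 | 0.98 | 0 | 0.95 | 0.65 | *Z*₀ = 5.5: smaller store, earlier arrest |

The *whi5* preset carries its own Δ*Z* (0.1): under symmetric splitting the
dominant depletion is dilution, and a loss as large as the low-metal preset's
would arrest the lineage after a single division, contrary to the observed
behaviour (most cells divide, cycles lengthen, final population below wild
type). The *whi5* vs wild-type comparison is therefore structural —
8 cells/founder (3 symmetric rounds) vs 9 cells/founder (8 sequential
daughters plus the mother) — and holds for every seed.

**Stress events** (`apply_stress`) act on all cells alive during a stress
window: each implodes independently with its class probability (mothers
8% vs daughters 30% for the osmotic preset; rapamycin inverts the
asymmetry), at a time uniform within the window. Divisions and descendants
dated after an implosion are pruned. Survivors of zinc-shock/rapamycin are
stamped with a recovery time (stress end + class delay); resumed cycling
after recovery is bookkeeping only and is not re-simulated, since no
downstream statistic depends on post-recovery divisions.

## Synthetic microscopy

Cells are rendered as non-overlapping discs with pixel area proportional to
size (220 px² per size unit; rasterization keeps the labelled area within
5% of the target at the radii used). Daughters are placed at the first free
angular position clockwise from the mother's previous bud site, spiralling
outward when a ring is full; founders sit on a grid sized from the largest
colony; an unplaceable cell raises an error naming the frame. The layout is
static, mimicking a monolayer flow cell. Four channels per frame (default
6-min interval, frame 0 at t = 0): ground-truth label mask; bright-field
proxy (uniform body intensity 600 over background 100); nuclear marker
(disc at each cell centre, 3000 counts — the daughter's switches on at
nuclear separation, 12 min before cytokinesis by default); bud-neck marker
(2000-count spot at the mother-bud neck from bud emergence, dropping
five-fold at birth, with a short residual before disappearing). Gaussian
pixel noise of configurable SD is added per channel; rendering is
deterministic given tree, parameters and seed.

## Lineage reconstruction

The tracker mirrors an end-anchored design: segment the **last** frame,
propagate every segment **backwards**, so no track can exist that is absent
from the final image. Per frame, the bright-field proxy is smoothed
(σ = 1 px), thresholded (Otsu), and split into cells by watershed on the
distance transform seeded at nuclear-marker peaks. The seed threshold is
`max(bg mean + 5·bg SD, 0.3 × peak signal)`; the relative floor prevents
smoothing tails of adjacent nuclei from bridging into one seed on low-noise
images. A pre-separation bud has no nuclear seed and therefore remains part
of its mother's region — exactly the desired semantics.

Backward assignment is by maximal overlap; when several tracks claim the
same earlier region the larger intersection-over-union wins, ties broken by
smaller centroid displacement, then lower label (deterministic). Losers are
recorded as having merged into the winner: the merge identifies the mother
and bounds the daughter's first existence. Nuclear separation is the first
frame the daughter's mean nuclear intensity clears the detection threshold;
birth is the largest fractional drop (≥ 50% after 3-frame median smoothing)
of the neck-probe intensity within 30 min after separation (the window is
one-sided by default, configurable to symmetric). Events without a
qualifying drop are kept but flagged and excluded from the tree. Sizes are
segmented areas in pixels; no volume conversion is attempted.

On noiseless renders the reconstruction is exact (isomorphic tree, births
within one frame, classification error zero — tested for low-metal, rich
and *whi5* trees). At pixel noise up to 20% of the body signal,
classification remains ≥ 95% accurate although birth times may shift by a
few frames.

## Analysis conventions

* Exponential fits: OLS on log₂(count) vs time (variance-stabilizing for
  count data); τ = 1/slope; r² on the log scale. Zero-count samples shrink
  the window to the longest positive run (logged); an all-zero window is an
  error; a non-positive slope flags τ undefined.
* Linear fits: OLS on raw counts; the "linear part" is auto-selected as the
  longest suffix after a 120-min post-shift transition whose r² ≥ 0.98.
* `classify_growth_mode` compares the two r² on one common window; a margin
  below 0.01 (or a flat/degenerate series) is `ambiguous`.
* Cycle tables aggregate successive division-time differences per post-shift
  division index; colonies are pooled by summing counts at matched times.
* Size gaps use medians (robust to lognormal skew). Age correction evaluates
  every cell's growth law at the age of the youngest cell alive at the
  snapshot, i.e. as if all cells were born together; on a fixture where both
  classes share one growth law this sends the gap to zero while the raw gap
  stays positive.
* Vacuole fractions are reported on the pre-loss pool (mother *f*, daughter
  1−*f*; they sum to one per division); divisions with a zero pool are
  excluded and counted.
* Stress outcomes report per-class implosion fractions with binomial
  standard errors; survivors count as recovered, with recovery delays where
  the stress defines them.

## Problem sizes

The test-suite and the acceptance script use: 8 pooled colonies × 10 h for
exponential-fit recovery; 30 founders run to arrest (25 h) for division
counts and cycle times; 20 seed pairs for the wild-type vs *whi5* final-size
ordering; 500 cells per class for stress fractions; and renders of 8–30-cell
trees for round-trip checks. These sizes put the Monte-Carlo standard errors
well inside the assertion tolerances (e.g. SE of the mean cycle time at 210
gaps is ≈ 1.2 min against a 12-min tolerance) while keeping any single test
in seconds.

## Limitations

The simulator omits spatial crowding, replicative aging, explicit
transporter kinetics and mechanistic pre-adaptation (the pre-adapted regime
is a parameter preset). Vacuole regeneration rates are order-of-magnitude
choices: media differences are encoded in the regeneration and retention
parameters, not in transport biochemistry. The renderer is deliberately
non-photorealistic (no photobleaching, focus drift or bright-field optics),
so passing round-trip tests demonstrates correctness of the tracking logic
on clean, cue-complete data — not robustness to real-microscopy artifacts.
Real data would add segmentation errors, drift and uneven illumination that
this benchmark does not model.
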